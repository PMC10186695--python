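"""Contact-matrix data model, I/O, normalisation and comparison statistics.

The in-memory representation is one dense symmetric ``float64`` matrix per
chromosome (only intra-chromosomal contacts are modelled).  At the bin counts
this package targets (a few thousand bins per chromosome) dense storage is
both simpler and faster than sparse.

Normalisation states move strictly forward:

``raw`` -> ``depth`` (pair scaled to the smaller total) -> ``balanced``
(Knight-Ruiz) -> ``oe`` (observed/expected per distance).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import BinnedGenome

log = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "read_contacts",
    "mask_low_coverage",
    "depth_normalize",
    "kr_balance",
    "oe_transform",
    "ps_curve",
    "log2_ratio_map",
    "scc",
    "window_similarity_z",
    "promoter_distal_change",
]


class ContactMatrix:
    """Per-chromosome symmetric contact matrices with a validity mask.

    Attributes
    ----------
    grid : BinnedGenome
    data : dict of chrom -> (n, n) float array, symmetric, nonnegative
        (O/E matrices may contain NaN at masked bins).
    mask : dict of chrom -> bool array, True where the bin is valid.
    normalization_state : {"raw", "depth", "balanced", "oe"}
    balance_weights : dict of chrom -> per-bin KR weight vector (after KR).
    """

    def __init__(self, grid: BinnedGenome, data: dict[str, np.ndarray],
                 mask: dict[str, np.ndarray] | None = None,
                 normalization_state: str = "raw"):
        self.grid = grid
        self.data = {}
        for c in grid.chroms:
            n = grid.n_bins(c)
            m = np.asarray(data.get(c, np.zeros((n, n))), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"matrix shape mismatch on {c}")
            self.data[c] = m
        if mask is None:
            mask = {c: np.ones(grid.n_bins(c), dtype=bool) for c in grid.chroms}
        self.mask = {c: np.asarray(mask[c], dtype=bool) for c in grid.chroms}
        self.normalization_state = normalization_state
        self.balance_weights: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    def copy(self) -> "ContactMatrix":
        out = ContactMatrix(self.grid, {c: m.copy() for c, m in self.data.items()},
                            {c: m.copy() for c, m in self.mask.items()},
                            self.normalization_state)
        out.balance_weights = {c: w.copy() for c, w in self.balance_weights.items()}
        return out

    def total(self) -> float:
        """Total contact count over all chromosomes (full matrix sum / 2
        plus the diagonal, i.e. the number of contact pairs)."""
        tot = 0.0
        for c, m in self.data.items():
            v = np.nan_to_num(m)
            tot += (v.sum() + np.trace(v)) / 2.0
        return tot

    def scale(self, factor: float) -> "ContactMatrix":
        out = self.copy()
        for c in out.data:
            out.data[c] *= factor
        return out

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Aggregate counts into ``factor``-times-larger bins (raw/depth only)."""
        if self.normalization_state not in ("raw", "depth"):
            raise ValueError("coarsen counts before balancing")
        grid2 = self.grid.coarsen(factor)
        data2, mask2 = {}, {}
        for c in self.grid.chroms:
            n, n2 = self.grid.n_bins(c), grid2.n_bins(c)
            pad = n2 * factor - n
            m = np.pad(np.nan_to_num(self.data[c]), ((0, pad), (0, pad)))
            m = m.reshape(n2, factor, n2, factor).sum(axis=(1, 3))
            data2[c] = m
            mask2[c] = np.pad(self.mask[c], (0, pad), constant_values=False) \
                .reshape(n2, factor).any(axis=1)
        out = ContactMatrix(grid2, data2, mask2, self.normalization_state)
        return out

    # -- I/O -----------------------------------------------------------
    def write_coo(self, path) -> None:
        """Upper-triangle COO text: chrom, bin_i, bin_j, count."""
        with open(path, "w") as fh:
            for c in self.grid.chroms:
                m = self.data[c]
                iu, ju = np.nonzero(np.triu(np.nan_to_num(m)))
                for i, j in zip(iu, ju):
                    fh.write(f"{c}\t{i}\t{j}\t{m[i, j]:.10g}\n")

    def write_dense_tsv(self, path, chrom: str) -> None:
        np.savetxt(path, self.data[chrom], delimiter="\t", fmt="%.6g")


def read_contacts(path, grid: BinnedGenome) -> ContactMatrix:
    """Build a raw ContactMatrix from a pair list or COO text file.

    Accepted formats (tab/space separated, ``#`` comments skipped):

    * pairs: ``chrom pos1 pos2`` or ``chrom1 pos1 chrom2 pos2``
    * COO:   ``chrom bin_i bin_j count`` (distinguished by 4 columns whose
      second/third fields are bin indices; auto-detected by header sniffing
      is deliberately avoided — COO rows always have 4 fields with the count
      last, pair rows either 3 fields or 4 with a chromosome name third).

    Inter-chromosomal pairs are tallied and discarded; unknown chromosomes
    and malformed lines raise.
    """
    data = {c: np.zeros((grid.n_bins(c), grid.n_bins(c))) for c in grid.chroms}
    inter = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) == 3:
                    chrom, p1, p2 = parts[0], int(parts[1]), int(parts[2])
                    _add_pair(data, grid, chrom, p1, p2, 1.0, ln)
                elif len(parts) == 4:
                    if parts[2] in grid.chrom_sizes:  # chrom1 pos1 chrom2 pos2
                        c1, p1, c2, p2 = parts[0], int(parts[1]), parts[2], int(parts[3])
                        if c1 != c2:
                            inter += 1
                            continue
                        _add_pair(data, grid, c1, p1, p2, 1.0, ln)
                    else:  # COO: chrom bin_i bin_j count
                        chrom, bi, bj = parts[0], int(parts[1]), int(parts[2])
                        cnt = float(parts[3])
                        if chrom not in data:
                            raise ValueError(f"unknown chromosome {chrom!r}")
                        data[chrom][bi, bj] += cnt
                        if bi != bj:
                            data[chrom][bj, bi] += cnt
                else:
                    raise ValueError("expected 3 or 4 fields")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {ln}: {exc}") from None
    if inter:
        log.info("read_contacts: discarded %d inter-chromosomal pairs", inter)
    m = ContactMatrix(grid, data)
    m.n_interchromosomal_discarded = inter
    return m


def _add_pair(data, grid, chrom, p1, p2, weight, ln):
    if chrom not in data:
        raise ValueError(f"unknown chromosome {chrom!r}")
    b1 = grid.bin_index(chrom, p1)
    b2 = grid.bin_index(chrom, p2)
    data[chrom][b1, b2] += weight
    if b1 != b2:
        data[chrom][b2, b1] += weight


# ----------------------------------------------------------------------
def mask_low_coverage(matrix: ContactMatrix, min_fraction: float = 0.1
                      ) -> ContactMatrix:
    """Mask bins whose marginal sum falls below ``min_fraction`` times the
    median positive marginal (per chromosome).  Masked rows/columns are
    zeroed.  The rule is scale-free."""
    out = matrix.copy()
    any_valid = False
    for c in out.grid.chroms:
        m = out.data[c]
        marg = np.nan_to_num(m).sum(axis=1)
        pos = marg[marg > 0]
        if len(pos) == 0:
            out.mask[c][:] = False
            continue
        thresh = min_fraction * np.median(pos)
        keep = marg >= thresh
        out.mask[c] = keep
        m[~keep, :] = 0.0
        m[:, ~keep] = 0.0
        any_valid = any_valid or keep.any()
    if not any_valid:
        raise ValueError("all bins masked by coverage filter")
    return out


def depth_normalize(matrix_a: ContactMatrix, matrix_b: ContactMatrix
                    ) -> tuple[ContactMatrix, ContactMatrix]:
    """Scale both matrices to the smaller total contact count."""
    if not matrix_a.grid.same_grid(matrix_b.grid):
        raise ValueError("grids differ")
    ta, tb = matrix_a.total(), matrix_b.total()
    if ta <= 0 or tb <= 0:
        raise ValueError("zero-total matrix cannot be depth normalized")
    target = min(ta, tb)
    out_a, out_b = matrix_a.scale(target / ta), matrix_b.scale(target / tb)
    out_a.normalization_state = out_b.normalization_state = "depth"
    return out_a, out_b


# -- Knight-Ruiz balancing --------------------------------------------
def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration: returns positive x with
    diag(x) A diag(x) having unit row sums.  ``A`` must be symmetric,
    nonnegative, with strictly positive row sums."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    n_outer = 0
    while rout > rt:
        n_outer += 1
        if n_outer > max_iter:
            raise RuntimeError(
                f"KR did not converge: residual {math.sqrt(rout):.3e} "
                f"after {max_iter} outer iterations")
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = math.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def kr_balance(matrix: ContactMatrix, tol: float = 1e-6,
               max_iter: int = 1000) -> ContactMatrix:
    """Knight-Ruiz balancing of every chromosome's unmasked submatrix.

    The balanced matrix is rescaled to preserve the chromosome's original
    total so depth comparability survives balancing; the KR weight vectors
    are stored in ``balance_weights``.  Masked bins stay zero and are
    excluded from (not zero-imputed into) the iteration.
    """
    out = matrix.copy()
    for c in out.grid.chroms:
        keep = out.mask[c].copy()
        m = out.data[c]
        # bins with zero marginal cannot be balanced: mask them too
        marg = np.nan_to_num(m).sum(axis=1)
        keep &= marg > 0
        out.mask[c] = keep
        idx = np.flatnonzero(keep)
        if len(idx) < 2:
            out.data[c][:] = 0.0
            continue
        sub = m[np.ix_(idx, idx)]
        x = _kr_vector(sub, tol=tol, max_iter=max_iter)
        bal = sub * np.outer(x, x)
        bal *= sub.sum() / bal.sum()  # preserve total
        new = np.zeros_like(m)
        new[np.ix_(idx, idx)] = bal
        out.data[c] = new
        w = np.full(len(keep), np.nan)
        w[idx] = x
        out.balance_weights[c] = w
    out.normalization_state = "balanced"
    return out


def oe_transform(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected: each diagonal divided by the mean of its unmasked
    entries.  Masked bins become NaN; empty diagonals stay NaN."""
    out = matrix.copy()
    for c in out.grid.chroms:
        m = out.data[c].copy()
        keep = out.mask[c]
        n = m.shape[0]
        valid2d = np.outer(keep, keep)
        oe = np.full_like(m, np.nan)
        for d in range(n):
            diag = np.diagonal(m, offset=d)
            vmask = np.diagonal(valid2d, offset=d)
            if not vmask.any():
                continue
            mu = diag[vmask].mean()
            if mu <= 0:
                continue
            vals = np.where(vmask, diag / mu, np.nan)
            ii = np.arange(n - d)
            oe[ii, ii + d] = vals
            oe[ii + d, ii] = vals
        out.data[c] = oe
    out.normalization_state = "oe"
    return out


def ps_curve(matrix: ContactMatrix, n_log_bins: int = 30) -> pd.DataFrame:
    """Contact probability versus genomic distance P(s).

    Mean unmasked contact per log-spaced distance bin, pooled over
    chromosomes.  Rows with no contributing pairs are omitted.
    """
    bs = matrix.grid.bin_size
    max_d = max(matrix.grid.n_bins(c) for c in matrix.grid.chroms)
    edges = np.unique(np.geomspace(1, max_d, n_log_bins + 1).astype(int))
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    for c in matrix.grid.chroms:
        m = np.nan_to_num(matrix.data[c])
        keep = matrix.mask[c]
        n = m.shape[0]
        for k in range(len(edges) - 1):
            for d in range(edges[k], min(edges[k + 1], n)):
                diag = np.diagonal(m, offset=d)
                vmask = keep[:-d] & keep[d:]
                sums[k] += diag[vmask].sum()
                counts[k] += vmask.sum()
    rows = []
    for k in range(len(edges) - 1):
        if counts[k] == 0:
            continue
        # geometric midpoint of the distance bin, in bp
        mid = math.sqrt(edges[k] * max(edges[k + 1] - 1, edges[k])) * bs
        rows.append((mid, sums[k] / counts[k], int(counts[k])))
    return pd.DataFrame(rows, columns=["distance_bp", "mean_contact", "n_pairs"])


def fit_decay_exponent(curve: pd.DataFrame,
                       min_bp: float | None = None,
                       max_bp: float | None = None) -> float:
    """Log-log slope of a P(s) curve (returned as the slope; a power law
    P(s) ~ s^-a gives slope -a)."""
    sel = curve[curve["mean_contact"] > 0]
    if min_bp is not None:
        sel = sel[sel["distance_bp"] >= min_bp]
    if max_bp is not None:
        sel = sel[sel["distance_bp"] <= max_bp]
    slope, _ = np.polyfit(np.log10(sel["distance_bp"]),
                          np.log10(sel["mean_contact"]), 1)
    return float(slope)


def log2_ratio_map(matrix_a: ContactMatrix, matrix_b: ContactMatrix,
                   pseudocount: float = 1.0) -> dict[str, np.ndarray]:
    """Per-chromosome ``log2((a + pc) / (b + pc))`` differential maps.

    Antisymmetric under swapping the inputs; bins masked in either input
    are NaN.  Inputs must be depth-normalised on the same grid.
    """
    if not matrix_a.grid.same_grid(matrix_b.grid):
        raise ValueError("grids differ")
    out = {}
    for c in matrix_a.grid.chroms:
        a, b = matrix_a.data[c], matrix_b.data[c]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2((a + pseudocount) / (b + pseudocount))
        keep = matrix_a.mask[c] & matrix_b.mask[c]
        r[~keep, :] = np.nan
        r[:, ~keep] = np.nan
        out[c] = r
    return out


# -- stratum-adjusted correlation (HiCRep-style) -----------------------
def scc(matrix_a: ContactMatrix, matrix_b: ContactMatrix,
        max_distance: int = 5_000_000, smooth_h: int = 1) -> float:
    """Stratum-adjusted correlation coefficient.

    Per-distance-stratum Pearson correlations combined with weights
    ``n_k * sd_a,k * sd_b,k`` (pair count times the geometric mean of the
    stratum variances), after optional 2D mean-filter smoothing of radius
    ``smooth_h`` bins.  Both matrices must share grid and normalisation
    state.
    """
    if not matrix_a.grid.same_grid(matrix_b.grid):
        raise ValueError("grids differ")
    bs = matrix_a.grid.bin_size
    max_d = max(1, int(max_distance // bs))
    num = den = 0.0
    n_strata = 0
    for c in matrix_a.grid.chroms:
        a = np.nan_to_num(matrix_a.data[c])
        b = np.nan_to_num(matrix_b.data[c])
        if smooth_h > 0:
            size = 2 * smooth_h + 1
            a = ndimage.uniform_filter(a, size=size, mode="constant")
            b = ndimage.uniform_filter(b, size=size, mode="constant")
        keep = matrix_a.mask[c] & matrix_b.mask[c]
        n = a.shape[0]
        for d in range(1, min(max_d + 1, n)):
            va = np.diagonal(a, offset=d)
            vb = np.diagonal(b, offset=d)
            vmask = keep[:-d] & keep[d:]
            if vmask.sum() < 3:
                continue
            xa, xb = va[vmask], vb[vmask]
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            w = len(xa) * sa * sb
            num += w * r
            den += w
            n_strata += 1
    if n_strata < 2:
        raise ValueError("fewer than 2 usable distance strata")
    return float(num / den)


# -- windowed structural similarity (CHESS-style) ----------------------
def _ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Structural-similarity index (luminance * contrast * structure) between
    two equal-shape arrays, with standard stabilising constants derived from
    the joint dynamic range."""
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() < 4:
        return np.nan
    x, y = x[finite], y[finite]
    L = max(np.max(np.concatenate([x, y])) - np.min(np.concatenate([x, y])), 1e-12)
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def window_similarity_z(matrix_a: ContactMatrix, matrix_b: ContactMatrix,
                        window_bp: int = 500_000, step_bp: int = 5_000
                        ) -> pd.DataFrame:
    """Sliding-window structural similarity between two Hi-C maps.

    For each on-diagonal window the SSIM between the two log2 O/E
    submatrices is computed; z-scores are taken per chromosome (lower z =
    more different).  Returns a table (chrom, start, end, ssim, z).
    """
    if not matrix_a.grid.same_grid(matrix_b.grid):
        raise ValueError("grids differ")
    bs = matrix_a.grid.bin_size
    wb, sb = int(window_bp // bs), max(1, int(step_bp // bs))
    if wb < 3:
        raise ValueError("window must span at least 3 bins")
    oe_a = matrix_a if matrix_a.normalization_state == "oe" else oe_transform(matrix_a)
    oe_b = matrix_b if matrix_b.normalization_state == "oe" else oe_transform(matrix_b)
    rows = []
    for c in matrix_a.grid.chroms:
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.log2(oe_a.data[c])
            lb = np.log2(oe_b.data[c])
        n = la.shape[0]
        ssims, starts = [], []
        for s in range(0, n - wb + 1, sb):
            v = _ssim(la[s:s + wb, s:s + wb], lb[s:s + wb, s:s + wb])
            ssims.append(v)
            starts.append(s)
        ssims = np.asarray(ssims, dtype=float)
        finite = np.isfinite(ssims)
        z = np.full_like(ssims, np.nan)
        if finite.sum() >= 2:
            sd = ssims[finite].std()
            mu = ssims[finite].mean()
            z[finite] = 0.0 if sd == 0 else (ssims[finite] - mu) / sd
        elif finite.sum() == 1:
            z[finite] = 0.0
        for s, v, zz in zip(starts, ssims, z):
            rows.append((c, s * bs, min((s + wb) * bs, matrix_a.grid.chrom_sizes[c]),
                         v, zz))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ssim", "z"])
    df.attrs["z_normalization"] = "per-chromosome"
    return df


# -- promoter-distal contact change ------------------------------------
DEFAULT_DISTANCE_CLASSES = [
    (20_000, 50_000), (50_000, 100_000), (100_000, 500_000),
    (500_000, 1_000_000), (1_000_000, None),
]


def promoter_distal_change(matrix_cold: ContactMatrix,
                           matrix_normal: ContactMatrix,
                           genes: pd.DataFrame,
                           distance_classes=None,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Mean log2 change of promoter-to-distal contact per distance band.

    The promoter is the 2 kb region upstream of the TSS (strand aware); its
    bin is the bin of the promoter midpoint.  For each gene set (all / up /
    down DEGs) and half-open distance band [lo, hi) the statistic is the
    mean over genes of ``log2((sum_cold + pc) / (sum_normal + pc))`` where
    the sums run over contacts between the promoter bin and every bin whose
    centre lies in the band (both directions pooled).
    """
    if distance_classes is None:
        distance_classes = DEFAULT_DISTANCE_CLASSES
    grid = matrix_cold.grid
    if not grid.same_grid(matrix_normal.grid):
        raise ValueError("grids differ")
    bs = grid.bin_size
    skipped = 0
    per_gene: dict[int, list[list[float]]] = {}
    gene_sets = {"all": [], "up": [], "down": []}
    values = {k: [[] for _ in distance_classes] for k in gene_sets}
    for row in genes.itertuples(index=False):
        if row.chrom not in grid.chrom_sizes:
            skipped += 1
            continue
        tss = int(row.start) if row.strand == "+" else int(row.end)
        pmid = tss - 1000 if row.strand == "+" else tss + 1000
        pmid = min(max(pmid, 0), grid.chrom_sizes[row.chrom] - 1)
        pbin = grid.bin_index(row.chrom, pmid)
        n = grid.n_bins(row.chrom)
        dist = np.abs(np.arange(n) - pbin) * bs
        rc = matrix_cold.data[row.chrom][pbin]
        rn = matrix_normal.data[row.chrom][pbin]
        keep = matrix_cold.mask[row.chrom] & matrix_normal.mask[row.chrom]
        for k, (lo, hi) in enumerate(distance_classes):
            band = (dist >= lo) & keep
            if hi is not None:
                band &= dist < hi
            if not band.any():
                continue
            sc = np.nansum(rc[band])
            sn = np.nansum(rn[band])
            v = math.log2((sc + pseudocount) / (sn + pseudocount))
            values["all"][k].append(v)
            label = getattr(row, "deg_label", "ns")
            if label in ("up", "down"):
                values[label][k].append(v)
    rows = []
    for gset, per_class in values.items():
        for k, (lo, hi) in enumerate(distance_classes):
            name = _class_name(lo, hi)
            vals = per_class[k]
            rows.append((gset, name,
                         float(np.mean(vals)) if vals else np.nan, len(vals)))
    df = pd.DataFrame(rows, columns=["gene_set", "distance_class",
                                     "mean_log2_change", "n_genes"])
    df.attrs["skipped_genes"] = skipped
    return df


def _class_name(lo, hi):
    def fmt(x):
        if x >= 1_000_000 and x % 1_000_000 == 0:
            return f"{x // 1_000_000}Mb"
        return f"{x // 1000}kb"
    return f">{fmt(lo)}" if hi is None else f"{fmt(lo)}-{fmt(hi)}"
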