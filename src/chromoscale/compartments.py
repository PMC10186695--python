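"""A/B compartment calling, sign orientation, switches and saddle strength.

Compartments are called per chromosome from the leading eigenvector (PC1)
of the Pearson-correlation matrix of the observed/expected contact map,
conventionally at 50 kb resolution.  The sign of PC1 is arbitrary per
chromosome and is oriented so that it correlates positively with an
active-chromatin track (H3K27ac); after orientation, positive PC1 = A
(active), negative = B (inactive).

Compartment strength follows the saddle-plot statistic
``ln(AA * BB / AB^2)`` where AA/BB/AB are mean O/E contact levels between
the strongest-A and strongest-B percentile classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contact import ContactMatrix, oe_transform
from .genome import BinnedGenome, SignalTrack

__all__ = [
    "CompartmentProfile",
    "SaddleSummary",
    "compartment_eigenvector",
    "orient_sign",
    "compartment_fractions",
    "classify_switches",
    "saddle",
    "compartment_gene_summary",
]


@dataclass
class CompartmentProfile:
    """Per-bin PC1 values and A/B labels (NaN PC1 = masked)."""

    grid: BinnedGenome
    pc1: dict[str, np.ndarray]
    orientation_evidence: dict[str, float] = field(default_factory=dict)
    oriented: bool = False

    def label(self, chrom: str) -> np.ndarray:
        """'A' where pc1 > 0, 'B' where pc1 < 0, '.' where masked/zero."""
        v = self.pc1[chrom]
        out = np.full(len(v), ".", dtype="<U1")
        out[v > 0] = "A"
        out[v < 0] = "B"
        return out

    def concat_pc1(self) -> np.ndarray:
        return np.concatenate([self.pc1[c] for c in self.grid.chroms])

    def to_bedgraph(self, path) -> None:
        SignalTrack(self.grid, {c: self.pc1[c] for c in self.grid.chroms},
                    name="pc1").to_bedgraph(path)

    def intervals(self) -> pd.DataFrame:
        """Maximal runs of same-label bins as BED-like intervals (no
        smoothing; single-bin islands kept)."""
        rows = []
        for c in self.grid.chroms:
            lab = self.label(c)
            b = 0
            while b < len(lab):
                e = b
                while e < len(lab) and lab[e] == lab[b]:
                    e += 1
                if lab[b] != ".":
                    rows.append((c, self.grid.bin_start(c, b),
                                 self.grid.bin_end(c, e - 1), lab[b]))
                b = e
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


@dataclass
class SaddleSummary:
    percentile_edges: np.ndarray
    matrix: np.ndarray            # mean O/E per PC1-percentile class pair
    aa: float
    bb: float
    ab: float
    strength: float


def compartment_eigenvector(matrix: ContactMatrix,
                            min_unmasked: int = 20) -> CompartmentProfile:
    """Unoriented PC1 of the per-chromosome O/E correlation matrix.

    The balanced input is O/E-transformed if it is not already; PC1 is the
    leading eigenvector of ``corrcoef(O/E)`` over unmasked bins, unit
    normalised then scaled by sqrt(leading eigenvalue).  Masked bins are
    NaN.  An (almost) degenerate leading eigen-gap triggers a warning but
    still returns.
    """
    oe = matrix if matrix.normalization_state == "oe" else oe_transform(matrix)
    pc1 = {}
    for c in oe.grid.chroms:
        n = oe.grid.n_bins(c)
        out = np.full(n, np.nan)
        idx = np.flatnonzero(oe.mask[c])
        if len(idx) < min_unmasked:
            warnings.warn(f"{c}: fewer than {min_unmasked} unmasked bins; "
                          "compartments not called")
            pc1[c] = out
            continue
        sub = oe.data[c][np.ix_(idx, idx)]
        sub = np.nan_to_num(sub, nan=1.0)
        sd = sub.std(axis=1)
        good = sd > 0
        if good.sum() < min_unmasked:
            warnings.warn(f"{c}: degenerate (constant) O/E matrix")
            pc1[c] = out
            continue
        idx = idx[good]
        sub = sub[np.ix_(good, good)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        vals, vecs = np.linalg.eigh(corr)
        lead, second = vals[-1], vals[-2]
        if lead - second < 1e-8:
            warnings.warn(f"{c}: degenerate leading eigenvalue "
                          f"(gap {lead - second:.2e})")
        v = vecs[:, -1]
        v = v / np.linalg.norm(v) * np.sqrt(max(lead, 0.0))
        out[idx] = v
        pc1[c] = out
    return CompartmentProfile(oe.grid, pc1)


def orient_sign(profile: CompartmentProfile, active_track: SignalTrack,
                fallback_track: SignalTrack | None = None
                ) -> CompartmentProfile:
    """Orient PC1 per chromosome so it correlates positively with an
    active-chromatin track; falls back to a secondary track (e.g. gene
    density) when the primary has no variance on a chromosome."""
    pc1 = {}
    evidence = {}
    for c in profile.grid.chroms:
        v = profile.pc1[c].copy()
        finite = np.isfinite(v)
        r = np.nan
        for track in (active_track, fallback_track):
            if track is None:
                continue
            t = track.values[c]
            ok = finite & np.isfinite(t)
            if ok.sum() >= 3 and np.std(t[ok]) > 0 and np.std(v[ok]) > 0:
                r = float(np.corrcoef(v[ok], t[ok])[0, 1])
                break
        if np.isnan(r):
            if finite.any():
                raise ValueError(
                    f"{c}: no usable orientation track (zero variance)")
            pc1[c] = v
            evidence[c] = np.nan
            continue
        if r < 0:
            v = -v
            r = -r
        pc1[c] = v
        evidence[c] = r
    return CompartmentProfile(profile.grid, pc1, evidence, oriented=True)


def compartment_fractions(profile: CompartmentProfile) -> pd.DataFrame:
    """bp and percentage of the unmasked genome per label (partial last
    bins counted at true length)."""
    bp = {"A": 0, "B": 0}
    for c in profile.grid.chroms:
        lab = profile.label(c)
        lengths = profile.grid.bin_lengths(c)
        for key in ("A", "B"):
            bp[key] += int(lengths[lab == key].sum())
    total = bp["A"] + bp["B"]
    rows = [(k, v, 100.0 * v / total if total else np.nan)
            for k, v in bp.items()]
    return pd.DataFrame(rows, columns=["label", "bp", "fraction_pct"])


def classify_switches(profile_1: CompartmentProfile,
                      profile_2: CompartmentProfile
                      ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Joint per-bin compartment category between two oriented profiles.

    Returns per-chromosome category arrays (``A-to-A`` etc.; ``masked``
    where either profile is undefined) and a summary table of bp and
    percentage per category over jointly assessed bins.
    """
    if not profile_1.grid.same_grid(profile_2.grid):
        raise ValueError("grids differ")
    cats = {}
    bp = {"A-to-A": 0, "A-to-B": 0, "B-to-A": 0, "B-to-B": 0}
    for c in profile_1.grid.chroms:
        l1, l2 = profile_1.label(c), profile_2.label(c)
        out = np.full(len(l1), "masked", dtype="<U6")
        ok = (l1 != ".") & (l2 != ".")
        joint = np.char.add(np.char.add(l1, "-to-"), l2)
        out[ok] = joint[ok]
        cats[c] = out
        lengths = profile_1.grid.bin_lengths(c)
        for key in bp:
            bp[key] += int(lengths[out == key].sum())
    total = sum(bp.values())
    rows = []
    for key in ("A-to-A", "B-to-B", "A-to-B", "B-to-A"):
        rows.append((key, bp[key],
                     100.0 * bp[key] / total if total else np.nan))
    switched = bp["A-to-B"] + bp["B-to-A"]
    rows.append(("switched", switched,
                 100.0 * switched / total if total else np.nan))
    return cats, pd.DataFrame(rows, columns=["category", "bp", "fraction_pct"])


def saddle(matrix: ContactMatrix, profile: CompartmentProfile,
           percentiles: np.ndarray | None = None,
           corner_classes: int = 10, min_separation_bins: int = 2
           ) -> SaddleSummary:
    """Saddle plot and compartment strength from an O/E matrix.

    Bins are ranked by PC1 within each chromosome and cut at the given
    percentile edges (default 2, 4, ..., 100, i.e. 50 classes from
    strongest B to strongest A); per-chromosome ranking keeps every class
    populated on every chromosome, so the cross-corner always has
    intra-chromosomal pairs (only those are counted).  Each saddle cell is
    the mean unmasked O/E over bin pairs in the two classes at separation
    >= ``min_separation_bins``.  AA pools pairs within the top
    ``corner_classes`` classes, BB within the bottom ones, AB across the
    two corners; strength = ln(AA * BB / AB^2).
    """
    if percentiles is None:
        percentiles = np.arange(2, 101, 2)
    percentiles = np.asarray(percentiles, dtype=float)
    oe = matrix if matrix.normalization_state == "oe" else oe_transform(matrix)
    if not any(np.isfinite(profile.pc1[c]).any()
               for c in profile.grid.chroms):
        raise ValueError("profile has no defined bins")
    n_class = len(percentiles)
    sums = np.zeros((n_class, n_class))
    counts = np.zeros((n_class, n_class))
    corner = {"aa": [0.0, 0], "bb": [0.0, 0], "ab": [0.0, 0]}
    for c in profile.grid.chroms:
        v = profile.pc1[c]
        cls = np.full(len(v), -1)
        ok = np.isfinite(v) & oe.mask[c]
        if not ok.any():
            continue
        edges = np.percentile(v[ok], np.concatenate([[0.0], percentiles]))
        edges[0] -= 1e-12
        edges[-1] += 1e-12
        cls[ok] = np.clip(np.searchsorted(edges, v[ok], side="right") - 1,
                          0, n_class - 1)
        m = oe.data[c]
        n = len(v)
        ii, jj = np.triu_indices(n, k=min_separation_bins)
        ci, cj = cls[ii], cls[jj]
        vals = m[ii, jj]
        keep = (ci >= 0) & (cj >= 0) & np.isfinite(vals)
        ci, cj, vals = ci[keep], cj[keep], vals[keep]
        np.add.at(sums, (ci, cj), vals)
        np.add.at(counts, (ci, cj), 1)
        np.add.at(sums, (cj, ci), vals)
        np.add.at(counts, (cj, ci), 1)
        hi = n_class - corner_classes
        in_a_i, in_a_j = ci >= hi, cj >= hi
        in_b_i, in_b_j = ci < corner_classes, cj < corner_classes
        for key, sel in (("aa", in_a_i & in_a_j), ("bb", in_b_i & in_b_j),
                         ("ab", (in_a_i & in_b_j) | (in_b_i & in_a_j))):
            corner[key][0] += vals[sel].sum()
            corner[key][1] += int(sel.sum())
    with np.errstate(invalid="ignore"):
        saddle_m = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    for key, (s, k) in corner.items():
        if k == 0:
            raise ValueError(
                f"empty saddle corner {key!r}; class pair counts: "
                f"{ {k2: v2[1] for k2, v2 in corner.items()} }")
    aa = corner["aa"][0] / corner["aa"][1]
    bb = corner["bb"][0] / corner["bb"][1]
    ab = corner["ab"][0] / corner["ab"][1]
    strength = float(np.log(aa * bb / ab ** 2))
    return SaddleSummary(np.concatenate([[0.0], percentiles]), saddle_m,
                         float(aa), float(bb), float(ab), strength)


def compartment_strength(aa: float, bb: float, ab: float) -> float:
    """ln(AA * BB / AB^2) from corner means (exposed for direct checks)."""
    return float(np.log(aa * bb / ab ** 2))


def compartment_gene_summary(profile: CompartmentProfile,
                             genes: pd.DataFrame,
                             profile_2: CompartmentProfile | None = None
                             ) -> dict[str, pd.DataFrame]:
    """Gene density and expression per compartment label, and PC1
    distributions per DEG class.

    Genes map to bins by midpoint (deterministic single assignment).
    Returns ``{"per_label": ..., "pc1_by_class": ...}``; the per-label
    table carries a Wilcoxon rank-sum p for the A-vs-B FPKM comparison in
    ``attrs["fpkm_rank_sum_p"]``.
    """
    grid = profile.grid
    mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    gene_label = np.full(len(genes), ".", dtype="<U1")
    gene_pc1 = {1: np.full(len(genes), np.nan)}
    if profile_2 is not None:
        gene_pc1[2] = np.full(len(genes), np.nan)
    for c in grid.chroms:
        on_c = (genes["chrom"] == c).to_numpy()
        if not on_c.any():
            continue
        bins = np.minimum(mid[on_c] // grid.bin_size, grid.n_bins(c) - 1)
        gene_label[on_c] = profile.label(c)[bins]
        gene_pc1[1][on_c] = profile.pc1[c][bins]
        if profile_2 is not None:
            gene_pc1[2][on_c] = profile_2.pc1[c][bins]
    fracs = compartment_fractions(profile)
    mb = dict(zip(fracs["label"], fracs["bp"] / 1e6))
    rows = []
    fpkm = {}
    for lab in ("A", "B"):
        sel = gene_label == lab
        fpkm[lab] = genes.loc[sel, "fpkm_1"].to_numpy()
        density = sel.sum() / mb[lab] if mb.get(lab, 0) > 0 else np.nan
        rows.append((lab, int(sel.sum()), density,
                     float(np.mean(fpkm[lab])) if sel.any() else np.nan,
                     float(np.median(fpkm[lab])) if sel.any() else np.nan))
    per_label = pd.DataFrame(rows, columns=["label", "n_genes",
                                            "genes_per_mb", "mean_fpkm",
                                            "median_fpkm"])
    if len(fpkm["A"]) and len(fpkm["B"]):
        per_label.attrs["fpkm_rank_sum_p"] = float(
            stats.ranksums(fpkm["A"], fpkm["B"]).pvalue)
    else:
        per_label.attrs["fpkm_rank_sum_p"] = np.nan
    rows = []
    for cls in ("up", "down", "ns"):
        sel = (genes["deg_label"] == cls).to_numpy()
        for cond, pc1 in gene_pc1.items():
            v = pc1[sel]
            v = v[np.isfinite(v)]
            rows.append((cls, cond, len(v),
                         float(np.mean(v)) if len(v) else np.nan,
                         float(np.median(v)) if len(v) else np.nan))
    pc1_by_class = pd.DataFrame(rows, columns=["deg_class", "condition",
                                               "n_genes", "mean_pc1",
                                               "median_pc1"])
    return {"per_label": per_label, "pc1_by_class": pc1_by_class}
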