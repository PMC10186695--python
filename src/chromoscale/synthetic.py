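"""Two-condition synthetic Hi-C data with planted multiscale architecture.

The generator emulates the statistical structure of a plant Hi-C experiment
at desk scale: a power-law distance decay, an alternating A/B compartment
checkerboard, block-diagonal TAD enrichment, focal loop peaks, and Poisson
count sampling at a stated sequencing depth.  A paired "stress" condition is
produced by flipping a stated fraction of compartment blocks (A->B biased),
gaining/losing TAD boundaries, and deleting loops — with the exact change
sets recorded so recovery can be scored.

Gene, histone-mark and DHS tracks are generated consistently with the
planted states: ~70% of genes sit in A bins and express higher, H3K27ac
peaks mark TSSs of highly expressed genes, H3K27me3 covers low-expression
(B) blocks, and DHSs sit at every loop anchor plus random background sites.
Differential-expression labels follow the |log2 FC| > 1 rule applied to the
planted FPKM pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact import ContactMatrix
from .genome import BinnedGenome, SignalTrack

__all__ = [
    "ArchitectureConfig",
    "GroundTruth",
    "ConditionChanges",
    "generate_architecture",
    "expected_intensity",
    "sample_contacts",
    "perturb_condition",
    "simulate_study",
    "SimulatedStudy",
]


@dataclass
class ArchitectureConfig:
    """Parameters of the planted architecture.

    Defaults describe the benchmark condition used throughout the test
    suite: a 10 Mb two-chromosome genome at 5 kb bins sampled to 5e6
    contact pairs, with compartment blocks of ~500 kb, TADs of ~120 kb
    (matching the genome-wide mean TAD size implied by ~2,300 domains on a
    271 Mb genome), 3-fold intra-TAD enrichment, and 5-fold loop peaks.
    The perturbation fractions mirror the observed two-condition changes:
    15.5% of bins switch compartment (90% of switched blocks A->B), ~29%
    of boundaries change, and 30% of loops are lost (with gains at 0.8x
    the lost count).
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    bin_size: int = 5_000
    decay_exponent: float = 1.0
    compartment_amplitude: float = 0.5
    compartment_block_mean: int = 100          # bins
    tad_mean_size: int = 24                    # bins
    tad_enrichment: float = 3.0
    n_loops: int = 40
    loop_enrichment: float = 5.0
    depth: float = 5_000_000
    switch_fraction: float = 0.155
    boundary_change_fraction: float = 0.29
    loop_loss_fraction: float = 0.3
    loop_gain_ratio: float = 0.8               # gained loops per lost loop
    ab_bias: float = 0.9                       # fraction of switched blocks A->B
    genes_per_mb: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name in ("switch_fraction", "boundary_change_fraction",
                     "loop_loss_fraction", "ab_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if self.compartment_amplitude < 0:
            raise ValueError("compartment_amplitude must be >= 0")
        if self.tad_enrichment < 1 or self.loop_enrichment < 1:
            raise ValueError("enrichment folds must be >= 1")
        for c, size in self.chrom_sizes.items():
            if size < 10 * self.bin_size:
                raise ValueError(f"chromosome {c} shorter than 10 bins")

    @property
    def grid(self) -> BinnedGenome:
        return BinnedGenome(self.chrom_sizes, self.bin_size)


@dataclass
class ConditionChanges:
    """Exact planted change sets between condition 1 and condition 2."""

    switched_bins: dict[str, np.ndarray] = field(default_factory=dict)
    switched_a_to_b_bins: dict[str, np.ndarray] = field(default_factory=dict)
    boundaries_lost: dict[str, np.ndarray] = field(default_factory=dict)
    boundaries_gained: dict[str, np.ndarray] = field(default_factory=dict)
    loops_lost: list[tuple] = field(default_factory=list)
    loops_gained: list[tuple] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Planted architecture for one condition."""

    grid: BinnedGenome
    compartment_labels: dict[str, np.ndarray]      # 'A'/'B' per bin
    boundaries: dict[str, np.ndarray]              # sorted interior bin indices
    loops: list[tuple]                             # (chrom, bin_i, bin_j)
    genes: pd.DataFrame                            # gene table, shared columns
    mark_peaks: dict[str, pd.DataFrame]            # mark -> BED-like intervals
    dhs: pd.DataFrame                              # BED-like intervals
    changes: ConditionChanges | None = None        # set on perturbed copies

    # -- derived helpers ----------------------------------------------
    def tad_id(self, chrom: str) -> np.ndarray:
        """Per-bin TAD identifier implied by the boundary set."""
        n = self.grid.n_bins(chrom)
        ids = np.zeros(n, dtype=int)
        for k, b in enumerate(self.boundaries[chrom], start=1):
            ids[b:] = k
        return ids

    def mark_signal(self, mark: str, noise: float = 0.1,
                    rng: np.random.Generator | None = None) -> SignalTrack:
        """Per-bin signal implied by a mark's peaks: 1.0 inside peaks over a
        low noise floor."""
        if rng is None:
            rng = np.random.default_rng(0)
        values = {c: rng.uniform(0, noise, self.grid.n_bins(c))
                  for c in self.grid.chroms}
        for row in self.mark_peaks[mark].itertuples(index=False):
            b0 = int(row.start) // self.grid.bin_size
            b1 = min((int(row.end) - 1) // self.grid.bin_size,
                     self.grid.n_bins(row.chrom) - 1)
            values[row.chrom][b0:b1 + 1] += 1.0
        return SignalTrack(self.grid, values, name=mark)

    def loop_anchor_intervals(self) -> pd.DataFrame:
        """Both anchors of every loop as BED-like bin intervals."""
        rows = []
        for chrom, bi, bj in self.loops:
            for b in (bi, bj):
                rows.append((chrom, self.grid.bin_start(chrom, b),
                             self.grid.bin_end(chrom, b)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # -- writers -------------------------------------------------------
    def write_genes_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    def write_boundaries_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.grid.chroms:
                for b in self.boundaries[c]:
                    fh.write(f"{c}\t{self.grid.bin_start(c, int(b))}"
                             f"\t{self.grid.bin_end(c, int(b))}\n")


def _deg_label(fpkm_1: float, fpkm_2: float, floor: float = 0.01) -> str:
    lfc = math.log2(max(fpkm_2, floor) / max(fpkm_1, floor))
    if lfc > 1:
        return "up"
    if lfc < -1:
        return "down"
    return "ns"


def _alternating_blocks(n: int, mean_len: int, rng) -> np.ndarray:
    """'A'/'B' labels in alternating geometric-length blocks."""
    labels = np.empty(n, dtype="<U1")
    state = rng.choice(["A", "B"])
    i = 0
    while i < n:
        length = max(1, rng.geometric(1.0 / mean_len))
        labels[i:i + length] = state
        state = "B" if state == "A" else "A"
        i += length
    return labels


def _draw_boundaries(n: int, mean_gap: int, rng) -> np.ndarray:
    """Interior boundary bins with roughly exponential inter-boundary gaps
    (minimum gap 3 bins)."""
    bounds = []
    pos = 0
    while True:
        gap = 3 + rng.poisson(max(mean_gap - 3, 1))
        pos += gap
        if pos >= n - 3:
            break
        bounds.append(pos)
    return np.asarray(bounds, dtype=int)


def generate_architecture(config: ArchitectureConfig) -> GroundTruth:
    """Draw a complete planted architecture; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    labels, boundaries = {}, {}
    for c in grid.chroms:
        n = grid.n_bins(c)
        if n < config.compartment_block_mean:
            raise ValueError(
                f"chromosome {c} shorter than one compartment block")
        labels[c] = _alternating_blocks(n, config.compartment_block_mean, rng)
        boundaries[c] = _draw_boundaries(n, config.tad_mean_size, rng)

    loops = _place_loops(grid, boundaries, config.n_loops, rng)
    genes = _draw_genes(grid, labels, config, rng)
    mark_peaks = _draw_marks(grid, labels, genes, rng)
    dhs = _draw_dhs(grid, loops, rng)
    return GroundTruth(grid, labels, boundaries, loops, genes, mark_peaks, dhs)


def _place_loops(grid, boundaries, n_loops, rng,
                 min_dist_bins: int = 24, max_dist_bins: int = 150):
    """Focal loops with log-uniform anchor separation (120-750 kb at 5 kb
    bins), anchors kept off boundary bins and away from chromosome ends.
    The upper bound keeps every planted loop detectable at the default
    depth: beyond ~1 Mb a 5-fold focal peak carries only ~10 pairs at
    5e6 total, below any reasonable clustering threshold."""
    loops = []
    chroms = grid.chroms
    attempts = 0
    while len(loops) < n_loops and attempts < n_loops * 200:
        attempts += 1
        c = chroms[rng.integers(len(chroms))]
        n = grid.n_bins(c)
        hi = min(max_dist_bins, n - 6)
        if hi <= min_dist_bins:
            continue
        d = int(round(math.exp(rng.uniform(math.log(min_dist_bins),
                                           math.log(hi)))))
        bi = int(rng.integers(2, n - d - 2))
        bj = bi + d
        bset = set(boundaries[c].tolist())
        if bi in bset or bj in bset:
            continue
        # keep anchors separated from existing loops (>= 4 bins in Chebyshev)
        if any(cc == c and max(abs(bi - pi), abs(bj - pj)) < 4
               for cc, pi, pj in loops):
            continue
        loops.append((c, bi, bj))
    return loops


def _draw_genes(grid, labels, config, rng) -> pd.DataFrame:
    total_mb = sum(grid.chrom_sizes.values()) / 1e6
    n_genes = int(round(config.genes_per_mb * total_mb))
    rows = []
    a_bins = {c: np.flatnonzero(labels[c] == "A") for c in grid.chroms}
    b_bins = {c: np.flatnonzero(labels[c] == "B") for c in grid.chroms}
    chrom_weights = np.array([grid.chrom_sizes[c] for c in grid.chroms],
                             dtype=float)
    chrom_weights /= chrom_weights.sum()
    for g in range(n_genes):
        c = grid.chroms[rng.choice(len(grid.chroms), p=chrom_weights)]
        in_a = rng.random() < 0.7
        pool = a_bins[c] if in_a and len(a_bins[c]) else b_bins[c]
        if len(pool) == 0:
            pool = np.arange(grid.n_bins(c))
            in_a = False
        b = int(pool[rng.integers(len(pool))])
        start = grid.bin_start(c, b) + int(rng.integers(0, grid.bin_size))
        length = int(rng.integers(1_000, 5_000))
        end = min(start + length, grid.chrom_sizes[c])
        strand = "+" if rng.random() < 0.5 else "-"
        # A-compartment genes express higher on average
        fpkm_1 = float(np.exp(rng.normal(2.0 if in_a else 0.0, 1.0)))
        rows.append((f"gene{g:05d}", c, start, end, strand, fpkm_1))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "fpkm_1"])
    genes = genes.sort_values(["chrom", "start"], ignore_index=True)
    # background differential expression: ~9.5% DEGs (down-biased, as in
    # a cold-stress transcriptome), remainder mild multiplicative noise
    u = rng.random(len(genes))
    lfc = np.clip(rng.normal(0.0, 0.25, len(genes)), -0.9, 0.9)
    up = u < 0.042
    down = (u >= 0.042) & (u < 0.095)
    lfc[up] = 1.2 + np.abs(rng.normal(0.0, 0.5, int(up.sum())))
    lfc[down] = -(1.2 + np.abs(rng.normal(0.0, 0.5, int(down.sum()))))
    genes["fpkm_2"] = np.maximum(genes["fpkm_1"], 0.01) * 2.0 ** lfc
    genes["deg_label"] = [
        _deg_label(a, b) for a, b in zip(genes["fpkm_1"], genes["fpkm_2"])]
    return genes


def _draw_marks(grid, labels, genes, rng) -> dict[str, pd.DataFrame]:
    # H3K27ac: ~1 kb peaks at TSSs of the top-30% expressed genes
    thr = genes["fpkm_1"].quantile(0.7)
    ac_rows = []
    for row in genes[genes["fpkm_1"] >= thr].itertuples(index=False):
        tss = row.start if row.strand == "+" else row.end
        ac_rows.append((row.chrom, max(tss - 500, 0),
                        min(tss + 500, grid.chrom_sizes[row.chrom])))
    # H3K27me3: broad domains over B (low-expression) blocks
    me3_rows = []
    for c in grid.chroms:
        lab = labels[c]
        b = 0
        while b < len(lab):
            if lab[b] == "B":
                e = b
                while e < len(lab) and lab[e] == "B":
                    e += 1
                me3_rows.append((c, grid.bin_start(c, b), grid.bin_end(c, e - 1)))
                b = e
            else:
                b += 1
    return {
        "H3K27ac": pd.DataFrame(ac_rows, columns=["chrom", "start", "end"]),
        "H3K27me3": pd.DataFrame(me3_rows, columns=["chrom", "start", "end"]),
    }


def _draw_dhs(grid, loops, rng, n_background_per_mb: float = 5.0) -> pd.DataFrame:
    rows = []
    for chrom, bi, bj in loops:
        for b in (bi, bj):
            rows.append((chrom, grid.bin_start(chrom, b), grid.bin_end(chrom, b)))
    for c in grid.chroms:
        n_bg = int(round(n_background_per_mb * grid.chrom_sizes[c] / 1e6))
        for _ in range(n_bg):
            start = int(rng.integers(0, grid.chrom_sizes[c] - 500))
            rows.append((c, start, start + 500))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]) \
        .sort_values(["chrom", "start"], ignore_index=True)


# ----------------------------------------------------------------------
def expected_intensity(truth: GroundTruth, config: ArchitectureConfig
                       ) -> dict[str, np.ndarray]:
    """Noise-free contact-rate matrices implied by the planted architecture.

    rate(i, j) = (|i-j| * bin_size)^(-decay_exponent)
                 * c(i, j) * t(i, j) * l(i, j)

    with c the compartment checkerboard factor ((1+amplitude) for matching
    labels, its reciprocal otherwise), t the intra-TAD fold, and l the loop
    fold on each planted loop's 3x3 bin neighbourhood.  Symmetric; diagonal
    zero.
    """
    out = {}
    for c in truth.grid.chroms:
        n = truth.grid.n_bins(c)
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            rate = (dist * config.bin_size) ** (-config.decay_exponent)
        rate[dist == 0] = 0.0
        amp = config.compartment_amplitude
        if amp > 0:
            same = truth.compartment_labels[c][:, None] == \
                truth.compartment_labels[c][None, :]
            rate *= np.where(same, 1.0 + amp, 1.0 / (1.0 + amp))
        if config.tad_enrichment > 1:
            tid = truth.tad_id(c)
            rate *= np.where(tid[:, None] == tid[None, :],
                             config.tad_enrichment, 1.0)
        if config.loop_enrichment > 1:
            for chrom, bi, bj in truth.loops:
                if chrom != c:
                    continue
                i0, i1 = max(bi - 1, 0), min(bi + 2, n)
                j0, j1 = max(bj - 1, 0), min(bj + 2, n)
                rate[i0:i1, j0:j1] *= config.loop_enrichment
                rate[j0:j1, i0:i1] *= config.loop_enrichment
        out[c] = rate
    return out


def sample_contacts(rates: dict[str, np.ndarray], depth: float, seed: int,
                    grid: BinnedGenome, return_pairs: bool = False):
    """Poisson-sample a ContactMatrix (and optionally a raw pair list) from
    rate matrices, scaled so the expected total pair count equals ``depth``.

    Upper-triangle cells are sampled independently and mirrored; pair
    positions (when requested) are uniform within their bins.
    """
    rng = np.random.default_rng(seed)
    total_rate = 0.0
    for c in grid.chroms:
        total_rate += np.triu(rates[c], k=1).sum()
    scale = 0.0 if total_rate == 0 or depth == 0 else depth / total_rate
    data = {}
    pair_frames = []
    for c in grid.chroms:
        n = grid.n_bins(c)
        lam = np.triu(rates[c], k=1) * scale
        counts = rng.poisson(lam)
        m = counts + counts.T
        data[c] = m.astype(float)
        if return_pairs:
            iu, ju = np.nonzero(counts)
            reps = counts[iu, ju]
            bi = np.repeat(iu, reps)
            bj = np.repeat(ju, reps)
            pos1 = bi * grid.bin_size + rng.integers(
                0, grid.bin_size, size=len(bi))
            pos2 = bj * grid.bin_size + rng.integers(
                0, grid.bin_size, size=len(bj))
            pos1 = np.minimum(pos1, grid.chrom_sizes[c] - 1)
            pos2 = np.minimum(pos2, grid.chrom_sizes[c] - 1)
            pair_frames.append(pd.DataFrame(
                {"chrom": c, "pos1": pos1, "pos2": pos2}))
    matrix = ContactMatrix(grid, data)
    if return_pairs:
        pairs = (pd.concat(pair_frames, ignore_index=True) if pair_frames
                 else pd.DataFrame(columns=["chrom", "pos1", "pos2"]))
        return matrix, pairs
    return matrix


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
def perturb_condition(truth: GroundTruth, config: ArchitectureConfig
                      ) -> GroundTruth:
    """Derive the condition-2 architecture with recorded change sets.

    Whole compartment blocks flip until ~``switch_fraction`` of bins have
    switched (``ab_bias`` of flipped blocks go A->B); a
    ``boundary_change_fraction`` of boundaries is removed (condition-1
    specific) and the same number gained at new positions;
    ``loop_loss_fraction`` of loops is deleted and ``loop_gain_ratio``
    times that count of new loops added.  Planted differential expression
    is concentrated at changed boundaries and lost-loop anchors.
    """
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    grid = truth.grid
    changes = ConditionChanges()

    labels2 = _switch_blocks(truth, config, rng, changes)
    boundaries2 = _change_boundaries(truth, config, rng, changes)
    loops2 = _change_loops(truth, config, rng, changes, boundaries2)
    genes2 = _replant_degs(truth, config, rng, changes, grid)
    dhs2 = _extend_dhs(truth, changes, grid)

    return GroundTruth(grid, labels2, boundaries2, loops2, genes2,
                       truth.mark_peaks, dhs2, changes=changes)


def _switch_blocks(truth, config, rng, changes):
    grid = truth.grid
    labels2 = {c: truth.compartment_labels[c].copy() for c in grid.chroms}
    total_bins = sum(grid.n_bins(c) for c in grid.chroms)
    target = config.switch_fraction * total_bins
    blocks = []  # (chrom, start, end, label)
    for c in grid.chroms:
        lab = truth.compartment_labels[c]
        b = 0
        while b < len(lab):
            e = b
            while e < len(lab) and lab[e] == lab[b]:
                e += 1
            blocks.append((c, b, e, lab[b]))
            b = e
    a_blocks = [blk for blk in blocks if blk[3] == "A"]
    b_blocks = [blk for blk in blocks if blk[3] == "B"]
    rng.shuffle(a_blocks)
    rng.shuffle(b_blocks)
    switched = {c: np.zeros(grid.n_bins(c), dtype=bool) for c in grid.chroms}
    a2b = {c: np.zeros(grid.n_bins(c), dtype=bool) for c in grid.chroms}
    flipped = 0
    while flipped < target and (a_blocks or b_blocks):
        take_a = (rng.random() < config.ab_bias and a_blocks) or not b_blocks
        c, s, e, lab = a_blocks.pop() if take_a else b_blocks.pop()
        labels2[c][s:e] = "B" if lab == "A" else "A"
        switched[c][s:e] = True
        if lab == "A":
            a2b[c][s:e] = True
        flipped += e - s
    changes.switched_bins = switched
    changes.switched_a_to_b_bins = a2b
    return labels2


def _change_boundaries(truth, config, rng, changes):
    grid = truth.grid
    boundaries2 = {}
    for c in grid.chroms:
        b = truth.boundaries[c]
        n_change = int(round(config.boundary_change_fraction * len(b)))
        if n_change > len(b):
            raise ValueError("boundary changes exceed available boundaries")
        lost_idx = rng.choice(len(b), size=n_change, replace=False)
        lost = np.sort(b[lost_idx])
        kept = np.sort(np.delete(b, lost_idx))
        occupied = set(b.tolist())
        n = grid.n_bins(c)
        gained = []
        tries = 0
        while len(gained) < n_change and tries < n_change * 500:
            tries += 1
            cand = int(rng.integers(4, n - 4))
            if all(abs(cand - o) >= 4 for o in occupied):
                gained.append(cand)
                occupied.add(cand)
        gained = np.sort(np.asarray(gained, dtype=int))
        boundaries2[c] = np.sort(np.concatenate([kept, gained]))
        changes.boundaries_lost[c] = lost
        changes.boundaries_gained[c] = gained
    return boundaries2


def _change_loops(truth, config, rng, changes, boundaries2):
    n_lost = int(round(config.loop_loss_fraction * len(truth.loops)))
    if n_lost > len(truth.loops):
        raise ValueError("loop losses exceed available loops")
    lost_idx = set(rng.choice(len(truth.loops), size=n_lost,
                              replace=False).tolist())
    kept = [lp for k, lp in enumerate(truth.loops) if k not in lost_idx]
    lost = [lp for k, lp in enumerate(truth.loops) if k in lost_idx]
    n_gain = int(round(config.loop_gain_ratio * n_lost))
    gained = _place_loops(truth.grid, boundaries2, n_gain + len(kept), rng)
    # filter gains that collide with kept loops
    new = []
    for c, bi, bj in gained:
        if len(new) >= n_gain:
            break
        if any(cc == c and max(abs(bi - pi), abs(bj - pj)) < 6
               for cc, pi, pj in kept + lost + new):
            continue
        new.append((c, bi, bj))
    changes.loops_lost = lost
    changes.loops_gained = new
    return kept + new


def _replant_degs(truth, config, rng, changes, grid):
    """Re-draw condition-2 FPKMs so DEGs concentrate at changed features."""
    genes = truth.genes.copy()
    flank = 2 * grid.bin_size
    near_gained = np.zeros(len(genes), dtype=bool)
    near_lost = np.zeros(len(genes), dtype=bool)
    at_lost_loop = np.zeros(len(genes), dtype=bool)
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    for c in grid.chroms:
        on_c = chroms == c
        for barr, target in ((changes.boundaries_gained.get(c, []), near_gained),
                             (changes.boundaries_lost.get(c, []), near_lost)):
            for b in barr:
                lo = grid.bin_start(c, int(b)) - flank
                hi = grid.bin_end(c, int(b)) + flank
                target |= on_c & (starts < hi) & (ends > lo)
    # promoters at lost-loop anchors
    prom_start = np.where(genes["strand"] == "+", starts - 2000, ends)
    prom_end = np.where(genes["strand"] == "+", starts, ends + 2000)
    for c, bi, bj in changes.loops_lost:
        on_c = chroms == c
        for b in (bi, bj):
            lo, hi = grid.bin_start(c, b), grid.bin_end(c, b)
            at_lost_loop |= on_c & (prom_start < hi) & (prom_end > lo)

    u = rng.random(len(genes))
    p_up = np.full(len(genes), 0.042)
    p_down = np.full(len(genes), 0.053)
    p_up[near_gained] = 0.15
    p_down[near_gained] = 0.08
    p_up[near_lost] = 0.08
    p_down[near_lost] = 0.15
    p_up[at_lost_loop] = np.maximum(p_up[at_lost_loop], 0.10)
    p_down[at_lost_loop] = np.maximum(p_down[at_lost_loop], 0.10)
    lfc = np.clip(rng.normal(0.0, 0.25, len(genes)), -0.9, 0.9)
    up = u < p_up
    down = (u >= p_up) & (u < p_up + p_down)
    lfc[up] = 1.2 + np.abs(rng.normal(0.0, 0.5, int(up.sum())))
    lfc[down] = -(1.2 + np.abs(rng.normal(0.0, 0.5, int(down.sum()))))
    genes["fpkm_2"] = np.maximum(genes["fpkm_1"].to_numpy(), 0.01) * 2.0 ** lfc
    genes["deg_label"] = [
        _deg_label(a, b) for a, b in zip(genes["fpkm_1"], genes["fpkm_2"])]
    return genes


def _extend_dhs(truth, changes, grid):
    rows = [tuple(r) for r in truth.dhs.itertuples(index=False)]
    for c, bi, bj in changes.loops_gained:
        for b in (bi, bj):
            rows.append((c, grid.bin_start(c, b), grid.bin_end(c, b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]) \
        .sort_values(["chrom", "start"], ignore_index=True)


# ----------------------------------------------------------------------
@dataclass
class SimulatedStudy:
    """A complete paired-condition dataset plus its ground truth."""

    config: ArchitectureConfig
    grid: BinnedGenome
    truth_1: GroundTruth
    truth_2: GroundTruth
    matrix_1: ContactMatrix
    matrix_2: ContactMatrix
    pairs_1: pd.DataFrame | None = None
    pairs_2: pd.DataFrame | None = None

    @property
    def changes(self) -> ConditionChanges:
        return self.truth_2.changes


def simulate_study(config: ArchitectureConfig,
                   return_pairs: bool = False) -> SimulatedStudy:
    """Generate both conditions end-to-end from one config."""
    truth_1 = generate_architecture(config)
    truth_2 = perturb_condition(truth_1, config)
    rates_1 = expected_intensity(truth_1, config)
    rates_2 = expected_intensity(truth_2, config)
    out_1 = sample_contacts(rates_1, config.depth, config.seed + 1,
                            config.grid, return_pairs=return_pairs)
    out_2 = sample_contacts(rates_2, config.depth, config.seed + 2,
                            config.grid, return_pairs=return_pairs)
    if return_pairs:
        m1, p1 = out_1
        m2, p2 = out_2
    else:
        m1, m2, p1, p2 = out_1, out_2, None, None
    return SimulatedStudy(config, config.grid, truth_1, truth_2,
                          m1, m2, p1, p2)
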