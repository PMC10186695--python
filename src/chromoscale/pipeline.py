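"""End-to-end two-condition comparison and structured JSON report.

``compare_study`` orchestrates the full analysis on in-memory objects
(matrix prep -> compartments -> TADs -> loops -> integration);
``run_compare`` is the file-reading wrapper behind ``chromoscale run``.
The report echoes every threshold used, and the whole run is
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import compartments as comp
from . import contact, integration, loops as loops_mod, tads as tads_mod
from .genome import BinnedGenome, SignalTrack, read_chrom_sizes
from .synthetic import SimulatedStudy

log = logging.getLogger(__name__)

__all__ = ["CompareParams", "RunConfig", "compare_study", "run_compare",
           "report_to_json"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class CompareParams:
    """Thresholds and resolutions of the two-condition comparison."""

    compartment_bin: int = 50_000
    tad_bin: int = 5_000
    min_window: int = 20_000
    max_window: int = 300_000
    window_step: int = 5_000
    boundary_delta: float = 0.01
    boundary_fdr: float = 0.01
    shift_bins: int = 2
    top_fraction: float = 0.25
    loop_eps: tuple = (2_000, 5_000, 10_000)
    loop_min_pts: tuple = (20, 50)
    loop_q: float = 0.01
    diff_loop_p: float = 0.01
    apa_flank_bins: int = 10
    n_perm: int = 1_000
    boundary_gene_flank_bins: int = 2
    mask_min_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("boundary_delta", "boundary_fdr", "loop_q",
                     "diff_loop_p", "top_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.compartment_bin % self.tad_bin:
            raise ValueError("compartment_bin must be a multiple of tad_bin")


def peak_coverage_track(peaks: pd.DataFrame, grid: BinnedGenome,
                        name: str = "peaks") -> SignalTrack:
    """bp of peak coverage per bin."""
    values = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
    for row in peaks.itertuples(index=False):
        if row.chrom not in values:
            continue
        b0 = int(row.start) // grid.bin_size
        b1 = min((int(row.end) - 1) // grid.bin_size,
                 grid.n_bins(row.chrom) - 1)
        for b in range(b0, b1 + 1):
            lo = max(int(row.start), grid.bin_start(row.chrom, b))
            hi = min(int(row.end), grid.bin_end(row.chrom, b))
            values[row.chrom][b] += max(hi - lo, 0)
    return SignalTrack(grid, values, name=name)


def gene_density_track(genes: pd.DataFrame, grid: BinnedGenome) -> SignalTrack:
    values = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
    for row in genes.itertuples(index=False):
        if row.chrom not in values:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        values[row.chrom][min(mid // grid.bin_size,
                              grid.n_bins(row.chrom) - 1)] += 1
    return SignalTrack(grid, values, name="gene_density")


def _prep_condition_pair(matrix_1, matrix_2, params):
    """Depth-normalise, mask and balance both conditions at TAD and
    compartment resolution."""
    d1, d2 = contact.depth_normalize(matrix_1, matrix_2)
    out = {}
    for label, factor in (("tad", 1),
                          ("comp", params.compartment_bin // params.tad_bin)):
        pair = []
        for m in (d1, d2):
            mc = m.coarsen(factor) if factor > 1 else m.copy()
            mc = contact.mask_low_coverage(mc, params.mask_min_fraction)
            bal = contact.kr_balance(mc)
            pair.append((mc, bal, contact.oe_transform(bal)))
        out[label] = pair
    out["depth"] = (d1, d2)
    return out


def compare_study(matrix_1, matrix_2, genes: pd.DataFrame,
                  mark_peaks: dict[str, pd.DataFrame],
                  dhs: pd.DataFrame,
                  pairs_1: pd.DataFrame | None = None,
                  pairs_2: pd.DataFrame | None = None,
                  params: CompareParams | None = None) -> dict:
    """Full two-condition comparison; returns the report bundle.

    ``matrix_1``/``matrix_2`` are raw contact matrices at the TAD
    resolution; pair lists (if given) drive loop calling.  Stage order:
    matrix prep, compartments, TADs, loops, integration.
    """
    if params is None:
        params = CompareParams()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "params": asdict(params), "stages": {}}

    stage = "matrix_prep"
    try:
        prep = _prep_condition_pair(matrix_1, matrix_2, params)
        d1, d2 = prep["depth"]
        report["stages"]["matrix"] = {
            "total_contacts_after_depth_norm": float(d1.total()),
            "scc_between_conditions": contact.scc(d1, d2),
        }

        stage = "compartments"
        (comp_raw1, comp_bal1, comp_oe1), (comp_raw2, comp_bal2, comp_oe2) = \
            prep["comp"]
        comp_grid = comp_bal1.grid
        ac_track = peak_coverage_track(mark_peaks["H3K27ac"], comp_grid,
                                       "H3K27ac")
        gd_track = gene_density_track(genes, comp_grid)
        prof1 = comp.orient_sign(comp.compartment_eigenvector(comp_bal1),
                                 ac_track, gd_track)
        prof2 = comp.orient_sign(comp.compartment_eigenvector(comp_bal2),
                                 ac_track, gd_track)
        frac1 = comp.compartment_fractions(prof1)
        frac2 = comp.compartment_fractions(prof2)
        cats, switch_summary = comp.classify_switches(prof1, prof2)
        saddle1 = comp.saddle(comp_oe1, prof1)
        saddle2 = comp.saddle(comp_oe2, prof2)
        gene_summary = comp.compartment_gene_summary(prof1, genes, prof2)
        report["stages"]["compartments"] = {
            "fractions_1": frac1.to_dict("records"),
            "fractions_2": frac2.to_dict("records"),
            "switch_summary": switch_summary.to_dict("records"),
            "strength_1": saddle1.strength,
            "strength_2": saddle2.strength,
            "gene_summary_per_label":
                gene_summary["per_label"].to_dict("records"),
        }

        stage = "tads"
        (tad_raw1, tad_bal1, tad_oe1), (tad_raw2, tad_bal2, tad_oe2) = \
            prep["tad"]
        ins1 = tads_mod.insulation_profile(tad_bal1, params.min_window,
                                           params.max_window,
                                           params.window_step)
        ins2 = tads_mod.insulation_profile(tad_bal2, params.min_window,
                                           params.max_window,
                                           params.window_step)
        b1 = tads_mod.call_boundaries(ins1, tad_bal1, params.boundary_delta,
                                      params.boundary_fdr, condition="1")
        b2 = tads_mod.call_boundaries(ins2, tad_bal2, params.boundary_delta,
                                      params.boundary_fdr, condition="2")
        consensus = tads_mod.consensus_boundaries(b1, b2, params.shift_bins)
        tset1 = tads_mod.segment_tads(b1, tad_bal1.grid)
        tset2 = tads_mod.segment_tads(b2, tad_bal2.grid)
        strength_cmp = tads_mod.boundary_strength_compare(ins1, ins2, consensus)
        diff_tads = tads_mod.differential_tads(tset1, tad_raw1, tad_raw2)
        mark_pct = {}
        for mark, peaks in mark_peaks.items():
            sig = peak_coverage_track(peaks, tad_bal1.grid, mark)
            ann1 = tads_mod.annotate_tads_by_mark(tset1, peaks, sig,
                                                  params.top_fraction, mark)
            ann2 = tads_mod.annotate_tads_by_mark(tset2, peaks, sig,
                                                  params.top_fraction, mark)
            mark_pct[mark] = {
                "pct_enriched_1":
                    100.0 * ann1.table[f"{mark}_enriched"].mean(),
                "pct_enriched_2":
                    100.0 * ann2.table[f"{mark}_enriched"].mean(),
            }
        report["stages"]["tads"] = {
            "n_boundaries_1": len(b1), "n_boundaries_2": len(b2),
            "n_tads_1": len(tset1), "n_tads_2": len(tset2),
            "median_tad_size_1": float(tset1.table["size_bp"].median()),
            "median_tad_size_2": float(tset2.table["size_bp"].median()),
            "n_conserved": consensus["n_conserved"],
            "n_specific_1": consensus["n_specific_1"],
            "n_specific_2": consensus["n_specific_2"],
            "conserved_fraction_of_1": consensus["conserved_fraction_of_1"],
            "boundary_strength": strength_cmp.to_dict("records"),
            "n_changed_tads": int((diff_tads["label"] == "changed").sum()),
            "mark_enriched_pct": mark_pct,
        }

        stage = "loops"
        loop_report: dict = {}
        diff = None
        loopset1 = loopset2 = None
        if pairs_1 is not None and pairs_2 is not None:
            loopset1 = loops_mod.call_loops(pairs_1, params.loop_eps,
                                            params.loop_min_pts,
                                            params.loop_q, condition="1")
            loopset2 = loops_mod.call_loops(pairs_2, params.loop_eps,
                                            params.loop_min_pts,
                                            params.loop_q, condition="2")
            union = pd.concat([loopset1.table, loopset2.table],
                              ignore_index=True)
            union = _dedupe_loops(union)
            diff = loops_mod.differential_loops(pairs_1, pairs_2, union,
                                                params.diff_loop_p,
                                                seed=params.seed)
            dist_table = loops_mod.distance_classify(diff["gained"],
                                                     diff["lost"],
                                                     diff["common"])
            _, apa1 = loops_mod.apa(tad_oe1, loopset1.table,
                                    params.apa_flank_bins)
            _, apa2 = loops_mod.apa(tad_oe2, loopset2.table,
                                    params.apa_flank_bins)
            loop_report = {
                "n_loops_1": len(loopset1), "n_loops_2": len(loopset2),
                "n_gained": len(diff["gained"]), "n_lost": len(diff["lost"]),
                "n_common": len(diff["common"]),
                "apa_1": apa1, "apa_2": apa2,
                "distance_classes": dist_table.to_dict("records"),
                "long_range_fold_lost_vs_gained":
                    dist_table.attrs["long_range_fold_lost_vs_gained"],
            }
        report["stages"]["loops"] = loop_report

        stage = "integration"
        grid_tad = tad_bal1.grid
        bdr_report = integration.boundary_deg_report(
            consensus, genes, grid_tad, params.boundary_gene_flank_bins)
        integ: dict = {"boundary_deg": _jsonable_report(bdr_report)}
        if loopset1 is not None:
            anchors1 = loopset1.table
            frac_dhs, _ = integration.anchor_dhs_overlap(anchors1, dhs)
            anchor_ivals = pd.DataFrame({
                "chrom": np.repeat(anchors1["chrom"].to_numpy(), 2),
                "start": np.ravel(anchors1[["start1", "start2"]].to_numpy()),
                "end": np.ravel(anchors1[["end1", "end2"]].to_numpy()),
            })
            perm = integration.permutation_enrichment(
                anchor_ivals, dhs, grid_tad.chrom_sizes,
                n_perm=params.n_perm, seed=params.seed + 1)
            integ["anchor_dhs_fraction"] = frac_dhs
            integ["anchor_dhs_permutation"] = perm.as_dict()
            # reorganisation-associated DEG summary
            switch_ivals = _category_intervals(cats, comp_grid,
                                               ("A-to-B", "B-to-A"))
            bnd_ivals = integration.boundary_regions(
                consensus["specific_1"] + consensus["specific_2"], grid_tad,
                params.boundary_gene_flank_bins)
            loop_ivals = pd.concat(
                [_anchor_intervals(diff["gained"]),
                 _anchor_intervals(diff["lost"])], ignore_index=True)
            integ["reorg_deg"] = integration.reorg_deg_summary(
                switch_ivals, bnd_ivals, loop_ivals, genes)
        report["stages"]["integration"] = integ
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return report


def _dedupe_loops(union: pd.DataFrame, tol: int = 10_000) -> pd.DataFrame:
    """Collapse union loops whose anchor midpoints agree within tol."""
    keep = []
    seen: list[tuple] = []
    for idx, row in enumerate(union.itertuples(index=False)):
        m1 = (row.start1 + row.end1) // 2
        m2 = (row.start2 + row.end2) // 2
        if any(c == row.chrom and abs(m1 - a) <= tol and abs(m2 - b) <= tol
               for c, a, b in seen):
            continue
        seen.append((row.chrom, m1, m2))
        keep.append(idx)
    return union.iloc[keep].reset_index(drop=True)


def _anchor_intervals(loop_table: pd.DataFrame) -> pd.DataFrame:
    if not len(loop_table):
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame({
        "chrom": np.repeat(loop_table["chrom"].to_numpy(), 2),
        "start": np.ravel(loop_table[["start1", "start2"]].to_numpy()),
        "end": np.ravel(loop_table[["end1", "end2"]].to_numpy()),
    })


def _category_intervals(cats: dict[str, np.ndarray], grid: BinnedGenome,
                        which: tuple) -> pd.DataFrame:
    rows = []
    for c, arr in cats.items():
        sel = np.isin(arr, which)
        for b in np.flatnonzero(sel):
            rows.append((c, grid.bin_start(c, b), grid.bin_end(c, b)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _jsonable_report(obj):
    from .integration import EnrichmentResult
    if isinstance(obj, EnrichmentResult):
        return obj.as_dict()
    if isinstance(obj, dict):
        return {k: _jsonable_report(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable_report(v) for v in obj]
    return obj


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def report_to_json(report: dict, path) -> None:
    def clean(x):
        if isinstance(x, float) and not np.isfinite(x):
            return None
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x
    with open(path, "w") as fh:
        json.dump(clean(_jsonable_report(report)), fh, indent=2,
                  sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


# -- file-driven entry point -------------------------------------------
@dataclass
class RunConfig:
    """Paths and parameters for a file-driven two-condition run."""

    chrom_sizes: str = ""
    pairs_1: str = ""
    pairs_2: str = ""
    genes: str = ""
    h3k27ac_peaks: str = ""
    h3k27me3_peaks: str = ""
    dhs: str = ""
    out_dir: str = "chromoscale_out"
    params: CompareParams = field(default_factory=CompareParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = CompareParams(**raw.pop("params", {}))
        return cls(**raw, params=params)


def _read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       usecols=[0, 1, 2],
                       names=["chrom", "start", "end"],
                       dtype={"chrom": str})


def run_compare(config: RunConfig) -> dict:
    """Read inputs, run ``compare_study``, write the JSON report and
    return it."""
    import os
    sizes = read_chrom_sizes(config.chrom_sizes)
    grid = BinnedGenome(sizes, config.params.tad_bin)
    pairs_1 = pd.read_csv(config.pairs_1, sep="\t", header=None,
                          names=["chrom", "pos1", "pos2"],
                          dtype={"chrom": str})
    pairs_2 = pd.read_csv(config.pairs_2, sep="\t", header=None,
                          names=["chrom", "pos1", "pos2"],
                          dtype={"chrom": str})
    m1 = _pairs_to_matrix(pairs_1, grid)
    m2 = _pairs_to_matrix(pairs_2, grid)
    genes = pd.read_csv(config.genes, sep="\t", dtype={"chrom": str})
    mark_peaks = {"H3K27ac": _read_bed(config.h3k27ac_peaks),
                  "H3K27me3": _read_bed(config.h3k27me3_peaks)}
    dhs = _read_bed(config.dhs)
    report = compare_study(m1, m2, genes, mark_peaks, dhs,
                           pairs_1, pairs_2, config.params)
    os.makedirs(config.out_dir, exist_ok=True)
    report_to_json(report, os.path.join(config.out_dir, "report.json"))
    return report


def _pairs_to_matrix(pairs: pd.DataFrame, grid: BinnedGenome):
    from .contact import ContactMatrix
    data = {c: np.zeros((grid.n_bins(c), grid.n_bins(c)))
            for c in grid.chroms}
    for c, sub in pairs.groupby("chrom", sort=False):
        if c not in data:
            continue
        b1 = np.minimum(sub["pos1"].to_numpy() // grid.bin_size,
                        grid.n_bins(c) - 1)
        b2 = np.minimum(sub["pos2"].to_numpy() // grid.bin_size,
                        grid.n_bins(c) - 1)
        np.add.at(data[c], (b1, b2), 1.0)
        off = b1 != b2
        np.add.at(data[c], (b2[off], b1[off]), 1.0)
    return ContactMatrix(grid, data)


def simulated_inputs(study: SimulatedStudy):
    """Unpack a SimulatedStudy into ``compare_study`` arguments."""
    return dict(
        matrix_1=study.matrix_1, matrix_2=study.matrix_2,
        genes=study.truth_2.genes,   # carries the two-condition FPKM pair
        mark_peaks=study.truth_1.mark_peaks,
        dhs=study.truth_2.dhs,
        pairs_1=study.pairs_1, pairs_2=study.pairs_2,
    )
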