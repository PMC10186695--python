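"""Insulation scores, boundary calling, consensus, differential TADs."""

import numpy as np
import pandas as pd
import pytest

import chromoscale.contact as cc
import chromoscale.tads as tm
from chromoscale.genome import BinnedGenome, SignalTrack


def _uniform_matrix(n=150, bin_size=5_000):
    grid = BinnedGenome({"chr1": n * bin_size}, bin_size)
    m = np.ones((n, n))
    np.fill_diagonal(m, 0.0)
    return cc.ContactMatrix(grid, {"chr1": m},
                            normalization_state="balanced")


class TestInsulationProfile:
    def test_uniform_matrix_combined_near_zero(self):
        cm = _uniform_matrix()
        prof = tm.insulation_profile(cm, 20_000, 100_000, 5_000)
        comb = prof.combined["chr1"]
        finite = comb[np.isfinite(comb)]
        assert np.abs(finite).max() < 0.5

    def test_two_bin_window_matches_direct_mean(self, balanced_5kb):
        _, bal = balanced_5kb
        prof = tm.insulation_profile(bal, 10_000, 20_000, 5_000)
        m = bal.data["chr1"]
        i = 200
        direct = m[i - 2:i, i:i + 2].mean()
        assert prof.raw[2]["chr1"][i] == pytest.approx(direct)

    def test_short_chromosome_skipped_with_warning(self):
        cm = _uniform_matrix(n=40)
        with pytest.warns(UserWarning, match="skipped"):
            prof = tm.insulation_profile(cm, 20_000, 300_000, 5_000)
        assert np.isnan(prof.combined["chr1"]).all()

    def test_planted_boundary_is_local_minimum(self, study, balanced_5kb):
        _, bal = balanced_5kb
        prof = tm.insulation_profile(bal)
        hits = total = 0
        for c in bal.grid.chroms:
            comb = prof.combined[c]
            for b in study.truth_1.boundaries[c]:
                window = comb[b - 2:b + 3]
                if not np.isfinite(window).all():
                    continue
                total += 1
                hits += window.argmin() in (1, 2, 3)
        assert hits / total > 0.9


class TestCallBoundaries:
    def test_monotone_in_thresholds(self, study, balanced_5kb):
        masked, bal = balanced_5kb
        prof = tm.insulation_profile(bal)
        base = tm.call_boundaries(prof, masked, delta_min=0.01, q_max=0.01)
        stricter_delta = tm.call_boundaries(prof, masked, delta_min=0.5,
                                            q_max=0.01)
        stricter_q = tm.call_boundaries(prof, masked, delta_min=0.01,
                                        q_max=1e-6)
        assert len(stricter_delta) <= len(base)
        assert len(stricter_q) <= len(base)


class TestSegmentTads:
    def test_two_boundaries_give_three_segments(self):
        grid = BinnedGenome({"chr1": 30 * 5_000}, 5_000)
        bs = tm.BoundarySet(grid, pd.DataFrame(
            {"chrom": "chr1", "bin": [10, 20], "score": 0.0,
             "delta": 1.0, "p": 0.0, "q": 0.0}))
        tads = tm.segment_tads(bs, grid)
        assert len(tads) == 3
        assert tads.table["end_segment"].tolist() == [True, False, True]

    def test_no_boundaries_whole_chromosome_flagged(self):
        grid = BinnedGenome({"chr1": 30 * 5_000}, 5_000)
        bs = tm.BoundarySet(grid, pd.DataFrame(
            columns=["chrom", "bin", "score", "delta", "p", "q"]))
        tads = tm.segment_tads(bs, grid)
        assert len(tads) == 1
        assert tads.table["end_segment"].iloc[0]

    def test_sizes_tile_chromosome(self):
        grid = BinnedGenome({"chr1": 123_456}, 5_000)
        bs = tm.BoundarySet(grid, pd.DataFrame(
            {"chrom": "chr1", "bin": [7, 13, 19], "score": 0.0,
             "delta": 1.0, "p": 0.0, "q": 0.0}))
        tads = tm.segment_tads(bs, grid)
        assert tads.table["size_bp"].sum() == 123_456


class TestConsensus:
    def _set(self, grid, bins):
        return tm.BoundarySet(grid, pd.DataFrame(
            {"chrom": "chr1", "bin": sorted(bins), "score": 0.0,
             "delta": 1.0, "p": 0.0, "q": 0.0}))

    def test_identical_sets_all_conserved(self):
        grid = BinnedGenome({"chr1": 500_000}, 5_000)
        s = self._set(grid, [10, 30, 50])
        out = tm.consensus_boundaries(s, s)
        assert out["n_conserved"] == 3
        assert out["n_specific_1"] == out["n_specific_2"] == 0

    def test_shift_threshold_edge(self):
        grid = BinnedGenome({"chr1": 500_000}, 5_000)
        s1 = self._set(grid, [20, 60])
        s2 = self._set(grid, [22, 63])     # offsets exactly 2 and 3
        out = tm.consensus_boundaries(s1, s2, shift_bins=2)
        assert out["n_conserved"] == 1
        assert out["n_specific_1"] == 1 and out["n_specific_2"] == 1

    def test_symmetric_conserved_count(self, study, balanced_5kb, depth_pair):
        masked, bal = balanced_5kb
        _, d2 = depth_pair
        masked2 = cc.mask_low_coverage(d2)
        bal2 = cc.kr_balance(masked2)
        b1 = tm.call_boundaries(tm.insulation_profile(bal), masked)
        b2 = tm.call_boundaries(tm.insulation_profile(bal2), masked2)
        ab = tm.consensus_boundaries(b1, b2)
        ba = tm.consensus_boundaries(b2, b1)
        assert ab["n_conserved"] == ba["n_conserved"]

    def test_strength_compare_shape_and_identity(self):
        grid = BinnedGenome({"chr1": 150 * 5_000}, 5_000)
        m = np.ones((150, 150))
        np.fill_diagonal(m, 0)
        cm = cc.ContactMatrix(grid, {"chr1": m},
                              normalization_state="balanced")
        prof = tm.insulation_profile(cm, 20_000, 100_000, 5_000)
        s1 = self._set(grid, [40, 80])
        s2 = self._set(grid, [40, 110])
        consensus = tm.consensus_boundaries(s1, s2)
        tab = tm.boundary_strength_compare(prof, prof, consensus)
        assert len(tab) == 4
        con = tab[tab["class"] == "conserved"].set_index("condition")
        assert con.loc[1, "mean_score"] == pytest.approx(
            con.loc[2, "mean_score"])


class TestDifferentialTads:
    def test_identity_all_conserved(self, study, depth_pair, balanced_5kb):
        masked, bal = balanced_5kb
        d1, _ = depth_pair
        b1 = tm.call_boundaries(tm.insulation_profile(bal), masked)
        tads = tm.segment_tads(b1, bal.grid)
        out = tm.differential_tads(tads, d1, d1)
        assert (out["label"] != "changed").all()

    def test_planted_intra_change_detected(self, depth_pair, balanced_5kb):
        masked, bal = balanced_5kb
        d1, _ = depth_pair
        b1 = tm.call_boundaries(tm.insulation_profile(bal), masked)
        tads = tm.segment_tads(b1, bal.grid)
        altered = d1.copy()
        row = tads.table.iloc[4]
        sl = slice(row.start_bin, row.end_bin)
        # a genuinely changed TAD alters intra and flank contacts alike
        altered.data[row.chrom][sl, :] *= 2.0
        altered.data[row.chrom][:, sl] *= 2.0
        out = tm.differential_tads(tads, d1, altered, mode="all")
        assert out.iloc[4]["label"] == "changed"
        intra_only = d1.copy()
        intra_only.data[row.chrom][sl, sl] *= 2.0
        out_one = tm.differential_tads(tads, d1, intra_only, mode="one")
        assert out_one.iloc[4]["label"] == "changed"

    def test_mode_one_is_superset_of_mode_all(self, depth_pair,
                                              balanced_5kb):
        masked, bal = balanced_5kb
        d1, d2 = depth_pair
        b1 = tm.call_boundaries(tm.insulation_profile(bal), masked)
        tads = tm.segment_tads(b1, bal.grid)
        out_all = tm.differential_tads(tads, d1, d2, mode="all")
        out_one = tm.differential_tads(tads, d1, d2, mode="one")
        changed_all = set(out_all.index[out_all["label"] == "changed"])
        changed_one = set(out_one.index[out_one["label"] == "changed"])
        assert changed_all <= changed_one


class TestAnnotateByMark:
    def _tads(self, n_tads=100, bins_per_tad=5):
        grid = BinnedGenome({"chr1": n_tads * bins_per_tad * 5_000}, 5_000)
        rows = [("chr1", k * bins_per_tad, (k + 1) * bins_per_tad,
                 bins_per_tad * 5_000, False) for k in range(n_tads)]
        return tm.TADSet(grid, pd.DataFrame(
            rows, columns=["chrom", "start_bin", "end_bin", "size_bp",
                           "end_segment"]))

    def test_no_peaks_means_no_enrichment(self):
        tads = self._tads()
        sig = SignalTrack(tads.grid,
                          {"chr1": np.linspace(0, 1,
                                               tads.grid.n_bins("chr1"))})
        out = tm.annotate_tads_by_mark(
            tads, pd.DataFrame(columns=["chrom", "start", "end"]), sig,
            0.25, "mark")
        assert not out.table["mark_enriched"].any()

    def test_quantile_arithmetic_hundred_tads(self):
        tads = self._tads(n_tads=100)
        n = tads.grid.n_bins("chr1")
        sig = SignalTrack(tads.grid, {"chr1": np.arange(n, dtype=float)})
        peaks = pd.DataFrame([("chr1", 0, tads.grid.chrom_sizes["chr1"])],
                             columns=["chrom", "start", "end"])
        out = tm.annotate_tads_by_mark(tads, peaks, sig, 0.25, "mark")
        assert out.table["mark_enriched"].sum() == 25
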