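"""Contact-matrix I/O, normalisation and comparison statistics."""

import numpy as np
import pandas as pd
import pytest

import chromoscale.contact as cc
from chromoscale.genome import BinnedGenome


# -- I/O ---------------------------------------------------------------
class TestReadContacts:
    def test_pair_binning_arithmetic(self, tmp_path, small_grid):
        path = tmp_path / "pairs.tsv"
        path.write_text("chr1\t1500\t7500\n")
        m = cc.read_contacts(path, small_grid)
        assert m.data["chr1"][0, 1] == 1
        assert m.data["chr1"][1, 0] == 1
        assert m.total() == 1

    def test_empty_file_gives_zero_matrix(self, tmp_path, small_grid):
        path = tmp_path / "pairs.tsv"
        path.write_text("")
        m = cc.read_contacts(path, small_grid)
        assert m.total() == 0

    def test_interchromosomal_discarded_with_tally(self, tmp_path, small_grid):
        path = tmp_path / "pairs.tsv"
        path.write_text("chr1\t1000\tchr2\t2000\nchr1\t1000\tchr1\t9000\n")
        m = cc.read_contacts(path, small_grid)
        assert m.n_interchromosomal_discarded == 1
        assert m.total() == 1

    def test_unknown_chromosome_rejected(self, tmp_path, small_grid):
        path = tmp_path / "pairs.tsv"
        path.write_text("chrX\t100\t200\n")
        with pytest.raises(ValueError, match="chrX"):
            cc.read_contacts(path, small_grid)

    def test_malformed_line_reports_line_number(self, tmp_path, small_grid):
        path = tmp_path / "pairs.tsv"
        path.write_text("chr1\t100\t200\nchr1\tabc\t200\n")
        with pytest.raises(ValueError, match="line 2"):
            cc.read_contacts(path, small_grid)

    def test_coo_round_trip(self, tmp_path, random_symmetric):
        path = tmp_path / "m.coo"
        random_symmetric.write_coo(path)
        back = cc.read_contacts(path, random_symmetric.grid)
        np.testing.assert_allclose(back.data["chr1"],
                                   random_symmetric.data["chr1"], rtol=1e-6)


# -- masking and depth normalisation -----------------------------------
class TestMaskAndDepth:
    def test_uniform_matrix_keeps_all_bins(self, small_grid):
        n = small_grid.n_bins("chr1")
        m = cc.ContactMatrix(small_grid, {
            "chr1": np.ones((n, n)),
            "chr2": np.ones((small_grid.n_bins("chr2"),) * 2)})
        masked = cc.mask_low_coverage(m)
        assert masked.mask["chr1"].all()

    def test_zero_row_masked_and_scale_free(self, random_symmetric):
        m = random_symmetric.copy()
        m.data["chr1"][5, :] = 0.0
        m.data["chr1"][:, 5] = 0.0
        masked = cc.mask_low_coverage(m)
        assert not masked.mask["chr1"][5]
        masked10 = cc.mask_low_coverage(m.scale(10.0))
        np.testing.assert_array_equal(masked.mask["chr1"],
                                      masked10.mask["chr1"])

    def test_all_masked_rejected(self, small_grid):
        m = cc.ContactMatrix(small_grid, {})
        with pytest.raises(ValueError):
            cc.mask_low_coverage(m)

    def test_depth_normalize_totals_and_identity(self, random_symmetric):
        a = random_symmetric
        b = random_symmetric.scale(2.0)
        na, nb = cc.depth_normalize(a, b)
        assert na.total() == pytest.approx(nb.total())
        assert na.total() == pytest.approx(a.total())
        ia, ib = cc.depth_normalize(a, a.copy())
        np.testing.assert_allclose(ia.data["chr1"], a.data["chr1"])

    def test_depth_normalize_preserves_oe(self, random_symmetric):
        a = random_symmetric
        b = random_symmetric.scale(3.7)
        na, nb = cc.depth_normalize(a, b)
        oe_before = cc.oe_transform(cc.kr_balance(cc.mask_low_coverage(b)))
        oe_after = cc.oe_transform(cc.kr_balance(cc.mask_low_coverage(nb)))
        np.testing.assert_allclose(oe_before.data["chr1"],
                                   oe_after.data["chr1"], rtol=1e-6)


# -- KR balancing ------------------------------------------------------
class TestKRBalance:
    def test_uniform_matrix_gives_constant_weights(self, small_grid):
        n = small_grid.n_bins("chr1")
        m = np.ones((n, n))
        np.fill_diagonal(m, 0)
        cm = cc.ContactMatrix(small_grid, {
            "chr1": m, "chr2": np.ones((small_grid.n_bins("chr2"),) * 2)})
        bal = cc.kr_balance(cc.mask_low_coverage(cm))
        w = bal.balance_weights["chr1"]
        w = w[np.isfinite(w)]
        assert np.allclose(w, w[0], rtol=1e-4)

    def test_row_sum_cv_below_tolerance(self, random_symmetric):
        bal = cc.kr_balance(cc.mask_low_coverage(random_symmetric))
        keep = bal.mask["chr1"]
        rs = bal.data["chr1"][keep][:, keep].sum(axis=1)
        assert rs.std() / rs.mean() < 1e-6

    def test_idempotence(self, random_symmetric):
        once = cc.kr_balance(cc.mask_low_coverage(random_symmetric))
        twice = cc.kr_balance(once)
        np.testing.assert_allclose(twice.data["chr1"], once.data["chr1"],
                                   rtol=1e-4)


# -- O/E ---------------------------------------------------------------
class TestOETransform:
    def test_diagonal_means_are_one(self, random_symmetric):
        oe = cc.oe_transform(cc.kr_balance(
            cc.mask_low_coverage(random_symmetric)))
        m = oe.data["chr1"]
        for d in range(1, 20):
            diag = np.diagonal(m, offset=d)
            assert np.nanmean(diag) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, random_symmetric):
        bal = cc.kr_balance(cc.mask_low_coverage(random_symmetric))
        oe1 = cc.oe_transform(bal)
        oe2 = cc.oe_transform(bal.scale(7.0))
        np.testing.assert_allclose(oe1.data["chr1"], oe2.data["chr1"],
                                   rtol=1e-9)

    def test_distance_profile_input_gives_ones(self, small_grid):
        n = small_grid.n_bins("chr1")
        idx = np.arange(n)
        m = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
        np.fill_diagonal(m, 0.0)
        cm = cc.ContactMatrix(small_grid, {
            "chr1": m, "chr2": np.ones((small_grid.n_bins("chr2"),) * 2)},
            normalization_state="balanced")
        oe = cc.oe_transform(cm)
        vals = oe.data["chr1"][np.triu_indices(n, k=1)]
        np.testing.assert_allclose(vals[np.isfinite(vals)], 1.0)


# -- log2 ratio map ----------------------------------------------------
class TestLog2Ratio:
    def test_identical_matrices_give_zero(self, random_symmetric):
        maps = cc.log2_ratio_map(random_symmetric, random_symmetric)
        assert np.nanmax(np.abs(maps["chr1"])) == 0.0

    def test_antisymmetry_under_swap(self, random_symmetric):
        other = random_symmetric.copy()
        other.data["chr1"] = other.data["chr1"][::-1, ::-1].copy()
        ab = cc.log2_ratio_map(random_symmetric, other)
        ba = cc.log2_ratio_map(other, random_symmetric)
        np.testing.assert_allclose(ab["chr1"], -ba["chr1"], atol=1e-12)

    def test_lost_loop_pixels_negative(self, study, depth_pair):
        d1, d2 = depth_pair
        maps = cc.log2_ratio_map(d2, d1)  # condition 2 over condition 1
        vals = [np.nanmean(maps[c][bi - 1:bi + 2, bj - 1:bj + 2])
                for c, bi, bj in study.changes.loops_lost]
        assert np.mean(vals) < 0


# -- SCC ---------------------------------------------------------------
class TestSCC:
    def test_self_correlation_is_one(self, random_symmetric):
        assert cc.scc(random_symmetric, random_symmetric) == pytest.approx(1.0)

    def test_scale_invariance(self, study):
        a = study.matrix_1
        b = study.matrix_2
        assert cc.scc(a, b) == pytest.approx(cc.scc(a.scale(5.0), b),
                                             abs=1e-9)

    def test_too_few_strata_rejected(self):
        grid = BinnedGenome({"chr1": 10_000}, 5_000)
        m = cc.ContactMatrix(grid, {"chr1": np.ones((2, 2))})
        with pytest.raises(ValueError):
            cc.scc(m, m)


# -- windowed structural similarity ------------------------------------
class TestWindowSimilarity:
    def test_identical_matrices(self, random_symmetric):
        bal = cc.kr_balance(cc.mask_low_coverage(random_symmetric))
        tab = cc.window_similarity_z(bal, bal, window_bp=50_000,
                                     step_bp=25_000)
        assert np.allclose(tab["ssim"].dropna(), 1.0)
        assert np.allclose(tab["z"].dropna(), 0.0)  # sd 0 handled as z=0

    def test_ssim_symmetric(self, depth_pair):
        d1, d2 = depth_pair
        t12 = cc.window_similarity_z(d1, d2, window_bp=500_000,
                                     step_bp=250_000)
        t21 = cc.window_similarity_z(d2, d1, window_bp=500_000,
                                     step_bp=250_000)
        np.testing.assert_allclose(t12["ssim"], t21["ssim"], rtol=1e-9)

    def test_window_below_three_bins_rejected(self, random_symmetric):
        with pytest.raises(ValueError):
            cc.window_similarity_z(random_symmetric, random_symmetric,
                                   window_bp=10_000, step_bp=5_000)


# -- promoter-distal change --------------------------------------------
class TestPromoterDistal:
    def test_identical_matrices_give_zero(self, study, depth_pair):
        d1, _ = depth_pair
        tab = cc.promoter_distal_change(d1, d1, study.truth_1.genes)
        assert np.allclose(tab["mean_log2_change"].dropna(), 0.0)

    def test_planted_band_fold_recovered(self, study, depth_pair):
        d1, d2 = depth_pair
        boosted = d2.copy()
        for c in boosted.grid.chroms:
            n = boosted.grid.n_bins(c)
            idx = np.arange(n)
            dist = np.abs(idx[:, None] - idx[None, :]) * 5_000
            band = (dist >= 50_000) & (dist < 100_000)
            boosted.data[c] = np.where(band, boosted.data[c] * 2,
                                       boosted.data[c])
        tab = cc.promoter_distal_change(boosted, d2, study.truth_2.genes)
        val = tab.loc[(tab["gene_set"] == "all")
                      & (tab["distance_class"] == "50kb-100kb"),
                      "mean_log2_change"].iloc[0]
        assert val == pytest.approx(1.0, abs=0.1)
        other = tab.loc[(tab["gene_set"] == "all")
                        & (tab["distance_class"] != "50kb-100kb"),
                        "mean_log2_change"]
        assert np.nanmax(np.abs(other)) < 0.1

    def test_strand_flip_moves_promoter_bin(self):
        grid = BinnedGenome({"chr1": 200_000}, 5_000)
        n = grid.n_bins("chr1")
        rng = np.random.default_rng(0)
        m = rng.poisson(5.0, (n, n)).astype(float)
        m = m + m.T
        cm = cc.ContactMatrix(grid, {"chr1": m})
        plus = pd.DataFrame([{"gene_id": "g", "chrom": "chr1",
                              "start": 100_000, "end": 110_000,
                              "strand": "+", "deg_label": "ns"}])
        minus = plus.assign(strand="-")
        cm2 = cm.copy()
        # make the two candidate promoter bins distinguishable: boost the
        # row of the minus-strand promoter bin (111 kb -> bin 22) only
        cm2.data["chr1"][22, :] *= 4
        cm2.data["chr1"][:, 22] *= 4
        classes = [(20_000, 50_000)]
        t_plus = cc.promoter_distal_change(cm2, cm, plus, classes)
        t_minus = cc.promoter_distal_change(cm2, cm, minus, classes)
        assert t_plus["n_genes"].iloc[0] == 1
        assert t_minus["n_genes"].iloc[0] == 1
        # only the minus-strand promoter sees the boosted row
        assert t_minus["mean_log2_change"].iloc[0] > \
            t_plus["mean_log2_change"].iloc[0] + 0.5
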