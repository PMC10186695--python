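"""Interval overlaps, Fisher and permutation enrichment, DEG reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromoscale.integration as integ
from chromoscale.genome import BinnedGenome


class TestOverlapGenes:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                           "end", "strand", "fpkm_1",
                                           "fpkm_2", "deg_label"])

    def test_promoter_overlaps_anchor(self):
        genes = self._genes([("g1", "chr1", 2_980, 4_000, "+",
                              1.0, 1.0, "ns")])
        anchors = pd.DataFrame([("chr1", 2_900, 3_400)],
                               columns=["chrom", "start", "end"])
        # promoter [980, 2980) meets anchor [2900, 3400) over [2900, 2980)
        out = integ.overlap_genes(anchors, genes, mode="promoter")
        assert out == [["g1"]]

    def test_minus_strand_promoter_at_end_side(self):
        genes = self._genes([("g1", "chr1", 1_000, 5_000, "-",
                              1.0, 1.0, "ns")])
        proms = integ.promoter_intervals(genes)
        assert proms.iloc[0]["start"] == 5_000
        assert proms.iloc[0]["end"] == 7_000

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(7)
        genes = self._genes([
            (f"g{i}", "chr1", s, s + rng.integers(500, 3_000), "+",
             1.0, 1.0, "ns")
            for i, s in enumerate(rng.integers(0, 100_000, 60))])
        feats = pd.DataFrame(
            [("chr1", s, s + rng.integers(200, 5_000))
             for s in rng.integers(0, 100_000, 40)],
            columns=["chrom", "start", "end"])
        fast = integ.overlap_genes(feats, genes, mode="gene_body")
        for k, row in enumerate(feats.itertuples(index=False)):
            brute = [g.gene_id for g in genes.itertuples(index=False)
                     if g.start < row.end and g.end > row.start]
            assert sorted(fast[k]) == sorted(brute)


class TestFisherEnrichment:
    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        tables = []
        for n_fg in range(1, 9):
            for n_bg in range(n_fg, 16):
                for k_fg in range(n_fg + 1):
                    for k_bg in range(n_bg + 1):
                        tables.append((k_fg, n_fg, k_bg, n_bg))
        for _ in range(300):
            n_fg = int(rng.integers(1, 200))
            n_bg = int(rng.integers(1, 200))
            tables.append((int(rng.integers(0, n_fg + 1)), n_fg,
                           int(rng.integers(0, n_bg + 1)), n_bg))
        for k_fg, n_fg, k_bg, n_bg in tables:
            res = integ.fisher_enrichment(k_fg, n_fg, k_bg, n_bg)
            oracle = _fisher_oracle(k_fg, n_fg - k_fg, k_bg, n_bg - k_bg)
            assert res.p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_rate_equal_background_fold_one(self):
        res = integ.fisher_enrichment(10, 100, 50, 500)
        assert res.fold == pytest.approx(1.0)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            integ.fisher_enrichment(0, 0, 5, 10)

    def test_exclude_foreground_flag(self):
        res = integ.fisher_enrichment(5, 10, 20, 100,
                                      exclude_foreground=True)
        assert res.k_bg == 15 and res.n_bg == 90


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric summation of all tables with
    probability <= that of the observed table."""
    import math
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def logp(x):
        return (math.lgamma(row1 + 1) - math.lgamma(x + 1)
                - math.lgamma(row1 - x + 1)
                + math.lgamma(n - row1 + 1) - math.lgamma(col1 - x + 1)
                - math.lgamma(n - row1 - col1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(col1 + 1)
                   - math.lgamma(n - col1 + 1)))

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


class TestPermutationEnrichment:
    def test_saturating_targets_not_significant(self):
        sizes = {"chr1": 100_000}
        queries = pd.DataFrame([("chr1", 10_000, 11_000),
                                ("chr1", 50_000, 51_000)],
                               columns=["chrom", "start", "end"])
        targets = pd.DataFrame([("chr1", 0, 100_000)],
                               columns=["chrom", "start", "end"])
        res = integ.permutation_enrichment(queries, targets, sizes,
                                           n_perm=100, seed=0)
        assert res.fg_rate == 1.0
        assert res.p == pytest.approx(1.0)

    def test_interval_longer_than_chromosome_rejected(self):
        sizes = {"chr1": 10_000}
        q = pd.DataFrame([("chr1", 0, 20_000)],
                         columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            integ.permutation_enrichment(q, q, sizes, n_perm=100, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        sizes = {"chr1": 1_000_000}
        qs = rng.integers(0, 900_000, 30)
        q = pd.DataFrame({"chrom": "chr1", "start": qs, "end": qs + 500})
        ts = rng.integers(0, 900_000, 50)
        t = pd.DataFrame({"chrom": "chr1", "start": ts, "end": ts + 500})
        a = integ.permutation_enrichment(q, t, sizes, n_perm=150, seed=42)
        b = integ.permutation_enrichment(q, t, sizes, n_perm=150, seed=42)
        assert a.p == b.p

    def test_planted_overlap_maximally_significant(self):
        sizes = {"chr1": 2_000_000}
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 1_900_000, 40)
        q = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 2_000})
        res = integ.permutation_enrichment(q, q, sizes, n_perm=999, seed=3)
        assert res.p <= 0.001


class TestAnchorDhs:
    def _loops(self):
        return pd.DataFrame([{
            "chrom": "chr1", "start1": 100_000, "end1": 105_000,
            "start2": 400_000, "end2": 405_000, "distance": 300_000.0}])

    def test_exact_match_fraction_one_profile_peaked(self):
        dhs = pd.DataFrame([("chr1", 100_000, 105_000),
                            ("chr1", 400_000, 405_000)],
                           columns=["chrom", "start", "end"])
        frac, profile = integ.anchor_dhs_overlap(self._loops(), dhs)
        assert frac == 1.0
        mean = profile.mean(axis=0)
        center = len(mean) // 2
        assert mean[center - 3:center + 3].sum() > mean[:10].sum()

    def test_no_dhs_fraction_zero(self):
        dhs = pd.DataFrame(columns=["chrom", "start", "end"])
        frac, _ = integ.anchor_dhs_overlap(self._loops(), dhs)
        assert frac == 0.0


class TestReports:
    def _genes(self, n=100, deg_every=10):
        starts = np.arange(n) * 10_000
        labels = ["up" if i % deg_every == 0 else "ns" for i in range(n)]
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)], "chrom": "chr1",
            "start": starts, "end": starts + 2_000, "strand": "+",
            "fpkm_1": 1.0, "fpkm_2": 1.0, "deg_label": labels})

    def test_reorg_union_disjoint_and_overlapping(self):
        genes = self._genes()
        degs = genes[genes["deg_label"] == "up"]
        r1 = pd.DataFrame([("chr1", 0, 2_000)],
                          columns=["chrom", "start", "end"])
        r2 = pd.DataFrame([("chr1", 100_000, 102_000)],
                          columns=["chrom", "start", "end"])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        disjoint = integ.reorg_deg_summary(r1, r2, empty, genes)
        assert disjoint["n_deg_reorganized"] == 2
        overlapping = integ.reorg_deg_summary(r1, r1, empty, genes)
        assert overlapping["n_deg_reorganized"] == 1

    def test_boundary_report_counts_consistent(self):
        genes = self._genes()
        grid = BinnedGenome({"chr1": 1_000_000}, 5_000)
        consensus = {"conserved": [], "specific_1": [("chr1", 10)],
                     "specific_2": [("chr1", 50), ("chr1", 100)]}
        out = integ.boundary_deg_report(consensus, genes, grid,
                                        flank_bins=2)
        assert out["dynamic"]["n_genes"] <= \
            out["lost"]["n_genes"] + out["gained"]["n_genes"]
        assert out["background"]["n_genes"] == len(genes)

    def test_no_degs_gives_unit_or_nan_enrichment(self):
        genes = self._genes(deg_every=10**9)   # no DEGs at all
        grid = BinnedGenome({"chr1": 1_000_000}, 5_000)
        consensus = {"conserved": [], "specific_1": [("chr1", 10)],
                     "specific_2": []}
        out = integ.boundary_deg_report(consensus, genes, grid)
        assert out["lost"]["n_deg"] == 0
        fold = out["lost"]["up_down_fold_vs_background"]
        assert np.isnan(fold)
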