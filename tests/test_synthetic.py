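"""Synthetic-data generator: determinism, conservation, planted structure."""

import numpy as np
import pytest

from chromoscale.synthetic import (ArchitectureConfig, expected_intensity,
                                   generate_architecture, perturb_condition,
                                   sample_contacts)


def _small(**kw):
    base = dict(chrom_sizes={"chr1": 1_500_000, "chr2": 1_000_000},
                depth=500_000, n_loops=6, compartment_block_mean=40,
                genes_per_mb=80, seed=11)
    base.update(kw)
    return ArchitectureConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(switch_fraction=1.5), dict(loop_loss_fraction=-0.1),
        dict(depth=-1), dict(tad_enrichment=0.5),
        dict(chrom_sizes={"chr1": 20_000}),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            _small(**bad)

    def test_chromosome_shorter_than_block_rejected(self):
        cfg = _small(chrom_sizes={"chr1": 100_000},
                     compartment_block_mean=100)
        with pytest.raises(ValueError, match="compartment block"):
            generate_architecture(cfg)


class TestGenerateArchitecture:
    def test_deterministic_given_seed(self):
        a = generate_architecture(_small())
        b = generate_architecture(_small())
        for c in a.grid.chroms:
            np.testing.assert_array_equal(a.compartment_labels[c],
                                          b.compartment_labels[c])
            np.testing.assert_array_equal(a.boundaries[c], b.boundaries[c])
        assert a.loops == b.loops
        assert a.genes.equals(b.genes)

    def test_no_loops_when_requested(self):
        truth = generate_architecture(_small(n_loops=0))
        assert truth.loops == []

    def test_boundaries_sorted_and_interior(self):
        truth = generate_architecture(_small())
        for c in truth.grid.chroms:
            b = truth.boundaries[c]
            assert np.all(np.diff(b) > 0)
            assert b.min() > 0 and b.max() < truth.grid.n_bins(c)

    def test_most_genes_in_a_compartment(self):
        truth = generate_architecture(_small())
        in_a = 0
        for row in truth.genes.itertuples(index=False):
            mid = (row.start + row.end) // 2
            b = truth.grid.bin_index(row.chrom, mid)
            in_a += truth.compartment_labels[row.chrom][b] == "A"
        assert 0.6 < in_a / len(truth.genes) < 0.8

    def test_deg_labels_follow_log2fc_rule(self):
        genes = generate_architecture(_small()).genes
        lfc = np.log2(np.maximum(genes["fpkm_2"], 0.01)
                      / np.maximum(genes["fpkm_1"], 0.01))
        expect = np.where(lfc > 1, "up", np.where(lfc < -1, "down", "ns"))
        assert (genes["deg_label"] == expect).all()

    def test_dhs_cover_all_loop_anchors(self):
        truth = generate_architecture(_small())
        dhs = truth.dhs
        for c, bi, bj in truth.loops:
            for b in (bi, bj):
                lo = truth.grid.bin_start(c, b)
                hi = truth.grid.bin_end(c, b)
                sel = dhs[(dhs["chrom"] == c) & (dhs["start"] < hi)
                          & (dhs["end"] > lo)]
                assert len(sel) >= 1


class TestExpectedIntensity:
    def test_structureless_depends_on_distance_only(self):
        cfg = _small(compartment_amplitude=0.0, tad_enrichment=1.0,
                     n_loops=0)
        rates = expected_intensity(generate_architecture(cfg), cfg)
        m = rates["chr1"]
        for d in (1, 5, 40):
            diag = np.diagonal(m, offset=d)
            assert np.allclose(diag, diag[0])

    def test_power_law_ratio(self):
        cfg = _small(compartment_amplitude=0.0, tad_enrichment=1.0,
                     n_loops=0, decay_exponent=1.0)
        m = expected_intensity(generate_architecture(cfg), cfg)["chr1"]
        assert m[0, 2] / m[0, 4] == pytest.approx(2.0)

    def test_same_tad_vs_straddling_ratio(self):
        cfg = _small(compartment_amplitude=0.0, n_loops=0,
                     tad_enrichment=3.0)
        truth = generate_architecture(cfg)
        m = expected_intensity(truth, cfg)["chr1"]
        b = int(truth.boundaries["chr1"][1])
        inside = m[b + 1, b + 3]          # same TAD, distance 2
        straddle = m[b - 1, b + 1]        # distance 2 across the boundary
        assert inside / straddle == pytest.approx(cfg.tad_enrichment)

    def test_symmetry_and_zero_diagonal(self):
        cfg = _small()
        m = expected_intensity(generate_architecture(cfg), cfg)["chr1"]
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diagonal(m) == 0)

    def test_loop_neighborhood_enrichment_factor(self):
        # structure-free background so the same-distance mean is the
        # loop-free rate (compartment/TAD factors would shift it)
        cfg = _small(loop_enrichment=5.0, compartment_amplitude=0.0,
                     tad_enrichment=1.0)
        truth = generate_architecture(cfg)
        rates = expected_intensity(truth, cfg)
        for c, bi, bj in truth.loops:
            m = rates[c]
            nb = m[bi - 1:bi + 2, bj - 1:bj + 2].mean()
            shift = 12
            bg = []
            for s in (-shift, shift):
                if 1 <= bi + s and bj + s < m.shape[0] - 1:
                    bg.append(m[bi + s - 1:bi + s + 2,
                                bj + s - 1:bj + s + 2].mean())
            assert nb / np.mean(bg) >= cfg.loop_enrichment * 0.9


class TestSampleContacts:
    def test_zero_depth_gives_zero_matrix(self, small_config):
        truth = generate_architecture(small_config)
        rates = expected_intensity(truth, small_config)
        m = sample_contacts(rates, 0, 1, small_config.grid)
        assert m.total() == 0

    def test_total_within_poisson_error(self, small_config):
        truth = generate_architecture(small_config)
        rates = expected_intensity(truth, small_config)
        m = sample_contacts(rates, small_config.depth, 2, small_config.grid)
        depth = small_config.depth
        assert abs(m.total() - depth) < 3 * np.sqrt(depth)

    def test_same_seed_identical(self, small_config):
        truth = generate_architecture(small_config)
        rates = expected_intensity(truth, small_config)
        a = sample_contacts(rates, 1e5, 7, small_config.grid)
        b = sample_contacts(rates, 1e5, 7, small_config.grid)
        for c in small_config.grid.chroms:
            np.testing.assert_array_equal(a.data[c], b.data[c])

    def test_pairs_fall_inside_their_bins(self, small_config):
        truth = generate_architecture(small_config)
        rates = expected_intensity(truth, small_config)
        m, pairs = sample_contacts(rates, 1e5, 3, small_config.grid,
                                   return_pairs=True)
        assert len(pairs) == m.total()
        for c, size in small_config.chrom_sizes.items():
            sub = pairs[pairs["chrom"] == c]
            assert sub["pos1"].between(0, size - 1).all()
            assert sub["pos2"].between(0, size - 1).all()


class TestPerturbCondition:
    def test_zero_fractions_identity(self):
        cfg = _small(switch_fraction=0.0, boundary_change_fraction=0.0,
                     loop_loss_fraction=0.0)
        t1 = generate_architecture(cfg)
        t2 = perturb_condition(t1, cfg)
        for c in t1.grid.chroms:
            np.testing.assert_array_equal(t1.compartment_labels[c],
                                          t2.compartment_labels[c])
            np.testing.assert_array_equal(t1.boundaries[c], t2.boundaries[c])
        assert set(t2.loops) == set(t1.loops)

    def test_full_loop_loss_empties_loops(self):
        cfg = _small(loop_loss_fraction=1.0, loop_gain_ratio=0.0)
        t1 = generate_architecture(cfg)
        t2 = perturb_condition(t1, cfg)
        assert t2.loops == []
        assert len(t2.changes.loops_lost) == len(t1.loops)

    def test_switched_fraction_within_one_block(self):
        cfg = _small(switch_fraction=0.2)
        t1 = generate_architecture(cfg)
        t2 = perturb_condition(t1, cfg)
        total = sum(t1.grid.n_bins(c) for c in t1.grid.chroms)
        switched = sum(t2.changes.switched_bins[c].sum()
                       for c in t1.grid.chroms)
        assert abs(switched / total - 0.2) < \
            cfg.compartment_block_mean / total * 3

    def test_a_to_b_bias(self):
        cfg = _small(switch_fraction=0.3, ab_bias=0.9, seed=2)
        t2 = perturb_condition(generate_architecture(cfg), cfg)
        a2b = sum(t2.changes.switched_a_to_b_bins[c].sum()
                  for c in cfg.grid.chroms)
        total = sum(t2.changes.switched_bins[c].sum()
                    for c in cfg.grid.chroms)
        assert a2b / total > 0.5

    def test_change_records_match_boundary_sets(self):
        cfg = _small(boundary_change_fraction=0.4)
        t1 = generate_architecture(cfg)
        t2 = perturb_condition(t1, cfg)
        for c in t1.grid.chroms:
            b1 = set(t1.boundaries[c].tolist())
            b2 = set(t2.boundaries[c].tolist())
            assert set(t2.changes.boundaries_lost[c].tolist()) == b1 - b2
            assert set(t2.changes.boundaries_gained[c].tolist()) == b2 - b1
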