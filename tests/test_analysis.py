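"""Representation analyses on synthetic spike data (no network needed)."""

import numpy as np
import pytest

from beeal.analysis import (binned_counts, change_in_activity,
                            contrast_regression, lfp, matrix_correlation,
                            pairwise_panel_correlation, pca_trajectory,
                            percept_activations, representation_correlation,
                            uniqueness_index)
from beeal.simulator import SpikeRecord


def make_record(rates_hz, duration=1000.0, seed=0, n_ln=0):
    """Poisson spike record with given per-PN rates."""
    rng = np.random.default_rng(seed)
    spikes = []
    for r in rates_hz:
        n = rng.poisson(r * duration / 1000.0)
        spikes.append(np.sort(rng.uniform(0, duration, n)))
    spikes += [np.array([])] * n_ln
    return SpikeRecord(n_pn=len(rates_hz), n_ln=n_ln, duration_ms=duration,
                       spikes=spikes)


class TestLFP:
    def test_single_and_identical_traces(self):
        v = np.linspace(-70, -50, 20)[:, None]
        assert np.array_equal(lfp(v, 1), v[:, 0])
        two = np.repeat(v, 2, axis=1)
        assert np.allclose(lfp(two, 2), v[:, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lfp(np.empty((10, 0)), 0)


class TestBinnedCounts:
    def test_empty_record_is_zero_matrix(self):
        rec = make_record([0.0] * 5)
        m = binned_counts(rec, 100.0, (0.0, 500.0))
        assert m.counts.shape == (5, 5) and not m.counts.any()

    def test_total_count_conserved(self):
        rec = make_record([20, 5, 40], seed=3)
        m = binned_counts(rec, 100.0, (0.0, 1000.0), normalize="none")
        in_window = sum(len(s) for s in rec.pn_spikes())
        assert m.counts.sum() == in_window == m.raw_total

    def test_uniform_spikes_give_equal_matrix(self):
        spikes = [np.arange(50.0, 1000.0, 100.0) for _ in range(3)]
        rec = SpikeRecord(n_pn=3, n_ln=0, duration_ms=1000.0, spikes=spikes)
        m = binned_counts(rec, 100.0, (0.0, 1000.0), normalize="none")
        assert np.all(m.counts == 1)

    def test_bin_must_tile_window(self):
        rec = make_record([10])
        with pytest.raises(ValueError):
            binned_counts(rec, 300.0, (0.0, 500.0))
        with pytest.raises(ValueError):
            binned_counts(rec, 600.0, (0.0, 500.0))

    def test_grand_sum_normalization(self):
        rec = make_record([20, 30], seed=1)
        m = binned_counts(rec, 100.0, (0.0, 1000.0))
        assert m.counts.sum() == pytest.approx(1.0)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        rec = make_record([10, 30, 50, 5], seed=2)
        assert representation_correlation(rec, rec, 100.0, (0, 1000)) == \
            pytest.approx(1.0)

    def test_symmetry(self):
        a = make_record([10, 30, 50, 5], seed=2)
        b = make_record([40, 10, 20, 35], seed=3)
        ab = representation_correlation(a, b, 100.0, (0, 1000))
        ba = representation_correlation(b, a, 100.0, (0, 1000))
        assert ab == pytest.approx(ba)

    def test_permutation_null_centered_at_zero(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(5, 60, 40)
        vals = []
        for k in range(30):
            a = make_record(rates, seed=100 + k)
            b = make_record(rng.permutation(rates), seed=200 + k)
            vals.append(representation_correlation(a, b, 100.0, (0, 1000)))
        assert abs(np.mean(vals)) < 0.1

    def test_zero_variance_bins_skipped(self):
        a = np.zeros((4, 3))
        a[:, 0] = [1, 2, 3, 4]
        b = np.zeros((4, 3))
        b[:, 0] = [1, 2, 3, 4.5]
        corr, skipped = matrix_correlation(a, b)
        assert skipped == 2
        assert corr == pytest.approx(np.corrcoef(a[:, 0], b[:, 0])[0, 1])

    def test_rate_structure_recovery(self):
        """Shared/unique Poisson rate designs produce the designed ordering
        of between-class correlations."""
        rng = np.random.default_rng(5)
        base = rng.uniform(10, 50, 30)
        # high-overlap pair: identical rates; low-overlap: disjoint support
        high_a, high_b = base, base
        low_a = np.where(np.arange(30) < 15, base, 1.0)
        low_b = np.where(np.arange(30) >= 15, base, 1.0)
        hi, lo = [], []
        for k in range(20):
            hi.append(representation_correlation(
                make_record(high_a, seed=k), make_record(high_b, seed=1000 + k),
                100.0, (0, 1000)))
            lo.append(representation_correlation(
                make_record(low_a, seed=k), make_record(low_b, seed=1000 + k),
                100.0, (0, 1000)))
        assert np.mean(hi) > np.mean(lo) + 0.3

    def test_panel_average_excludes_self_pairs(self):
        a = make_record([10, 20, 30], seed=0)
        b = make_record([30, 20, 10], seed=1)
        panel = {"x": [a], "y": [b]}
        v = pairwise_panel_correlation(panel, ["x"], ["y"], 100.0, (0, 1000))
        assert v == pytest.approx(
            representation_correlation(a, b, 100.0, (0, 1000)))
        assert np.isnan(pairwise_panel_correlation(panel, ["x"], ["x"],
                                                   100.0, (0, 1000)))


class TestPCA:
    def test_variance_ratios_valid(self):
        recs = [make_record(np.full(10, 20.0), seed=k) for k in range(4)]
        trajs, evr = pca_trajectory(recs, 100.0, 3, (0, 1000))
        assert evr.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)
        assert trajs[0].shape == (10, 3)

    def test_duplicate_trial_identical_trajectory(self):
        rec = make_record([10, 40, 20, 5, 35], seed=9)
        trajs, _ = pca_trajectory([rec, rec], 100.0, 2, (0, 1000))
        assert np.allclose(trajs[0], trajs[1])

    def test_separated_families_separate_in_pc_space(self):
        fam_a = [make_record([50] * 5 + [2] * 5, seed=k) for k in range(5)]
        fam_b = [make_record([2] * 5 + [50] * 5, seed=50 + k) for k in range(5)]
        trajs, _ = pca_trajectory(fam_a + fam_b, 100.0, 2, (0, 1000))
        cent_a = np.mean([t.mean(axis=0) for t in trajs[:5]], axis=0)
        cent_b = np.mean([t.mean(axis=0) for t in trajs[5:]], axis=0)
        spread = np.mean([np.linalg.norm(t.mean(axis=0) - cent_a)
                          for t in trajs[:5]])
        assert np.linalg.norm(cent_a - cent_b) > 2 * spread

    def test_too_many_components_rejected(self):
        recs = [make_record([10, 20], seed=0)]
        with pytest.raises(ValueError):
            pca_trajectory(recs, 100.0, 5, (0, 1000))


class TestContrastMetrics:
    def test_uniqueness_index_arithmetic(self):
        ui = uniqueness_index([2.0, 4.0, 0.0], [2.0, 2.0, 2.0])
        assert ui[0] == 0.0 and ui[1] == 1.0 and ui[2] == -1.0

    def test_undefined_units_flagged(self):
        ui = uniqueness_index([1.0, 1.0], [2.0, 0.0])
        assert np.isnan(ui[1])

    def test_change_in_activity_arithmetic(self):
        ch = change_in_activity([3.0, 4.5, 0.0], [3.0, 3.0, 3.0])
        assert ch[0] == 0.0 and ch[1] == 0.5 and ch[2] == -1.0

    def test_noiseless_line_recovers_slope(self):
        ui = np.array([-0.5, 0.0, 0.4, 1.0, 1.5])
        res = contrast_regression(ui, 0.7 * ui)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.7)

    def test_shuffled_pairing_has_low_r2(self):
        rng = np.random.default_rng(0)
        ui = rng.normal(size=200)
        res = contrast_regression(ui, rng.permutation(ui))
        assert res.r_squared < 0.05

    def test_invariant_to_unit_ordering(self):
        rng = np.random.default_rng(1)
        ui = rng.normal(size=10)
        ch = 0.3 * ui + rng.normal(0, 0.1, 10)
        perm = rng.permutation(10)
        a = contrast_regression(ui, ch)
        b = contrast_regression(ui[perm], ch[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            contrast_regression([0.1, np.nan, 0.3], [0.2, 0.1, np.nan])


class TestPerceptActivations:
    def test_rates_averaged_per_block_and_trial(self):
        spikes = [np.arange(0.0, 500.0, 10.0)] * 2 + [np.array([])] * 2
        rec = SpikeRecord(n_pn=4, n_ln=0, duration_ms=500.0, spikes=spikes)
        acts = percept_activations([rec, rec], 2, (0.0, 500.0))
        assert acts[0] == pytest.approx(100.0)  # 50 spikes / 0.5 s
        assert acts[1] == 0.0
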