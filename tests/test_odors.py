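"""Odor construction, stimulus waveforms, noise, and the synthetic
sensor dataset."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beeal.odors import (DEFAULT_WIDTH_RANGE, Odor, background_noise,
                         blend_to_odor, environment_case, make_odor_class,
                         percept_activation_profile, phpp_environment,
                         sensor_features_to_pulse, simple_environment,
                         stimulus_current, synthetic_sensor_dataset,
                         tile_percepts, zscore_sensor_features)


class TestPercepts:
    def test_tiling_partitions_population(self):
        percepts = tile_percepts(100, 7)
        assert percepts[0].lo == 0 and percepts[-1].hi == 100
        for a, b in zip(percepts, percepts[1:]):
            assert a.hi == b.lo

    def test_profile_peak_at_center_and_symmetry(self):
        prof = percept_activation_profile(0.4, 10, 25, peak=2.0, n_neurons=40)
        center = (10 + 24) // 2
        assert prof[center] == pytest.approx(2.0)
        assert prof[:10].sum() == 0 and prof[25:].sum() == 0
        left, right = prof[center - 5:center], prof[center + 1:center + 6][::-1]
        assert np.allclose(left, right)

    def test_wider_profile_activates_more_neurons(self):
        narrow = percept_activation_profile(0.1, 0, 14, n_neurons=14)
        wide = percept_activation_profile(0.372, 0, 14, n_neurons=14)
        for thr in (0.1, 0.3, 0.5):
            assert (wide > thr).sum() >= (narrow > thr).sum()
        assert (wide > 0.3).sum() > (narrow > 0.3).sum()

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            percept_activation_profile(0.0, 0, 10)


class TestOdorClasses:
    def test_simple_classes_share_two_percepts(self):
        env = simple_environment(seed=0)
        rew = env.by_reward("rewarded")[0]
        hab = env.by_reward("habituated")[0]
        assert len(rew.active_percepts) == 3
        assert len(set(rew.active_percepts) & set(hab.active_percepts)) == 2

    def test_one_odor_per_width_vector(self):
        odors = make_odor_class((0, 1, 2), [[0.3, 0.3, 0.3]] * 4, "rewarded", "A")
        assert len(odors) == 4
        assert odors[0].widths == odors[1].widths  # identical widths

    def test_duplicate_percepts_rejected(self):
        with pytest.raises(ValueError):
            make_odor_class((1, 1, 2), [[0.3, 0.3, 0.3]], "rewarded", "A")

    def test_unknown_reward_label_rejected(self):
        with pytest.raises(ValueError):
            Odor(name="x", class_label="A", reward="punished",
                 widths=(0.3, 0.0, 0.0))


class TestBlends:
    def test_printed_oci_width(self):
        env = phpp_environment()
        ph1 = env.by_class("PH")[0]
        assert ph1.widths[0] == pytest.approx(0.372)
        assert ph1.widths[6] == 0.0  # seventh percept inactive

    def test_proportions_become_widths(self):
        props = [0.2, 0.2, 0.2, 0.2, 0.1, 0.1]
        odor = blend_to_odor(props, "x", "PH", "rewarded")
        assert odor.widths[:6] == tuple(props)

    def test_degenerate_and_invalid_proportions(self):
        with pytest.raises(ValueError):
            blend_to_odor([0.0] * 6, "x", "PH", "rewarded")
        with pytest.raises(ValueError):
            blend_to_odor([0.5, 0.5, 0.2, 0, 0, 0], "x", "PH", "rewarded")
        with pytest.raises(ValueError):
            blend_to_odor([-0.1, 0.5, 0.6, 0, 0, 0], "x", "PH", "rewarded")

    def test_permutation_equivariance(self):
        props = np.array([0.3, 0.25, 0.2, 0.15, 0.06, 0.04])
        perm = [3, 1, 0, 5, 4, 2]
        a = blend_to_odor(props, "a", "PH", "rewarded")
        b = blend_to_odor(props[perm], "b", "PH", "rewarded")
        assert np.allclose(np.array(a.widths)[perm], np.array(b.widths)[:6].tolist())


class TestStimulusWaveform:
    def test_zero_before_onset(self):
        assert stimulus_current(99.9, 100.0, 1.0) == 0.0

    def test_rise_saturation_at_offset(self):
        v = stimulus_current(600.0, 100.0, 1.0)
        assert v == pytest.approx(1.0 - np.exp(-500.0 / 66.7), rel=1e-9)
        assert v == pytest.approx(0.99945, abs=1e-4)

    def test_decay_time_constant_after_offset(self):
        off = stimulus_current(600.0, 100.0, 1.0)
        later = stimulus_current(800.0, 100.0, 1.0)
        assert later / off == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_continuous_nonnegative_and_returns_to_baseline(self):
        t = np.linspace(0, 1700, 17001)
        w = stimulus_current(t, 100.0, 1.0)
        assert np.all(w >= 0)
        assert np.max(np.abs(np.diff(w))) < 2e-3  # no jumps at 0.1 ms steps
        assert w[-1] < 0.01  # < 1% of peak within 1 s of offset

    def test_negative_peak_rejected(self):
        with pytest.raises(ValueError):
            stimulus_current(0.0, 0.0, -1.0)


class TestSensorPulse:
    def test_proportionalities(self):
        p1, r1, d1 = sensor_features_to_pulse(1.0, 2e-3, 1e-3)
        p2, r2, d2 = sensor_features_to_pulse(2.0, 4e-3, 1e-3)
        assert p2 == pytest.approx(2 * p1)
        assert r2 == pytest.approx(r1 / 2)
        assert d2 == pytest.approx(d1)

    def test_reference_feature_scale_reproduces_standard_pulse(self):
        _, rise, decay = sensor_features_to_pulse(1.0, 1e-3, 1e-3)
        assert rise == pytest.approx(66.7)
        assert decay == pytest.approx(200.0)

    def test_nonpositive_ema_rejected(self):
        with pytest.raises(ValueError):
            sensor_features_to_pulse(1.0, 0.0, 1e-3)


class TestBackgroundNoise:
    def test_zero_amplitude_is_silent(self):
        rng = np.random.default_rng(0)
        assert not background_noise(rng, 100, 0.0).any()

    def test_sample_mean_near_zero(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([background_noise(rng, 1000, 0.5)
                                for _ in range(100)])
        assert abs(draws.mean()) < 3 * 0.5 / np.sqrt(draws.size)
        assert draws.std() == pytest.approx(0.5, rel=0.02)

    def test_reproducible_under_seed(self):
        a = background_noise(np.random.default_rng(7), 50, 1.0)
        b = background_noise(np.random.default_rng(7), 50, 1.0)
        assert np.array_equal(a, b)


class TestEnvironments:
    def test_simple_environment_widths_in_range(self):
        env = simple_environment(seed=3, n_odors_per_class=5)
        lo, hi = DEFAULT_WIDTH_RANGE
        for o in env.odors:
            w = np.array(o.widths)[list(o.active_percepts)]
            assert np.all((w >= lo) & (w <= hi))

    @pytest.mark.parametrize("case,c1,c2", [
        (1, "S", "T"), (2, "M", "N"), (3, "M", "S"), (4, "N", "S")])
    def test_case_class_structure(self, case, c1, c2):
        env1, env2 = environment_case(case, "pos", seed=0)
        assert env1.classes() == ["P", "Q"]
        assert env2.classes() == [c1, c2]
        # "pos" rewards the first Env2 class
        assert env2.by_class(c1)[0].reward == "rewarded"
        assert env2.by_class(c2)[0].reward == "habituated"

    def test_case1_is_disjoint_from_env1(self):
        env1, env2 = environment_case(1, "pos", seed=0)
        used1 = {p for o in env1.odors for p in o.active_percepts}
        used2 = {p for o in env2.odors for p in o.active_percepts}
        assert not used1 & used2

    def test_case2_fully_overlaps_env1(self):
        env1, env2 = environment_case(2, "neg", seed=0)
        assert {o.class_label: o.active_percepts for o in env2.odors[:1]}["M"] == \
            env1.odors[0].active_percepts

    def test_invalid_case_rejected(self):
        with pytest.raises(ValueError):
            environment_case(5, "pos", seed=0)
        with pytest.raises(ValueError):
            environment_case(1, "maybe", seed=0)


class TestSensorOdors:
    def test_environment_from_feature_table(self):
        from beeal.odors import sensor_odor_environment

        feat, lab = synthetic_sensor_dataset(seed=4, n_reps=3)
        env = sensor_odor_environment(feat, lab)
        assert len(env.odors) == 6 and env.n_percepts == 16
        assert len(env.by_reward("rewarded")) == 3
        o = env.odors[0]
        # strongest sensor reaches the normalized unit peak
        assert max(o.peak_scale) <= 1.0 + 1e-12
        assert all(t > 0 for t in o.tau_rise)

    def test_pulse_params_track_features(self):
        from beeal.odors import sensor_odor_environment

        feat, lab = synthetic_sensor_dataset(seed=4, n_reps=3)
        doubled = feat.copy()
        doubled["s0_ema_max_a001"] *= 2.0
        a = sensor_odor_environment(feat, lab).odors[0]
        b = sensor_odor_environment(doubled, lab).odors[0]
        assert b.tau_rise[0] == pytest.approx(a.tau_rise[0] / 2, rel=1e-6)
        assert b.tau_rise[1] == pytest.approx(a.tau_rise[1])


class TestSyntheticSensors:
    def test_shapes_and_labels(self):
        feat, lab = synthetic_sensor_dataset(seed=0, n_reps=4)
        assert feat.shape == (24, 16 * 8)
        assert (lab["reward"] == "rewarded").sum() == 12

    def test_zscore_normalization(self):
        feat, _ = synthetic_sensor_dataset(seed=0, n_reps=10)
        z = zscore_sensor_features(feat)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_templates_separated_beyond_jitter(self):
        feat, lab = synthetic_sensor_dataset(seed=1, n_reps=6, jitter=0.08)
        means = feat.groupby(lab["odor"].to_numpy()).mean()
        odors = means.index.tolist()
        for i, a in enumerate(odors):
            for b in odors[i + 1:]:
                dist = np.linalg.norm(means.loc[a] - means.loc[b])
                assert dist > 5 * 0.08

    def test_determinism(self):
        f1, _ = synthetic_sensor_dataset(seed=2, n_reps=2)
        f2, _ = synthetic_sensor_dataset(seed=2, n_reps=2)
        assert np.array_equal(f1.to_numpy(), f2.to_numpy())


@given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
@settings(max_examples=25, deadline=None)
def test_equal_blends_give_identical_inputs(w1, w2):
    """Blend odors with equal proportion vectors produce identical inputs."""
    from beeal.network import build_al_network
    from beeal.odors import odor_amplitudes

    topo = build_al_network(seed=0, n_glomeruli=2)
    props = np.array([w1, w2, 0.1, 0.1, 0.1, 0.1])
    props /= props.sum()
    a = blend_to_odor(props, "a", "PH", "rewarded")
    b = blend_to_odor(props.copy(), "b", "PH", "rewarded")
    pa, la = odor_amplitudes(a, topo)
    pb, lb = odor_amplitudes(b, topo)
    assert np.array_equal(pa, pb) and np.array_equal(la, lb)
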