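"""Trial execution, training protocols, record round trips."""

import copy

import numpy as np
import pytest

from beeal.odors import InputConfig, Odor, simple_environment
from beeal.simulator import (SimulationConfig, SpikeRecord, TrainingProtocol,
                             run_test_panel, run_training, run_trial,
                             split_seed)

CFG = SimulationConfig(trial_ms=600.0,
                       input=InputConfig(t_on=100.0))


@pytest.fixture(scope="module")
def env():
    return simple_environment(seed=11, n_odors_per_class=2)


class TestSpikeRecord:
    def test_spike_times_sorted_and_bounded(self, small_topology, env):
        rec = run_trial(small_topology, env.odors[0], CFG, seed=1)
        assert len(rec.spikes) == small_topology.n_neurons
        for s in rec.spikes:
            assert np.all(np.diff(s) > 0)
            if len(s):
                assert s[0] >= 0 and s[-1] <= rec.duration_ms

    def test_h5_round_trip(self, tmp_path, small_topology, env):
        rec = run_trial(small_topology, env.odors[0], CFG, seed=2)
        path = tmp_path / "rec.h5"
        rec.save_h5(path)
        back = SpikeRecord.load_h5(path)
        assert back.n_pn == rec.n_pn and back.n_ln == rec.n_ln
        for a, b in zip(rec.spikes, back.spikes):
            assert np.array_equal(a, b)
        assert np.array_equal(rec.voltages, back.voltages)
        assert back.meta["odor"] == rec.meta["odor"]

    def test_counts_in_window(self):
        rec = SpikeRecord(n_pn=2, n_ln=0, duration_ms=100.0,
                          spikes=[np.array([10.0, 20.0, 90.0]), np.array([])])
        assert rec.counts_in_window(0, 50).tolist() == [2, 0]


class TestRunTrial:
    def test_determinism(self, small_topology, env):
        a = run_trial(small_topology, env.odors[0], CFG, seed=3)
        b = run_trial(small_topology, env.odors[0], CFG, seed=3)
        assert [s.tolist() for s in a.spikes] == [s.tolist() for s in b.spikes]

    def test_null_odor_gives_background_rate(self, small_topology):
        null = Odor(name="null", class_label="none", reward="none",
                    widths=(0.0,) * 7)
        rec = run_trial(small_topology, null, CFG, seed=4)
        n_pn = small_topology.n_pn
        stim_counts = rec.counts_in_window(100.0, 600.0)[:n_pn]
        pre_counts = rec.counts_in_window(0.0, 100.0)[:n_pn]
        # odor window activity matches (quiescent) background
        assert stim_counts.sum() / 0.5 <= max(pre_counts.sum() / 0.1, 2.0)

    def test_activated_percepts_fire_during_pulse(self, small_topology, env):
        """At default calibration, at least half of the PNs in activated
        percepts emit a spike during the 500 ms odor pulse."""
        from beeal.odors import tile_percepts

        fracs = []
        for k, odor in enumerate(env.odors):
            rec = run_trial(small_topology, odor, CFG, seed=10 + k)
            counts = rec.counts_in_window(100.0, 600.0)[: small_topology.n_pn]
            mask = np.zeros(small_topology.n_pn, bool)
            for p in tile_percepts(small_topology.n_pn, odor.n_percepts):
                if odor.widths[p.id] > 0:
                    mask[p.lo:p.hi] = True
            fracs.append((counts[mask] > 0).mean())
        assert np.mean(fracs) >= 0.5

    def test_lfp_oscillates_during_odor(self, small_topology, env):
        """Odor-evoked LFP has more 5-60 Hz power than baseline."""
        from beeal.analysis import lfp

        cfg = SimulationConfig(trial_ms=1400.0, input=InputConfig(t_on=700.0))
        rec = run_trial(small_topology, env.odors[0], cfg, seed=5)
        sig = lfp(rec.voltages, small_topology.n_pn)

        def bandpower(x):
            x = x - x.mean()
            f = np.fft.rfftfreq(len(x), d=1e-3)
            p = np.abs(np.fft.rfft(x)) ** 2
            return p[(f >= 5) & (f <= 60)].sum()

        base, odor = sig[100:600], sig[750:1250]
        assert bandpower(odor) > 5 * bandpower(base)


class TestTraining:
    def test_mode_off_leaves_weights_untouched(self, small_topology, env):
        topo = copy.deepcopy(small_topology)
        proto = TrainingProtocol(environment=env, n_presentations=4,
                                 presentation_ms=600.0, mode="off")
        _, log = run_training(topo, proto, CFG, seed=6)
        assert len(log) == 4
        for name in ("lnpn", "lnln"):
            assert np.allclose(topo.facilitation[name].F, 1.0)

    def test_log_length_matches_presentations(self, small_topology, env):
        topo = copy.deepcopy(small_topology)
        proto = TrainingProtocol(environment=env, n_presentations=6,
                                 presentation_ms=600.0, mode="both")
        _, log = run_training(topo, proto, CFG, seed=7)
        assert len(log) == 6
        assert set(log["reward"]) <= {"rewarded", "habituated"}

    def test_training_increases_facilitation(self, small_topology, env):
        topo = copy.deepcopy(small_topology)
        proto = TrainingProtocol(environment=env, n_presentations=4,
                                 presentation_ms=600.0, mode="both")
        run_training(topo, proto, CFG, seed=8)
        mask = topo.masks["lnpn"]
        assert topo.facilitation["lnpn"].F[mask].mean() > 1.0

    def test_default_protocol_totals(self, env):
        proto = TrainingProtocol(environment=env)
        assert proto.n_presentations == 30
        assert proto.presentation_ms == 2000.0
        assert proto.total_ms == 60_000.0

    def test_rule_selected_by_odor_class(self, small_topology, env):
        """Rewarded presentations apply the presynaptic rule, habituated
        the postsynaptic one."""
        topo = copy.deepcopy(small_topology)
        proto = TrainingProtocol(environment=env, n_presentations=6,
                                 presentation_ms=600.0, mode="both")
        _, log = run_training(topo, proto, CFG, seed=9)
        modes = dict(zip(log["reward"], log["mode"]))
        assert modes.get("rewarded") == "pre_only"
        assert modes.get("habituated") == "post_only"


class TestFrozenTesting:
    def test_test_panel_never_mutates_weights(self, small_topology, env):
        topo = copy.deepcopy(small_topology)
        mask = topo.masks["lnpn"]
        topo.facilitation["lnpn"].F = np.where(mask, 1.7, 1.0)
        before = topo.facilitation["lnpn"].F.copy()
        run_test_panel(topo, env.odors[:2], CFG, seed=10, n_trials=1)
        assert np.array_equal(topo.facilitation["lnpn"].F, before)

    def test_panel_shape(self, small_topology, env):
        panel = run_test_panel(small_topology, env.odors[:2], CFG, seed=11,
                               n_trials=2)
        assert set(panel) == {env.odors[0].name, env.odors[1].name}
        assert all(len(v) == 2 for v in panel.values())


def test_split_seed_streams_are_independent_and_bounded():
    a = split_seed(123, 5)
    b = split_seed(123, 5)
    c = split_seed(124, 5)
    assert a == b != c
    assert all(0 <= s < 2 ** 31 for s in a)
    assert len(set(a)) == 5
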