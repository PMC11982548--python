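"""Trial execution and training protocols.

A *trial* is one 2 s odor presentation: membrane and synaptic kinetic
states start from rest, the 500 ms odor pulse (plus background noise)
drives the network, and spikes/voltages are recorded.  A *training run*
presents a randomized sequence of odors drawn from an environment's
classes; the plasticity rule applied during each presentation is selected
by the class of the presented odor (presynaptic facilitation for rewarded
odors, postsynaptic for habituated ones), gated by the protocol mode.
Facilitation persists across presentations with lazy exponential decay;
membrane and synaptic kinetics reset between presentations.

Randomness is organized around one master seed split into independent
streams for topology, odor order, and per-trial noise, so experiments can
vary one source at a time.  All simulations are deterministic given the
same seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import simulate_network
from .odors import InputConfig, OdorEnvironment, stimulus_matrix
from .plasticity import FacilitationParams, freeze_weights

__all__ = [
    "SimulationConfig", "TrainingProtocol", "SpikeRecord",
    "run_trial", "run_training", "run_test_panel",
    "run_environment_experiment", "split_seed",
]


def split_seed(master: int, n: int, salt: int = 0):
    """Derive n independent sub-seeds (< 2^31) from a master seed."""
    ss = np.random.SeedSequence([int(master), int(salt)])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.04  # ms, RK4 step
    trial_ms: float = 2000.0  # presentation duration
    input: InputConfig = field(default_factory=InputConfig)
    record_voltage: bool = True
    v_sample_ms: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class TrainingProtocol:
    environment: OdorEnvironment
    n_presentations: int = 30
    presentation_ms: float = 2000.0
    mode: str = "both"  # both | pre_only | post_only | off
    facilitation: FacilitationParams = field(default_factory=FacilitationParams)
    with_replacement: bool = True

    @property
    def total_ms(self) -> float:
        return self.n_presentations * self.presentation_ms


@dataclass
class SpikeRecord:
    """Per-neuron spike times plus optional sampled voltages for one trial."""

    n_pn: int
    n_ln: int
    duration_ms: float
    spikes: list  # per-neuron sorted arrays of spike times (ms)
    voltages: np.ndarray | None = None  # (n_samples, N) at v_sample_ms
    v_sample_ms: float = 1.0
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_flat(cls, spike_n, spike_t, n_pn, n_ln, duration_ms, **kw):
        spikes = [np.sort(spike_t[spike_n == i]) for i in range(n_pn + n_ln)]
        return cls(n_pn=n_pn, n_ln=n_ln, duration_ms=duration_ms,
                   spikes=spikes, **kw)

    def pn_spikes(self):
        return self.spikes[: self.n_pn]

    def counts_in_window(self, t0: float, t1: float) -> np.ndarray:
        return np.array([np.count_nonzero((s >= t0) & (s < t1))
                         for s in self.spikes])

    # -- HDF5 round trip ---------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            grp = fh.create_group("spikes")
            for i, s in enumerate(self.spikes):
                grp.create_dataset(str(i), data=np.asarray(s, dtype=float))
            if self.voltages is not None:
                fh.create_dataset("voltage", data=self.voltages)
            fh.attrs["n_pn"] = self.n_pn
            fh.attrs["n_ln"] = self.n_ln
            fh.attrs["duration_ms"] = self.duration_ms
            fh.attrs["v_sample_ms"] = self.v_sample_ms
            for k, v in self.meta.items():
                fh.attrs[f"meta_{k}"] = v

    @classmethod
    def load_h5(cls, path) -> "SpikeRecord":
        import h5py

        with h5py.File(path, "r") as fh:
            n_pn = int(fh.attrs["n_pn"])
            n_ln = int(fh.attrs["n_ln"])
            spikes = [fh["spikes"][str(i)][...] for i in range(n_pn + n_ln)]
            volt = fh["voltage"][...] if "voltage" in fh else None
            meta = {k[5:]: fh.attrs[k] for k in fh.attrs if k.startswith("meta_")}
            return cls(n_pn=n_pn, n_ln=n_ln,
                       duration_ms=float(fh.attrs["duration_ms"]),
                       spikes=spikes, voltages=volt,
                       v_sample_ms=float(fh.attrs["v_sample_ms"]), meta=meta)


def _noise_vector(topology, cfg: InputConfig) -> np.ndarray:
    out = np.empty(topology.n_pn + topology.n_ln)
    out[: topology.n_pn] = cfg.noise_std_pn
    out[topology.n_pn:] = cfg.noise_std_ln
    return out


def run_trial(topology, odor, config: SimulationConfig, seed: int,
              plasticity_mode: str = "off", t_global0: float = 0.0,
              fac_params: FacilitationParams | None = None) -> SpikeRecord:
    """Simulate one presentation of ``odor`` and return its SpikeRecord.

    With ``plasticity_mode="off"`` (the test-phase setting) facilitation
    state is untouched; otherwise spike-triggered facilitation updates the
    topology in place.
    """
    n_ms = int(round(config.trial_ms))
    stim = stimulus_matrix(odor, topology, n_ms, config.input)
    spike_n, spike_t, v_rec = simulate_network(
        topology, stim, config.trial_ms, dt=config.dt, seed=seed,
        noise_std=_noise_vector(topology, config.input),
        plasticity_mode=plasticity_mode, fac_params=fac_params,
        t_global0=t_global0, v_sample_ms=config.v_sample_ms)
    return SpikeRecord.from_flat(
        spike_n, spike_t, topology.n_pn, topology.n_ln, config.trial_ms,
        voltages=v_rec if config.record_voltage else None,
        v_sample_ms=config.v_sample_ms,
        meta={"odor": odor.name, "reward": odor.reward, "seed": seed})


def _presentation_sequence(protocol: TrainingProtocol, rng) -> list:
    """Randomized balanced sequence of odors over the two reward classes."""
    rew = protocol.environment.by_reward("rewarded")
    hab = protocol.environment.by_reward("habituated")
    n = protocol.n_presentations
    seq = []
    for group, count in ((rew, (n + 1) // 2), (hab, n // 2)):
        if not group:
            continue
        if protocol.with_replacement:
            seq += [group[k] for k in rng.integers(0, len(group), count)]
        else:
            reps = int(np.ceil(count / len(group)))
            pool = (group * reps)[:count]
            seq += pool
    order = rng.permutation(len(seq))
    return [seq[k] for k in order]


def run_training(topology, protocol: TrainingProtocol, config: SimulationConfig,
                 seed: int):
    """Train in place through one randomized presentation sequence.

    Returns ``(topology, log)`` where the log has one row per presentation
    with the presented odor and the running mean facilitation per plastic
    synapse class.  The facilitation clock ``topology.t_now`` advances by
    ``presentation_ms`` per presentation; lazy decay ties consecutive
    environments together (forgetting).
    """
    order_seed, *noise_seeds = split_seed(seed, protocol.n_presentations + 1,
                                          salt=101)
    rng = np.random.default_rng(order_seed)
    seq = _presentation_sequence(protocol, rng)

    topology.set_facilitation_params(protocol.facilitation)
    topology.frozen = False
    topology.training_active = True
    trial_cfg = replace(config, trial_ms=protocol.presentation_ms,
                        record_voltage=False)
    log = []
    for k, odor in enumerate(seq):
        if protocol.mode == "off":
            mode = "off"
        elif odor.reward == "rewarded":
            mode = "pre_only" if protocol.mode in ("both", "pre_only") else "off"
        else:
            mode = "post_only" if protocol.mode in ("both", "post_only") else "off"
        run_trial(topology, odor, trial_cfg, noise_seeds[k],
                  plasticity_mode=mode, t_global0=topology.t_now,
                  fac_params=protocol.facilitation)
        topology.t_now += protocol.presentation_ms
        mask_pn = topology.masks["lnpn"]
        mask_ll = topology.masks["lnln"]
        log.append({
            "presentation": k, "odor": odor.name, "reward": odor.reward,
            "mode": mode,
            "mean_F_lnpn": float(
                topology.facilitation["lnpn"].decayed(topology.t_now)[mask_pn].mean()),
            "mean_F_lnln": float(
                topology.facilitation["lnln"].decayed(topology.t_now)[mask_ll].mean()),
        })
    topology.training_active = False
    return topology, pd.DataFrame(log)


def run_test_panel(topology, odors, config: SimulationConfig, seed: int,
                   n_trials: int = 1) -> dict:
    """Frozen-weight test trials: {odor name: [SpikeRecord, ...]}.

    The topology is snapshotted and frozen at its current facilitation
    clock, so testing never mutates training state.
    """
    snap = copy.deepcopy(topology)
    freeze_weights(snap, t=snap.t_now)
    seeds = split_seed(seed, len(odors) * n_trials, salt=202)
    out = {}
    k = 0
    for odor in odors:
        recs = []
        for _ in range(n_trials):
            recs.append(run_trial(snap, odor, config, seeds[k],
                                  plasticity_mode="off", t_global0=snap.t_now))
            k += 1
        out[odor.name] = recs
    return out


def run_environment_experiment(case: int, env2_reward_sign: str, seed: int,
                               build_network, config: SimulationConfig,
                               protocol_kwargs: dict | None = None,
                               n_odors_per_class: int = 10,
                               n_test_odors: int = 2, n_trials: int = 1,
                               bin_ms: float = 100.0) -> pd.DataFrame:
    """Sequential two-environment training with stage-wise correlations.

    Builds Env1 (P rewarded, Q habituated) and the case-specific Env2,
    trains Env1 then Env2 on the same network (facilitation decays across
    the whole protocol, implementing slow forgetting), and measures
    between-class representation correlations for both environments' class
    pairs at the naive, post-Env1 and post-Env2 stages.  Returns a tidy
    frame (stage, pair, correlation).
    """
    from .analysis import pairwise_panel_correlation
    from .odors import environment_case

    pk = dict(protocol_kwargs or {})
    env_seed, train1_seed, train2_seed, test_seed = split_seed(seed, 4, salt=303)
    env1, env2 = environment_case(case, env2_reward_sign, env_seed,
                                  n_odors_per_class=n_odors_per_class)
    topo = build_network(seed)

    pairs = {
        "env1": (env1.classes()[0], env1.classes()[1], env1),
        "env2": (env2.classes()[0], env2.classes()[1], env2),
    }

    def measure(stage):
        rows = []
        for key, (ca, cb, env) in pairs.items():
            odors_a = env.by_class(ca)[:n_test_odors]
            odors_b = env.by_class(cb)[:n_test_odors]
            panel = run_test_panel(topo, odors_a + odors_b, config,
                                   test_seed, n_trials=n_trials)
            corr = pairwise_panel_correlation(
                panel, [o.name for o in odors_a], [o.name for o in odors_b],
                bin_ms=bin_ms, window=(config.input.t_on,
                                       config.input.t_on + config.input.duration))
            rows.append({"stage": stage, "pair": f"{ca}/{cb}",
                         "env": key, "correlation": corr})
        return rows

    rows = measure("naive")
    run_training(topo, TrainingProtocol(environment=env1, **pk), config, train1_seed)
    rows += measure("post_env1")
    run_training(topo, TrainingProtocol(environment=env2, **pk), config, train2_seed)
    rows += measure("post_env2")
    out = pd.DataFrame(rows)
    out["case"] = case
    out["reward_sign"] = env2_reward_sign
    out["seed"] = seed
    return out
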