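"""Odor stimuli: percept mixtures, input current waveforms, and sensor data.

An odor is a mixture of "pure" chemical *percepts*.  Percepts tile the PN
population in contiguous blocks; each active percept drives its block with
a Gaussian activation profile whose standard deviation (the *width*,
expressed as a fraction of the percept span) encodes how strongly that
chemical is represented in the blend.  During a presentation every
activated neuron receives a current pulse that rises with a 66.7 ms time
constant for 500 ms and then decays with a 200 ms time constant, plus
small-amplitude Gaussian noise.

Three odor families are provided:

* simple classes - 3 active percepts out of 7, class members differing in
  their Gaussian widths (discrimination experiments),
* blend odors - percept widths set equal to chemical proportions of a
  6-component floral blend (the PH/PP contrast-enhancement experiment),
* sensor-derived odors - pulse parameters computed from gas-sensor
  features (response magnitude and on/off EMA time constants), plus a
  synthetic generator emulating the 16-sensor x 8-feature, 6-odor schema
  of the UCI Gas Sensor Array Drift data so no download is required.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Percept", "Odor", "OdorEnvironment", "InputConfig",
    "tile_percepts", "percept_activation_profile", "make_odor_class",
    "blend_to_odor", "sensor_features_to_pulse", "stimulus_current",
    "background_noise", "synthetic_sensor_dataset", "zscore_sensor_features",
    "simple_environment", "phpp_environment", "environment_case",
    "odor_amplitudes", "stimulus_matrix",
]

STIM_TAU_RISE = 66.7  # ms
STIM_TAU_DECAY = 200.0  # ms
STIM_DURATION = 500.0  # ms


@dataclass(frozen=True)
class Percept:
    """One pure chemical's activation footprint: a contiguous PN block."""

    id: int
    lo: int  # first neuron index of the block (inclusive)
    hi: int  # one past the last index

    @property
    def center(self) -> int:
        """Central neuron of the block (the profile peaks on a neuron)."""
        return (self.lo + self.hi - 1) // 2

    @property
    def span(self) -> int:
        return self.hi - self.lo


def tile_percepts(n_neurons: int, n_percepts: int) -> list:
    """Partition [0, n_neurons) into n_percepts near-equal contiguous blocks."""
    bounds = np.linspace(0, n_neurons, n_percepts + 1).round().astype(int)
    return [Percept(id=k, lo=int(bounds[k]), hi=int(bounds[k + 1]))
            for k in range(n_percepts)]


@dataclass(frozen=True)
class Odor:
    """A percept mixture with a reward label.

    ``widths[p]`` is the Gaussian activation width of percept p (0 means
    inactive).  ``peak_scale``, ``tau_rise`` and ``tau_decay`` allow
    per-percept pulse shaping for sensor-derived odors; by default every
    active percept uses the standard pulse.
    """

    name: str
    class_label: str
    reward: str  # "rewarded" | "habituated" | "none"
    widths: tuple
    peak_scale: tuple = ()
    tau_rise: tuple = ()
    tau_decay: tuple = ()
    duration: float = STIM_DURATION

    def __post_init__(self):
        if self.reward not in ("rewarded", "habituated", "none"):
            raise ValueError(f"unknown reward label {self.reward!r}")
        n = len(self.widths)
        for attr, default in (("peak_scale", 1.0), ("tau_rise", STIM_TAU_RISE),
                              ("tau_decay", STIM_TAU_DECAY)):
            if not getattr(self, attr):
                object.__setattr__(self, attr, (default,) * n)

    @property
    def n_percepts(self) -> int:
        return len(self.widths)

    @property
    def active_percepts(self) -> tuple:
        return tuple(int(i) for i in np.nonzero(self.widths)[0])


@dataclass(frozen=True)
class OdorEnvironment:
    """A set of odor classes with reward labels defining a training context."""

    name: str
    odors: tuple  # of Odor
    n_percepts: int

    def by_reward(self, reward: str) -> list:
        return [o for o in self.odors if o.reward == reward]

    def classes(self) -> list:
        seen = []
        for o in self.odors:
            if o.class_label not in seen:
                seen.append(o.class_label)
        return seen

    def by_class(self, label: str) -> list:
        return [o for o in self.odors if o.class_label == label]


@dataclass(frozen=True)
class InputConfig:
    """Calibrated odor-input parameters (specific currents, uA/cm^2).

    Peak amplitudes and the PN/LN ratio are calibrated once so that the
    untrained network shows odor-evoked PN firing and LFP oscillations
    during the 500 ms pulse; they are not printed quantities.
    """

    peak_pn: float = 5.0
    peak_ln: float = 2.5
    multipolar_frac: float = 0.35  # multipolar LNs get this fraction of the
    # mean unipolar drive (reduced-amplitude global input)
    noise_std_pn: float = 0.15
    noise_std_ln: float = 0.15
    t_on: float = 200.0  # odor onset within a presentation, ms
    duration: float = STIM_DURATION


# ---------------------------------------------------------------------------
# elementary stimulus operations
# ---------------------------------------------------------------------------

def percept_activation_profile(width: float, lo: int, hi: int, peak: float = 1.0,
                               n_neurons: int | None = None) -> np.ndarray:
    """Gaussian activation over a percept block, zero outside.

    amplitude_i = peak * exp(-(i - center)^2 / (2*(width*span/2)^2)) for i
    in [lo, hi); ``width`` is the Gaussian std as a fraction of half the
    block span.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    n = n_neurons if n_neurons is not None else hi
    out = np.zeros(n)
    idx = np.arange(lo, hi)
    center = (lo + hi - 1) // 2
    sd = width * (hi - lo) / 2.0
    out[lo:hi] = peak * np.exp(-((idx - center) ** 2) / (2.0 * sd ** 2))
    return out


def make_odor_class(percept_ids, widths_per_odor, reward: str,
                    class_label: str, n_percepts: int = 7) -> list:
    """One odor per width vector, all sharing the same 3-percept support."""
    percept_ids = tuple(percept_ids)
    if len(set(percept_ids)) != len(percept_ids):
        raise ValueError("duplicate percepts in odor class")
    odors = []
    for k, widths in enumerate(widths_per_odor):
        w = np.zeros(n_percepts)
        w[list(percept_ids)] = widths
        odors.append(Odor(name=f"{class_label}{k + 1}", class_label=class_label,
                          reward=reward, widths=tuple(w)))
    return odors


def blend_to_odor(proportions, name: str, class_label: str, reward: str,
                  n_percepts: int = 7) -> Odor:
    """Blend odor: percept width = chemical proportion; last percept inactive."""
    prop = np.asarray(proportions, dtype=float)
    if np.any(prop < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(prop.sum() - 1.0) > 0.02:
        raise ValueError("proportions must sum to ~1")
    w = np.zeros(n_percepts)
    w[: len(prop)] = prop
    return Odor(name=name, class_label=class_label, reward=reward,
                widths=tuple(w))


def sensor_features_to_pulse(dR: float, ema_max: float, ema_min: float,
                             peak_per_dR: float = 1.0,
                             rise_const: float = STIM_TAU_RISE * 1e-3,
                             decay_const: float = STIM_TAU_DECAY * 1e-3):
    """Map (dR, ema_max, ema_min) sensor features to pulse parameters.

    peak = peak_per_dR * dR, tau_rise = rise_const / ema_max, tau_decay =
    decay_const / ema_min.  The default proportionality constants map the
    reference feature scale (ema ~ 1e-3) onto the standard 66.7/200 ms
    pulse.
    """
    if ema_max <= 0 or ema_min <= 0:
        raise ValueError("EMA features must be positive")
    return peak_per_dR * dR, rise_const / ema_max, decay_const / ema_min


def stimulus_current(t, t_on: float, peak: float,
                     tau_rise: float = STIM_TAU_RISE,
                     tau_decay: float = STIM_TAU_DECAY,
                     duration: float = STIM_DURATION):
    """Odor-pulse current waveform (uA/cm^2 for unit peak).

    Rises exponentially toward ``peak`` during [t_on, t_on+duration], then
    decays exponentially; zero before onset.
    """
    if peak < 0:
        raise ValueError("peak must be nonnegative")
    t = np.asarray(t, dtype=float)
    t_off = t_on + duration
    v_off = peak * -np.expm1(-duration / tau_rise)
    rising = peak * -np.expm1(-(t - t_on) / tau_rise)
    decaying = v_off * np.exp(-(t - t_off) / tau_decay)
    return np.where(t < t_on, 0.0, np.where(t <= t_off, rising, decaying))


def background_noise(rng: np.random.Generator, n_neurons: int,
                     amplitude: float | np.ndarray) -> np.ndarray:
    """One step of i.i.d. zero-mean Gaussian current noise per neuron."""
    if np.any(np.asarray(amplitude) < 0):
        raise ValueError("noise amplitude must be nonnegative")
    return rng.standard_normal(n_neurons) * amplitude


# ---------------------------------------------------------------------------
# network input assembly
# ---------------------------------------------------------------------------

def odor_amplitudes(odor: Odor, topology, config: InputConfig | None = None):
    """Per-neuron peak input amplitudes (PNs then LNs) for one odor.

    PNs within each active percept's block follow the Gaussian profile.
    Unipolar LNs inherit the mean profile value over their glomerulus's
    PNs; multipolar LNs receive a reduced uniform drive proportional to
    the mean unipolar input.  For sensor-derived odors the per-percept
    ``peak_scale`` multiplies the profile.
    """
    cfg = config or InputConfig()
    percepts = tile_percepts(topology.n_pn, odor.n_percepts)
    amp_pn = np.zeros(topology.n_pn)
    for p in percepts:
        w = odor.widths[p.id]
        if w > 0:
            amp_pn += odor.peak_scale[p.id] * percept_activation_profile(
                w, p.lo, p.hi, peak=1.0, n_neurons=topology.n_pn)

    amp_ln = np.zeros(topology.n_ln)
    if topology.glomeruli:
        for glom in topology.glomeruli:
            level = float(np.mean(amp_pn[list(glom.pn_ids)]))
            for ln in glom.unipolar_ln_ids:
                amp_ln[ln] = level
        n_uni = topology.n_ln - topology.n_multipolar
        if topology.n_multipolar and amp_ln[:n_uni].any():
            active = amp_ln[:n_uni][amp_ln[:n_uni] > 0]
            amp_ln[n_uni:] = cfg.multipolar_frac * active.mean()
    else:
        # uniform large network: first half of LNs mirrors the PN tiling
        n_rx = topology.n_ln // 2
        ln_percepts = tile_percepts(n_rx, odor.n_percepts)
        for p in ln_percepts:
            w = odor.widths[p.id]
            if w > 0:
                amp_ln[:n_rx] += odor.peak_scale[p.id] * percept_activation_profile(
                    w, p.lo, p.hi, peak=1.0, n_neurons=n_rx)
    return cfg.peak_pn * amp_pn, cfg.peak_ln * amp_ln


def stimulus_matrix(odor: Odor, topology, duration_ms: int,
                    config: InputConfig | None = None) -> np.ndarray:
    """Per-millisecond stimulus currents, shape (duration_ms, n_neurons).

    Each percept's pulse uses its own rise/decay constants (relevant for
    sensor-derived odors); neurons receiving several percepts sum the
    pulses.  The integrator holds each 1 ms sample constant within it.
    """
    cfg = config or InputConfig()
    t = np.arange(duration_ms, dtype=float)
    n = topology.n_pn + topology.n_ln
    out = np.zeros((duration_ms, n))
    # group percepts by identical pulse shape to reuse waveforms
    for pid in odor.active_percepts:
        sub = replace(odor, widths=tuple(
            w if i == pid else 0.0 for i, w in enumerate(odor.widths)))
        amp_pn, amp_ln = odor_amplitudes(sub, topology, cfg)
        wave = stimulus_current(t, cfg.t_on, 1.0, odor.tau_rise[pid],
                                odor.tau_decay[pid], odor.duration)
        out += wave[:, None] * np.concatenate([amp_pn, amp_ln])[None, :]
    return out


# ---------------------------------------------------------------------------
# odor environments
# ---------------------------------------------------------------------------

DEFAULT_WIDTH_RANGE = (0.25, 0.5)


def simple_environment(seed: int, n_odors_per_class: int = 3,
                       rewarded_percepts=(0, 1, 2), habituated_percepts=(1, 2, 3),
                       n_percepts: int = 7,
                       width_range=DEFAULT_WIDTH_RANGE) -> OdorEnvironment:
    """Two simple odor classes: 3 active percepts each, overlapping by 2.

    Individual odors within a class share percept support and differ in
    their per-percept Gaussian widths, drawn uniformly from
    ``width_range`` under the given seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = width_range
    w_a = rng.uniform(lo, hi, size=(n_odors_per_class, len(rewarded_percepts)))
    w_b = rng.uniform(lo, hi, size=(n_odors_per_class, len(habituated_percepts)))
    odors = make_odor_class(rewarded_percepts, w_a, "rewarded", "A", n_percepts)
    odors += make_odor_class(habituated_percepts, w_b, "habituated", "B", n_percepts)
    return OdorEnvironment(name="simple", odors=tuple(odors), n_percepts=n_percepts)


#: synthetic 6-component blend proportion templates emulating the two
#: snapdragon varieties (Pale Hybrid rewarded, Potomac Pink habituated);
#: the PH template pins the first component at the printed 0.372.
PH_TEMPLATE = (0.372, 0.220, 0.160, 0.120, 0.080, 0.048)
PP_TEMPLATE = (0.060, 0.100, 0.180, 0.300, 0.240, 0.120)


def phpp_environment(n_odors_per_class: int = 3,
                     jitter: float = 0.25) -> OdorEnvironment:
    """PH (rewarded) and PP (habituated) blend odors over 6 of 7 percepts.

    The blend set is a fixed study input (as a panel of measured blends
    would be), identical across simulation seeds: the first odor of each
    class is the variety template itself; further odors multiply the
    template by lognormal within-variety variation (fixed internal
    stream) and renormalize.
    """
    rng = np.random.default_rng(271828)
    odors = []
    for label, reward, template in (("PH", "rewarded", PH_TEMPLATE),
                                    ("PP", "habituated", PP_TEMPLATE)):
        base = np.asarray(template)
        for k in range(n_odors_per_class):
            if k == 0:
                prop = base
            else:
                prop = base * rng.lognormal(0.0, jitter, size=base.size)
                prop = prop / prop.sum()
            odors.append(blend_to_odor(prop, f"{label}{k + 1}", label, reward))
    return OdorEnvironment(name="phpp", odors=tuple(odors), n_percepts=7)


#: percept supports for the two-environment experiments (8-percept tiling)
_ENV_CLASSES = {
    "P": (0, 1, 2), "Q": (1, 2, 3),  # Env1, always P+ Q-
    "S": (4, 5, 6), "T": (5, 6, 7),  # disjoint from Env1
    "M": (0, 1, 2), "N": (1, 2, 3),  # fully overlapping with P / Q
}

_CASE_ENV2 = {1: ("S", "T"), 2: ("M", "N"), 3: ("M", "S"), 4: ("N", "S")}


def environment_case(case: int, env2_reward_sign: str, seed: int,
                     n_odors_per_class: int = 10,
                     width_range=DEFAULT_WIDTH_RANGE):
    """Build (Env1, Env2) for the four overlap scenarios.

    Env1 is always P (rewarded) vs Q (habituated).  Env2 contains the two
    classes listed for the case; ``env2_reward_sign`` "pos" rewards the
    first class, "neg" the second.
    """
    if case not in _CASE_ENV2:
        raise ValueError(f"unknown environment case {case!r}")
    if env2_reward_sign not in ("pos", "neg"):
        raise ValueError("env2_reward_sign must be 'pos' or 'neg'")
    rng = np.random.default_rng(seed)
    lo, hi = width_range
    n_percepts = 8

    def build(label, reward):
        pids = _ENV_CLASSES[label]
        widths = rng.uniform(lo, hi, size=(n_odors_per_class, len(pids)))
        return make_odor_class(pids, widths, reward, label, n_percepts)

    env1 = OdorEnvironment(
        name="Env1", n_percepts=n_percepts,
        odors=tuple(build("P", "rewarded") + build("Q", "habituated")))
    c1, c2 = _CASE_ENV2[case]
    rew1, rew2 = (("rewarded", "habituated") if env2_reward_sign == "pos"
                  else ("habituated", "rewarded"))
    env2 = OdorEnvironment(
        name="Env2", n_percepts=n_percepts,
        odors=tuple(build(c1, rew1) + build(c2, rew2)))
    return env1, env2


# ---------------------------------------------------------------------------
# synthetic gas-sensor data
# ---------------------------------------------------------------------------

SENSOR_FEATURES = ("dR", "dR_norm", "ema_max_a001", "ema_max_a01", "ema_max_a1",
                   "ema_min_a001", "ema_min_a01", "ema_min_a1")


def synthetic_sensor_dataset(seed: int, n_odors: int = 6, n_sensors: int = 16,
                             n_features: int = 8, n_reps: int = 30,
                             jitter: float = 0.08):
    """Synthetic stand-in for the gas-sensor-array feature schema.

    Each odor has a fixed sensor x feature response template; repetitions
    add Gaussian jitter.  Sensor selectivity is structured: one third of
    the sensors respond preferentially to the rewarded odor group, one
    third to the habituated group, and the rest respond to everything, so
    per-sensor uniqueness is well defined by construction.  Returns
    ``(features, labels)``: a DataFrame of n_reps*n_odors rows with
    ``s{i}_{feature}`` columns, and a DataFrame with odor and reward
    labels (first half of odors rewarded, second half habituated).
    """
    rng = np.random.default_rng(seed)
    fnames = SENSOR_FEATURES[:n_features] if n_features <= 8 else [
        f"f{k}" for k in range(n_features)]
    thirds = np.array_split(np.arange(n_sensors), 3)
    templates = np.empty((n_odors, n_sensors, n_features))
    base = rng.uniform(0.8, 1.6, size=(n_sensors, n_features))
    for o in range(n_odors):
        rewarded = o < n_odors // 2
        gain = np.full(n_sensors, 0.35)
        gain[thirds[0]] = 1.4 if rewarded else 0.25
        gain[thirds[1]] = 0.25 if rewarded else 1.4
        gain[thirds[2]] = 1.0
        templates[o] = base * gain[:, None] * rng.uniform(
            0.85, 1.15, size=(n_sensors, n_features))

    rows, odor_lab, reward_lab = [], [], []
    for o in range(n_odors):
        reps = templates[o][None] + jitter * rng.standard_normal(
            (n_reps, n_sensors, n_features))
        rows.append(reps.reshape(n_reps, -1))
        odor_lab += [f"odor{o}"] * n_reps
        reward_lab += ["rewarded" if o < n_odors // 2 else "habituated"] * n_reps
    cols = [f"s{si}_{fn}" for si in range(n_sensors) for fn in fnames]
    features = pd.DataFrame(np.concatenate(rows), columns=cols)
    labels = pd.DataFrame({"odor": odor_lab, "reward": reward_lab})
    return features, labels


def sensor_odor_environment(features: pd.DataFrame, labels: pd.DataFrame,
                            width: float = 0.5,
                            peak_per_dR: float = 1.0,
                            rise_const: float = STIM_TAU_RISE * 1e-3,
                            decay_const: float = STIM_TAU_DECAY * 1e-3,
                            n_sensors: int = 16) -> OdorEnvironment:
    """Build 16-percept odors from gas-sensor features for the large net.

    Per odor, the repetition-averaged (dR, ema_max, ema_min) of each
    sensor set that percept's pulse height and rise/decay constants via
    :func:`sensor_features_to_pulse`; every percept shares a fixed
    Gaussian width (sensor responses have no spatial footprint of their
    own).  The dR scale is normalized by the panel's maximum so the
    strongest sensor reaches ``peak_per_dR``.
    """
    means = features.groupby(labels["odor"].to_numpy()).mean()
    reward_of = dict(zip(labels["odor"], labels["reward"]))
    dr_cols = [f"s{k}_dR" for k in range(n_sensors)]
    rise_cols = [f"s{k}_ema_max_a001" for k in range(n_sensors)]
    decay_cols = [f"s{k}_ema_min_a001" for k in range(n_sensors)]
    dr_max = float(np.abs(means[dr_cols].to_numpy()).max())
    odors = []
    for name, row in means.iterrows():
        peaks, rises, decays = [], [], []
        for dc, rc, xc in zip(dr_cols, rise_cols, decay_cols):
            peak, rise, decay = sensor_features_to_pulse(
                max(row[dc], 0.0) / dr_max, abs(row[rc]) * 1e-3 + 1e-9,
                abs(row[xc]) * 1e-3 + 1e-9, peak_per_dR,
                rise_const, decay_const)
            peaks.append(peak)
            rises.append(rise)
            decays.append(decay)
        odors.append(Odor(
            name=str(name), class_label=str(name), reward=reward_of[name],
            widths=tuple(width if p > 0 else 0.0 for p in peaks),
            peak_scale=tuple(peaks), tau_rise=tuple(rises),
            tau_decay=tuple(decays)))
    return OdorEnvironment(name="sensor", odors=tuple(odors),
                           n_percepts=n_sensors)


def zscore_sensor_features(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring (subtract mean, divide by std) of sensor values."""
    std = features.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (features - features.mean(axis=0)) / std
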