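"""Synaptic currents of the antennal-lobe network.

Three receptor families connect PNs and LNs:

* fast GABA_A (LN -> PN and LN -> LN), first-order open-fraction kinetics
  driven by a sigmoid of the presynaptic voltage,
* nicotinic cholinergic (PN -> LN), first-order kinetics driven by a square
  transmitter pulse following each presynaptic spike,
* slow G-protein-coupled inhibition (LN -> PN), a two-stage receptor /
  G-protein cascade gating a K conductance with Hill coefficient 4.

All kinetic state lives per presynaptic neuron (the transmitter drive is a
function of the presynaptic cell only); per-connection strength is the
product of a base conductance and a facilitation multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FastSynapseParams", "FastSynapseState", "SlowSynapseParams",
    "SlowSynapseState", "GABA_A_PARAMS", "NACH_PARAMS", "SLOW_INH_PARAMS",
    "cholinergic_transmitter", "gaba_transmitter",
    "fast_open_fraction_derivative", "fast_synaptic_current",
    "slow_state_derivatives", "slow_synaptic_current",
]


@dataclass(frozen=True)
class FastSynapseParams:
    """First-order synapse: d[O]/dt = alpha*(1-O)*T - beta*O."""

    kind: str  # "GABA_A" or "nACh"
    g_max: float  # uS (per-target-class total; see network module)
    E_syn: float  # mV
    alpha: float  # 1/ms
    beta: float  # 1/ms
    A_T: float = 0.0  # transmitter amplitude (cholinergic)
    t_max: float = 0.0  # transmitter pulse duration, ms (cholinergic)
    V0: float = 0.0  # sigmoid midpoint, mV (GABA)
    sigma: float = 1.0  # sigmoid slope, mV (GABA)


GABA_A_PARAMS = FastSynapseParams(
    kind="GABA_A", g_max=0.015, E_syn=-70.0, alpha=10.0, beta=0.2,
    V0=-20.0, sigma=1.5,
)
NACH_PARAMS = FastSynapseParams(
    kind="nACh", g_max=0.3, E_syn=0.0, alpha=1.0, beta=0.2,
    A_T=0.5, t_max=0.3,
)


@dataclass
class FastSynapseState:
    O: float = 0.0  # open-channel fraction
    last_pre_spike_time: float = -1e9  # ms (cholinergic)


@dataclass(frozen=True)
class SlowSynapseParams:
    r1: float = 0.5  # 1/(mM*ms)
    r2: float = 0.0013  # 1/ms
    r3: float = 0.1  # 1/ms
    r4: float = 0.033  # 1/ms
    K: float = 100.0  # uM^4
    g_max: float = 0.02  # uS
    E_K: float = -95.0  # mV


SLOW_INH_PARAMS = SlowSynapseParams()


@dataclass
class SlowSynapseState:
    R: float = 0.0  # activated receptor fraction
    G: float = 0.0  # G-protein concentration


def cholinergic_transmitter(t, t0, A_T=NACH_PARAMS.A_T, t_max=NACH_PARAMS.t_max):
    """Square transmitter pulse of height A_T during [t0, t0 + t_max]."""
    t = np.asarray(t, dtype=float)
    return np.where((t >= t0) & (t <= t0 + t_max), A_T, 0.0)


def gaba_transmitter(V_pre, V0=GABA_A_PARAMS.V0, sigma=GABA_A_PARAMS.sigma):
    """Sigmoid transmitter drive 1/(1 + exp(-(V - V0)/sigma)) of presynaptic V."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (1.0 + np.exp(-(np.asarray(V_pre, dtype=float) - V0) / sigma))


def fast_open_fraction_derivative(O, T, alpha, beta):
    """d[O]/dt = alpha*(1-O)*T - beta*O; fixed point alpha*T/(alpha*T+beta)."""
    return alpha * (1.0 - np.asarray(O, dtype=float)) * T - beta * O


def fast_synaptic_current(O, g_max, F, V_post, E_syn):
    """I = g_max * F * O * (V_post - E_syn)."""
    return g_max * F * np.asarray(O, dtype=float) * (V_post - E_syn)


def slow_state_derivatives(state: SlowSynapseState, T,
                           params: SlowSynapseParams = SLOW_INH_PARAMS):
    """(dR/dt, dG/dt) of the G-protein cascade."""
    dR = params.r1 * (1.0 - state.R) * T - params.r2 * state.R
    dG = params.r3 * state.R - params.r4 * state.G
    return dR, dG


def slow_synaptic_current(G, g_max, F, V_post,
                          params: SlowSynapseParams = SLOW_INH_PARAMS):
    """I = g_max * F * G^4/(G^4 + K) * (V_post - E_K)."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be nonnegative")
    G4 = G ** 4
    return g_max * F * G4 / (G4 + params.K) * (V_post - params.E_K)
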