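"""Single-compartment Hodgkin-Huxley dynamics for antennal-lobe neurons.

Projection neurons (PNs) and local interneurons (LNs) are modeled as single
compartments with voltage- and calcium-dependent currents of the form

    I = g * m^M * h^N * (V - E)

PNs carry fast Na, delayed-rectifier K, transient A-type K, low-threshold
Ca (I_T), hyperpolarization-activated cation (I_h), leak and K-leak
currents; LNs carry the same set minus I_A and I_h.  Gating variables obey
first-order relaxation dx/dt = (x_inf(V) - x)/tau_x(V); the steady-state
and time-constant curves are supplied by a swappable :class:`KineticsTable`
whose default entries follow the antennal-lobe model lineage this network
is drawn from (Traub-type Na/K, Huguenard A-current, Destexhe low-threshold
Ca, McCormick h-current).

Units: voltages in mV, time in ms, specific conductances in mS/cm^2,
specific currents in uA/cm^2, specific capacitance 1 uF/cm^2 (total Cm
divided by the implicit membrane area, 2.9e-4 cm^2 for PNs and 1.43e-4 cm^2
for LNs).  Intracellular Ca is in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "KineticsTable",
    "PN_PARAMS",
    "LN_PARAMS",
    "intrinsic_current",
    "gating_derivative",
    "calcium_derivative",
    "membrane_derivative",
    "CHANNEL_GATES",
]

# membrane areas implied by the printed total capacitances at 1 uF/cm^2
PN_AREA_CM2 = 2.9e-4
LN_AREA_CM2 = 1.43e-4

#: gate exponents (M, N) per channel; N=0 means no inactivation gate
CHANNEL_GATES = {
    "Na": (3, 1),
    "K": (4, 0),
    "A": (4, 1),
    "T": (2, 1),
    "h": (1, 0),
}


@dataclass(frozen=True)
class NeuronParams:
    """Per-cell-class parameter set (specific units, mS/cm^2 and mV)."""

    cell_class: str  # "PN" or "LN"
    Cm: float  # total capacitance, uF
    gL: float
    gKL: float
    EL: float
    EKL: float
    gNa: float
    gK: float
    gT: float
    gA: float = 0.0  # PN only
    gh: float = 0.0  # PN only
    ENa: float = 50.0
    EK: float = -95.0
    ECa: float = 140.0
    # first-order intracellular Ca model
    A_ca: float = 5.2e-5  # mM*cm^2/(ms*uA)
    tau_ca: float = 5.0  # ms
    Ca_inf: float = 2.4e-4  # mM

    def __post_init__(self):
        if self.cell_class not in ("PN", "LN"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        for name in ("gL", "gKL", "gNa", "gK", "gT", "gA", "gh"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative conductance {name}")

    @property
    def area_cm2(self) -> float:
        return PN_AREA_CM2 if self.cell_class == "PN" else LN_AREA_CM2

    def with_overrides(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


PN_PARAMS = NeuronParams(
    cell_class="PN", Cm=2.9e-4, gL=0.01, gKL=0.012, EL=-70.0, EKL=-95.0,
    gNa=90.0, gK=10.0, gA=10.0, gT=2.0, gh=0.02,
)

LN_PARAMS = NeuronParams(
    cell_class="LN", Cm=1.43e-4, gL=0.05, gKL=0.018, EL=-70.0, EKL=-95.0,
    gNa=100.0, gK=10.0, gT=1.75,
)


@dataclass
class NeuronState:
    """Instantaneous state of one neuron: V, gating variables, Ca."""

    V: float
    gating: dict = field(default_factory=dict)  # channel -> (m, h)
    Ca: float = 2.4e-4

    def validate(self) -> None:
        for ch, (m, h) in self.gating.items():
            if not (0.0 <= m <= 1.0 and 0.0 <= h <= 1.0):
                raise ValueError(f"gating variable of {ch} outside [0,1]")
        if self.Ca <= 0:
            raise ValueError("Ca must be positive")


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

_VSHIFT = 50.0  # Traub-style resting-potential shift for Na/K rates


def _lim(x: np.ndarray, a: float) -> np.ndarray:
    """x / (exp(x/a) - 1) with the removable singularity at x=0 filled."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-9
    xs = np.where(small, 1.0, x)
    out = xs / np.expm1(xs / a)
    return np.where(small, a, out)


def _na_rates(V):
    v = V + _VSHIFT
    am = 0.32 * _lim(13.0 - v, 4.0)
    bm = 0.28 * _lim(v - 40.0, 5.0)
    ah = 0.128 * np.exp((17.0 - v) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - v) / 5.0))
    return am, bm, ah, bh


def _k_rates(V):
    v = V + _VSHIFT
    an = 0.032 * _lim(15.0 - v, 5.0)
    bn = 0.5 * np.exp((10.0 - v) / 40.0)
    return an, bn


def _a_current(V):
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V + 60.0) / 8.5))
    tau_m = 1.0 / (np.exp((V + 35.82) / 19.69) + np.exp(-(V + 79.69) / 12.7)) + 0.37
    h_inf = 1.0 / (1.0 + np.exp((V + 78.0) / 6.0))
    tau_h = np.where(
        V < -63.0,
        1.0 / (np.exp((V + 46.05) / 5.0) + np.exp(-(V + 238.4) / 37.45)),
        19.0,
    )
    return m_inf, tau_m, h_inf, tau_h


def _t_current(V):
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V + 59.0) / 6.2))
    tau_m = 1.0 / (np.exp(-(V + 131.6) / 16.7) + np.exp((V + 16.8) / 18.2)) + 0.612
    h_inf = 1.0 / (1.0 + np.exp((V + 83.0) / 4.0))
    tau_h = np.where(
        V < -80.0,
        np.exp((V + 467.0) / 66.6),
        np.exp(-(V + 21.88) / 10.2) + 28.0,
    )
    return m_inf, tau_m, h_inf, tau_h


def _h_current(V):
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp((V + 75.0) / 5.5))
    tau_m = 20.0 + 1000.0 / (np.exp((V + 71.5) / 14.2) + np.exp(-(V + 89.0) / 11.6))
    return m_inf, tau_m


def _t_current_ln(V):
    """LN Ca current: depolarized activation, spike-coupled rather than a
    low-threshold rebound conductance (the LN variant of the lineage)."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 6.5))
    tau_m = np.full_like(V, 1.5)
    h_inf = 1.0 / (1.0 + np.exp((V + 25.0) / 12.0))
    tau_h = 18.0 + 4.0 / (np.exp((V + 45.0) / 10.0) + np.exp(-(V + 70.0) / 12.0))
    return m_inf, tau_m, h_inf, tau_h


# column order of the sampled kinetics table; (inf, tau) pairs per gate
TABLE_GATES = ("Na_m", "Na_h", "K_n", "A_m", "A_h", "T_m", "T_h", "h_m")


class KineticsTable:
    """Sampled x_inf(V)/tau_x(V) curves on a uniform voltage grid.

    The table is the single source of truth for gating kinetics: both the
    reference (numpy) dynamics and the compiled integrator interpolate the
    same arrays, so alternative kinetics sources can be dropped in by
    constructing a table from different curve functions.
    """

    def __init__(self, cell_class: str = "PN", v_min: float = -130.0,
                 v_max: float = 70.0, dv: float = 0.05):
        if cell_class not in ("PN", "LN"):
            raise ValueError(f"unknown cell class {cell_class!r}")
        self.cell_class = cell_class
        self.v_min = float(v_min)
        self.v_max = float(v_max)
        self.dv = float(dv)
        self.v_grid = np.arange(v_min, v_max + dv / 2, dv)
        self.data = np.empty((self.v_grid.size, 2 * len(TABLE_GATES)))
        self._fill(self.v_grid)

    def _fill(self, V):
        am, bm, ah, bh = _na_rates(V)
        an, bn = _k_rates(V)
        a_mi, a_tm, a_hi, a_th = _a_current(V)
        t_fn = _t_current if self.cell_class == "PN" else _t_current_ln
        t_mi, t_tm, t_hi, t_th = t_fn(V)
        h_mi, h_tm = _h_current(V)
        cols = [
            (am / (am + bm), 1.0 / (am + bm)),
            (ah / (ah + bh), 1.0 / (ah + bh)),
            (an / (an + bn), 1.0 / (an + bn)),
            (a_mi, a_tm),
            (a_hi, a_th),
            (t_mi, t_tm),
            (t_hi, t_th),
            (h_mi, h_tm),
        ]
        for k, (inf, tau) in enumerate(cols):
            self.data[:, 2 * k] = inf
            self.data[:, 2 * k + 1] = np.maximum(tau, 1e-3)

    def lookup(self, V):
        """Linear interpolation of all 16 columns at voltage(s) V."""
        V = np.atleast_1d(np.asarray(V, dtype=float))
        x = np.clip((V - self.v_min) / self.dv, 0.0, self.v_grid.size - 1.001)
        i0 = x.astype(np.int64)
        w = (x - i0)[:, None]
        return (1.0 - w) * self.data[i0] + w * self.data[i0 + 1]

    def steady_state(self, V):
        """Gate values at their voltage fixed points (columns 0,2,4,...)."""
        return self.lookup(V)[:, 0::2]


DEFAULT_KINETICS = KineticsTable("PN")
LN_KINETICS = KineticsTable("LN")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def intrinsic_current(g, m, M, h, N, V, E):
    """Ionic current g * m^M * h^N * (V - E).

    Positive values are outward contributions that enter the membrane
    equation with a minus sign.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("conductance must be nonnegative")
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any((m < 0) | (m > 1)) or np.any((h < 0) | (h > 1)):
        raise ValueError("gating variables must lie in [0, 1]")
    return g * m ** M * h ** N * (V - E)


def gating_derivative(x, x_inf, tau_x):
    """First-order relaxation rate (x_inf - x)/tau_x (1/ms)."""
    if np.any(np.asarray(tau_x) <= 0):
        raise ValueError("tau_x must be positive")
    return (np.asarray(x_inf, dtype=float) - x) / tau_x


def calcium_derivative(Ca, I_T, params: NeuronParams):
    """d[Ca]/dt = -A*I_T - (Ca - Ca_inf)/tau  (mM/ms, I_T in uA/cm^2)."""
    if np.any(np.asarray(Ca) <= 0):
        raise ValueError("Ca must be positive")
    return -params.A_ca * I_T - (Ca - params.Ca_inf) / params.tau_ca


def membrane_derivative(state: NeuronState, params: NeuronParams,
                        I_syn_total: float = 0.0, I_stim: float = 0.0) -> float:
    """dV/dt (mV/ms) for one neuron in specific units.

    ``I_syn_total`` and ``I_stim`` follow the printed sign convention:
    positive values are outward (hyperpolarizing) and are subtracted.
    """
    if params.cell_class not in ("PN", "LN"):
        raise ValueError("unknown cell class")
    V = state.V
    total = params.gL * (V - params.EL) + params.gKL * (V - params.EKL)
    for ch, g, E in (
        ("Na", params.gNa, params.ENa),
        ("K", params.gK, params.EK),
        ("A", params.gA, params.EK),
        ("T", params.gT, params.ECa),
        ("h", params.gh, -43.0),
    ):
        if g == 0.0 or ch not in state.gating:
            continue
        if params.cell_class == "LN" and ch in ("A", "h"):
            continue
        M, N = CHANNEL_GATES[ch]
        m, h = state.gating[ch]
        total += intrinsic_current(g, m, M, h, N, V, E)
    total += I_syn_total + I_stim
    return -total  # Cm/area = 1 uF/cm^2

E_H = -43.0  # reversal of the hyperpolarization-activated cation current


def resting_gates(V: float, cell_class: str) -> dict:
    """Gating dict at the voltage fixed point, for building NeuronStates."""
    table = DEFAULT_KINETICS if cell_class == "PN" else LN_KINETICS
    row = table.lookup(V)[0]
    gates = {
        "Na": (row[0], row[2]),
        "K": (row[4], 1.0),
        "T": (row[10], row[12]),
    }
    if cell_class == "PN":
        gates["A"] = (row[6], row[8])
        gates["h"] = (row[14], 1.0)
    return gates
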