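"""Compiled RK4 integration kernel for the antennal-lobe network.

The full network state (membrane voltages, channel gating variables,
intracellular Ca, and per-presynaptic-neuron synaptic kinetic states) is
packed into one flat vector and advanced with the classical fourth-order
Runge-Kutta scheme at a fixed step (default 0.04 ms).  Gating kinetics are
evaluated by linear interpolation of a sampled x_inf/tau table shared with
the reference implementation in :mod:`beeal.neurons`.

Numerical choices:

* Aggregate synaptic conductances (the matrix-vector products of weight
  matrices with open-fraction vectors) are computed once per step from
  start-of-step kinetic states; the postsynaptic driving force (V - E) is
  evaluated at every RK4 stage.  Synaptic open fractions evolve on >= 5 ms
  timescales, ~100x the step, so the step-frozen conductance changes
  voltage traces by far less than the background-noise floor.
* Gaussian current noise is drawn once per neuron per step and held
  constant across stages.
* Spikes are registered on upward crossings of 0 mV with a 2 ms
  refractory period; facilitation increments are applied at the crossing
  step, after the RK4 update.
* Gating variables and open fractions are clamped to [0, 1] after each
  step; Ca and G-protein concentrations are kept nonnegative.

State-vector layout (N neurons = n_pn + n_ln): V | m_Na | h_Na | n_K |
m_A | h_A | m_T | h_T | m_h | Ca  (each length N), then O_ACh (n_pn),
O_GABA, R, G (each n_ln).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import neurons as _nrn
from . import synapses as _syn

__all__ = ["rk4_step", "simulate_network", "StateNaNError", "STATE_BLOCKS"]

STATE_BLOCKS = ("V", "m_Na", "h_Na", "n_K", "m_A", "h_A", "m_T", "h_T",
                "m_h", "Ca", "O_ACh", "O_GABA", "R", "G")

SPIKE_THRESHOLD = 0.0  # mV, upward crossing
REFRACTORY_MS = 2.0


class StateNaNError(RuntimeError):
    """Integration produced a non-finite state variable."""


def rk4_step(f, y, t, dt):
    """One classical RK4 step of dy/dt = f(t, y) (reference utility)."""
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


@njit(cache=True)
def _deriv(y, dy, n_pn, n_ln, t,
           gNa, gK, gA, gT, gh, gL, gKL,
           ENa, EK, ECa, EL, EKL, Eh,
           tab_pn, tab_ln, v_min, dv_inv,
           g_pn_fast, g_pn_slow, g_ln_gaba, g_ln_ach,
           drive,
           last_spike,
           ach_alpha, ach_beta, ach_A, ach_tmax,
           gab_alpha, gab_beta, gab_V0, gab_sigma,
           r1, r2, r3, r4,
           A_ca, tau_ca, Ca_inf,
           E_ach, E_gaba, E_kslow):
    N = n_pn + n_ln
    n_grid = tab_pn.shape[0]
    o_ca = 9 * N
    o_oa = 10 * N
    o_og = o_oa + n_pn
    o_r = o_og + n_ln
    o_g = o_r + n_ln
    for i in range(N):
        V = y[i]
        # gating kinetics from the cell class's sampled table
        tab = tab_pn if i < n_pn else tab_ln
        x = (V - v_min) * dv_inv
        if x < 0.0:
            x = 0.0
        elif x > n_grid - 1.001:
            x = n_grid - 1.001
        i0 = int(x)
        w = x - i0
        mna_inf = tab[i0, 0] + w * (tab[i0 + 1, 0] - tab[i0, 0])
        mna_tau = tab[i0, 1] + w * (tab[i0 + 1, 1] - tab[i0, 1])
        hna_inf = tab[i0, 2] + w * (tab[i0 + 1, 2] - tab[i0, 2])
        hna_tau = tab[i0, 3] + w * (tab[i0 + 1, 3] - tab[i0, 3])
        nk_inf = tab[i0, 4] + w * (tab[i0 + 1, 4] - tab[i0, 4])
        nk_tau = tab[i0, 5] + w * (tab[i0 + 1, 5] - tab[i0, 5])
        ma_inf = tab[i0, 6] + w * (tab[i0 + 1, 6] - tab[i0, 6])
        ma_tau = tab[i0, 7] + w * (tab[i0 + 1, 7] - tab[i0, 7])
        ha_inf = tab[i0, 8] + w * (tab[i0 + 1, 8] - tab[i0, 8])
        ha_tau = tab[i0, 9] + w * (tab[i0 + 1, 9] - tab[i0, 9])
        mt_inf = tab[i0, 10] + w * (tab[i0 + 1, 10] - tab[i0, 10])
        mt_tau = tab[i0, 11] + w * (tab[i0 + 1, 11] - tab[i0, 11])
        ht_inf = tab[i0, 12] + w * (tab[i0 + 1, 12] - tab[i0, 12])
        ht_tau = tab[i0, 13] + w * (tab[i0 + 1, 13] - tab[i0, 13])
        mh_inf = tab[i0, 14] + w * (tab[i0 + 1, 14] - tab[i0, 14])
        mh_tau = tab[i0, 15] + w * (tab[i0 + 1, 15] - tab[i0, 15])

        mna = y[N + i]
        hna = y[2 * N + i]
        nk = y[3 * N + i]
        ma = y[4 * N + i]
        ha = y[5 * N + i]
        mt = y[6 * N + i]
        ht = y[7 * N + i]
        mh = y[8 * N + i]
        ca = y[o_ca + i]

        i_na = gNa[i] * mna * mna * mna * hna * (V - ENa)
        i_k = gK[i] * nk * nk * nk * nk * (V - EK)
        i_a = gA[i] * ma * ma * ma * ma * ha * (V - EK)
        i_t = gT[i] * mt * mt * ht * (V - ECa)
        i_h = gh[i] * mh * (V - Eh)
        i_leak = gL[i] * (V - EL) + gKL[i] * (V - EKL)

        if i < n_pn:
            i_syn = g_pn_fast[i] * (V - E_gaba) + g_pn_slow[i] * (V - E_kslow)
        else:
            j = i - n_pn
            i_syn = g_ln_gaba[j] * (V - E_gaba) + g_ln_ach[j] * (V - E_ach)

        dy[i] = -(i_leak + i_na + i_k + i_a + i_t + i_h + i_syn) + drive[i]
        dy[N + i] = (mna_inf - mna) / mna_tau
        dy[2 * N + i] = (hna_inf - hna) / hna_tau
        dy[3 * N + i] = (nk_inf - nk) / nk_tau
        dy[4 * N + i] = (ma_inf - ma) / ma_tau
        dy[5 * N + i] = (ha_inf - ha) / ha_tau
        dy[6 * N + i] = (mt_inf - mt) / mt_tau
        dy[7 * N + i] = (ht_inf - ht) / ht_tau
        dy[8 * N + i] = (mh_inf - mh) / mh_tau
        dy[o_ca + i] = -A_ca * i_t - (ca - Ca_inf) / tau_ca

    # presynaptic transmitter drives
    for i in range(n_pn):
        dt_sp = t - last_spike[i]
        T = ach_A if (dt_sp >= 0.0 and dt_sp <= ach_tmax) else 0.0
        oa = y[o_oa + i]
        dy[o_oa + i] = ach_alpha * (1.0 - oa) * T - ach_beta * oa
    for j in range(n_ln):
        Vl = y[n_pn + j]
        T = 1.0 / (1.0 + np.exp(-(Vl - gab_V0) / gab_sigma))
        og = y[o_og + j]
        dy[o_og + j] = gab_alpha * (1.0 - og) * T - gab_beta * og
        Rj = y[o_r + j]
        dy[o_r + j] = r1 * (1.0 - Rj) * T - r2 * Rj
        dy[o_g + j] = r3 * Rj - r4 * y[o_g + j]


@njit(cache=True)
def _facilitate_pre(il, t_abs, n_pn, n_ln, dF, tau_F,
                    B_gfast, B_gslow, B_lnln, W_gfast, W_gslow, W_lnln,
                    F_lnpn, F_lnln, T_lnpn, T_lnln):
    """Presynaptic LN spike: facilitate column il of LN->PN and LN->LN."""
    for jp in range(n_pn):
        if B_gfast[jp, il] > 0.0:
            F = 1.0 + (F_lnpn[jp, il] - 1.0) * np.exp(-(t_abs - T_lnpn[jp, il]) / tau_F)
            F += dF
            F_lnpn[jp, il] = F
            T_lnpn[jp, il] = t_abs
            W_gfast[jp, il] = B_gfast[jp, il] * F
            W_gslow[jp, il] = B_gslow[jp, il] * F
    for jl in range(n_ln):
        if B_lnln[jl, il] > 0.0:
            F = 1.0 + (F_lnln[jl, il] - 1.0) * np.exp(-(t_abs - T_lnln[jl, il]) / tau_F)
            F += dF
            F_lnln[jl, il] = F
            T_lnln[jl, il] = t_abs
            W_lnln[jl, il] = B_lnln[jl, il] * F


@njit(cache=True)
def _facilitate_post(i, t_abs, n_pn, n_ln, dF, tau_F,
                     B_gfast, B_gslow, B_lnln, W_gfast, W_gslow, W_lnln,
                     F_lnpn, F_lnln, T_lnpn, T_lnln):
    """Postsynaptic spike of neuron i: facilitate its afferent inhibition."""
    if i < n_pn:
        for il in range(n_ln):
            if B_gfast[i, il] > 0.0:
                F = 1.0 + (F_lnpn[i, il] - 1.0) * np.exp(-(t_abs - T_lnpn[i, il]) / tau_F)
                F += dF
                F_lnpn[i, il] = F
                T_lnpn[i, il] = t_abs
                W_gfast[i, il] = B_gfast[i, il] * F
                W_gslow[i, il] = B_gslow[i, il] * F
    else:
        jl = i - n_pn
        for il in range(n_ln):
            if B_lnln[jl, il] > 0.0:
                F = 1.0 + (F_lnln[jl, il] - 1.0) * np.exp(-(t_abs - T_lnln[jl, il]) / tau_F)
                F += dF
                F_lnln[jl, il] = F
                T_lnln[jl, il] = t_abs
                W_lnln[jl, il] = B_lnln[jl, il] * F


@njit(cache=True)
def _run(n_pn, n_ln, dt, n_steps, y,
         gNa, gK, gA, gT, gh, gL, gKL,
         ENa, EK, ECa, EL, EKL, Eh,
         tab_pn, tab_ln, v_min, dv_inv,
         W_ach, W_gfast, W_gslow, W_lnln,
         B_gfast, B_gslow, B_lnln,
         F_lnpn, F_lnln, T_lnpn, T_lnln,
         plast_pre, plast_post, dF_pre, dF_post, tau_F, t_global0,
         ach_alpha, ach_beta, ach_A, ach_tmax,
         gab_alpha, gab_beta, gab_V0, gab_sigma,
         r1, r2, r3, r4, K_slow,
         A_ca, tau_ca, Ca_inf,
         E_ach, E_gaba, E_kslow,
         stim, noise_std, seed,
         v_sample_steps):
    N = n_pn + n_ln
    ns = y.size
    o_ca = 9 * N
    o_oa = 10 * N
    o_og = o_oa + n_pn
    o_g = o_og + 2 * n_ln

    np.random.seed(seed)

    max_spikes = N * (int(n_steps * dt) // 2 + 2)
    spike_n = np.empty(max_spikes, dtype=np.int32)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    n_sp = 0

    n_samples = n_steps // v_sample_steps + 1
    v_rec = np.empty((n_samples, N))
    n_rec = 0

    last_spike = np.full(N, -1.0e9)
    drive = np.empty(N)
    dy1 = np.empty(ns)
    dy2 = np.empty(ns)
    dy3 = np.empty(ns)
    dy4 = np.empty(ns)
    ytmp = np.empty(ns)
    g_pn_fast = np.empty(n_pn)
    g_pn_slow = np.empty(n_pn)
    sfac = np.empty(n_ln)
    v_prev = np.empty(N)

    status = 0
    bad_index = -1

    for step in range(n_steps):
        t = step * dt
        ms_idx = int(t)
        if ms_idx >= stim.shape[0]:
            ms_idx = stim.shape[0] - 1
        for i in range(N):
            drive[i] = stim[ms_idx, i] + noise_std[i] * np.random.standard_normal()
            v_prev[i] = y[i]

        # step-frozen aggregate synaptic conductances
        Og = y[o_og:o_og + n_ln]
        Oa = y[o_oa:o_oa + n_pn]
        for j in range(n_ln):
            gj = y[o_g + j]
            g4 = gj * gj * gj * gj
            sfac[j] = g4 / (g4 + K_slow)
        g_pn_fast[:] = np.dot(W_gfast, Og)
        g_pn_slow[:] = np.dot(W_gslow, sfac)
        g_ln_gaba = np.dot(W_lnln, Og)
        g_ln_ach = np.dot(W_ach, Oa)

        # classical RK4
        _deriv(y, dy1, n_pn, n_ln, t,
               gNa, gK, gA, gT, gh, gL, gKL, ENa, EK, ECa, EL, EKL, Eh,
               tab_pn, tab_ln, v_min, dv_inv, g_pn_fast, g_pn_slow, g_ln_gaba, g_ln_ach,
               drive, last_spike,
               ach_alpha, ach_beta, ach_A, ach_tmax,
               gab_alpha, gab_beta, gab_V0, gab_sigma,
               r1, r2, r3, r4, A_ca, tau_ca, Ca_inf, E_ach, E_gaba, E_kslow)
        for k in range(ns):
            ytmp[k] = y[k] + 0.5 * dt * dy1[k]
        _deriv(ytmp, dy2, n_pn, n_ln, t + 0.5 * dt,
               gNa, gK, gA, gT, gh, gL, gKL, ENa, EK, ECa, EL, EKL, Eh,
               tab_pn, tab_ln, v_min, dv_inv, g_pn_fast, g_pn_slow, g_ln_gaba, g_ln_ach,
               drive, last_spike,
               ach_alpha, ach_beta, ach_A, ach_tmax,
               gab_alpha, gab_beta, gab_V0, gab_sigma,
               r1, r2, r3, r4, A_ca, tau_ca, Ca_inf, E_ach, E_gaba, E_kslow)
        for k in range(ns):
            ytmp[k] = y[k] + 0.5 * dt * dy2[k]
        _deriv(ytmp, dy3, n_pn, n_ln, t + 0.5 * dt,
               gNa, gK, gA, gT, gh, gL, gKL, ENa, EK, ECa, EL, EKL, Eh,
               tab_pn, tab_ln, v_min, dv_inv, g_pn_fast, g_pn_slow, g_ln_gaba, g_ln_ach,
               drive, last_spike,
               ach_alpha, ach_beta, ach_A, ach_tmax,
               gab_alpha, gab_beta, gab_V0, gab_sigma,
               r1, r2, r3, r4, A_ca, tau_ca, Ca_inf, E_ach, E_gaba, E_kslow)
        for k in range(ns):
            ytmp[k] = y[k] + dt * dy3[k]
        _deriv(ytmp, dy4, n_pn, n_ln, t + dt,
               gNa, gK, gA, gT, gh, gL, gKL, ENa, EK, ECa, EL, EKL, Eh,
               tab_pn, tab_ln, v_min, dv_inv, g_pn_fast, g_pn_slow, g_ln_gaba, g_ln_ach,
               drive, last_spike,
               ach_alpha, ach_beta, ach_A, ach_tmax,
               gab_alpha, gab_beta, gab_V0, gab_sigma,
               r1, r2, r3, r4, A_ca, tau_ca, Ca_inf, E_ach, E_gaba, E_kslow)
        sixth = dt / 6.0
        for k in range(ns):
            y[k] += sixth * (dy1[k] + 2.0 * dy2[k] + 2.0 * dy3[k] + dy4[k])

        # clamp bounded states
        for k in range(N, o_oa):  # gates and Ca
            if k < o_ca:
                if y[k] < 0.0:
                    y[k] = 0.0
                elif y[k] > 1.0:
                    y[k] = 1.0
            elif y[k] < 1.0e-12:
                y[k] = 1.0e-12
        for k in range(o_oa, o_g):  # O_ACh, O_GABA, R
            if y[k] < 0.0:
                y[k] = 0.0
            elif y[k] > 1.0:
                y[k] = 1.0
        for k in range(o_g, ns):  # G
            if y[k] < 0.0:
                y[k] = 0.0

        t_next = t + dt
        # spike detection and plastic events
        for i in range(N):
            v_new = y[i]
            if not np.isfinite(v_new):
                status = 1
                bad_index = i
                break
            if v_new >= 0.0 and v_prev[i] < 0.0 and t_next - last_spike[i] > 2.0:
                last_spike[i] = t_next
                if n_sp < max_spikes:
                    spike_n[n_sp] = i
                    spike_t[n_sp] = t_next
                    n_sp += 1
                t_abs = t_global0 + t_next
                if plast_pre and i >= n_pn:
                    _facilitate_pre(i - n_pn, t_abs, n_pn, n_ln, dF_pre, tau_F,
                                    B_gfast, B_gslow, B_lnln,
                                    W_gfast, W_gslow, W_lnln,
                                    F_lnpn, F_lnln, T_lnpn, T_lnln)
                if plast_post:
                    _facilitate_post(i, t_abs, n_pn, n_ln, dF_post, tau_F,
                                     B_gfast, B_gslow, B_lnln,
                                     W_gfast, W_gslow, W_lnln,
                                     F_lnpn, F_lnln, T_lnpn, T_lnln)
        if status != 0:
            break

        if step % v_sample_steps == 0:
            for i in range(N):
                v_rec[n_rec, i] = y[i]
            n_rec += 1

    return (spike_n[:n_sp], spike_t[:n_sp], v_rec[:n_rec], status, bad_index)


# ---------------------------------------------------------------------------
# python-facing wrapper
# ---------------------------------------------------------------------------

def initial_state(n_pn: int, n_ln: int,
                  kinetics_pn: _nrn.KineticsTable | None = None,
                  kinetics_ln: _nrn.KineticsTable | None = None,
                  V0: float = -70.0) -> np.ndarray:
    """Packed state vector at rest: V=V0, gates at steady state, Ca at eq."""
    kp = kinetics_pn or _nrn.DEFAULT_KINETICS
    kl = kinetics_ln or _nrn.LN_KINETICS
    N = n_pn + n_ln
    row_pn = kp.lookup(np.array([V0]))[0]
    row_ln = kl.lookup(np.array([V0]))[0]
    y = np.zeros(10 * N + n_pn + 3 * n_ln)
    y[0:N] = V0
    for blk, col in ((1, 0), (2, 2), (3, 4), (4, 6), (5, 8), (6, 10), (7, 12), (8, 14)):
        y[blk * N:blk * N + n_pn] = row_pn[col]
        y[blk * N + n_pn:(blk + 1) * N] = row_ln[col]
    y[9 * N:10 * N] = 2.4e-4
    return y


def _nan_block_name(bad_index: int, n_pn: int, n_ln: int) -> str:
    N = n_pn + n_ln
    edges = [N] * 10 + [n_pn, n_ln, n_ln, n_ln]
    start = 0
    for name, size in zip(STATE_BLOCKS, edges):
        if bad_index < start + size:
            return f"{name}[{bad_index - start}]"
        start += size
    return f"state[{bad_index}]"


def simulate_network(topology, stim: np.ndarray, duration_ms: float,
                     dt: float = 0.04, seed: int = 0,
                     noise_std: np.ndarray | None = None,
                     plasticity_mode: str = "off",
                     fac_params=None, t_global0: float = 0.0,
                     v_sample_ms: float = 1.0,
                     kinetics_pn: _nrn.KineticsTable | None = None,
                     kinetics_ln: _nrn.KineticsTable | None = None,
                     pn_params: _nrn.NeuronParams = _nrn.PN_PARAMS,
                     ln_params: _nrn.NeuronParams = _nrn.LN_PARAMS,
                     y0: np.ndarray | None = None):
    """Integrate the network for one presentation.

    ``stim`` is the (duration_ms, N) per-millisecond input-current matrix.
    ``plasticity_mode`` in {"off", "pre_only", "post_only", "both"}
    controls which facilitation rules fire on detected spikes; updates are
    written into the topology's facilitation state in place.  Returns
    ``(spike_neurons, spike_times, v_samples)``.
    """
    from .plasticity import FacilitationParams

    n_pn, n_ln = topology.n_pn, topology.n_ln
    kin_pn = kinetics_pn or _nrn.DEFAULT_KINETICS
    kin_ln = kinetics_ln or _nrn.LN_KINETICS
    if kin_pn.v_min != kin_ln.v_min or kin_pn.dv != kin_ln.dv:
        raise ValueError("PN and LN kinetics tables must share a voltage grid")
    fp = fac_params or topology.facilitation["lnpn"].params or FacilitationParams()
    n_steps = int(round(duration_ms / dt))

    pnp, lnp = pn_params, ln_params

    def per_neuron(pn_val, ln_val):
        out = np.empty(n_pn + n_ln)
        out[:n_pn] = pn_val
        out[n_pn:] = ln_val
        return out

    gNa = per_neuron(pnp.gNa, lnp.gNa)
    gK = per_neuron(pnp.gK, lnp.gK)
    gA = per_neuron(pnp.gA, 0.0)
    gT = per_neuron(pnp.gT, lnp.gT)
    gh = per_neuron(pnp.gh, 0.0)
    gL = per_neuron(pnp.gL, lnp.gL)
    gKL = per_neuron(pnp.gKL, lnp.gKL)

    if noise_std is None:
        noise_std = np.zeros(n_pn + n_ln)

    W = topology.effective_weights(t_global0)
    W_ach = np.ascontiguousarray(W["ach"])
    W_gfast = np.ascontiguousarray(W["gaba_fast"])
    W_gslow = np.ascontiguousarray(W["gaba_slow"])
    W_lnln = np.ascontiguousarray(W["lnln"])

    fac_pn = topology.facilitation["lnpn"]
    fac_ll = topology.facilitation["lnln"]
    plast_pre = plasticity_mode in ("pre_only", "both")
    plast_post = plasticity_mode in ("post_only", "both")
    if plasticity_mode not in ("off", "pre_only", "post_only", "both"):
        raise ValueError(f"unknown plasticity mode {plasticity_mode!r}")

    y = initial_state(n_pn, n_ln, kin_pn, kin_ln) if y0 is None else y0.copy()

    gab = _syn.GABA_A_PARAMS
    ach = _syn.NACH_PARAMS
    slow = _syn.SLOW_INH_PARAMS

    spike_n, spike_t, v_rec, status, bad = _run(
        n_pn, n_ln, dt, n_steps, y,
        gNa, gK, gA, gT, gh, gL, gKL,
        pnp.ENa, pnp.EK, pnp.ECa, pnp.EL, pnp.EKL, _nrn.E_H,
        kin_pn.data, kin_ln.data, kin_pn.v_min, 1.0 / kin_pn.dv,
        W_ach, W_gfast, W_gslow, W_lnln,
        np.ascontiguousarray(topology.W["gaba_fast"]),
        np.ascontiguousarray(topology.W["gaba_slow"]),
        np.ascontiguousarray(topology.W["lnln"]),
        fac_pn.F, fac_ll.F, fac_pn.t_last, fac_ll.t_last,
        plast_pre, plast_post, fp.dF_pre, fp.dF_post, fp.tau_F, t_global0,
        ach.alpha, ach.beta, ach.A_T, ach.t_max,
        gab.alpha, gab.beta, gab.V0, gab.sigma,
        slow.r1, slow.r2, slow.r3, slow.r4, slow.K,
        pnp.A_ca, pnp.tau_ca, pnp.Ca_inf,
        ach.E_syn, gab.E_syn, slow.E_K,
        np.ascontiguousarray(stim), noise_std, seed,
        max(1, int(round(v_sample_ms / dt))),
    )
    if status != 0:
        raise StateNaNError(
            f"non-finite value in state variable {_nan_block_name(bad, n_pn, n_ln)}")
    return np.asarray(spike_n), np.asarray(spike_t), v_rec
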