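"""Spike-triggered facilitation of inhibitory synapses.

Every LN->PN and LN->LN synapse carries a multiplicative facilitation
variable F >= 1.  On each spike the rule matched to the class of the odor
being presented fires:

* presynaptic (associative, reward-gated): a presynaptic LN spike adds
  dF_pre to F of all its outgoing inhibitory synapses,
* postsynaptic (nonassociative, habituation-gated): a postsynaptic spike
  adds dF_post to F of all inhibitory synapses onto the spiking cell.

Between spiking events F relaxes exponentially back to 1 with a slow time
constant (default 30 s), which also implements the "forgetting" used in
the two-environment experiments.  Decay is applied lazily: F is stored
with the timestamp of its last update and decayed on read/update, which is
numerically identical to continuous decay for this two-equation rule.

PN->LN cholinergic weights are fixed; only the inhibitory network is
plastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FacilitationParams", "FacilitationState", "MODES",
    "apply_spike_facilitation", "decay_facilitation",
    "freeze_weights", "shuffle_weights",
]

MODES = ("pre_only", "post_only", "both", "off")


@dataclass(frozen=True)
class FacilitationParams:
    dF_pre: float = 0.15
    dF_post: float = 0.15
    tau_F: float = 30_000.0  # ms

    def __post_init__(self):
        if self.tau_F <= 0:
            raise ValueError("tau_F must be positive")


@dataclass
class FacilitationState:
    """Per-synapse facilitation multiplier with lazy-decay bookkeeping."""

    F: np.ndarray  # (n_post, n_pre), >= 1 where an edge exists
    t_last: np.ndarray  # ms of last update per edge
    params: FacilitationParams = FacilitationParams()

    @classmethod
    def ones(cls, shape, params: FacilitationParams | None = None):
        return cls(F=np.ones(shape), t_last=np.zeros(shape),
                   params=params or FacilitationParams())

    def decayed(self, t: float) -> np.ndarray:
        """F decayed from each edge's last event to time t (no mutation)."""
        return decay_facilitation(self.F, t - self.t_last, self.params.tau_F)

    def settle(self, t: float) -> None:
        """Apply lazy decay in place up to time t."""
        self.F = self.decayed(t)
        self.t_last = np.full_like(self.t_last, t)


def apply_spike_facilitation(F, is_pre_spike: bool, is_post_spike: bool,
                             mode: str, params: FacilitationParams = FacilitationParams()):
    """Increment F for one spike event under the given plasticity mode.

    ``mode`` selects which increments are live: during rewarded-odor
    presentations the presynaptic rule is active (``pre_only``/``both``),
    during habituated presentations the postsynaptic rule
    (``post_only``/``both``); ``off`` disables both.
    """
    if mode not in MODES:
        raise ValueError(f"unknown plasticity mode {mode!r}")
    F = np.asarray(F, dtype=float)
    if np.any(F < 1.0):
        raise ValueError("facilitation multiplier must be >= 1")
    inc = 0.0
    if mode in ("pre_only", "both") and is_pre_spike:
        inc += params.dF_pre
    if mode in ("post_only", "both") and is_post_spike:
        inc += params.dF_post
    return F + inc


def decay_facilitation(F, dt_since_event, tau_F=30_000.0):
    """F(t) = 1 + (F - 1) * exp(-dt/tau_F); fixed point at F = 1."""
    if np.any(np.asarray(dt_since_event) < 0):
        raise ValueError("elapsed time must be nonnegative")
    F = np.asarray(F, dtype=float)
    return 1.0 + (F - 1.0) * np.exp(-np.asarray(dt_since_event, dtype=float) / tau_F)


def freeze_weights(topology, t: float | None = None):
    """Capture effective conductances g_max * F as static test-phase weights.

    Decays every facilitation variable to ``t`` (default: the topology's
    training-end time), marks the topology frozen, and returns the dict of
    effective weight matrices.  Freezing twice is idempotent.  Raises if
    the topology reports an unfinished training stage.
    """
    if getattr(topology, "training_active", False):
        raise RuntimeError("cannot freeze weights mid-training")
    if t is None:
        t = getattr(topology, "t_now", 0.0)
    if not getattr(topology, "frozen", False):
        for fac in topology.facilitation.values():
            fac.settle(t)
        topology.frozen = True
    return topology.effective_weights()


def shuffle_weights(topology, rng_seed: int):
    """Permute trained facilitation values within each plastic synapse class.

    Returns a deep-copied topology whose per-class multiset of F values on
    existing connections is identical but randomly reassigned across those
    connections, destroying learned structure while preserving the total
    inhibitory drive exactly.
    """
    import copy

    rng = np.random.default_rng(rng_seed)
    shuffled = copy.deepcopy(topology)
    n_edges = 0
    for name, fac in shuffled.facilitation.items():
        mask = shuffled.edge_mask(name)
        n_edges += int(mask.sum())
        vals = fac.F[mask]
        fac.F = fac.F.copy()
        fac.F[mask] = rng.permutation(vals)
    if n_edges == 0:
        raise ValueError("topology has no plastic synapses to shuffle")
    return shuffled
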