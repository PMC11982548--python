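"""Antennal-lobe network topology.

The reference network contains 100 PNs and 280 LNs organized into 20
glomeruli of 5 PNs and 12 unipolar LNs each, plus 40 glomerulus-free
multipolar LNs providing global inhibition.  Directed connections are
drawn independently per admissible pair with class-specific Bernoulli
probabilities; unipolar LNs never contact cells of their own glomerulus
and PNs never contact each other.

Four directed synapse classes are materialized as dense (post, pre)
weight matrices in specific units (mS/cm^2):

* ``ach``        PN -> LN, nicotinic cholinergic (fixed weights)
* ``gaba_fast``  LN -> PN, fast GABA_A (plastic)
* ``gaba_slow``  LN -> PN, slow G-protein inhibition (plastic, shares the
  fast adjacency: one LN->PN pathway with two receptor types)
* ``lnln``       LN -> LN, fast GABA_A (plastic)

The printed class conductances (uS) are interpreted as per-target totals:
each edge receives g_class / n_afferents(post), divided by the
postsynaptic membrane area to reach specific units.  A 4x-scaled variant
with uniform connectivity supports the sensor-data experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neurons import LN_AREA_CM2, PN_AREA_CM2
from .plasticity import FacilitationParams, FacilitationState

__all__ = [
    "Glomerulus", "NetworkTopology", "ConnectionProbabilities",
    "build_al_network", "build_large_network",
    "SMALL_NET_CONDUCTANCES", "LARGE_NET_CONDUCTANCES",
]

#: class conductance totals, uS (printed values)
SMALL_NET_CONDUCTANCES = {
    "lnln": 0.02, "gaba_fast": 0.015, "ach": 0.3, "gaba_slow": 0.02,
}
LARGE_NET_CONDUCTANCES = {
    "lnln": 0.024, "gaba_fast": 0.019, "ach": 0.075, "gaba_slow": 0.02,
}


@dataclass(frozen=True)
class ConnectionProbabilities:
    """Bernoulli edge probabilities between neuron groups."""

    pn_to_uni: float = 0.4
    pn_to_multi: float = 0.4
    uni_to_pn_other: float = 0.5  # same-glomerulus probability is 0
    uni_to_uni_other: float = 0.4  # same-glomerulus probability is 0
    uni_to_multi: float = 0.3
    multi_to_pn: float = 0.3
    multi_to_multi: float = 0.1
    multi_to_uni: float = 0.4


@dataclass(frozen=True)
class Glomerulus:
    id: int
    pn_ids: tuple
    unipolar_ln_ids: tuple


@dataclass
class NetworkTopology:
    """Dense-matrix network with per-edge facilitation state."""

    n_pn: int
    n_ln: int
    glomeruli: list
    n_multipolar: int
    masks: dict  # "ach" (n_ln,n_pn), "lnpn" (n_pn,n_ln), "lnln" (n_ln,n_ln)
    W: dict  # base specific weights per synapse class, mS/cm^2
    conductances: dict  # class totals in uS (provenance)
    facilitation: dict = field(default_factory=dict)  # "lnpn", "lnln"
    seed: int = 0
    frozen: bool = False
    training_active: bool = False
    t_now: float = 0.0  # global protocol time, ms

    def __post_init__(self):
        if not self.facilitation:
            self.facilitation = {
                "lnpn": FacilitationState.ones((self.n_pn, self.n_ln)),
                "lnln": FacilitationState.ones((self.n_ln, self.n_ln)),
            }

    # -- facilitation plumbing -------------------------------------------
    def edge_mask(self, fac_name: str) -> np.ndarray:
        return self.masks["lnpn" if fac_name == "lnpn" else "lnln"]

    def set_facilitation_params(self, params: FacilitationParams) -> None:
        for fac in self.facilitation.values():
            fac.params = params

    def effective_weights(self, t: float | None = None) -> dict:
        """Base weights times facilitation (lazily decayed to time t)."""
        if t is None:
            t = self.t_now
        F_lnpn = (self.facilitation["lnpn"].F if self.frozen
                  else self.facilitation["lnpn"].decayed(t))
        F_lnln = (self.facilitation["lnln"].F if self.frozen
                  else self.facilitation["lnln"].decayed(t))
        return {
            "ach": self.W["ach"],
            "gaba_fast": self.W["gaba_fast"] * F_lnpn,
            "gaba_slow": self.W["gaba_slow"] * F_lnpn,
            "lnln": self.W["lnln"] * F_lnln,
        }

    # -- percept geometry -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.n_pn + self.n_ln

    def glomerulus_of_pn(self, pn: int) -> int:
        return pn // (self.n_pn // max(len(self.glomeruli), 1)) if self.glomeruli else -1

    # -- serialization -----------------------------------------------------
    _CLASS_SHAPES = ("ach", "gaba_fast", "gaba_slow", "lnln")

    def to_edge_frame(self) -> pd.DataFrame:
        """Edge list (source, target, class, g_base, F) over existing edges."""
        rows = []
        fmap = {"ach": None, "gaba_fast": "lnpn", "gaba_slow": "lnpn", "lnln": "lnln"}
        for cls in self._CLASS_SHAPES:
            W = self.W[cls]
            post, pre = np.nonzero(W)
            F = np.ones(len(post)) if fmap[cls] is None else self.facilitation[fmap[cls]].F[post, pre]
            rows.append(pd.DataFrame({
                "source": pre, "target": post, "class": cls,
                "g_base": W[post, pre], "F": F,
            }))
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write(f"# n_pn={self.n_pn} n_ln={self.n_ln} "
                  f"n_glomeruli={len(self.glomeruli)} "
                  f"n_multipolar={self.n_multipolar} seed={self.seed} "
                  f"frozen={int(self.frozen)}\n")
        self.to_edge_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load_csv(cls, path) -> "NetworkTopology":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        n_pn, n_ln = int(meta["n_pn"]), int(meta["n_ln"])
        n_glom = int(meta["n_glomeruli"])
        df = pd.read_csv(path, comment="#")
        shapes = {"ach": (n_ln, n_pn), "gaba_fast": (n_pn, n_ln),
                  "gaba_slow": (n_pn, n_ln), "lnln": (n_ln, n_ln)}
        W = {k: np.zeros(s) for k, s in shapes.items()}
        F = {"lnpn": np.ones((n_pn, n_ln)), "lnln": np.ones((n_ln, n_ln))}
        for cname, sub in df.groupby("class"):
            W[cname][sub["target"], sub["source"]] = sub["g_base"]
            if cname in ("gaba_fast", "lnln"):
                key = "lnpn" if cname == "gaba_fast" else "lnln"
                F[key][sub["target"], sub["source"]] = sub["F"]
        glomeruli = _make_glomeruli(n_glom, n_pn, n_ln - int(meta["n_multipolar"]))
        topo = cls(
            n_pn=n_pn, n_ln=n_ln, glomeruli=glomeruli,
            n_multipolar=int(meta["n_multipolar"]),
            masks={"ach": W["ach"] > 0, "lnpn": W["gaba_fast"] > 0,
                   "lnln": W["lnln"] > 0},
            W=W, conductances={}, seed=int(meta["seed"]),
            frozen=bool(int(meta["frozen"])),
        )
        topo.facilitation["lnpn"].F = F["lnpn"]
        topo.facilitation["lnln"].F = F["lnln"]
        return topo


def _make_glomeruli(n_glom: int, n_pn: int, n_uni: int) -> list:
    if n_glom == 0:
        return []
    pn_per = n_pn // n_glom
    uni_per = n_uni // n_glom
    return [
        Glomerulus(
            id=g,
            pn_ids=tuple(range(g * pn_per, (g + 1) * pn_per)),
            unipolar_ln_ids=tuple(range(g * uni_per, (g + 1) * uni_per)),
        )
        for g in range(n_glom)
    ]


def _specific(mask: np.ndarray, g_class_us: float, area_post: float) -> np.ndarray:
    """Per-edge specific weight: class total / n_afferents / membrane area."""
    n_in = mask.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n_in > 0, g_class_us * 1e-3 / (n_in * area_post), 0.0)
    return mask * w


def build_al_network(seed: int, n_glomeruli: int = 20, pn_per_glomerulus: int = 5,
                     uni_per_glomerulus: int = 12, multipolar_per_glomerulus: int = 2,
                     probabilities: ConnectionProbabilities | None = None,
                     conductances: dict | None = None) -> NetworkTopology:
    """Draw a glomerular AL network (defaults: 100 PNs, 240+40 LNs).

    Smaller, structurally identical networks are obtained by reducing
    ``n_glomeruli``; all group-wise connection probabilities and the
    zero-probability rules (no PN->PN, no same-glomerulus unipolar-LN
    edges) are preserved at any scale.
    """
    p = probabilities or ConnectionProbabilities()
    g_us = dict(SMALL_NET_CONDUCTANCES, **(conductances or {}))
    rng = np.random.default_rng(seed)

    n_pn = n_glomeruli * pn_per_glomerulus
    n_uni = n_glomeruli * uni_per_glomerulus
    n_multi = n_glomeruli * multipolar_per_glomerulus
    n_ln = n_uni + n_multi
    glomeruli = _make_glomeruli(n_glomeruli, n_pn, n_uni)

    glom_of_pn = np.repeat(np.arange(n_glomeruli), pn_per_glomerulus)
    glom_of_ln = np.concatenate([
        np.repeat(np.arange(n_glomeruli), uni_per_glomerulus),
        np.full(n_multi, -1),  # multipolar LNs are glomerulus-free
    ])
    is_multi = glom_of_ln < 0

    # PN -> LN (cholinergic), shape (n_ln, n_pn)
    p_ach = np.where(is_multi[:, None], p.pn_to_multi, p.pn_to_uni)
    mask_ach = rng.random((n_ln, n_pn)) < p_ach

    # LN -> PN, shape (n_pn, n_ln)
    same_glom_pn = glom_of_pn[:, None] == glom_of_ln[None, :]
    p_lnpn = np.where(is_multi[None, :], p.multi_to_pn, p.uni_to_pn_other)
    mask_lnpn = (rng.random((n_pn, n_ln)) < p_lnpn) & ~same_glom_pn

    # LN -> LN, shape (n_ln, n_ln)
    same_glom_ln = (glom_of_ln[:, None] == glom_of_ln[None, :]) & \
        ~is_multi[:, None] & ~is_multi[None, :]
    p_lnln = np.where(
        is_multi[None, :],  # presynaptic multipolar
        np.where(is_multi[:, None], p.multi_to_multi, p.multi_to_uni),
        np.where(is_multi[:, None], p.uni_to_multi, p.uni_to_uni_other),
    )
    mask_lnln = (rng.random((n_ln, n_ln)) < p_lnln) & ~same_glom_ln
    np.fill_diagonal(mask_lnln, False)

    W = {
        "ach": _specific(mask_ach, g_us["ach"], LN_AREA_CM2),
        "gaba_fast": _specific(mask_lnpn, g_us["gaba_fast"], PN_AREA_CM2),
        "gaba_slow": _specific(mask_lnpn, g_us["gaba_slow"], PN_AREA_CM2),
        "lnln": _specific(mask_lnln, g_us["lnln"], LN_AREA_CM2),
    }
    return NetworkTopology(
        n_pn=n_pn, n_ln=n_ln, glomeruli=glomeruli, n_multipolar=n_multi,
        masks={"ach": mask_ach, "lnpn": mask_lnpn, "lnln": mask_lnln},
        W=W, conductances=g_us, seed=seed,
    )


def build_large_network(seed: int, n_pn: int = 400, n_ln: int = 1120,
                        p: float = 0.125,
                        conductances: dict | None = None) -> NetworkTopology:
    """Uniformly connected 4x-scaled network for sensor-derived odors.

    LN->LN, LN->PN and PN->LN edges are each Bernoulli(p); there are no
    PN->PN connections and no glomerular structure.  Large-network
    conductance defaults (0.024/0.019/0.075 uS) are applied.
    """
    g_us = dict(LARGE_NET_CONDUCTANCES, **(conductances or {}))
    rng = np.random.default_rng(seed)
    mask_ach = rng.random((n_ln, n_pn)) < p
    mask_lnpn = rng.random((n_pn, n_ln)) < p
    mask_lnln = rng.random((n_ln, n_ln)) < p
    np.fill_diagonal(mask_lnln, False)
    W = {
        "ach": _specific(mask_ach, g_us["ach"], LN_AREA_CM2),
        "gaba_fast": _specific(mask_lnpn, g_us["gaba_fast"], PN_AREA_CM2),
        "gaba_slow": _specific(mask_lnpn, g_us["gaba_slow"], PN_AREA_CM2),
        "lnln": _specific(mask_lnln, g_us["lnln"], LN_AREA_CM2),
    }
    return NetworkTopology(
        n_pn=n_pn, n_ln=n_ln, glomeruli=[], n_multipolar=0,
        masks={"ach": mask_ach, "lnpn": mask_lnpn, "lnln": mask_lnln},
        W=W, conductances=g_us, seed=seed,
    )
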