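"""Shared fixtures: tiny deterministic networks and cached simulations."""

import numpy as np
import pytest

from beeal.network import NetworkTopology, build_al_network


def unconnected_topology(n_pn: int, n_ln: int) -> NetworkTopology:
    """Neurons with no synapses, for single-cell dynamics tests."""
    masks = {"ach": np.zeros((n_ln, n_pn), bool),
             "lnpn": np.zeros((n_pn, n_ln), bool),
             "lnln": np.zeros((n_ln, n_ln), bool)}
    W = {"ach": np.zeros((n_ln, n_pn)), "gaba_fast": np.zeros((n_pn, n_ln)),
         "gaba_slow": np.zeros((n_pn, n_ln)), "lnln": np.zeros((n_ln, n_ln))}
    return NetworkTopology(n_pn=n_pn, n_ln=n_ln, glomeruli=[], n_multipolar=0,
                           masks=masks, W=W, conductances={})


@pytest.fixture(scope="session")
def single_pair():
    """One PN and one LN, unconnected."""
    return unconnected_topology(1, 1)


@pytest.fixture(scope="session")
def tiny_topology():
    """2-glomerulus AL network: 10 PNs, 28 LNs."""
    return build_al_network(seed=42, n_glomeruli=2)


@pytest.fixture(scope="session")
def small_topology():
    """8-glomerulus AL network used by the slower integration tests."""
    return build_al_network(seed=7, n_glomeruli=8)
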