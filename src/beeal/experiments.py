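"""High-level experiment protocols built on the simulator.

These functions bundle network construction, training, frozen-weight test
panels and analysis into the study designs used throughout the package:

* :func:`conditioning_study` - naive vs trained between/within-class
  correlations for any subset of plasticity modes, plus the
  shuffled-weight control,
* :func:`contrast_enhancement_experiment` - the PH/PP blend experiment:
  per-percept uniqueness index vs change in activity after differential
  conditioning, with the OLS regression summary,
* :func:`environment_study` - the four two-environment relearning cases
  (re-exported from the simulator with network defaults applied).

Every function takes one integer seed controlling topology, odor
construction, presentation order and noise via independent derived
streams.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plasticity import FacilitationParams
from .analysis import (ContrastResult, change_in_activity, contrast_regression,
                       pairwise_panel_correlation, percept_activations,
                       uniqueness_index)
from .network import build_al_network
from .odors import OdorEnvironment, phpp_environment, simple_environment
from .plasticity import shuffle_weights
from .simulator import (SimulationConfig, TrainingProtocol,
                        run_environment_experiment, run_test_panel,
                        run_training, split_seed)

__all__ = ["StudyScale", "SMALL_SCALE", "ACCEPTANCE_SCALE",
           "conditioning_study", "contrast_enhancement_experiment",
           "environment_study"]


@dataclass(frozen=True)
class StudyScale:
    """Problem-size bundle: network size and protocol length.

    ``n_glomeruli=20`` reproduces the reference 100 PN / 280 LN network
    with the 30 x 2 s training protocol; smaller bundles keep the same
    architecture, probabilities and plasticity rule at reduced size for
    fast exploration and testing.
    """

    n_glomeruli: int = 20
    n_presentations: int = 30
    presentation_ms: float = 2000.0
    n_trials: int = 2  # frozen-weight test trials per odor

    @property
    def config(self) -> SimulationConfig:
        return SimulationConfig(trial_ms=self.presentation_ms)

    @property
    def facilitation(self) -> FacilitationParams:
        """Facilitation parameters with the forgetting time constant tied
        to the protocol length (tau_F = total training time / 2, which at
        the reference 30 x 2 s protocol equals the printed 30 s)."""
        return FacilitationParams(
            tau_F=self.n_presentations * self.presentation_ms / 2.0)


#: reduced scale used by the fast directional tests
SMALL_SCALE = StudyScale(n_glomeruli=8, n_presentations=12,
                         presentation_ms=1000.0, n_trials=1)
#: the reference network with the full training protocol
ACCEPTANCE_SCALE = StudyScale(n_glomeruli=20, n_presentations=30,
                              presentation_ms=2000.0, n_trials=1)


def _window(cfg: SimulationConfig):
    return (cfg.input.t_on, cfg.input.t_on + cfg.input.duration)


def _between_within(panel, env: OdorEnvironment, cfg, bin_ms=100.0):
    rew = [o.name for o in env.by_reward("rewarded")]
    hab = [o.name for o in env.by_reward("habituated")]
    win = _window(cfg)
    between = pairwise_panel_correlation(panel, rew, hab, bin_ms, win)
    w_r = pairwise_panel_correlation(panel, rew, rew, bin_ms, win)
    w_h = pairwise_panel_correlation(panel, hab, hab, bin_ms, win)
    within = np.nanmean([w_r, w_h])
    return between, float(within)


def conditioning_study(seed: int, modes=("both",), include_shuffled: bool = False,
                       scale: StudyScale = SMALL_SCALE,
                       environment: OdorEnvironment | None = None) -> pd.DataFrame:
    """Between/within-class correlations for naive and trained networks.

    Trains one fresh copy of the same naive network per plasticity mode
    ("both" = differential, "pre_only" = associative only, "post_only" =
    nonassociative only, "off" = sham) and measures frozen-weight
    correlations; ``include_shuffled`` adds the structure-destroying
    weight permutation of the "both"-trained network.  Returns one row per
    condition.
    """
    env_seed, net_seed, train_seed, test_seed, shuf_seed = split_seed(seed, 5)
    env = environment or simple_environment(env_seed)
    cfg = scale.config
    topo = build_al_network(net_seed, n_glomeruli=scale.n_glomeruli)

    def measure(t, label):
        panel = run_test_panel(t, list(env.odors), cfg, test_seed,
                               n_trials=scale.n_trials)
        b, w = _between_within(panel, env, cfg)
        return {"condition": label, "between": b, "within": w, "seed": seed}

    rows = [measure(topo, "naive")]
    trained_both = None
    for mode in modes:
        t2 = copy.deepcopy(topo)
        proto = TrainingProtocol(environment=env,
                                 n_presentations=scale.n_presentations,
                                 presentation_ms=scale.presentation_ms,
                                 mode=mode, facilitation=scale.facilitation)
        run_training(t2, proto, cfg, train_seed)
        rows.append(measure(t2, mode))
        if mode == "both":
            trained_both = t2
    if include_shuffled:
        if trained_both is None:
            raise ValueError("shuffled control requires the 'both' mode")
        rows.append(measure(shuffle_weights(trained_both, shuf_seed), "shuffled"))
    return pd.DataFrame(rows)


def contrast_enhancement_experiment(seed: int,
                                    scale: StudyScale = ACCEPTANCE_SCALE,
                                    environment: OdorEnvironment | None = None):
    """PH/PP differential conditioning and the contrast regression.

    Protocol: build the glomerular network, present the naive network with
    the PH (rewarded) and PP (habituated) blend odors to measure per-percept
    activations, train with differential conditioning, re-measure the
    rewarded-odor response, and regress the per-percept fractional change
    in activity on the naive uniqueness index.

    Returns ``(ContrastResult, frame)`` where the frame holds the stagewise
    between/within correlations of the same panels.
    """
    net_seed, train_seed, test_seed = split_seed(seed, 3, salt=7)
    env = environment or phpp_environment()
    cfg = scale.config
    win = _window(cfg)
    topo = build_al_network(net_seed, n_glomeruli=scale.n_glomeruli)
    rew_odors = env.by_reward("rewarded")
    hab_odors = env.by_reward("habituated")

    naive_panel = run_test_panel(topo, list(env.odors), cfg, test_seed,
                                 n_trials=scale.n_trials)
    recs = lambda panel, odors: [r for o in odors for r in panel[o.name]]
    act_rew_naive = percept_activations(recs(naive_panel, rew_odors),
                                        env.n_percepts, win)
    act_hab_naive = percept_activations(recs(naive_panel, hab_odors),
                                        env.n_percepts, win)

    proto = TrainingProtocol(environment=env,
                             n_presentations=scale.n_presentations,
                             presentation_ms=scale.presentation_ms, mode="both",
                             facilitation=scale.facilitation)
    run_training(topo, proto, cfg, train_seed)

    trained_panel = run_test_panel(topo, list(env.odors), cfg, test_seed,
                                   n_trials=scale.n_trials)
    act_rew_diff = percept_activations(recs(trained_panel, rew_odors),
                                       env.n_percepts, win)

    ui = uniqueness_index(act_rew_naive, act_hab_naive)
    change = change_in_activity(act_rew_diff, act_rew_naive)
    result = contrast_regression(ui, change)

    corr_rows = []
    for stage, panel in (("naive", naive_panel), ("post_training", trained_panel)):
        b, w = _between_within(panel, env, cfg)
        corr_rows.append({"stage": stage, "between": b, "within": w,
                          "seed": seed})
    return result, pd.DataFrame(corr_rows)


def environment_study(case: int, env2_reward_sign: str, seed: int,
                      scale: StudyScale = SMALL_SCALE,
                      n_odors_per_class: int = 10,
                      n_test_odors: int = 2) -> pd.DataFrame:
    """One two-environment relearning case at the given scale."""
    cfg = scale.config
    build = lambda s: build_al_network(split_seed(s, 1, salt=13)[0],
                                       n_glomeruli=scale.n_glomeruli)
    return run_environment_experiment(
        case, env2_reward_sign, seed, build, cfg,
        protocol_kwargs={"n_presentations": scale.n_presentations,
                         "presentation_ms": scale.presentation_ms,
                         "facilitation": scale.facilitation},
        n_odors_per_class=n_odors_per_class, n_test_odors=n_test_odors,
        n_trials=scale.n_trials)
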