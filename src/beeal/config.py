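"""Experiment configuration bundles and fixture generation.

Each named bundle resolves every tunable of one experiment protocol
(network size, odor environment, training schedule, input calibration,
GCN hyperparameters) into a schema-validated configuration.  Parameters
carry provenance notes: ``printed`` values come straight from the model
description (integration step, training schedule, facilitation rule,
synaptic conductances, connection probabilities), ``decided`` values are
package calibration or design choices (input amplitudes, noise levels,
Gaussian-width ranges, GCN widths).  Unknown keys are rejected on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ExperimentConfig", "BUNDLES", "load_config", "save_config",
           "make_fixture", "FIXTURES"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSection(_Section):
    kind: str = "glomerular"  # glomerular | large
    n_glomeruli: int = 20
    pn_per_glomerulus: int = 5
    uni_per_glomerulus: int = 12
    multipolar_per_glomerulus: int = 2
    large_n_pn: int = 400
    large_n_ln: int = 1120
    large_p: float = 0.125


class ProtocolSection(_Section):
    n_presentations: int = 30
    presentation_ms: float = 2000.0
    mode: str = "both"
    dF_pre: float = 0.15
    dF_post: float = 0.15
    tau_F_ms: float = 30000.0
    dt_ms: float = 0.04


class InputSection(_Section):
    peak_pn: float = 5.0
    peak_ln: float = 2.5
    multipolar_frac: float = 0.35
    noise_std_pn: float = 0.15
    noise_std_ln: float = 0.15
    t_on_ms: float = 200.0
    duration_ms: float = 500.0


class EnvironmentSection(_Section):
    kind: str = "simple"  # simple | phpp | case | sensor
    n_odors_per_class: int = 3
    case: int | None = None
    reward_sign: str | None = None
    width_lo: float = 0.25
    width_hi: float = 0.5


class GcnSection(_Section):
    d1: int = 8
    lr: float = 0.01
    epochs: int = 20
    reward_edge_dropout: float = 0.5
    normalize_adjacency: bool = False
    n_reps: int = 30


#: provenance of every leaf parameter: printed model description vs
#: package design/calibration decision
PROVENANCE = {
    "network": {k: "printed" for k in NetworkSection.model_fields},
    "protocol": {k: "printed" for k in ProtocolSection.model_fields},
    "input": {k: "decided" for k in InputSection.model_fields},
    "environment": dict({k: "decided" for k in EnvironmentSection.model_fields},
                        n_odors_per_class="printed"),
    "gcn": dict({k: "decided" for k in GcnSection.model_fields},
                lr="printed", epochs="printed"),
}
PROVENANCE["input"]["duration_ms"] = "printed"


class ExperimentConfig(_Section):
    bundle: str = "defaults"
    network: NetworkSection = Field(default_factory=NetworkSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    input: InputSection = Field(default_factory=InputSection)
    environment: EnvironmentSection = Field(default_factory=EnvironmentSection)
    gcn: GcnSection = Field(default_factory=GcnSection)

    def provenance(self) -> dict:
        return PROVENANCE

    # -- conversions into runtime objects ---------------------------------
    def input_config(self):
        from .odors import InputConfig

        i = self.input
        return InputConfig(peak_pn=i.peak_pn, peak_ln=i.peak_ln,
                           multipolar_frac=i.multipolar_frac,
                           noise_std_pn=i.noise_std_pn,
                           noise_std_ln=i.noise_std_ln,
                           t_on=i.t_on_ms, duration=i.duration_ms)

    def simulation_config(self):
        from .simulator import SimulationConfig

        return SimulationConfig(dt=self.protocol.dt_ms,
                                trial_ms=self.protocol.presentation_ms,
                                input=self.input_config())

    def build_network(self, seed: int):
        from .network import build_al_network, build_large_network

        n = self.network
        if n.kind == "large":
            return build_large_network(seed, n_pn=n.large_n_pn,
                                       n_ln=n.large_n_ln, p=n.large_p)
        return build_al_network(
            seed, n_glomeruli=n.n_glomeruli,
            pn_per_glomerulus=n.pn_per_glomerulus,
            uni_per_glomerulus=n.uni_per_glomerulus,
            multipolar_per_glomerulus=n.multipolar_per_glomerulus)

    def build_environment(self, seed: int):
        from .odors import environment_case, phpp_environment, simple_environment

        e = self.environment
        wr = (e.width_lo, e.width_hi)
        if e.kind == "simple":
            return simple_environment(seed, n_odors_per_class=e.n_odors_per_class,
                                      width_range=wr)
        if e.kind == "phpp":
            return phpp_environment(n_odors_per_class=e.n_odors_per_class)
        if e.kind == "case":
            return environment_case(e.case, e.reward_sign, seed,
                                    n_odors_per_class=e.n_odors_per_class,
                                    width_range=wr)
        if e.kind == "sensor":
            from .odors import sensor_odor_environment, synthetic_sensor_dataset

            feat, lab = synthetic_sensor_dataset(seed, n_reps=self.gcn.n_reps)
            return sensor_odor_environment(feat, lab)
        raise ValueError(f"environment kind {e.kind!r} has no builder")

    def training_protocol(self, environment):
        from .plasticity import FacilitationParams
        from .simulator import TrainingProtocol

        p = self.protocol
        return TrainingProtocol(
            environment=environment, n_presentations=p.n_presentations,
            presentation_ms=p.presentation_ms, mode=p.mode,
            facilitation=FacilitationParams(dF_pre=p.dF_pre, dF_post=p.dF_post,
                                            tau_F=p.tau_F_ms))


def _bundle(name: str, **sections) -> ExperimentConfig:
    return ExperimentConfig(bundle=name, **{
        k: v for k, v in sections.items()})


BUNDLES = {
    "defaults": ExperimentConfig(),
    "simple_conditioning": _bundle(
        "simple_conditioning",
        environment=EnvironmentSection(kind="simple", n_odors_per_class=3)),
    "mode_dissociation": _bundle(
        "mode_dissociation",
        environment=EnvironmentSection(kind="simple", n_odors_per_class=3)),
    "blend_contrast": _bundle(
        "blend_contrast",
        environment=EnvironmentSection(kind="phpp", n_odors_per_class=3)),
    "large_sensor": _bundle(
        "large_sensor",
        network=NetworkSection(kind="large"),
        environment=EnvironmentSection(kind="sensor", n_odors_per_class=3)),
    "gcn_analog": _bundle("gcn_analog"),
}
for _case in (1, 2, 3, 4):
    for _sign in ("pos", "neg"):
        BUNDLES[f"env_case{_case}{_sign}"] = _bundle(
            f"env_case{_case}{_sign}",
            environment=EnvironmentSection(kind="case", case=_case,
                                           reward_sign=_sign,
                                           n_odors_per_class=10))


def load_config(path) -> ExperimentConfig:
    """Load and schema-validate a YAML config; empty file -> defaults.

    A top-level ``bundle`` key starts from that named bundle's values;
    remaining keys override section fields.  Unknown keys raise a
    validation error naming the offending path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return ExperimentConfig()
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    bundle = raw.get("bundle", "defaults")
    if bundle in BUNDLES:
        base = BUNDLES[bundle].model_dump()
        for key, val in raw.items():
            if key == "bundle":
                continue
            if isinstance(val, dict):
                base.setdefault(key, {}).update(val)
            else:
                base[key] = val
        base["bundle"] = bundle
        return ExperimentConfig.model_validate(base)
    return ExperimentConfig.model_validate(raw)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# deterministic test fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("toy_network", "simple_odors", "sensor_table", "gcn_case")


def make_fixture(name: str, seed: int, out_dir) -> list:
    """Write one named deterministic fixture; returns the file paths.

    * ``toy_network`` - a 2-glomerulus (10 PN / 28 LN) topology edge list,
    * ``simple_odors`` - a 2-odor-per-class simple environment as YAML,
    * ``sensor_table`` - a 3-rep synthetic sensor feature table (CSV),
    * ``gcn_case`` - a 3-node, 2-feature graph-convolution example with
      the expected brute-force output (JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "toy_network":
        from .network import build_al_network

        topo = build_al_network(seed, n_glomeruli=2)
        path = out / f"toy_network_{seed}.csv"
        topo.save_csv(path)
        return [path]
    if name == "simple_odors":
        from .odors import simple_environment

        env = simple_environment(seed, n_odors_per_class=2)
        path = out / f"simple_odors_{seed}.yaml"
        path.write_text(yaml.safe_dump([
            {"name": o.name, "class": o.class_label, "reward": o.reward,
             "widths": [float(w) for w in o.widths]} for o in env.odors]))
        return [path]
    if name == "sensor_table":
        from .odors import synthetic_sensor_dataset

        feat, lab = synthetic_sensor_dataset(seed, n_reps=3)
        p1, p2 = out / f"sensor_features_{seed}.csv", out / f"sensor_labels_{seed}.csv"
        feat.round(6).to_csv(p1, index=False)
        lab.to_csv(p2, index=False)
        return [p1, p2]
    if name == "gcn_case":
        from .gcn import gcn_layer, relu

        rng = np.random.default_rng(seed)
        A = rng.integers(0, 2, size=(3, 3)).astype(float)
        H = rng.normal(size=(3, 2)).round(4)
        W = rng.normal(size=(2, 2)).round(4)
        path = out / f"gcn_case_{seed}.json"
        path.write_text(json.dumps({
            "A": A.tolist(), "H": H.tolist(), "W": W.tolist(),
            "expected": gcn_layer(H, A, W, relu).tolist()}, indent=1))
        return [path]
    raise ValueError(f"unknown fixture {name!r}")
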