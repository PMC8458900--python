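"""Run configuration: YAML loading, validation, defaults, provenance echo.

A run is fully determined by one YAML file plus one master seed.  Unknown
keys are rejected so typos fail loudly; the effective (post-default)
configuration can be re-serialized next to the outputs for provenance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model_core import NetworkSpec, ParameterSet
from .protocols import PulseProtocol, SimConfig

__all__ = ["RunConfig", "load_config", "default_basal"]


def default_basal() -> tuple[ParameterSet, float]:
    """The shipped basal parameter set and sigmoid gain."""
    ref = importlib.resources.files("hpa_pipeline.data") / "basal_default.yaml"
    raw = yaml.safe_load(ref.read_text())
    return ParameterSet.from_dict(raw["parameters"]), float(raw["sigma"])


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of the full pipeline."""

    sigma: float = 10.0
    basal: dict = field(default_factory=dict)   # empty -> shipped default
    n: int = 5000
    fold: float = 10.0
    pulse_t_on: float = 20.0
    pulse_duration: float = 10.0
    pulse_amplitude: float = 2.0
    scan_t_on: float = 40.0
    scan_duration: float = 10.0
    magnitude_max: float = 10.0
    n_treatments_per_patient: int = 1
    targeted_t_on: float = 60.0
    targeted_duration: float = 10.0
    safety_factor: float = 1.5
    tie_points: float = 10.0
    tol: float = 0.05
    horizon: float = 100.0
    dt_out: float = 0.1
    n_trees: int = 500
    n_permutations: int = 10
    tree_max_depth: int = 4
    tree_min_leaf: int = 5
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        positive = ["sigma", "fold", "pulse_duration", "scan_duration",
                    "targeted_duration", "magnitude_max", "tol", "horizon",
                    "dt_out", "safety_factor"]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"config key {name!r} must be > 0, got "
                                 f"{getattr(self, name)}")
        if self.fold <= 1:
            raise ValueError(f"config key 'fold' must be > 1, got {self.fold}")
        if self.n < 1:
            raise ValueError(f"config key 'n' must be >= 1, got {self.n}")
        if self.pulse_amplitude < 0:
            raise ValueError("config key 'pulse_amplitude' must be >= 0")
        if self.n_trees < 100:
            raise ValueError("config key 'n_trees' must be >= 100")
        for name in ("n_permutations", "tree_max_depth", "tree_min_leaf",
                     "n_treatments_per_patient"):
            if getattr(self, name) < 1:
                raise ValueError(f"config key {name!r} must be >= 1")
        # force full validation of the pieces the modules will construct
        self.basal_params()
        self.network_spec()
        self.pulse()

    # -- derived objects ---------------------------------------------------
    def basal_params(self) -> ParameterSet:
        if not self.basal:
            return default_basal()[0]
        return ParameterSet.from_dict(self.basal)

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(sigma=self.sigma)

    def pulse(self) -> PulseProtocol:
        return PulseProtocol(self.pulse_t_on, self.pulse_duration,
                             self.pulse_amplitude)

    def sim(self) -> SimConfig:
        return SimConfig(spec=self.network_spec(), horizon=self.horizon,
                         dt_out=self.dt_out, tol=self.tol)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        eff = asdict(self)
        if not eff["basal"]:
            eff["basal"] = self.basal_params().to_dict()
        Path(path).write_text(yaml.safe_dump(eff, sort_keys=False))


def load_config(path=None, **overrides) -> RunConfig:
    """Load and validate a YAML config; missing keys get defaults.

    An empty or absent file yields the all-default configuration.  Unknown
    keys raise, naming the key.  Keyword overrides (e.g. from CLI flags)
    take precedence over the file.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a YAML mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)
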