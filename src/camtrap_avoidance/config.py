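"""Run configuration: one YAML file wiring paths, species roles, exclusions,
test parameters, and (for simulation) the scenario."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import TestParams
from .simulate import Scenario

__all__ = ["AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """The configuration is inconsistent or incomplete."""


@dataclass
class AnalysisConfig:
    detections_path: str | None = None
    rolls_path: str | None = None
    species_roles: dict = field(default_factory=dict)
    excluded_cameras: list = field(default_factory=list)
    params: TestParams = field(default_factory=TestParams)
    scenario: Scenario | None = None
    output_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        params = TestParams(**raw.pop("params", {}) or {})
        scen_raw = raw.pop("scenario", None)
        scenario = None
        if scen_raw is not None:
            scen_raw = dict(scen_raw)
            for key in ("prey_diel", "predator_diel"):
                if key in scen_raw:
                    scen_raw[key] = tuple(scen_raw[key])
            scenario = Scenario(**scen_raw)
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(params=params, scenario=scenario, **raw)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    def require_species(self, species: str, role: str) -> None:
        """Fail fast when a requested species is absent or mis-roled."""
        got = self.species_roles.get(species)
        if got is None:
            raise ConfigError(f"species {species!r} not present in species_roles")
        if got != role:
            raise ConfigError(f"species {species!r} has role {got!r}, expected {role!r}")

    def resolve_output(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out
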