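"""Run configuration: packaged defaults plus YAML overrides."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .core import ArenaGeometry
from .simulate import BehaviorParams, PharmacodynamicParams


def load_defaults() -> dict:
    """Parsed copy of the packaged default calibration."""
    text = resources.files("openfield").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    raw: dict = field(default_factory=load_defaults)

    @classmethod
    def from_yaml(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        cfg = load_defaults()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            _deep_update(cfg, user)
        if overrides:
            _deep_update(cfg, copy.deepcopy(overrides))
        return cls(raw=cfg)

    @property
    def arena(self) -> ArenaGeometry:
        a = self.raw["arena"]
        return ArenaGeometry(
            side_length=a["side_length"],
            grid_cell=a["grid_cell"],
            wall_height=a.get("wall_height", 35.0),
        )

    @property
    def behavior(self) -> BehaviorParams:
        return BehaviorParams(**self.raw["behavior"])

    def pharmacodynamics(self, drug: str) -> PharmacodynamicParams:
        try:
            block = self.raw["pharmacodynamics"][drug]
        except KeyError as exc:
            raise KeyError(f"no pharmacodynamic block for drug {drug!r}") from exc
        return PharmacodynamicParams(**block)

    @property
    def pd_by_drug(self) -> dict[str, PharmacodynamicParams]:
        return {
            drug: self.pharmacodynamics(drug) for drug in self.raw["pharmacodynamics"]
        }

    @property
    def doses(self) -> dict[str, list[float]]:
        return {d: list(v) for d, v in self.raw["doses"].items()}

    @property
    def dt(self) -> float:
        return float(self.raw["recording"]["dt"])

    @property
    def duration(self) -> float:
        return float(self.raw["recording"]["duration_s"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def toi(self) -> tuple[float, float]:
        t = self.raw["toi"]
        return (float(t["start_min"]) * 60.0, float(t["end_min"]) * 60.0)

    @property
    def seg_kwargs(self) -> dict:
        m = self.raw["metrics"]
        return {
            "min_dur": float(m["min_dur"]),
            "v_thresh": float(m["v_thresh"]),
            "smooth_win": float(m["smooth_win"]),
            "gap_merge": float(m["gap_merge"]),
        }

    @property
    def filter_cap(self) -> float:
        return float(self.raw["metrics"]["filter_cap"])

    @property
    def sidak_family(self) -> str:
        return str(self.raw["stats"]["sidak_family"])

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
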