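"""Pipeline configuration: parsing, validation, canonical serialization.

A run is described by one YAML/dict config. Inputs come either from a
``simulate`` block (the synthetic generator) or from an ``inputs`` block
of raster paths. Validation is fail-fast: every referenced path must
resolve before any stage executes, and the config round-trips losslessly
through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .carbon import DEFAULT_CARBON_PARAMS, CropCarbonParams
from .grids import GridSpec
from .synthetic import (
    DEFAULT_CROP_TRUTHS,
    DEFAULT_SCENARIOS,
    BaselineClimateParams,
    CropTruthParams,
    EcologyParams,
    EnsembleParams,
    PeriodForcing,
)

BUILTIN_REGIONS = ("tropics", "global")


@dataclass
class SimulateBlock:
    ocean_fraction: float = 0.2
    climate: BaselineClimateParams = field(default_factory=BaselineClimateParams)
    ensemble: EnsembleParams = field(default_factory=EnsembleParams)
    crops: tuple[CropTruthParams, ...] = DEFAULT_CROP_TRUTHS
    scenarios: dict[str, dict[str, PeriodForcing]] = field(
        default_factory=lambda: {
            s: dict(p) for s, p in DEFAULT_SCENARIOS.items()
        }
    )
    ecology: EcologyParams = field(default_factory=EcologyParams)
    #: "ensemble" derives futures from the multi-model generator;
    #: "planted" constructs per-period futures with planted outside
    #: fractions (single-crop configs only).
    future_mode: str = "ensemble"
    planted_fractions: dict[str, float] = field(default_factory=dict)
    planted_scenario: str = "planted"
    planted_bump: float = 5.0


@dataclass
class InputsBlock:
    """External-raster mode: paths checked for existence at parse time."""

    baseline_nc: str = ""
    futures: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    crops: dict[str, str] = field(default_factory=dict)
    agb: str = ""
    richness: str = ""
    total_npp: str = ""
    intact: str = ""


@dataclass
class PipelineConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(50, 50, -30, 30, -30, 30))
    coverage_target: float = 0.95
    envelope_mode: str = "rectangular"
    density_bins: tuple[int, int] = (100, 100)
    regions: dict[str, str] = field(
        default_factory=lambda: {"tropics": "tropics", "global": "global"}
    )
    carbon_region: str = "tropics"
    carbon_params: dict[str, CropCarbonParams] = field(
        default_factory=lambda: dict(DEFAULT_CARBON_PARAMS)
    )
    shoot_as_divisor: bool = False
    terciles: bool = False
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    inputs: InputsBlock | None = None

    def validate(self) -> None:
        if not (0.0 < self.coverage_target <= 1.0):
            raise ValueError("coverage_target must lie in (0, 1]")
        if self.envelope_mode not in ("rectangular", "density"):
            raise ValueError(f"unknown envelope_mode '{self.envelope_mode}'")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        for name, source in self.regions.items():
            if source not in BUILTIN_REGIONS and not Path(source).exists():
                raise FileNotFoundError(f"region '{name}': raster '{source}' not found")
        if self.carbon_region not in self.regions:
            raise ValueError(f"carbon_region '{self.carbon_region}' not in regions")
        if self.simulate is not None:
            if self.simulate.future_mode not in ("ensemble", "planted"):
                raise ValueError("future_mode must be 'ensemble' or 'planted'")
            if self.simulate.future_mode == "planted":
                if len(self.simulate.crops) != 1:
                    raise ValueError("planted future mode supports exactly one crop")
                if not self.simulate.planted_fractions:
                    raise ValueError("planted future mode needs planted_fractions")
            names = [c.crop_name for c in self.simulate.crops]
            if len(set(names)) != len(names):
                raise ValueError("duplicate crop names in simulate block")
        if self.inputs is not None:
            blk = self.inputs
            paths = [blk.baseline_nc, blk.agb, blk.richness, blk.total_npp, blk.intact]
            paths += list(blk.crops.values())
            for sc in blk.futures.values():
                for members in sc.values():
                    paths += list(members)
            for p in paths:
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"input raster '{p}' not found")
            if not blk.crops:
                raise ValueError("inputs mode needs at least one crop raster")

    # -- lossless dict/yaml round-trip -----------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "seed": self.seed,
            "grid": asdict(self.grid),
            "coverage_target": self.coverage_target,
            "envelope_mode": self.envelope_mode,
            "density_bins": list(self.density_bins),
            "regions": dict(self.regions),
            "carbon_region": self.carbon_region,
            "carbon_params": {k: asdict(v) for k, v in self.carbon_params.items()},
            "shoot_as_divisor": self.shoot_as_divisor,
            "terciles": self.terciles,
        }
        if self.simulate is not None:
            s = self.simulate
            d["simulate"] = {
                "ocean_fraction": s.ocean_fraction,
                "climate": asdict(s.climate),
                "ensemble": asdict(s.ensemble),
                "crops": [
                    {**asdict(c), "t_bounds": list(c.t_bounds), "p_bounds": list(c.p_bounds)}
                    for c in s.crops
                ],
                "scenarios": {
                    sc: {per: asdict(f) for per, f in periods.items()}
                    for sc, periods in s.scenarios.items()
                },
                "ecology": {
                    **asdict(s.ecology),
                    "agb_range": list(s.ecology.agb_range),
                    "richness_range": list(s.ecology.richness_range),
                    "npp_range": list(s.ecology.npp_range),
                },
                "future_mode": s.future_mode,
                "planted_fractions": dict(s.planted_fractions),
                "planted_scenario": s.planted_scenario,
                "planted_bump": s.planted_bump,
            }
        if self.inputs is not None:
            d["inputs"] = asdict(self.inputs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        kw: dict[str, Any] = {}
        for key in ("seed", "coverage_target", "envelope_mode", "carbon_region",
                    "shoot_as_divisor", "terciles"):
            if key in d:
                kw[key] = d[key]
        if "grid" in d:
            kw["grid"] = GridSpec(**d["grid"])
        if "density_bins" in d:
            kw["density_bins"] = tuple(d["density_bins"])
        if "regions" in d:
            kw["regions"] = dict(d["regions"])
        if "carbon_params" in d:
            kw["carbon_params"] = {
                k: CropCarbonParams(**v) for k, v in d["carbon_params"].items()
            }
        if d.get("inputs") is not None:
            kw["inputs"] = InputsBlock(**d["inputs"])
            kw["simulate"] = None
        elif "simulate" in d:
            s = dict(d["simulate"] or {})
            blk = SimulateBlock()
            if "ocean_fraction" in s:
                blk.ocean_fraction = s["ocean_fraction"]
            if "climate" in s:
                blk.climate = BaselineClimateParams(**s["climate"])
            if "ensemble" in s:
                blk.ensemble = EnsembleParams(**s["ensemble"])
            if "crops" in s:
                blk.crops = tuple(
                    CropTruthParams(**{
                        **c,
                        "t_bounds": tuple(c["t_bounds"]),
                        "p_bounds": tuple(c["p_bounds"]),
                    })
                    for c in s["crops"]
                )
            if "scenarios" in s:
                blk.scenarios = {
                    sc: {per: PeriodForcing(**f) for per, f in periods.items()}
                    for sc, periods in s["scenarios"].items()
                }
            if "ecology" in s:
                e = dict(s["ecology"])
                for key in ("agb_range", "richness_range", "npp_range"):
                    if key in e:
                        e[key] = tuple(e[key])
                blk.ecology = EcologyParams(**e)
            for key in ("future_mode", "planted_scenario", "planted_bump"):
                if key in s:
                    setattr(blk, key, s[key])
            if "planted_fractions" in s:
                blk.planted_fractions = dict(s["planted_fractions"])
            kw["simulate"] = blk
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        """Stable provenance hash of the canonical config."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
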