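"""End-to-end orchestration: simulate/load -> envelopes -> classification
-> exposure -> carbon -> trade-offs, with a provenance manifest.

Every run writes, under the output directory:

- ``envelopes/<crop>.json`` — fitted envelope models
- ``exposure.csv`` — crop x region x scenario x period exposure table
- ``carbon/potential_summary.csv``, ``carbon/potential_change.csv`` and
  the combined potential raster
- ``tradeoffs/`` — class/bivariate rasters, legends, regional summary
- ``manifest.json`` — config hash, seed, package version, per-stage
  accounting (excluded nodata mass, clipped cells) and, for synthetic
  runs, the planted ground truth

Rerunning with an identical config and seed reproduces all CSV outputs
bit-identically. Stage failures abort the run naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .carbon import (
    CarbonRaster,
    cropland_npp,
    future_potential_change,
    natural_npp_residual,
    negative_emission_potential,
)
from .climate import AnnualClimate, ClimateCube, annual_aggregate, ensemble_mean
from .config import PipelineConfig
from .envelope import (
    CropLayer,
    EnvelopeModel,
    SCSMask,
    classify_cells,
    exposure_timeseries,
    fit_envelope,
)
from .grids import cell_areas, tropics_mask
from .raster_io import read_cube_netcdf, read_geotiff, write_cube_netcdf, write_geotiff
from .synthetic import (
    SyntheticTruth,
    generate_climate_baseline,
    generate_crop_production,
    generate_ecology_layers,
    generate_future_ensemble,
    generate_nodata_mask,
    plant_future_outside,
    weighted_outside_fraction,
)
from .tradeoffs import (
    bivariate_classify,
    classify_three_bins,
    intact_overlap,
    rescale_percent_of_max,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    out_dir: Path
    baseline_annual: AnnualClimate
    crops: dict[str, CropLayer]
    envelopes: dict[str, EnvelopeModel]
    masks: dict[str, dict[tuple[str, str], SCSMask]]  # crop -> slice -> mask
    exposure: pd.DataFrame
    potential_summary: pd.DataFrame
    potential_change: pd.DataFrame
    regional_summary: pd.DataFrame
    truth: SyntheticTruth | None = None
    manifest: dict[str, Any] = field(default_factory=dict)


def _region_masks(config: PipelineConfig) -> dict[str, np.ndarray]:
    spec = config.grid
    out: dict[str, np.ndarray] = {}
    for name, source in config.regions.items():
        if source == "tropics":
            out[name] = tropics_mask(spec)
        elif source == "global":
            out[name] = np.ones(spec.shape, dtype=bool)
        else:
            values, rspec, _ = read_geotiff(source)
            if rspec != spec:
                raise ValueError(f"region raster '{source}' is not on the analysis grid")
            out[name] = np.nan_to_num(values[0]) > 0
    return out


def _simulate_inputs(config: PipelineConfig, out_dir: Path):
    sim = config.simulate
    spec = config.grid
    seed = config.seed
    nodata = generate_nodata_mask(spec, sim.ocean_fraction, seed=seed)
    baseline = generate_climate_baseline(spec, sim.climate, seed=seed + 1, nodata_mask=nodata)
    baseline_annual = annual_aggregate(baseline)

    truth = SyntheticTruth(seed=seed)
    crops: dict[str, CropLayer] = {}
    crop_params = {c.crop_name: c for c in sim.crops}
    for i, cp in enumerate(sim.crops):
        crop, t = generate_crop_production(spec, baseline_annual, cp, seed=seed + 10 + i)
        crops[cp.crop_name] = crop
        truth.envelope_bounds_true.update(t.envelope_bounds_true)
        truth.baseline_outside_fraction.update(t.baseline_outside_fraction)

    if sim.future_mode == "ensemble":
        future_cubes = generate_future_ensemble(
            baseline, sim.scenarios, sim.ensemble, seed=seed + 100
        )
        for (scenario, period), members in future_cubes.items():
            future_annual = annual_aggregate(ensemble_mean(members))
            for name, cp in crop_params.items():
                truth.planted_outside_fraction[(name, scenario, period)] = (
                    weighted_outside_fraction(crops[name], future_annual, cp)
                )
    else:
        (crop_name, cp), = crop_params.items()
        scenario = sim.planted_scenario
        future_cubes = {}
        for j, (period, frac) in enumerate(sorted(sim.planted_fractions.items())):
            cube, achieved = plant_future_outside(
                baseline, crops[crop_name], cp, frac,
                seed=seed + 200 + j, bump=sim.planted_bump,
                scenario=scenario, period=period,
            )
            future_cubes[(scenario, period)] = [cube]
            truth.planted_outside_fraction[(crop_name, scenario, period)] = achieved

    ecology = generate_ecology_layers(spec, sim.ecology, seed=seed + 300, nodata_mask=nodata)

    # persist the generated inputs alongside the results
    in_dir = out_dir / "inputs"
    in_dir.mkdir(parents=True, exist_ok=True)
    write_cube_netcdf(in_dir / "baseline.nc", baseline)
    for name, crop in crops.items():
        write_geotiff(in_dir / f"crop_{name.replace(' ', '_')}.tif", crop.production, spec)
    write_geotiff(in_dir / "agb.tif", ecology.agb, spec)
    write_geotiff(in_dir / "richness.tif", ecology.richness, spec)
    write_geotiff(in_dir / "total_npp.tif", ecology.total_npp, spec)
    write_geotiff(in_dir / "intact.tif", ecology.intact_mask.astype(float), spec)
    return baseline, baseline_annual, crops, future_cubes, ecology, truth


@dataclass
class _LoadedEcology:
    spec: Any
    agb: np.ndarray
    richness: np.ndarray
    total_npp: np.ndarray
    intact_mask: np.ndarray


def _load_inputs(config: PipelineConfig):
    blk = config.inputs
    spec = config.grid
    baseline = read_cube_netcdf(blk.baseline_nc)
    if baseline.spec != spec:
        raise ValueError("baseline cube is not on the analysis grid")
    baseline_annual = annual_aggregate(baseline)
    crops = {}
    for name, path in blk.crops.items():
        values, rspec, _ = read_geotiff(path)
        if rspec != spec:
            raise ValueError(f"crop raster '{path}' is not on the analysis grid")
        crops[name] = CropLayer(crop_name=name, production=values[0], spec=spec)
    future_cubes: dict[tuple[str, str], list[ClimateCube]] = {}
    for scenario, periods in blk.futures.items():
        for period, paths in periods.items():
            future_cubes[(scenario, period)] = [read_cube_netcdf(p) for p in paths]

    def _layer(path, fallback):
        if not path:
            return fallback
        values, rspec, _ = read_geotiff(path)
        if rspec != spec:
            raise ValueError(f"raster '{path}' is not on the analysis grid")
        return values[0]

    zeros = np.zeros(spec.shape)
    ecology = _LoadedEcology(
        spec=spec,
        agb=_layer(blk.agb, zeros),
        richness=_layer(blk.richness, zeros),
        total_npp=_layer(blk.total_npp, zeros),
        intact_mask=np.nan_to_num(_layer(blk.intact, zeros)) > 0,
    )
    return baseline, baseline_annual, crops, future_cubes, ecology, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute all stages; see the module docstring for outputs."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    stage = "simulate/load"
    try:
        if config.simulate is not None:
            (baseline, baseline_annual, crops, future_cubes, ecology, truth) = (
                _simulate_inputs(config, out_dir)
            )
        else:
            (baseline, baseline_annual, crops, future_cubes, ecology, truth) = (
                _load_inputs(config)
            )
        manifest["stages"][stage] = {
            "n_crops": len(crops), "n_future_slices": len(future_cubes),
        }

        stage = "envelopes"
        env_dir = out_dir / "envelopes"
        env_dir.mkdir(exist_ok=True)
        envelopes: dict[str, EnvelopeModel] = {}
        for name in sorted(crops):
            env = fit_envelope(
                baseline_annual, crops[name],
                coverage_target=config.coverage_target,
                mode=config.envelope_mode, bins=config.density_bins,
                provenance=f"baseline:{config.digest()}",
            )
            envelopes[name] = env
            (env_dir / f"{name.replace(' ', '_')}.json").write_text(env.to_json())
        manifest["stages"][stage] = {
            name: {
                "achieved_coverage": envelopes[name].achieved_coverage,
                "excluded_mass": envelopes[name].excluded_mass,
            }
            for name in sorted(envelopes)
        }

        stage = "classification+exposure"
        regions = _region_masks(config)
        masks: dict[str, dict[tuple[str, str], SCSMask]] = {name: {} for name in crops}
        for (scenario, period), members in sorted(future_cubes.items()):
            future_annual = annual_aggregate(ensemble_mean(members))
            for name in sorted(crops):
                masks[name][(scenario, period)] = classify_cells(
                    envelopes[name], future_annual, scenario=scenario, period=period
                )
        exposure = exposure_timeseries(envelopes, future_cubes, crops, regions)
        exposure.to_csv(out_dir / "exposure.csv", index=False)
        manifest["stages"][stage] = {"rows": int(len(exposure))}

        stage = "carbon"
        carbon_dir = out_dir / "carbon"
        carbon_dir.mkdir(exist_ok=True)
        crop_list = [crops[name] for name in sorted(crops)]
        combined, per_crop_pot, pot_summary = negative_emission_potential(
            crop_list, config.carbon_params, shoot_as_divisor=config.shoot_as_divisor
        )
        cropland_total = np.zeros(config.grid.shape)
        for name in sorted(crops):
            npp = cropland_npp(
                crops[name], config.carbon_params[name],
                shoot_as_divisor=config.shoot_as_divisor,
            )
            cropland_total += np.nan_to_num(npp.value)
        total_npp_raster = CarbonRaster(
            spec=config.grid, value=ecology.total_npp, kind="total_npp"
        )
        natural, n_clipped = natural_npp_residual(
            total_npp_raster,
            CarbonRaster(spec=config.grid, value=cropland_total, kind="cropland_npp"),
        )
        change_frames = [
            future_potential_change(
                per_crop_pot[name], masks[name],
                regions[config.carbon_region], crops[name],
            )
            for name in sorted(crops)
        ]
        pot_change = pd.concat(change_frames, ignore_index=True)
        pot_summary.to_csv(carbon_dir / "potential_summary.csv", index=False)
        pot_change.to_csv(carbon_dir / "potential_change.csv", index=False)
        write_geotiff(carbon_dir / "potential_combined.tif", combined.value, config.grid)
        write_geotiff(carbon_dir / "natural_npp.tif", natural.value, config.grid)
        manifest["stages"][stage] = {"clipped_cells": n_clipped}

        stage = "tradeoffs"
        to_dir = out_dir / "tradeoffs"
        to_dir.mkdir(exist_ok=True)
        areas = cell_areas(config.grid)
        layers = {"agb": ecology.agb, "richness": ecology.richness,
                  "potential": combined.value}
        class_rasters = {}
        for name, layer in layers.items():
            scaled = rescale_percent_of_max(layer)
            cr = classify_three_bins(scaled, config.grid, terciles=config.terciles)
            class_rasters[name] = cr
            write_geotiff(to_dir / f"class_{name}.tif", cr.cls.astype(float), config.grid)
        bivars = {
            "richness_vs_agb": bivariate_classify(
                class_rasters["richness"], class_rasters["agb"]
            ),
            "potential_vs_agb": bivariate_classify(
                class_rasters["potential"], class_rasters["agb"]
            ),
        }
        for name, bv in bivars.items():
            write_geotiff(to_dir / f"bivar_{name}.tif", bv.code.astype(float), config.grid)
            (to_dir / f"bivar_{name}_legend.json").write_text(
                json.dumps({str(k): v for k, v in bv.legend.items()}, indent=1, sort_keys=True)
            )
        regional = intact_overlap(
            ecology.agb, ecology.richness, ecology.intact_mask, areas, regions
        )
        regional.to_csv(to_dir / "regional_summary.csv", index=False)
        manifest["stages"][stage] = {"regions": sorted(regions)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if truth is not None:
        manifest["truth"] = {
            "seed": truth.seed,
            "envelope_bounds_true": {
                k: [list(v[0]), list(v[1])] for k, v in truth.envelope_bounds_true.items()
            },
            "baseline_outside_fraction": dict(truth.baseline_outside_fraction),
            "planted_outside_fraction": {
                f"{c}|{s}|{p}": v
                for (c, s, p), v in sorted(truth.planted_outside_fraction.items())
            },
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        config=config, out_dir=out_dir,
        baseline_annual=baseline_annual, crops=crops,
        envelopes=envelopes, masks=masks, exposure=exposure,
        potential_summary=pot_summary, potential_change=pot_change,
        regional_summary=regional, truth=truth, manifest=manifest,
    )
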