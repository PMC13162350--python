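"""Cropland NPP accounting and negative-emission potential.

Cropland net primary production is the four-factor product

    NPP_crop = production x f_dry x f_shoot x f_carbon

(tonnes fresh production per cell and year; fractions of dry matter in
fresh biomass, of biomass allocated to shoots, and of carbon in dry
biomass), converted to Tg C per cell per year. The per-crop fractions are
feedstock properties that the user supplies from the crop-carbon
literature; the defaults below are documented placeholders in plausible
ranges, not measured constants. An alternative harvest-index reading
(dividing by f_shoot to scale harvested mass up to whole-plant NPP) is
available via ``shoot_as_divisor``.

Negative-emission potential is cropland NPP times a capture efficiency
(default 1.0, i.e. potential equals crop carbon uptake; any life-cycle
discount of a capture chain is user-supplied). The natural-vegetation NPP
of mixed cells is the residual total NPP minus cropland NPP, clipped at
zero with the clip count reported — subtracting independently estimated
rasters can go negative and silent negatives would corrupt area summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .envelope import CropLayer, SCSMask
from .grids import GridSpec

logger = logging.getLogger(__name__)

TONNES_C_PER_TG = 1e6


@dataclass(frozen=True)
class CropCarbonParams:
    crop_name: str
    f_dry: float        # dry-matter fraction of fresh production
    f_shoot: float      # fraction of biomass in shoots
    f_carbon: float     # carbon fraction of dry biomass
    capture_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_dry", "f_shoot", "f_carbon", "capture_efficiency"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]; got {v}")


# Placeholder defaults: dry-matter fractions reflect typical harvest
# moisture (grain ~0.87-0.90, cassava roots ~0.35, oil-palm fresh fruit
# bunches ~0.47, sugarcane stalks ~0.30); shoot fraction ~0.80-0.90;
# carbon fraction of dry biomass ~0.45 across crops. Override from config
# for any quantitative use.
DEFAULT_CARBON_PARAMS: dict[str, CropCarbonParams] = {
    "maize": CropCarbonParams("maize", 0.87, 0.90, 0.45),
    "cassava": CropCarbonParams("cassava", 0.35, 0.50, 0.45),
    "oil palm": CropCarbonParams("oil palm", 0.47, 0.80, 0.45),
    "millet": CropCarbonParams("millet", 0.88, 0.85, 0.45),
    "rice": CropCarbonParams("rice", 0.87, 0.85, 0.45),
    "sorghum": CropCarbonParams("sorghum", 0.87, 0.85, 0.45),
    "soybean": CropCarbonParams("soybean", 0.90, 0.85, 0.45),
    "sugarcane": CropCarbonParams("sugarcane", 0.30, 0.85, 0.45),
}


@dataclass
class CarbonRaster:
    """Per-cell carbon flux, Tg C per cell per year (NaN = nodata)."""

    spec: GridSpec
    value: np.ndarray
    kind: str  # cropland_npp | natural_npp | total_npp | nep_potential

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.value.shape != self.spec.shape:
            raise ValueError("carbon raster must match the GridSpec shape")


def cropland_npp(
    crop: CropLayer,
    params: CropCarbonParams,
    shoot_as_divisor: bool = False,
) -> CarbonRaster:
    """Cropland NPP per cell from production and carbon fractions.

    ``shoot_as_divisor=True`` divides by f_shoot (harvest-index scaling of
    harvested mass to whole-plant NPP) instead of multiplying.
    """
    if params.crop_name != crop.crop_name:
        raise ValueError(
            f"carbon parameters are for '{params.crop_name}', crop is '{crop.crop_name}'"
        )
    shoot = (1.0 / params.f_shoot) if shoot_as_divisor else params.f_shoot
    tonnes_c = crop.production * params.f_dry * shoot * params.f_carbon
    return CarbonRaster(
        spec=crop.spec, value=tonnes_c / TONNES_C_PER_TG, kind="cropland_npp"
    )


def natural_npp_residual(
    total_npp: CarbonRaster, cropland_npp_all: CarbonRaster
) -> tuple[CarbonRaster, int]:
    """Natural-vegetation NPP as total minus cropland on mixed-use cells.

    On cells without any crop the residual equals the total. Negative
    residuals are clipped to zero; the number of clipped cells is
    returned (and logged) rather than silently absorbed.
    """
    if total_npp.spec != cropland_npp_all.spec:
        raise ValueError("total and cropland NPP must share one GridSpec")
    crop_v = cropland_npp_all.value
    has_crop = np.isfinite(crop_v) & (crop_v > 0)
    residual = np.where(has_crop, total_npp.value - crop_v, total_npp.value)
    with np.errstate(invalid="ignore"):
        clipped = residual < 0
    n_clipped = int(np.sum(clipped))
    if n_clipped:
        logger.info("natural_npp_residual: %d cells clipped at zero", n_clipped)
    residual = np.where(clipped, 0.0, residual)
    return CarbonRaster(spec=total_npp.spec, value=residual, kind="natural_npp"), n_clipped


POTENTIAL_QUANTILES = (5, 25, 50, 75, 95)


def negative_emission_potential(
    crops: Sequence[CropLayer],
    params: Mapping[str, CropCarbonParams],
    shoot_as_divisor: bool = False,
) -> tuple[CarbonRaster, dict[str, CarbonRaster], pd.DataFrame]:
    """Per-crop and combined negative-emission potential.

    Per-crop potential = cropland NPP x capture efficiency. The combined
    cell value is the mean over crops present (production > 0) in that
    cell. Summaries are per-crop distribution quantiles (5/25/50/75/95)
    over cells where the crop is grown.
    """
    if not crops:
        raise ValueError("need at least one crop")
    per_crop: dict[str, CarbonRaster] = {}
    rows = []
    spec = crops[0].spec
    num = np.zeros(spec.shape)
    den = np.zeros(spec.shape)
    for crop in crops:
        if crop.crop_name not in params:
            raise KeyError(f"missing carbon parameters for crop '{crop.crop_name}'")
        p = params[crop.crop_name]
        pot = cropland_npp(crop, p, shoot_as_divisor=shoot_as_divisor)
        pot = CarbonRaster(
            spec=pot.spec, value=pot.value * p.capture_efficiency, kind="nep_potential"
        )
        per_crop[crop.crop_name] = pot
        present = np.isfinite(crop.production) & (crop.production > 0)
        num[present] += pot.value[present]
        den[present] += 1.0
        qs = np.percentile(pot.value[present], POTENTIAL_QUANTILES)
        rows.append({
            "crop": crop.crop_name,
            **{f"q{q:02d}": v for q, v in zip(POTENTIAL_QUANTILES, qs)},
        })
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(den > 0, num / den, np.nan)
    combined_raster = CarbonRaster(spec=spec, value=combined, kind="nep_potential")
    summary = pd.DataFrame(rows).sort_values("crop", kind="stable").reset_index(drop=True)
    return combined_raster, per_crop, summary


def future_potential_change(
    potential: CarbonRaster,
    masks: Mapping[tuple[str, str], SCSMask],
    region_mask: np.ndarray,
    crop: CropLayer,
) -> pd.DataFrame:
    """Remaining and lost negative-emission potential per scenario x period.

    remaining = sum of potential over region cells classified inside the
    SCS / sum over all region cells with valid classification;
    reduction = 1 - remaining. A zero denominator is flagged (NaN).
    """
    rows = []
    pot = np.where(np.isfinite(potential.value), potential.value, 0.0)
    for (scenario, period), mask in sorted(masks.items()):
        if mask.spec != potential.spec:
            raise ValueError("mask and potential must share one GridSpec")
        in_region = region_mask & mask.valid
        denom = float(np.sum(pot[in_region]))
        if denom > 0:
            remaining = float(np.sum(pot[in_region & mask.inside])) / denom
            flagged = False
        else:
            remaining = float("nan")
            flagged = True
            logger.warning(
                "future_potential_change[%s %s/%s]: zero regional potential",
                crop.crop_name, scenario, period,
            )
        rows.append({
            "crop": crop.crop_name, "scenario": scenario, "period": period,
            "remaining": remaining,
            "reduction": 1.0 - remaining if not flagged else float("nan"),
        })
    return pd.DataFrame(rows, columns=["crop", "scenario", "period", "remaining", "reduction"])
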