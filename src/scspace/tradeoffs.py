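"""Ecological trade-off layers: rescaling, three-class and bivariate maps,
intact-forest overlap and per-area densities.

Continuous layers (aboveground biomass carbon, vertebrate species
richness, negative-emission potential) are rescaled to percent of their
maximum and cut into three classes at the 25th and 75th percentiles: low
(< p25), medium (p25..p75 inclusive), high (> p75). Note these published
cut points give ~25/50/25 cell shares, not equal thirds; a terciles
option (33.3/66.7) is provided for a genuinely equal-frequency split.
Percentiles use the same left-continuous weighted-quantile convention as
the envelope fitting, unweighted by default (cell-area weights optional).

Two class rasters combine into a 3x3 bivariate code raster (the classic
bivariate-choropleth legend); overlap with an intact-forest mask and
area-true per-100-km2 densities summarize the trade-off per region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .envelope import weighted_quantile
from .grids import GridSpec

logger = logging.getLogger(__name__)

CLASS_LABELS = {0: "low", 1: "medium", 2: "high"}


@dataclass
class ClassRaster:
    spec: GridSpec
    cls: np.ndarray  # int8: 0 low, 1 medium, 2 high; -1 nodata
    thresholds: tuple[float, float]  # (p25_value, p75_value)


@dataclass
class BivariateRaster:
    """3x3 joint classification; code = 3 * cls_a + cls_b, -1 where either is nodata."""

    spec: GridSpec
    code: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)


def rescale_percent_of_max(raster: np.ndarray) -> np.ndarray:
    """Rescale to percent of the maximum over non-nodata cells (0..100]."""
    raster = np.asarray(raster, dtype=np.float64)
    finite = np.isfinite(raster)
    if not finite.any():
        raise ValueError("raster is entirely nodata")
    m = raster[finite].max()
    if m <= 0:
        raise ValueError("raster has no positive value to rescale against")
    return 100.0 * raster / m


def classify_three_bins(
    raster: np.ndarray,
    spec: GridSpec,
    weights: np.ndarray | None = None,
    terciles: bool = False,
) -> ClassRaster:
    """Three-class split at the (weighted) 25th/75th percentiles.

    cls 0 if value < p25, 2 if value > p75, else 1 — values exactly at a
    threshold are medium. ``terciles=True`` uses the 33.3/66.7 cut points
    instead (a true equal-frequency split). Fewer than four distinct
    values degenerate gracefully (with a warning): a constant raster is
    all medium since p25 = p75 = the value.
    """
    raster = np.asarray(raster, dtype=np.float64)
    finite = np.isfinite(raster)
    if not finite.any():
        raise ValueError("raster is entirely nodata")
    vals = raster[finite]
    if np.unique(vals).size < 4:
        warnings.warn(
            "fewer than 4 distinct values; three-class split is degenerate",
            stacklevel=2,
        )
    w = np.ones_like(vals) if weights is None else np.asarray(weights, dtype=np.float64)[finite]
    q = (1 / 3, 2 / 3) if terciles else (0.25, 0.75)
    lo, hi = (float(x) for x in weighted_quantile(vals, w, np.asarray(q)))
    cls = np.full(raster.shape, -1, dtype=np.int8)
    cls[finite] = 1
    cls[finite & (raster < lo)] = 0
    cls[finite & (raster > hi)] = 2
    return ClassRaster(spec=spec, cls=cls, thresholds=(lo, hi))


def bivariate_classify(a: ClassRaster, b: ClassRaster) -> BivariateRaster:
    """Pair two three-class rasters into a 3x3 bivariate code raster."""
    if a.spec != b.spec:
        raise ValueError("class rasters must share one GridSpec")
    both = (a.cls >= 0) & (b.cls >= 0)
    code = np.where(both, 3 * a.cls.astype(np.int16) + b.cls, -1).astype(np.int16)
    legend = {
        3 * i + j: f"a={CLASS_LABELS[i]}, b={CLASS_LABELS[j]}"
        for i in range(3) for j in range(3)
    }
    return BivariateRaster(spec=a.spec, code=code, legend=legend)


REGIONAL_COLUMNS = [
    "region", "mean_agb_per_100km2", "mean_richness_per_100km2",
    "intact_area_km2", "intact_share_of_total_intact",
]


def per_area_density(
    stock: np.ndarray,
    areas: np.ndarray,
    region_mask: np.ndarray,
) -> float:
    """Area-true density of a per-cell stock, expressed per 100 km2.

    density = (sum of stock over region / sum of cell areas over region)
    * 100; nodata stock cells are excluded from both sums.
    """
    sel = region_mask & np.isfinite(stock)
    area = float(np.sum(areas[sel]))
    if area <= 0:
        raise ValueError("region has zero valid area")
    return float(np.sum(stock[sel])) / area * 100.0


def intact_overlap(
    agb: np.ndarray,
    richness: np.ndarray,
    intact_mask: np.ndarray,
    areas: np.ndarray,
    regions: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-region intact-forest area and mean AGB / richness densities.

    Intact area is the sum of cell areas under the mask within the
    region; its share is relative to the global intact total over all
    supplied regions' union complement — i.e. over the whole grid, so
    shares over disjoint regions covering the mask sum to 1.
    """
    total_intact = float(np.sum(areas[intact_mask]))
    rows = []
    for name in sorted(regions):
        sel = regions[name]
        if not np.any(sel):
            logger.warning("intact_overlap: region '%s' is empty", name)
        area_i = float(np.sum(areas[sel & intact_mask]))
        rows.append({
            "region": name,
            "mean_agb_per_100km2": per_area_density(agb, areas, sel),
            "mean_richness_per_100km2": per_area_density(richness, areas, sel),
            "intact_area_km2": area_i,
            "intact_share_of_total_intact": (
                area_i / total_intact if total_intact > 0 else 0.0
            ),
        })
    return pd.DataFrame(rows, columns=REGIONAL_COLUMNS)
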