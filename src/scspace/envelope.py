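"""Safe-climate-space (SCS) envelopes, classification and exposure.

The SCS of a crop is the region of the (annual mean temperature, annual
precipitation) plane that contains at least a target fraction (default
95%) of the crop's baseline production mass; the remaining mass marks
marginal, low-yield cultivation and is trimmed. Two envelope geometries
are supported:

``rectangular``
    Per-axis production-weighted quantile bounds. A symmetric tail mass
    alpha is found by bisection so that the joint rectangle is the
    smallest one with coverage >= target, then each bound is greedily
    tightened to the next-inner distinct weighted-quantile candidate while
    coverage stays >= target. The result is minimal: moving any single
    bound one candidate inward drops coverage below the target.

``density``
    A 2-D production-weighted histogram on (T, P); bins are retained in
    descending order of production mass until the cumulative mass reaches
    the target.

A future climate cell is *inside* the SCS iff it violates neither the
temperature nor the precipitation limits (rectangular: both intervals,
bounds inclusive; density: lands in a retained bin). Exposure is the
production-weighted share of a region's cells classified outside.

All weighted quantiles use the left-continuous inverse CDF: the smallest
data value whose cumulative mass reaches the requested fraction, ties
toward the smaller value. Results depend on this convention, so it is
fixed here and reused by the trade-off module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import AnnualClimate, ClimateCube, annual_aggregate, ensemble_mean
from .grids import GridSpec, tropics_mask

logger = logging.getLogger(__name__)

CROPS = (
    "maize", "cassava", "oil palm", "millet",
    "rice", "sorghum", "soybean", "sugarcane",
)


@dataclass
class CropLayer:
    """Per-crop rainfed production raster (tonnes per cell, NaN = nodata)."""

    crop_name: str
    production: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.production = np.asarray(self.production, dtype=np.float64)
        if self.production.shape != self.spec.shape:
            raise ValueError("production raster must match the GridSpec shape")
        with np.errstate(invalid="ignore"):
            if np.any(self.production < 0):
                raise ValueError("production must be non-negative or nodata")
        if not np.any(self.production > 0):
            raise ValueError(f"crop '{self.crop_name}' has no positive production")

    @property
    def total(self) -> float:
        return float(np.nansum(self.production))


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> float | np.ndarray:
    """Left-continuous weighted empirical quantile(s).

    Returns the smallest value v such that the total weight of samples
    with value <= v is at least q * sum(weights). Ties break toward the
    smaller value. q may be a scalar or an array in [0, 1].
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if values.shape != weights.shape:
        raise ValueError("values and weights must share shape")
    if values.size == 0:
        raise ValueError("empty sample")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order])
    total = cum[-1]
    if total <= 0:
        raise ValueError("total weight must be positive")
    q_arr = np.atleast_1d(np.asarray(q, dtype=np.float64))
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    idx = np.searchsorted(cum, q_arr * total, side="left")
    idx = np.minimum(idx, v.size - 1)
    out = v[idx]
    return float(out[0]) if np.isscalar(q) or np.ndim(q) == 0 else out


@dataclass
class EnvelopeModel:
    """A fitted safe-climate-space envelope for one crop."""

    crop_name: str
    mode: str  # "rectangular" | "density"
    coverage_target: float
    achieved_coverage: float
    t_bounds: tuple[float, float] | None = None
    p_bounds: tuple[float, float] | None = None
    t_edges: np.ndarray | None = None
    p_edges: np.ndarray | None = None
    retained_bins: np.ndarray | None = None  # flat indices into the (T,P) histogram
    excluded_mass: float = 0.0  # production mass on nodata baseline climate
    provenance: str = ""

    def to_json(self) -> str:
        d = {
            "crop_name": self.crop_name,
            "mode": self.mode,
            "coverage_target": self.coverage_target,
            "achieved_coverage": self.achieved_coverage,
            "excluded_mass": self.excluded_mass,
            "provenance": self.provenance,
        }
        if self.mode == "rectangular":
            d["t_bounds"] = list(self.t_bounds)
            d["p_bounds"] = list(self.p_bounds)
        else:
            d["t_edges"] = list(map(float, self.t_edges))
            d["p_edges"] = list(map(float, self.p_edges))
            d["retained_bins"] = list(map(int, self.retained_bins))
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EnvelopeModel":
        d = json.loads(text)
        kw = dict(
            crop_name=d["crop_name"], mode=d["mode"],
            coverage_target=d["coverage_target"],
            achieved_coverage=d["achieved_coverage"],
            excluded_mass=d.get("excluded_mass", 0.0),
            provenance=d.get("provenance", ""),
        )
        if d["mode"] == "rectangular":
            kw["t_bounds"] = tuple(d["t_bounds"])
            kw["p_bounds"] = tuple(d["p_bounds"])
        else:
            kw["t_edges"] = np.asarray(d["t_edges"])
            kw["p_edges"] = np.asarray(d["p_edges"])
            kw["retained_bins"] = np.asarray(d["retained_bins"], dtype=np.int64)
        return cls(**kw)


@dataclass
class SCSMask:
    """Inside/outside classification of one future climate against one envelope.

    ``inside`` is defined exactly on cells with valid future climate
    (``valid``); the mask is climate-only — cells without production still
    carry a value.
    """

    spec: GridSpec
    inside: np.ndarray
    valid: np.ndarray
    crop_name: str
    scenario: str = ""
    period: str = ""


@dataclass
class ExposureRecord:
    crop_name: str
    region: str
    scenario: str
    period: str
    production_total: float
    production_outside: float
    share_outside: float  # NaN when production_total == 0
    flagged: bool = False


def _rect_coverage(
    t: np.ndarray, p: np.ndarray, w: np.ndarray,
    tb: tuple[float, float], pb: tuple[float, float],
) -> float:
    inside = (t >= tb[0]) & (t <= tb[1]) & (p >= pb[0]) & (p <= pb[1])
    return float(w[inside].sum() / w.sum())


def _fit_rectangular(
    t: np.ndarray, p: np.ndarray, w: np.ndarray, target: float
) -> tuple[tuple[float, float], tuple[float, float], float]:
    def bounds_at(alpha: float):
        q = np.array([alpha / 2.0, 1.0 - alpha / 2.0])
        tq = weighted_quantile(t, w, q)
        pq = weighted_quantile(p, w, q)
        return (float(tq[0]), float(tq[1])), (float(pq[0]), float(pq[1]))

    # bisect on the symmetric trimmed tail mass: coverage(alpha) is
    # non-increasing, coverage(0) = 1
    lo, hi = 0.0, 1.0
    if _rect_coverage(t, p, w, *bounds_at(hi)) >= target:
        lo = hi
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _rect_coverage(t, p, w, *bounds_at(mid)) >= target:
            lo = mid
        else:
            hi = mid
    tb, pb = bounds_at(lo)

    # greedy polish: tighten each bound to the next-inner distinct value
    # while coverage stays >= target -> minimality holds by construction
    t_vals = np.unique(t)
    p_vals = np.unique(p)
    tb, pb = list(tb), list(pb)
    changed = True
    while changed:
        changed = False
        for which, axis_vals, idx, inward in (
            ("t", t_vals, 0, +1), ("t", t_vals, 1, -1),
            ("p", p_vals, 0, +1), ("p", p_vals, 1, -1),
        ):
            b = tb if which == "t" else pb
            pos = np.searchsorted(axis_vals, b[idx], side="left" if inward > 0 else "right")
            cand_pos = pos + inward if inward > 0 else pos - 2
            if cand_pos < 0 or cand_pos >= axis_vals.size:
                continue
            cand = float(axis_vals[cand_pos])
            if (inward > 0 and cand <= b[idx]) or (inward < 0 and cand >= b[idx]):
                continue
            trial = list(b)
            trial[idx] = cand
            if trial[0] > trial[1]:
                continue
            args = (tuple(trial), tuple(pb)) if which == "t" else (tuple(tb), tuple(trial))
            if _rect_coverage(t, p, w, *args) >= target:
                b[idx] = cand
                changed = True
    cov = _rect_coverage(t, p, w, tuple(tb), tuple(pb))
    return (tb[0], tb[1]), (pb[0], pb[1]), cov


def _fit_density(
    t: np.ndarray, p: np.ndarray, w: np.ndarray, target: float, bins: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    hist, t_edges, p_edges = np.histogram2d(t, p, bins=bins, weights=w)
    flat = hist.ravel()
    # descending mass, stable tie-break on flat bin index
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    total = flat.sum()
    n_keep = int(np.searchsorted(cum, target * total, side="left")) + 1
    retained = np.sort(order[:n_keep])
    retained = retained[flat[retained] > 0]
    cov = float(flat[retained].sum() / total)
    return t_edges, p_edges, retained, cov


def fit_envelope(
    baseline: AnnualClimate,
    crop: CropLayer,
    coverage_target: float = 0.95,
    mode: str = "rectangular",
    bins: tuple[int, int] = (100, 100),
    provenance: str = "",
) -> EnvelopeModel:
    """Fit the safe-climate-space envelope of one crop.

    Production mass sitting on nodata baseline climate is excluded from
    the fit and from the coverage denominator; the excluded mass is
    recorded on the model and logged.
    """
    if not (0.0 < coverage_target <= 1.0):
        raise ValueError("coverage_target must lie in (0, 1]")
    if mode not in ("rectangular", "density"):
        raise ValueError(f"unknown envelope mode '{mode}'")
    if baseline.spec != crop.spec:
        raise ValueError("baseline climate and crop raster must share one GridSpec")

    prod = crop.production
    has_prod = np.isfinite(prod) & (prod > 0)
    usable = has_prod & baseline.valid
    excluded = float(np.nansum(prod[has_prod & ~baseline.valid]))
    if excluded > 0:
        logger.info(
            "fit_envelope[%s]: %.6g t of production on nodata climate excluded",
            crop.crop_name, excluded,
        )
    if not np.any(usable):
        raise ValueError(
            f"all production of '{crop.crop_name}' sits on nodata baseline climate"
        )

    t = baseline.t_ann[usable]
    p = baseline.p_ann[usable]
    w = prod[usable]

    if mode == "rectangular":
        tb, pb, cov = _fit_rectangular(t, p, w, coverage_target)
        return EnvelopeModel(
            crop_name=crop.crop_name, mode=mode,
            coverage_target=coverage_target, achieved_coverage=cov,
            t_bounds=tb, p_bounds=pb,
            excluded_mass=excluded, provenance=provenance,
        )
    t_edges, p_edges, retained, cov = _fit_density(t, p, w, coverage_target, bins)
    return EnvelopeModel(
        crop_name=crop.crop_name, mode=mode,
        coverage_target=coverage_target, achieved_coverage=cov,
        t_edges=t_edges, p_edges=p_edges, retained_bins=retained,
        excluded_mass=excluded, provenance=provenance,
    )


def _density_inside(
    env: EnvelopeModel, t: np.ndarray, p: np.ndarray
) -> np.ndarray:
    n_t = env.t_edges.size - 1
    n_p = env.p_edges.size - 1
    # histogram bin membership: half-open [lo, hi) except the last bin,
    # which includes its right edge (numpy histogram convention)
    ti = np.digitize(t, env.t_edges, right=False) - 1
    pi = np.digitize(p, env.p_edges, right=False) - 1
    ti = np.where(np.isclose(t, env.t_edges[-1]), n_t - 1, ti)
    pi = np.where(np.isclose(p, env.p_edges[-1]), n_p - 1, pi)
    in_range = (ti >= 0) & (ti < n_t) & (pi >= 0) & (pi < n_p)
    flat = np.where(in_range, ti * n_p + pi, -1)
    retained = np.zeros(n_t * n_p, dtype=bool)
    retained[env.retained_bins] = True
    inside = np.zeros(t.shape, dtype=bool)
    inside[in_range] = retained[flat[in_range]]
    return inside


def classify_cells(
    env: EnvelopeModel,
    future: AnnualClimate,
    scenario: str = "",
    period: str = "",
) -> SCSMask:
    """Classify future annual climate cells against a fitted envelope.

    Rectangular mode: inside iff T_low <= T <= T_high AND
    P_low <= P <= P_high — exceeding either axis limit puts the cell
    outside; values exactly at a limit are inside. Density mode: inside
    iff the (T, P) pair lands in a retained histogram bin. Nodata future
    climate leaves the cell undefined (``valid`` False).
    """
    valid = future.valid
    t = future.t_ann
    p = future.p_ann
    if env.mode == "rectangular":
        inside = (
            (t >= env.t_bounds[0]) & (t <= env.t_bounds[1])
            & (p >= env.p_bounds[0]) & (p <= env.p_bounds[1])
        )
    else:
        inside = _density_inside(env, np.where(valid, t, 0.0), np.where(valid, p, 0.0))
    inside = np.where(valid, inside, False)
    return SCSMask(
        spec=future.spec, inside=inside, valid=valid,
        crop_name=env.crop_name, scenario=scenario, period=period,
    )


def exposure_share(
    mask: SCSMask,
    crop: CropLayer,
    region_mask: np.ndarray | None = None,
    region: str = "tropics",
) -> ExposureRecord:
    """Production-weighted share of a region's crop production outside the SCS.

    The region defaults to the tropics (|lat| <= 23.5 deg). Production on
    cells without valid future climate is excluded from both numerator
    and denominator (and logged); a region with zero production yields a
    flagged record with share NaN rather than a silent zero.
    """
    if crop.spec != mask.spec:
        raise ValueError("mask and crop must share one GridSpec")
    if region_mask is None:
        region_mask = tropics_mask(mask.spec)
    if region_mask.shape != mask.spec.shape:
        raise ValueError("region mask must match the GridSpec shape")

    prod = np.where(np.isfinite(crop.production), crop.production, 0.0)
    in_region = region_mask & mask.valid
    dropped = float(np.sum(prod[region_mask & ~mask.valid]))
    if dropped > 0:
        logger.info(
            "exposure_share[%s/%s]: %.6g t of production on nodata future climate dropped",
            crop.crop_name, region, dropped,
        )
    total = float(np.sum(prod[in_region]))
    outside = float(np.sum(prod[in_region & ~mask.inside]))
    if total > 0:
        share = outside / total
        flagged = False
    else:
        share = float("nan")
        flagged = True
        logger.warning(
            "exposure_share[%s/%s]: zero regional production", crop.crop_name, region
        )
    return ExposureRecord(
        crop_name=crop.crop_name, region=region,
        scenario=mask.scenario, period=mask.period,
        production_total=total, production_outside=outside,
        share_outside=share, flagged=flagged,
    )


EXPOSURE_COLUMNS = [
    "crop", "region", "scenario", "period",
    "production_total", "production_outside", "share_outside",
]


def exposure_timeseries(
    envelopes: Mapping[str, EnvelopeModel],
    future_cubes: Mapping[tuple[str, str], Sequence[ClimateCube]],
    crops: Mapping[str, CropLayer],
    regions: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Exposure table over crops x regions x scenarios x periods.

    ``future_cubes`` maps (scenario, period) to the ensemble members for
    that slice. For each slice the pipeline is ensemble mean -> annual
    aggregation -> classification -> production-weighted exposure. Output
    is a long-form table with a fixed column order and deterministic row
    ordering (crop, region, scenario, period).
    """
    rows = []
    for (scenario, period), members in sorted(future_cubes.items()):
        if not members:
            raise ValueError(f"no ensemble members for ({scenario}, {period})")
        future = annual_aggregate(
            ensemble_mean(members, source=f"{scenario}/{period}")
        )
        for crop_name in sorted(crops):
            env = envelopes[crop_name]
            mask = classify_cells(env, future, scenario=scenario, period=period)
            for region_name in sorted(regions):
                rec = exposure_share(
                    mask, crops[crop_name],
                    region_mask=regions[region_name], region=region_name,
                )
                rows.append({
                    "crop": rec.crop_name, "region": rec.region,
                    "scenario": rec.scenario, "period": rec.period,
                    "production_total": rec.production_total,
                    "production_outside": rec.production_outside,
                    "share_outside": rec.share_outside,
                })
    df = pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)
    return df.sort_values(
        ["crop", "region", "scenario", "period"], kind="stable"
    ).reset_index(drop=True)
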