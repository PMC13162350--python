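"""Monthly climate cubes, annual aggregation, ensemble means and Holdridge
life zones.

A :class:`ClimateCube` holds 12 monthly mean-temperature and precipitation
layers for one source (the observed baseline climatology or one climate
model under one scenario and period). Downstream stages work on
:class:`AnnualClimate` (annual mean temperature, annual total
precipitation). Nodata is carried as NaN and propagates: a cell missing in
any month is missing in the annual field, and an ensemble-mean cell is
missing if any member is missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grids import GridSpec

logger = logging.getLogger(__name__)

MONTHS = 12

#: Biotemperature class edges, degC (log2-spaced, Holdridge convention).
BIOTEMP_EDGES = (1.5, 3.0, 6.0, 12.0, 24.0)
#: Annual-precipitation class edges, mm (log2-spaced).
PRECIP_EDGES = (62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)


@dataclass
class ClimateCube:
    """Monthly climate fields for one source on one grid.

    tavg and prec are (12, n_rows, n_cols) float arrays, degC and mm/month,
    NaN = nodata. ``source`` tags provenance: "baseline" or a
    (model, scenario, period) triple rendered as a string.
    """

    spec: GridSpec
    tavg: np.ndarray
    prec: np.ndarray
    source: str = "baseline"

    def __post_init__(self) -> None:
        self.tavg = np.asarray(self.tavg, dtype=np.float64)
        self.prec = np.asarray(self.prec, dtype=np.float64)
        expected = (MONTHS, *self.spec.shape)
        if self.tavg.shape != expected or self.prec.shape != expected:
            raise ValueError(
                f"cube layers must have shape {expected}; got "
                f"tavg {self.tavg.shape}, prec {self.prec.shape}"
            )
        if np.nanmin(self.prec, initial=0.0) < 0:
            raise ValueError("precipitation must be non-negative or nodata")


@dataclass
class AnnualClimate:
    """Annual mean temperature (degC) and total precipitation (mm/yr)."""

    spec: GridSpec
    t_ann: np.ndarray
    p_ann: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t_ann) & np.isfinite(self.p_ann)


@dataclass
class LifeZoneRaster:
    """Holdridge life-zone codes with a code -> label legend."""

    spec: GridSpec
    zone_code: np.ndarray  # int codes, -1 = nodata
    legend: Mapping[int, str] = field(default_factory=dict)


def annual_aggregate(cube: ClimateCube) -> AnnualClimate:
    """Aggregate a monthly cube to annual values.

    T_ann is the unweighted mean of the 12 monthly mean temperatures and
    P_ann the sum of the 12 monthly totals; any nodata month makes the
    cell nodata (plain mean/sum propagate NaN).
    """
    t_ann = cube.tavg.mean(axis=0)
    p_ann = cube.prec.sum(axis=0)
    # keep nodata consistent across the two variables
    bad = ~(np.isfinite(t_ann) & np.isfinite(p_ann))
    t_ann = np.where(bad, np.nan, t_ann)
    p_ann = np.where(bad, np.nan, p_ann)
    return AnnualClimate(spec=cube.spec, t_ann=t_ann, p_ann=p_ann)


def mean_temperature_from_extremes(
    tmax: np.ndarray, tmin: np.ndarray
) -> np.ndarray:
    """Monthly mean temperature as (tmax + tmin) / 2, cell-wise.

    Projection sources often publish only monthly extremes; the midpoint
    stands in for the monthly mean. Cells with tmax < tmin are counted and
    warned about but still computed (the midpoint is order-free).
    """
    tmax = np.asarray(tmax, dtype=np.float64)
    tmin = np.asarray(tmin, dtype=np.float64)
    if tmax.shape != tmin.shape:
        raise ValueError("tmax and tmin must share shape")
    with np.errstate(invalid="ignore"):
        n_bad = int(np.sum(tmax < tmin))
    if n_bad:
        warnings.warn(
            f"{n_bad} cell-months have tmax < tmin; midpoint computed anyway",
            stacklevel=2,
        )
    return (tmax + tmin) / 2.0


def ensemble_mean(cubes: Sequence[ClimateCube], source: str | None = None) -> ClimateCube:
    """Unweighted per-cell, per-month mean over ensemble members.

    A cell is nodata iff it is nodata in any member (conservative; keeps
    the effective model count identical across cells).
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("ensemble_mean needs at least one member")
    spec = cubes[0].spec
    for c in cubes[1:]:
        if c.spec != spec:
            raise ValueError("ensemble members must share one GridSpec")
    tavg = np.mean([c.tavg for c in cubes], axis=0)
    prec = np.mean([c.prec for c in cubes], axis=0)
    return ClimateCube(
        spec=spec, tavg=tavg, prec=prec,
        source=source or f"ensemble_mean(n={len(cubes)})",
    )


def _classify_edges(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Class index per value with half-open (low, high] intervals.

    A value exactly on an edge belongs to the lower class.
    """
    return np.searchsorted(np.asarray(edges), values, side="left")


def holdridge_classify(cube: ClimateCube) -> LifeZoneRaster:
    """Holdridge life zones on the biotemperature x annual-precipitation plane.

    Biotemperature is the mean of the 12 monthly temperatures after
    clamping each month to [0, 30] degC (clamp-then-average, the standard
    convention). Both axes use log2-spaced class edges; intervals are
    half-open (low, high] so an exact boundary value takes the lower
    class. The potential-evapotranspiration axis of the full Holdridge
    triangle is not carried — the two axes here are the ones the safe
    climate space is defined on.
    """
    bio = np.clip(cube.tavg, 0.0, 30.0).mean(axis=0)
    p_ann = cube.prec.sum(axis=0)
    valid = np.isfinite(bio) & np.isfinite(p_ann)

    n_p = len(PRECIP_EDGES) + 1
    bio_cls = _classify_edges(np.where(valid, bio, 0.0), BIOTEMP_EDGES)
    p_cls = _classify_edges(np.where(valid, p_ann, 0.0), PRECIP_EDGES)
    code = bio_cls * n_p + p_cls
    code = np.where(valid, code, -1).astype(np.int32)

    bio_labels = _interval_labels(BIOTEMP_EDGES, "degC")
    p_labels = _interval_labels(PRECIP_EDGES, "mm")
    legend = {
        b * n_p + p: f"biotemp {bio_labels[b]} / precip {p_labels[p]}"
        for b in range(len(BIOTEMP_EDGES) + 1)
        for p in range(n_p)
    }
    return LifeZoneRaster(spec=cube.spec, zone_code=code, legend=legend)


def _interval_labels(edges: Sequence[float], unit: str) -> list[str]:
    labels = [f"<={edges[0]:g} {unit}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"({lo:g}, {hi:g}] {unit}")
    labels.append(f">{edges[-1]:g} {unit}")
    return labels


def warming_offsets(cubes: Iterable[ClimateCube], baseline: ClimateCube) -> np.ndarray:
    """Convenience: per-member global-mean warming relative to baseline."""
    out = []
    for c in cubes:
        out.append(np.nanmean(c.tavg - baseline.tavg))
    return np.asarray(out)
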