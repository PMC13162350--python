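"""Synthetic pipeline inputs with planted, exactly recoverable ground truth.

Every downstream stage (envelope fitting, classification, exposure,
carbon, trade-offs) is testable without external downloads: this module
generates climate cubes, crop production and ecology layers on one grid,
records what it planted in a :class:`SyntheticTruth`, and every recorded
truth is recomputed from the generated rasters themselves (direct
inspection), never copied from the request.

Random-field recipe (all generators; fixed so tests can re-derive fields
independently):

1. ``rng = numpy.random.default_rng(seed)``; draws happen in the
   documented order for each generator.
2. A *smoothed unit field* is ``gaussian_filter(rng.standard_normal(shape),
   sigma, mode="nearest")``, then centred and scaled to zero mean / unit
   standard deviation over the whole grid. Smoothed white noise is the
   simplest spatially autocorrelated field with a controllable length
   scale (the kernel width, in cells).

Baseline climate: monthly mean temperature is a latitudinal gradient
plus ``noise_sd`` times a smoothed unit field (one spatial field shared
by all months) plus a hemisphere-signed seasonal cosine whose 12 monthly
values sum to zero, so the annual mean equals the prescribed field
exactly. Monthly precipitation distributes a non-negative annual field
over months with cosine weights that sum to one.

Future ensemble: member = baseline + period warming offset + one
model-specific scalar temperature perturbation (drawn once per model,
shared across periods and scenarios), with precipitation scaled by the
period factor times a model-specific factor.

Crop production: cells whose baseline (T, P) falls inside the true
envelope bounds receive ``1 - frac_outside_baseline`` of the total mass;
cells beyond the bounds by at least a margin (one envelope direction per
cell) receive the remainder; buffer cells get nothing, so the inside and
outside populations are separated in climate space. Within each
population, mass is proportional to a log-normal smoothed field
(``concentration`` controls how peaked). Optional *anchor cells* pin a
stated mass fraction at the four climatic extremes of the inside
population, which makes the fitted envelope coincide exactly with the
inside hull — the configuration used for planted-truth recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate import AnnualClimate, ClimateCube, annual_aggregate
from .envelope import CropLayer
from .grids import GridSpec


def default_grid() -> GridSpec:
    """Desk-scale default: 50x50 cells spanning 30S-30N, 30W-30E.

    Small enough for tests, wide enough in latitude that the tropics mask
    (|lat| <= 23.5) and latitude-dependent cell areas are both exercised.
    """
    return GridSpec(50, 50, -30.0, 30.0, -30.0, 30.0)


def smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Smoothed standard-normal field, centred to mean 0 / sd 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def generate_nodata_mask(
    spec: GridSpec, ocean_fraction: float = 0.2, sigma: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Boolean "ocean" mask covering exactly round(fraction * n_cells) cells.

    The mask is the top-k cells of one smoothed unit field (ties broken
    by flat cell index), giving contiguous blobs that every layer shares.
    """
    if not (0.0 <= ocean_fraction <= 1.0):
        raise ValueError("ocean_fraction must lie in [0, 1]")
    n = spec.n_rows * spec.n_cols
    k = int(round(ocean_fraction * n))
    mask = np.zeros(spec.shape, dtype=bool)
    if k == 0:
        return mask
    rng = np.random.default_rng(seed)
    f = smooth_unit_field(rng, spec.shape, sigma)
    order = np.lexsort((np.arange(n), -f.ravel()))
    mask.ravel()[order[:k]] = True
    return mask


@dataclass(frozen=True)
class BaselineClimateParams:
    """Deterministic skeleton of the baseline climatology.

    Annual mean temperature decreases linearly with |latitude| from
    ``t_equator``; annual precipitation likewise from ``p_equator``.
    Defaults give a tropical domain spanning roughly 19-27 degC and
    700-2000 mm/yr, the range over which the study crops are grown.
    """

    t_equator: float = 27.0        # degC at the equator
    t_gradient: float = 0.25       # degC decline per degree |lat|
    seasonal_amplitude: float = 2.0  # degC monthly cosine amplitude
    p_equator: float = 2000.0      # mm/yr at the equator
    p_gradient: float = 25.0       # mm/yr decline per degree |lat|
    p_seasonality: float = 0.5     # monthly cosine weight amplitude (<1)
    noise_sd: float = 1.0          # degC, spatial noise on T_ann
    p_noise_sd: float = 250.0      # mm/yr, spatial noise on P_ann
    smooth_sigma: float = 2.0      # kernel width of the noise, cells

    def __post_init__(self) -> None:
        for name in ("noise_sd", "p_noise_sd", "smooth_sigma"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("t_equator", "t_gradient", "seasonal_amplitude",
                     "p_equator", "p_gradient", "p_seasonality"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 <= self.p_seasonality < 1.0):
            raise ValueError("p_seasonality must lie in [0, 1)")


MONTH_PHASE = 2.0 * np.pi * np.arange(12) / 12.0


def generate_climate_baseline(
    spec: GridSpec,
    params: BaselineClimateParams = BaselineClimateParams(),
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> ClimateCube:
    """Baseline monthly climatology (see module docstring for the recipe).

    Draw order: temperature noise field first, then precipitation noise
    field. With ``noise_sd = 0`` every cell's monthly temperature equals
    the prescribed deterministic field.
    """
    rng = np.random.default_rng(seed)
    lat = spec.lat_field()
    t_noise = params.noise_sd * smooth_unit_field(rng, spec.shape, params.smooth_sigma) \
        if params.noise_sd > 0 else np.zeros(spec.shape)
    p_noise = params.p_noise_sd * smooth_unit_field(rng, spec.shape, params.smooth_sigma) \
        if params.p_noise_sd > 0 else np.zeros(spec.shape)

    t_ann = params.t_equator - params.t_gradient * np.abs(lat) + t_noise
    p_ann = np.maximum(params.p_equator - params.p_gradient * np.abs(lat) + p_noise, 0.0)

    hemi = np.where(lat >= 0, 1.0, -1.0)
    seasonal = np.cos(MONTH_PHASE)[:, None, None] * params.seasonal_amplitude * hemi
    tavg = t_ann[None, :, :] + seasonal

    month_w = (1.0 + params.p_seasonality * np.cos(MONTH_PHASE)) / 12.0
    prec = p_ann[None, :, :] * month_w[:, None, None]

    if nodata_mask is not None:
        tavg = np.where(nodata_mask[None, :, :], np.nan, tavg)
        prec = np.where(nodata_mask[None, :, :], np.nan, prec)
    return ClimateCube(spec=spec, tavg=tavg, prec=prec, source="baseline")


@dataclass(frozen=True)
class PeriodForcing:
    """Warming offset (degC) and precipitation scale for one period."""

    delta_t: float
    precip_scale: float = 1.0


@dataclass(frozen=True)
class EnsembleParams:
    """Multi-model spread emulation: 14 models, as in downscaled CMIP6
    ensembles, with a scalar per-model temperature perturbation."""

    n_models: int = 14
    inter_model_sd: float = 0.3       # degC, sd of per-model T offset
    inter_model_precip_sd: float = 0.05  # relative sd of per-model P scale

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.inter_model_sd < 0 or self.inter_model_precip_sd < 0:
            raise ValueError("spread parameters must be >= 0")


def generate_future_ensemble(
    baseline: ClimateCube,
    scenarios: Mapping[str, Mapping[str, PeriodForcing]],
    params: EnsembleParams = EnsembleParams(),
    seed: int = 0,
) -> dict[tuple[str, str], list[ClimateCube]]:
    """Future ensemble members indexed by (scenario, period).

    Draw order: per-model temperature offsets (n_models standard normals
    scaled by inter_model_sd), then per-model precipitation factors.
    Offsets are drawn once and shared across scenarios and periods, so a
    warm model is consistently warm. With ``inter_model_sd = 0`` every
    member equals baseline + the period offset and the ensemble mean of
    the offsets equals the period forcing exactly.
    """
    rng = np.random.default_rng(seed)
    t_eps = params.inter_model_sd * rng.standard_normal(params.n_models)
    p_fac = 1.0 + params.inter_model_precip_sd * rng.standard_normal(params.n_models)
    out: dict[tuple[str, str], list[ClimateCube]] = {}
    for scenario in scenarios:
        for period, forcing in scenarios[scenario].items():
            members = []
            for m in range(params.n_models):
                tavg = baseline.tavg + forcing.delta_t + t_eps[m]
                prec = np.maximum(baseline.prec * forcing.precip_scale * p_fac[m], 0.0)
                members.append(ClimateCube(
                    spec=baseline.spec, tavg=tavg, prec=prec,
                    source=f"model{m:02d}/{scenario}/{period}",
                ))
            out[(scenario, period)] = members
    return out


@dataclass(frozen=True)
class CropTruthParams:
    """True envelope bounds and mass layout for one synthetic crop."""

    crop_name: str
    t_bounds: tuple[float, float]   # degC, true envelope
    p_bounds: tuple[float, float]   # mm/yr, true envelope
    total_production: float = 1e6   # tonnes
    concentration: float = 1.0      # log-normal sd of the mass field
    frac_outside_baseline: float = 0.05  # mass planted beyond the bounds
    margin: float = 0.10            # buffer width, fraction of bound width
    anchor_mass: float = 0.0        # mass pinned at each climatic extreme

    def __post_init__(self) -> None:
        if not (self.t_bounds[0] < self.t_bounds[1] and self.p_bounds[0] < self.p_bounds[1]):
            raise ValueError("envelope bounds must be well-ordered")
        if self.total_production <= 0:
            raise ValueError("total_production must be positive")
        if not (0.0 <= self.frac_outside_baseline < 1.0):
            raise ValueError("frac_outside_baseline must lie in [0, 1)")
        if not (0.0 <= self.anchor_mass < 0.25):
            raise ValueError("anchor_mass must lie in [0, 0.25) per extreme")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, recomputed from its own outputs."""

    seed: int
    envelope_bounds_true: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=dict)
    baseline_outside_fraction: dict[str, float] = field(default_factory=dict)
    #: (crop, scenario, period) -> exact production-weighted fraction of
    #: mass whose future annual climate lies outside the true bounds
    planted_outside_fraction: dict[tuple[str, str, str], float] = field(default_factory=dict)


def outside_true_bounds(
    annual: AnnualClimate, params: CropTruthParams
) -> np.ndarray:
    """Cells whose (T, P) lies outside the true envelope bounds."""
    (t_lo, t_hi), (p_lo, p_hi) = params.t_bounds, params.p_bounds
    inside = (
        (annual.t_ann >= t_lo) & (annual.t_ann <= t_hi)
        & (annual.p_ann >= p_lo) & (annual.p_ann <= p_hi)
    )
    return annual.valid & ~inside


def weighted_outside_fraction(
    crop: CropLayer, annual: AnnualClimate, params: CropTruthParams
) -> float:
    """Direct-inspection oracle: production-weighted share outside the
    true bounds (the quantity every recovery test compares against)."""
    prod = np.where(np.isfinite(crop.production), crop.production, 0.0)
    out = outside_true_bounds(annual, params)
    return float(prod[out].sum() / prod.sum())


def generate_crop_production(
    spec: GridSpec,
    baseline_annual: AnnualClimate,
    params: CropTruthParams,
    seed: int = 0,
    smooth_sigma: float = 1.5,
) -> tuple[CropLayer, SyntheticTruth]:
    """Plant a crop-production raster against known envelope bounds.

    Draw order: one smoothed unit field for the log-normal mass surface,
    then one integer draw per outside cell choosing which of the four
    envelope directions it violates (only the violating axis is pushed
    beyond the margin — the cell keeps its other coordinate, so each
    outside cell is separated from the inside population along exactly
    one axis). Production sums to ``total_production`` to ~1e-15 relative
    and exactly ``frac_outside_baseline`` of the mass sits outside the
    true bounds.

    Note the generator does not alter the climate; it *selects* cells by
    their baseline climate. Outside mass goes to cells beyond the margin
    buffer; if no such cells exist the generator fails loudly.
    """
    (t_lo, t_hi), (p_lo, p_hi) = params.t_bounds, params.p_bounds
    mt = params.margin * (t_hi - t_lo)
    mp = params.margin * (p_hi - p_lo)
    t, p = baseline_annual.t_ann, baseline_annual.p_ann
    valid = baseline_annual.valid

    inside = valid & (t >= t_lo) & (t <= t_hi) & (p >= p_lo) & (p <= p_hi)
    beyond = valid & (
        (t > t_hi + mt) | (t < t_lo - mt) | (p > p_hi + mp) | (p < p_lo - mp)
    )
    if not inside.any():
        raise ValueError(
            f"no cells satisfy the true envelope bounds for '{params.crop_name}'"
        )
    if params.frac_outside_baseline > 0 and not beyond.any():
        raise ValueError(
            f"no cells beyond the margin to hold outside mass for '{params.crop_name}'"
        )

    rng = np.random.default_rng(seed)
    mass = np.exp(params.concentration * smooth_unit_field(rng, spec.shape, smooth_sigma))

    prod = np.zeros(spec.shape)
    f_out = params.frac_outside_baseline
    inside_total = (1.0 - f_out) * params.total_production

    anchor_total = 0.0
    if params.anchor_mass > 0:
        # pin mass at the four climatic extremes of the inside population
        # so the production-weighted hull is held by heavy cells
        idx_in = np.flatnonzero(inside.ravel())
        t_in, p_in = t.ravel()[idx_in], p.ravel()[idx_in]
        extremes = {
            idx_in[np.argmin(t_in)], idx_in[np.argmax(t_in)],
            idx_in[np.argmin(p_in)], idx_in[np.argmax(p_in)],
        }
        per_anchor = params.anchor_mass * params.total_production
        for flat in sorted(extremes):
            prod.ravel()[flat] += per_anchor
            anchor_total += per_anchor
        if anchor_total >= inside_total:
            raise ValueError("anchor mass exceeds the inside production budget")

    free_inside = inside & (prod == 0)
    w_in = np.where(free_inside, mass, 0.0)
    prod += w_in / w_in.sum() * (inside_total - anchor_total)

    if f_out > 0:
        w_out = np.where(beyond, mass, 0.0)
        prod += w_out / w_out.sum() * f_out * params.total_production

    nodata = ~valid
    prod = np.where(nodata, np.nan, prod)
    crop = CropLayer(crop_name=params.crop_name, production=prod, spec=spec)

    truth = SyntheticTruth(seed=seed)
    truth.envelope_bounds_true[params.crop_name] = (params.t_bounds, params.p_bounds)
    truth.baseline_outside_fraction[params.crop_name] = weighted_outside_fraction(
        crop, baseline_annual, params
    )
    return crop, truth


def plant_future_outside(
    baseline: ClimateCube,
    crop: CropLayer,
    params: CropTruthParams,
    target_fraction: float,
    seed: int = 0,
    bump: float = 5.0,
    scenario: str = "planted",
    period: str = "p1",
) -> tuple[ClimateCube, float]:
    """Construct a future cube whose outside fraction is planted.

    Starting from the baseline, a randomly ordered subset of
    currently-inside production cells is warmed by ``bump`` degC beyond
    the true upper temperature bound until the cumulative production mass
    (plus any mass already outside at baseline) reaches
    ``target_fraction`` of the total. Returns the cube and the exact
    achieved fraction, recomputed from the resulting annual fields.
    """
    if not (0.0 <= target_fraction <= 1.0):
        raise ValueError("target_fraction must lie in [0, 1]")
    annual = annual_aggregate(baseline)
    prod = np.where(np.isfinite(crop.production), crop.production, 0.0)
    total = prod.sum()
    already_out = outside_true_bounds(annual, params)
    base_out_mass = prod[already_out].sum()

    need = target_fraction * total - base_out_mass
    delta = np.zeros(baseline.spec.shape)
    if need > 0:
        candidates = np.flatnonzero((prod.ravel() > 0) & ~already_out.ravel())
        rng = np.random.default_rng(seed)
        order = rng.permutation(candidates)
        # random-order subset selection: skip cells that would overshoot,
        # then top up with the smallest remaining cell, so the achieved
        # mass exceeds the request by at most one small cell
        chosen = []
        cum = 0.0
        leftover = []
        for flat in order:
            m = prod.ravel()[flat]
            if cum + m <= need:
                chosen.append(flat)
                cum += m
            else:
                leftover.append(flat)
        if cum < need and leftover:
            top_up = min(leftover, key=lambda f: prod.ravel()[f])
            chosen.append(top_up)
        t_hi = params.t_bounds[1]
        mt = params.margin * (params.t_bounds[1] - params.t_bounds[0])
        for flat in chosen:
            # lift the cell's annual mean beyond the true (and margin) bound
            lift = (t_hi + mt + bump) - annual.t_ann.ravel()[flat]
            delta.ravel()[flat] = max(lift, 0.0)

    future = ClimateCube(
        spec=baseline.spec,
        tavg=baseline.tavg + delta[None, :, :],
        prec=baseline.prec.copy(),
        source=f"planted/{scenario}/{period}",
    )
    achieved = weighted_outside_fraction(crop, annual_aggregate(future), params)
    return future, achieved


@dataclass(frozen=True)
class EcologyParams:
    agb_range: tuple[float, float] = (0.0, 2.0)        # Tg C per cell
    richness_range: tuple[float, float] = (50.0, 1200.0)  # species per cell
    npp_range: tuple[float, float] = (0.0, 0.2)        # Tg C per cell per yr
    agb_richness_corr: float = 0.6
    intact_fraction: float = 0.15
    n_ecoregions: int = 5
    smooth_sigma: float = 1.5

    def __post_init__(self) -> None:
        for name in ("agb_range", "richness_range", "npp_range"):
            lo, hi = getattr(self, name)
            if not (hi > lo):
                raise ValueError(f"{name} must be well-ordered")
        if not (-1.0 <= self.agb_richness_corr <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        if not (0.0 <= self.intact_fraction <= 1.0):
            raise ValueError("intact_fraction must lie in [0, 1]")
        if self.n_ecoregions < 1:
            raise ValueError("n_ecoregions must be >= 1")


@dataclass
class EcologyLayers:
    spec: GridSpec
    agb: np.ndarray          # Tg C per cell
    richness: np.ndarray     # species per cell
    total_npp: np.ndarray    # Tg C per cell per year
    intact_mask: np.ndarray  # bool
    ecoregions: np.ndarray   # int class per land cell, -1 on nodata


def _affine_to_range(u: np.ndarray, rng_pair: tuple[float, float]) -> np.ndarray:
    """Affine map of a unit field onto [lo, hi] by its own min/max."""
    lo, hi = rng_pair
    u_min, u_max = u.min(), u.max()
    if u_max == u_min:
        return np.full_like(u, (lo + hi) / 2.0)
    return lo + (u - u_min) / (u_max - u_min) * (hi - lo)


def generate_ecology_layers(
    spec: GridSpec,
    params: EcologyParams = EcologyParams(),
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> EcologyLayers:
    """Ecology rasters: AGB, richness, NPP, intact mask, ecoregions.

    Draw order: four smoothed unit fields g1..g4. AGB is an affine map of
    g1; richness of rho*g1 + sqrt(1-rho^2)*g2 (so the AGB-richness
    correlation is rho by construction, exactly affine when |rho| = 1);
    NPP of 0.5*g1 + sqrt(0.75)*g3; the intact mask takes the top
    round(fraction * n_land) land cells of g4; ecoregions are
    equal-count slices of g4 (a partition of all land cells).
    """
    rng = np.random.default_rng(seed)
    g1 = smooth_unit_field(rng, spec.shape, params.smooth_sigma)
    g2 = smooth_unit_field(rng, spec.shape, params.smooth_sigma)
    g3 = smooth_unit_field(rng, spec.shape, params.smooth_sigma)
    g4 = smooth_unit_field(rng, spec.shape, params.smooth_sigma)

    rho = params.agb_richness_corr
    rich_u = rho * g1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * g2
    agb = _affine_to_range(g1, params.agb_range)
    richness = _affine_to_range(rich_u, params.richness_range)
    npp = _affine_to_range(0.5 * g1 + np.sqrt(0.75) * g3, params.npp_range)

    land = np.ones(spec.shape, dtype=bool) if nodata_mask is None else ~nodata_mask
    n_land = int(land.sum())
    k = int(round(params.intact_fraction * n_land))
    intact = np.zeros(spec.shape, dtype=bool)
    if k > 0:
        land_idx = np.flatnonzero(land.ravel())
        vals = g4.ravel()[land_idx]
        order = np.lexsort((land_idx, -vals))
        intact.ravel()[land_idx[order[:k]]] = True

    eco = np.full(spec.shape, -1, dtype=np.int32)
    if n_land:
        land_idx = np.flatnonzero(land.ravel())
        ranks = np.argsort(np.argsort(g4.ravel()[land_idx], kind="stable"), kind="stable")
        eco.ravel()[land_idx] = (ranks * params.n_ecoregions) // n_land

    if nodata_mask is not None:
        agb = np.where(nodata_mask, np.nan, agb)
        richness = np.where(nodata_mask, np.nan, richness)
        npp = np.where(nodata_mask, np.nan, npp)

    return EcologyLayers(
        spec=spec, agb=agb, richness=richness, total_npp=npp,
        intact_mask=intact, ecoregions=eco,
    )


#: Per-crop true envelopes for the default synthetic study: bounds sit
#: inside the domain's climate range (~19-27 degC, ~700-2000 mm) and
#: differ across crops the way thermal niches of the eight feedstocks do
#: (oil palm hot-wet and narrow, millet/sorghum hot-dry tolerant, ...).
DEFAULT_CROP_TRUTHS: tuple[CropTruthParams, ...] = (
    CropTruthParams("maize", (20.0, 26.0), (800.0, 1800.0)),
    CropTruthParams("cassava", (21.0, 26.5), (900.0, 1900.0)),
    CropTruthParams("oil palm", (24.0, 26.8), (1400.0, 2000.0)),
    CropTruthParams("millet", (21.0, 26.5), (700.0, 1400.0)),
    CropTruthParams("rice", (22.0, 26.5), (1100.0, 1950.0)),
    CropTruthParams("sorghum", (20.5, 26.5), (700.0, 1500.0)),
    CropTruthParams("soybean", (20.0, 25.5), (900.0, 1700.0)),
    CropTruthParams("sugarcane", (22.0, 26.5), (1200.0, 1950.0)),
)

#: Four 20-year periods under two warming scenarios; the lower scenario
#: stabilizes near +2 degC, the higher near +2.5 degC, with mild
#: precipitation declines accompanying the warming.
DEFAULT_SCENARIOS: dict[str, dict[str, PeriodForcing]] = {
    "2C": {
        "2021-2040": PeriodForcing(0.8, 0.99),
        "2041-2060": PeriodForcing(1.4, 0.98),
        "2061-2080": PeriodForcing(1.8, 0.97),
        "2081-2100": PeriodForcing(2.0, 0.97),
    },
    "2.5C": {
        "2021-2040": PeriodForcing(0.9, 0.99),
        "2041-2060": PeriodForcing(1.7, 0.97),
        "2061-2080": PeriodForcing(2.2, 0.96),
        "2081-2100": PeriodForcing(2.5, 0.95),
    },
}
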