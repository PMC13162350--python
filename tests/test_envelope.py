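import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scspace.climate import AnnualClimate
from scspace.envelope import (
    CropLayer,
    EnvelopeModel,
    classify_cells,
    exposure_share,
    exposure_timeseries,
    fit_envelope,
    weighted_quantile,
)
from scspace.grids import GridSpec

from conftest import make_annual, point_set_layers


def brute_quantile(values, weights, q):
    """Enumeration oracle: smallest value with cumulative mass >= q*total."""
    order = np.argsort(values, kind="stable")
    total = np.sum(weights)
    cum = 0.0
    for i in order:
        cum += weights[i]
        if cum >= q * total - 1e-12 * total:
            return values[i]
    return values[order[-1]]


class TestWeightedQuantile:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(1, 50)
            v = rng.normal(size=n)
            w = rng.uniform(0.01, 2.0, size=n)
            for q in (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0):
                assert weighted_quantile(v, w, q) == brute_quantile(v, w, q)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(0.0, 1.0),
    )
    def test_returns_a_data_value_with_sufficient_mass(self, values, q):
        v = np.asarray(values)
        w = np.ones_like(v)
        out = weighted_quantile(v, w, q)
        assert out in v
        assert np.sum(w[v <= out]) >= q * w.sum() - 1e-9

    def test_ties_break_toward_smaller_value(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([0.25, 0.25, 0.25, 0.25])
        # cumulative mass at 2.0 is exactly 0.5 -> 2.0, not 3.0
        assert weighted_quantile(v, w, 0.5) == 2.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile(np.array([1.0]), np.array([-1.0]), 0.5)
        with pytest.raises(ValueError):
            weighted_quantile(np.array([1.0]), np.array([1.0]), 1.5)


def brute_coverage(annual, crop, env):
    """Weighted recount of inside mass, independent of the fit path."""
    prod = np.nan_to_num(crop.production)
    usable = (prod > 0) & annual.valid
    t, p, w = annual.t_ann[usable], annual.p_ann[usable], prod[usable]
    if env.mode == "rectangular":
        inside = (
            (t >= env.t_bounds[0]) & (t <= env.t_bounds[1])
            & (p >= env.p_bounds[0]) & (p <= env.p_bounds[1])
        )
    else:
        n_p = env.p_edges.size - 1
        inside = np.zeros(t.size, dtype=bool)
        retained = set(int(b) for b in env.retained_bins)
        for i in range(t.size):
            ti = np.searchsorted(env.t_edges, t[i], side="right") - 1
            pi = np.searchsorted(env.p_edges, p[i], side="right") - 1
            ti = min(ti, env.t_edges.size - 2)
            pi = min(pi, n_p - 1)
            inside[i] = (ti * n_p + pi) in retained
    return float(w[inside].sum() / w.sum())


def random_point_set(rng, n):
    t = rng.normal(22, 4, n)
    p = rng.gamma(4, 300, n)
    w = rng.uniform(0.1, 10, n)
    return point_set_layers(t, p, w)


class TestFitEnvelopeRectangular:
    def test_single_cell_degenerate(self):
        annual, crop = point_set_layers([23.0], [1200.0], [5.0])
        env = fit_envelope(annual, crop)
        assert env.t_bounds == (23.0, 23.0)
        assert env.p_bounds == (1200.0, 1200.0)
        assert env.achieved_coverage == 1.0

    def test_five_cell_worked_example(self):
        # tails of 2.5% mass fall within the extreme cells under the
        # cumulative-mass->= quantile convention, so all five stay inside
        annual, crop = point_set_layers(
            [10, 15, 20, 25, 30], [1000] * 5, [10, 20, 40, 20, 10]
        )
        env = fit_envelope(annual, crop, coverage_target=0.95)
        assert env.t_bounds == (10.0, 30.0)
        assert env.achieved_coverage == 1.0

    def test_coverage_and_minimality_randomized(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            annual, crop = random_point_set(rng, int(rng.integers(20, 300)))
            env = fit_envelope(annual, crop, coverage_target=0.95)
            assert env.achieved_coverage >= 0.95
            assert abs(env.achieved_coverage - brute_coverage(annual, crop, env)) < 1e-12
            assert_minimal(annual, crop, env, 0.95)

    def test_excluded_nodata_mass_recorded(self):
        annual, crop = point_set_layers(
            [20, 21, 22, 23], [1000] * 4, [1, 1, 1, 7]
        )
        annual.t_ann[0, 3] = np.nan
        env = fit_envelope(annual, crop)
        assert env.excluded_mass == 7.0
        assert env.t_bounds == (20.0, 22.0)

    def test_all_production_on_nodata_fails(self):
        annual, crop = point_set_layers([20.0], [1000.0], [3.0])
        annual.t_ann[:] = np.nan
        with pytest.raises(ValueError, match="nodata"):
            fit_envelope(annual, crop)

    def test_bad_coverage_target_rejected(self):
        annual, crop = point_set_layers([20.0], [1000.0], [1.0])
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                fit_envelope(annual, crop, coverage_target=bad)


def assert_minimal(annual, crop, env, target):
    """Next-inner distinct quantile candidate on any axis drops coverage."""
    prod = np.nan_to_num(crop.production)
    usable = (prod > 0) & annual.valid
    t, p = annual.t_ann[usable], annual.p_ann[usable]
    t_vals, p_vals = np.unique(t), np.unique(p)

    def cov(tb, pb):
        w = prod[usable]
        inside = (t >= tb[0]) & (t <= tb[1]) & (p >= pb[0]) & (p <= pb[1])
        return w[inside].sum() / w.sum()

    tb, pb = env.t_bounds, env.p_bounds
    for vals, bounds, other, is_t in (
        (t_vals, tb, pb, True), (p_vals, pb, tb, False),
    ):
        lo_i = np.searchsorted(vals, bounds[0], side="left")
        hi_i = np.searchsorted(vals, bounds[1], side="right") - 1
        if lo_i + 1 <= hi_i:  # a next-inner lower candidate exists
            shrunk = (float(vals[lo_i + 1]), bounds[1])
            args = (shrunk, other) if is_t else (other, shrunk)
            assert cov(*args) < target
        if hi_i - 1 >= lo_i:
            shrunk = (bounds[0], float(vals[hi_i - 1]))
            args = (shrunk, other) if is_t else (other, shrunk)
            assert cov(*args) < target


class TestFitEnvelopeDensity:
    def test_coverage_matches_brute_recount(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            annual, crop = random_point_set(rng, 400)
            env = fit_envelope(annual, crop, mode="density", bins=(30, 30))
            assert env.achieved_coverage >= 0.95
            assert abs(env.achieved_coverage - brute_coverage(annual, crop, env)) < 1e-12

    def test_retained_bins_are_heaviest_first(self):
        rng = np.random.default_rng(8)
        annual, crop = random_point_set(rng, 300)
        env = fit_envelope(annual, crop, mode="density", bins=(20, 20))
        prod = np.nan_to_num(crop.production)
        usable = (prod > 0) & annual.valid
        hist, _, _ = np.histogram2d(
            annual.t_ann[usable], annual.p_ann[usable],
            bins=[env.t_edges, env.p_edges], weights=prod[usable],
        )
        flat = hist.ravel()
        retained = np.zeros(flat.size, dtype=bool)
        retained[env.retained_bins] = True
        # every retained bin holds at least as much mass as any dropped bin
        if retained.any() and (~retained).any():
            assert flat[retained].min() >= flat[~retained].max() - 1e-12


class TestClassifyCells:
    def test_identity_climate_stays_inside(self):
        rng = np.random.default_rng(2)
        annual, crop = random_point_set(rng, 200)
        env = fit_envelope(annual, crop)
        mask = classify_cells(env, annual)
        prod = np.nan_to_num(crop.production)
        inside_at_fit = (
            (annual.t_ann >= env.t_bounds[0]) & (annual.t_ann <= env.t_bounds[1])
            & (annual.p_ann >= env.p_bounds[0]) & (annual.p_ann <= env.p_bounds[1])
        )
        assert np.all(mask.inside[inside_at_fit])

    def test_forced_exceedance(self):
        annual, crop = point_set_layers([20, 22, 24], [1000] * 3, [1, 1, 1])
        env = fit_envelope(annual, crop)
        warmed = AnnualClimate(
            spec=annual.spec, t_ann=annual.t_ann + 10.0, p_ann=annual.p_ann
        )
        mask = classify_cells(env, warmed)
        assert not mask.inside.any()

    def test_matches_elementwise_bound_check(self):
        rng = np.random.default_rng(31)
        spec = GridSpec(50, 50, -25, 25, 0, 50)
        annual = make_annual(spec, rng.normal(22, 4, spec.shape),
                             rng.gamma(4, 300, spec.shape))
        prod = rng.uniform(0, 5, spec.shape)
        crop = CropLayer("x", prod, spec)
        env = fit_envelope(annual, crop)
        future = make_annual(spec, rng.normal(24, 4, spec.shape),
                             rng.gamma(4, 300, spec.shape))
        mask = classify_cells(env, future)
        for i in range(0, 50, 7):
            for j in range(0, 50, 7):
                expected = (
                    env.t_bounds[0] <= future.t_ann[i, j] <= env.t_bounds[1]
                    and env.p_bounds[0] <= future.p_ann[i, j] <= env.p_bounds[1]
                )
                assert mask.inside[i, j] == expected

    def test_value_exactly_at_limit_is_inside(self):
        annual, crop = point_set_layers([20, 25], [1000, 1000], [1, 1])
        env = fit_envelope(annual, crop)
        at_limit = AnnualClimate(
            spec=annual.spec,
            t_ann=np.full(annual.spec.shape, env.t_bounds[1]),
            p_ann=np.full(annual.spec.shape, env.p_bounds[1]),
        )
        assert classify_cells(env, at_limit).inside.all()

    def test_shift_consistency(self):
        # adding a constant to baseline (before fit) and future (before
        # classify) leaves the mask unchanged
        rng = np.random.default_rng(4)
        annual, crop = random_point_set(rng, 150)
        future = AnnualClimate(
            spec=annual.spec,
            t_ann=annual.t_ann + rng.normal(1, 1, annual.spec.shape),
            p_ann=annual.p_ann,
        )
        env = fit_envelope(annual, crop)
        mask = classify_cells(env, future)
        c = 7.25
        shifted_annual = AnnualClimate(
            spec=annual.spec, t_ann=annual.t_ann + c, p_ann=annual.p_ann
        )
        shifted_future = AnnualClimate(
            spec=annual.spec, t_ann=future.t_ann + c, p_ann=future.p_ann
        )
        env2 = fit_envelope(shifted_annual, crop)
        mask2 = classify_cells(env2, shifted_future)
        np.testing.assert_array_equal(mask.inside, mask2.inside)

    def test_nodata_future_cell_absent(self):
        annual, crop = point_set_layers([20, 22, 24], [1000] * 3, [1, 1, 1])
        env = fit_envelope(annual, crop)
        future = AnnualClimate(
            spec=annual.spec, t_ann=annual.t_ann.copy(), p_ann=annual.p_ann.copy()
        )
        future.t_ann[0, 1] = np.nan
        mask = classify_cells(env, future)
        assert not mask.valid[0, 1]
        assert not mask.inside[0, 1]


class TestExposureShare:
    def make_mask(self, env, annual, **kw):
        return classify_cells(env, annual, **kw)

    def test_all_inside_and_all_outside(self):
        annual, crop = point_set_layers([20, 22, 24], [1000] * 3, [1, 1, 1])
        env = fit_envelope(annual, crop)
        region = np.ones(annual.spec.shape, dtype=bool)
        rec = exposure_share(self.make_mask(env, annual), crop, region)
        assert rec.share_outside == 0.0
        warmed = AnnualClimate(annual.spec, annual.t_ann + 50, annual.p_ann)
        rec = exposure_share(self.make_mask(env, warmed), crop, region)
        assert rec.share_outside == 1.0

    def test_five_cell_weighted_share(self):
        # only the T=30 cell (mass 10 of 100) is pushed outside
        annual, crop = point_set_layers(
            [10, 15, 20, 25, 30], [1000] * 5, [10, 20, 40, 20, 10]
        )
        env = fit_envelope(annual, crop, coverage_target=0.95)
        future = AnnualClimate(annual.spec, annual.t_ann + 2.0, annual.p_ann)
        # +2 pushes only the 30 degC cell past T_high = 30
        rec = exposure_share(
            self.make_mask(env, future), crop, np.ones(annual.spec.shape, bool)
        )
        assert rec.share_outside == pytest.approx(0.10, abs=1e-12)

    def test_zero_regional_production_flagged(self):
        annual, crop = point_set_layers([20, 22], [1000] * 2, [1, 1])
        env = fit_envelope(annual, crop)
        empty_region = np.zeros(annual.spec.shape, dtype=bool)
        rec = exposure_share(self.make_mask(env, annual), crop, empty_region)
        assert rec.flagged and np.isnan(rec.share_outside)


class TestExposureTimeseries:
    def test_single_slice_equals_direct_call(self, tropical_spec):
        from scspace.synthetic import (
            CropTruthParams, generate_climate_baseline, generate_crop_production,
        )
        from scspace.climate import annual_aggregate

        baseline = generate_climate_baseline(tropical_spec, seed=1)
        annual = annual_aggregate(baseline)
        params = CropTruthParams("maize", (20.0, 26.0), (800.0, 1800.0))
        crop, _ = generate_crop_production(tropical_spec, annual, params, seed=1)
        env = fit_envelope(annual, crop)
        region = np.ones(tropical_spec.shape, dtype=bool)
        df = exposure_timeseries(
            {"maize": env}, {("s", "p"): [baseline]}, {"maize": crop},
            {"all": region},
        )
        assert len(df) == 1
        direct = exposure_share(classify_cells(env, annual), crop, region)
        assert df.share_outside.iloc[0] == direct.share_outside

    def test_missing_period_members_rejected(self):
        annual, crop = point_set_layers([20, 22], [1000] * 2, [1, 1])
        env = fit_envelope(annual, crop)
        with pytest.raises(ValueError, match="no ensemble members"):
            exposure_timeseries(
                {"crop": env}, {("s", "p"): []}, {"crop": crop},
                {"all": np.ones(annual.spec.shape, bool)},
            )


def test_envelope_json_round_trip():
    rng = np.random.default_rng(55)
    annual, crop = random_point_set(rng, 100)
    for mode in ("rectangular", "density"):
        env = fit_envelope(annual, crop, mode=mode, bins=(15, 15))
        back = EnvelopeModel.from_json(env.to_json())
        assert back.mode == env.mode
        assert back.achieved_coverage == env.achieved_coverage
        if mode == "rectangular":
            assert back.t_bounds == env.t_bounds
        else:
            np.testing.assert_array_equal(back.retained_bins, env.retained_bins)
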