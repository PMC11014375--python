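"""Semi-variogram estimation, model families, fitting and selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatial_al.variogram import (
    EstimationError,
    VariogramEstimate,
    VariogramModel,
    empirical_variogram,
    empirical_variogram_xy,
    fit_all_families,
    fit_variogram,
    model_semivariance,
    select_model_per_month,
    select_range,
)

from conftest import make_set


def brute_force_variogram(coords, values, n_lags, max_lag):
    """All-pairs oracle with right-closed equal-width bins."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, int)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d <= 0 or d > max_lag:
                continue
            for b in range(n_lags):
                if edges[b] < d <= edges[b + 1]:
                    sums[b] += 0.5 * (values[i] - values[j]) ** 2
                    counts[b] += 1
                    break
    return edges, sums, counts


class TestEmpiricalVariogram:
    def test_hand_example_three_collinear_points(self):
        coords = [(0, 0), (1, 0), (2, 0)]
        values = [0.2, 0.4, 0.8]
        est = empirical_variogram_xy(coords, values, n_lags=2, max_lag=2, min_pairs=1)
        np.testing.assert_allclose(est.gamma, [0.05, 0.18])
        assert est.pair_counts == (2, 1)

    def test_constant_values_give_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(30, 2))
        est = empirical_variogram_xy(coords, np.full(30, 0.3), n_lags=5, min_pairs=1)
        assert all(g == 0 for g in est.gamma)

    def test_min_pairs_drops_bin(self):
        # 10 clustered points plus 1 outlier: the far bins have < 30 pairs
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.uniform(0, 10, size=(10, 2)), [[1000.0, 0.0]]])
        values = rng.uniform(0, 0.5, 11)
        est = empirical_variogram_xy(coords, values, n_lags=4, max_lag=1000, min_pairs=30)
        assert est.lag_centers == (125.0,)  # only the within-cluster bin survives
        assert all(c >= 30 for c in est.pair_counts)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            coords = rng.uniform(0, 500, size=(n, 2))
            values = rng.uniform(-0.5, 0.5, n)
            n_lags = int(rng.integers(3, 10))
            max_lag = float(rng.uniform(100, 600))
            edges, sums, counts = brute_force_variogram(coords, values, n_lags, max_lag)
            try:
                est = empirical_variogram_xy(
                    coords, values, n_lags=n_lags, max_lag=max_lag, min_pairs=1
                )
            except EstimationError:
                assert counts.sum() == 0
                continue
            kept = counts > 0
            np.testing.assert_allclose(est.gamma, sums[kept] / counts[kept], rtol=1e-12)
            np.testing.assert_array_equal(est.pair_counts, counts[kept])

    def test_month_indexing_on_sample_set(self, small_set):
        est = empirical_variogram(small_set, month=3, n_lags=3, min_pairs=1)
        assert len(est) >= 1
        with pytest.raises(ValueError):
            empirical_variogram(small_set, month=13)

    def test_no_surviving_bin_raises(self):
        with pytest.raises(EstimationError, match="insufficient"):
            empirical_variogram_xy([(0, 0), (1, 0)], [0.1, 0.2], n_lags=3, min_pairs=30)


class TestModelSemivariance:
    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_nugget_at_zero(self, family):
        m = VariogramModel(family, 0.01, 0.04, 300.0)
        assert model_semivariance(m, 0.0) == pytest.approx(0.01)

    def test_spherical_sill_at_range(self):
        m = VariogramModel("spherical", 0.01, 0.04, 300.0)
        assert model_semivariance(m, 300.0) == pytest.approx(0.05)
        assert model_semivariance(m, 5000.0) == pytest.approx(0.05)

    def test_spherical_half_range_closed_form(self):
        m = VariogramModel("spherical", 0.025, 0.04, 417.6)
        # nugget + ps * (1.5*0.5 - 0.5*0.125) = 0.025 + 0.04*0.6875
        assert model_semivariance(m, 208.8) == pytest.approx(0.0525)

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_effective_range_reaches_95pct(self, family):
        m = VariogramModel(family, 0.0, 1.0, 200.0)
        assert model_semivariance(m, 200.0) == pytest.approx(0.95, abs=0.002)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            model_semivariance(VariogramModel("spherical", 0, 1, 100), -1.0)

    @given(
        family=st.sampled_from(["spherical", "exponential", "gaussian"]),
        nugget=st.floats(0, 0.1),
        ps=st.floats(0, 0.1),
        rng_m=st.floats(10, 2000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_nondecreasing(self, family, nugget, ps, rng_m):
        m = VariogramModel(family, nugget, ps, rng_m)
        h = np.linspace(0, 3 * rng_m, 200)
        gamma = model_semivariance(m, h)
        assert np.all(np.diff(gamma) >= -1e-12)


class TestFitVariogram:
    def make_noiseless(self, family="spherical", nugget=0.01, ps=0.04, rng_m=400.0):
        truth = VariogramModel(family, nugget, ps, rng_m)
        lags = np.linspace(40, 1000, 12)
        gamma = model_semivariance(truth, lags)
        return truth, VariogramEstimate(
            tuple(lags), tuple(gamma), (100,) * 12, max_lag=1000, min_pairs=30
        )

    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_self_consistency_noiseless(self, family):
        truth, est = self.make_noiseless(family)
        fit = fit_variogram(est, family)
        assert fit.nugget == pytest.approx(truth.nugget, abs=0.01 * truth.sill)
        assert fit.range_m == pytest.approx(truth.range_m, rel=0.01)
        assert fit.sserr < 1e-8

    def test_true_family_has_smallest_sserr(self):
        _, est = self.make_noiseless("spherical")
        fits = {f.family: f for f in fit_all_families(est)}
        assert fits["spherical"].sserr <= fits["exponential"].sserr
        assert fits["spherical"].sserr <= fits["gaussian"].sserr

    def test_flat_estimate_fits_constant(self):
        est = VariogramEstimate(
            (100.0, 200.0, 300.0, 400.0), (0.03,) * 4, (50,) * 4, 400.0
        )
        fit = fit_variogram(est, "spherical")
        # sill must match the constant; structure is degenerate (ps~0 or tiny range)
        assert fit.sill == pytest.approx(0.03, rel=0.02)
        assert fit.sserr < 1e-9

    def test_fit_beats_brute_force_grid(self):
        # WLS minimum found by the optimizer is at least as good as a coarse grid
        rng = np.random.default_rng(5)
        truth = VariogramModel("spherical", 0.005, 0.03, 400.0)
        lags = np.linspace(50, 1200, 10)
        gamma = model_semivariance(truth, lags) * rng.uniform(0.8, 1.2, 10)
        est = VariogramEstimate(tuple(lags), tuple(gamma), (80,) * 10, 1200.0)
        fit = fit_variogram(est, "spherical")
        w = np.array(est.pair_counts, float)

        def sserr(n0, ps, a):
            m = VariogramModel("spherical", n0, ps, a)
            return float(np.sum(w * (np.array(est.gamma) - model_semivariance(m, lags)) ** 2))

        grid_best = min(
            sserr(n0, ps, a)
            for n0 in np.linspace(0, 0.04, 20)
            for ps in np.linspace(0, 0.06, 25)
            for a in np.linspace(50, 2400, 40)
        )
        assert fit.sserr <= grid_best + 1e-12

    def test_too_few_bins_rejected(self):
        est = VariogramEstimate((100.0, 200.0), (0.01, 0.02), (50, 50), 200.0)
        with pytest.raises(EstimationError, match="insufficient"):
            fit_variogram(est, "spherical")


class TestSelectionRules:
    def mk(self, nugget, rng_m=500.0, sserr=0.1, family="spherical"):
        return VariogramModel(family, nugget, 0.02, rng_m, sserr)

    def test_lowest_nugget_wins(self):
        fits = [self.mk(0.010), self.mk(0.005), self.mk(0.020)]
        assert select_model_per_month(fits).nugget == 0.005

    def test_single_fit_is_identity(self):
        fit = self.mk(0.01)
        assert select_model_per_month([fit]) is fit

    def test_nugget_tie_broken_by_sserr_then_family(self):
        a = self.mk(0.01, sserr=0.3, family="spherical")
        b = self.mk(0.01, sserr=0.1, family="gaussian")
        assert select_model_per_month([a, b]) is b
        c = self.mk(0.01, sserr=0.1, family="spherical")
        assert select_model_per_month([b, c]) is c

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_model_per_month([])
        with pytest.raises(ValueError):
            select_range([])

    def test_select_range_minimum(self):
        models = [self.mk(0.01, rng_m=r) for r in (529.0, 600.0, 800.0)]
        assert select_range(models) == 529.0

    def test_select_range_constant(self):
        models = [self.mk(0.01, rng_m=700.0)] * 3
        assert select_range(models) == 700.0

    def test_selection_pipeline_deterministic(self):
        data = make_set(n=80, n_parcels=8, seed=11, spread=2000.0)
        from spatial_al import select_threshold

        t1, m1 = select_threshold(data, n_lags=8, min_pairs=5)
        t2, m2 = select_threshold(data, n_lags=8, min_pairs=5)
        assert t1 == t2
        assert [m.to_dict() for m in m1] == [m.to_dict() for m in m2]
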