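"""Semivariogram estimation, model equations, WLS fitting, DSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermozone as tz
from thermozone.variogram import FitError, VariogramEstimator

pytestmark = pytest.mark.filterwarnings(
    "ignore:semivariogram from only"
)


def brute_force_variogram(points, values, lag_width, n_lags):
    """All-pairs double-loop Matheron estimator (independent oracle)."""
    n = len(values)
    sums = np.zeros(n_lags)
    dist_sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = float(np.hypot(*(points[i] - points[j])))
            if h == 0.0:
                continue
            k = int(h // lag_width)
            if k >= n_lags:
                continue
            counts[k] += 1
            sums[k] += (values[i] - values[j]) ** 2
            dist_sums[k] += h
    gamma = np.full(n_lags, np.nan)
    centers = (np.arange(n_lags) + 0.5) * lag_width
    nz = counts > 0
    gamma[nz] = sums[nz] / (2.0 * counts[nz])
    centers[nz] = dist_sums[nz] / counts[nz]
    return centers, gamma, counts


class TestEmpiricalVariogram:
    def test_three_point_worked_example(self):
        """x = 0,1,2 m with z = 0,1,3: gamma at lag 1 is (1+4)/(2*2), at
        lag 2 is 9/(2*1)."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        emp = tz.empirical_semivariogram(
            pts, [0.0, 1.0, 3.0], n_lags=3, lag_width=1.0, max_dist=3.0
        )
        by_lag = dict(zip(emp.lag_centers, emp.semivariances))
        assert by_lag[1.0] == pytest.approx(1.25)
        assert by_lag[2.0] == pytest.approx(4.5)
        assert emp.pair_counts.sum() == 3

    def test_constant_field_is_flat_zero(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        emp = tz.empirical_semivariogram(pts, np.full(30, 7.0), n_lags=8)
        assert np.nanmax(emp.semivariances) == 0.0

    def test_duplicate_coordinates_excluded_with_warning(self):
        pts = np.array([[0, 0], [0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.warns(UserWarning, match="duplicate"):
            emp = tz.empirical_semivariogram(
                pts, [1.0, 1.0, 2.0, 4.0], n_lags=3, lag_width=1.0,
                max_dist=3.0,
            )
        # 6 pairs total, one at distance zero -> 5 retained
        assert emp.pair_counts.sum() == 5

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 31))
            pts = rng.uniform(0, 1000, (n, 2))
            vals = rng.normal(70, 3, n)
            lag_w = float(rng.uniform(50, 200))
            n_lags = int(rng.integers(4, 10))
            emp = tz.empirical_semivariogram(
                pts, vals, n_lags=n_lags, lag_width=lag_w,
                max_dist=lag_w * n_lags,
            )
            centers, gamma, counts = brute_force_variogram(
                pts, vals, lag_w, n_lags
            )
            np.testing.assert_array_equal(emp.pair_counts, counts)
            np.testing.assert_allclose(emp.semivariances, gamma, rtol=1e-12)
            np.testing.assert_allclose(emp.lag_centers, centers, rtol=1e-12)
            assert emp.pair_counts.sum() <= n * (n - 1) // 2

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 1000, (25, 2))
        vals = rng.normal(0, 1, 25)
        perm = rng.permutation(25)
        a = tz.empirical_semivariogram(pts, vals, n_lags=6)
        b = tz.empirical_semivariogram(pts[perm], vals[perm], n_lags=6)
        np.testing.assert_allclose(a.semivariances, b.semivariances)
        np.testing.assert_array_equal(a.pair_counts, b.pair_counts)

    def test_all_pairs_beyond_max_dist_errors(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        with pytest.raises(ValueError, match="beyond"):
            tz.empirical_semivariogram(
                pts, [1.0, 2.0, 3.0], n_lags=2, lag_width=10.0, max_dist=20.0
            )


class TestModelSemivariance:
    def test_spherical_reaches_sill_at_range(self):
        assert tz.model_semivariance("spherical", 0.1, 1.0, 10.0, 10.0) == \
            pytest.approx(1.0)
        assert tz.model_semivariance("spherical", 0.1, 1.0, 10.0, 50.0) == \
            pytest.approx(1.0)

    def test_gaussian_hand_value_at_range(self):
        # C0 + C*(1 - e^-3) with C = 1.6217 - 0.1585
        got = tz.model_semivariance("gaussian", 0.1585, 1.6217, 59_902, 59_902)
        assert got == pytest.approx(0.1585 + 1.4632 * (1 - np.exp(-3)), abs=2e-4)
        assert got == pytest.approx(1.5488, abs=1e-3)

    @pytest.mark.parametrize("family", tz.variogram.FAMILIES)
    def test_zero_distance_is_zero(self, family):
        assert tz.model_semivariance(family, 0.5, 2.0, 100.0, 0.0) == 0.0

    @pytest.mark.parametrize("family", ["exponential", "gaussian"])
    def test_practical_range_scaling(self, family):
        """-3 scaling: the model reaches C0 + 0.95 C at h = a."""
        c0, sill, a = 0.2, 1.2, 5000.0
        got = tz.model_semivariance(family, c0, sill, a, a)
        assert got == pytest.approx(c0 + 0.95 * (sill - c0), rel=1e-3)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            tz.model_semivariance("gaussian", 0.0, 1.0, 10.0, -1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        family=st.sampled_from(tz.variogram.FAMILIES),
        c0=st.floats(0.0, 1.0),
        psill=st.floats(0.0, 5.0),
        a=st.floats(10.0, 1e5),
    )
    def test_monotone_and_bounded_by_sill(self, family, c0, psill, a):
        sill = c0 + psill
        h = np.linspace(0, 3 * a, 200)
        g = tz.model_semivariance(family, c0, sill, a, h)
        assert np.all(np.diff(g) >= -1e-9)
        assert np.all(g <= sill + 1e-9)


class TestDSD:
    @pytest.mark.parametrize(
        "nugget,sill,expected",
        [
            (0.1585, 1.6217, 9.77),
            (0.1296, 1.7412, 7.44),
            (0.1356, 1.7220, 7.87),
            (0.1356, 1.7313, 7.83),
        ],
    )
    def test_published_parameter_pairs(self, nugget, sill, expected):
        pct, cls = tz.dsd(nugget, sill)
        assert pct == pytest.approx(expected, abs=0.05)
        assert cls == "strong"

    @pytest.mark.parametrize(
        "nugget,sill,pct,cls",
        [
            (0.0, 1.0, 0.0, "strong"),
            (0.8, 1.0, 80.0, "weak"),
            (0.5, 1.0, 50.0, "moderate"),
            (0.25, 1.0, 25.0, "moderate"),
            (0.75, 1.0, 75.0, "moderate"),
        ],
    )
    def test_threshold_conventions(self, nugget, sill, pct, cls):
        assert tz.dsd(nugget, sill) == (pytest.approx(pct), cls)

    def test_zero_sill_undefined(self):
        with pytest.raises(ValueError):
            tz.dsd(0.0, 0.0)


class TestFitModel:
    def _exact_empirical(self, family, c0, sill, a):
        h = np.linspace(2000, 80_000, 15)
        g = tz.model_semivariance(family, c0, sill, a, h)
        return tz.EmpiricalVariogram(
            lag_centers=h,
            semivariances=np.asarray(g),
            pair_counts=np.full(15, 200),
            lag_width=float(h[1] - h[0]),
            max_dist=80_000.0,
        )

    @pytest.mark.parametrize("family", tz.variogram.FAMILIES)
    def test_recovers_exact_model_curve(self, family):
        emp = self._exact_empirical(family, 0.15, 1.7, 50_000.0)
        m = tz.fit_model(emp, family)
        assert m.nugget_c0 == pytest.approx(0.15, rel=1e-3, abs=1e-4)
        assert m.sill_total == pytest.approx(1.7, rel=1e-3)
        assert m.range_a == pytest.approx(50_000.0, rel=1e-3)
        assert m.fit_r2 > 0.999

    def test_pure_nugget_flat_variogram(self):
        h = np.linspace(2000, 80_000, 12)
        emp = tz.EmpiricalVariogram(
            lag_centers=h,
            semivariances=np.full(12, 0.8),
            pair_counts=np.full(12, 100),
            lag_width=float(h[1] - h[0]),
            max_dist=80_000.0,
        )
        m = tz.fit_model(emp, "spherical")
        assert m.dsd_pct > 95.0
        assert m.sill_total - m.nugget_c0 == pytest.approx(0.0, abs=0.01)

    def test_too_few_bins_errors(self):
        emp = tz.EmpiricalVariogram(
            lag_centers=np.array([1.0, 2.0, 3.0]),
            semivariances=np.array([0.1, 0.2, 0.3]),
            pair_counts=np.array([5, 5, 5]),
            lag_width=1.0,
            max_dist=3.0,
        )
        with pytest.raises(FitError):
            tz.fit_model(emp, "gaussian")

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            tz.VariogramModel("gaussian", 1.0, 0.5, 100.0)  # nugget > sill
        with pytest.raises(ValueError):
            tz.VariogramModel("cubic", 0.0, 1.0, 100.0)


class TestEstimatorInterface:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = VariogramEstimator(family="spherical", n_lags=10)
        params = est.get_params()
        assert params["family"] == "spherical"
        est2 = clone(est).set_params(family="gaussian")
        assert est2.get_params()["family"] == "gaussian"

    def test_fit_exposes_parameters(self, square_region):
        coords = square_region.points[["x_m", "y_m"]].to_numpy()
        p = tz.FieldParams(mean=73.0, nugget=0.13, sill=1.7, range_m=60_000)
        v = tz.simulate_gaussian_field(square_region, p, 3)
        est = VariogramEstimator(family="gaussian").fit(coords, v)
        assert 0 <= est.nugget_ <= est.sill_
        assert est.range_ > 0
        assert est.dsd_class_ in {"strong", "moderate", "weak"}
        np.testing.assert_allclose(
            est.predict_semivariance([0.0]), [0.0]
        )
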