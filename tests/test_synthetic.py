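"""Region construction and Gaussian-field climate simulation."""

import numpy as np
import pytest
from shapely.geometry import box

import thermozone as tz
from thermozone.region import RegionConfigError


class TestMakeRegion:
    def test_100km_square_at_4km_has_676_points(self, square_region):
        assert len(square_region.points) == 676  # 26 x 26 inclusive lattice

    def test_minimal_lattice_has_corner_points(self):
        bounds = (0.0, 0.0, 4000.0, 4000.0)
        reg = tz.make_region("tiny", bounds, tz.strip_subregions(bounds, ["a"]))
        assert len(reg.points) == 4

    def test_half_plane_partition_labels_every_point(self):
        bounds = (0.0, 0.0, 20_000.0, 20_000.0)
        reg = tz.make_region(
            "halves", bounds, tz.strip_subregions(bounds, ["west", "east"])
        )
        counts = reg.points["region"].value_counts()
        assert set(counts.index) == {"west", "east"}
        assert counts.sum() == len(reg.points)

    def test_overlapping_subregions_rejected(self):
        bounds = (0.0, 0.0, 10_000.0, 10_000.0)
        subs = [
            ("a", box(0, 0, 7000, 10_000)),
            ("b", box(5000, 0, 10_000, 10_000)),
        ]
        with pytest.raises(RegionConfigError, match="overlap"):
            tz.make_region("bad", bounds, subs)

    def test_gap_in_coverage_rejected(self):
        bounds = (0.0, 0.0, 10_000.0, 10_000.0)
        subs = [("a", box(0, 0, 4000, 10_000))]
        with pytest.raises(RegionConfigError, match="cover"):
            tz.make_region("bad", bounds, subs)

    def test_deterministic_materialization(self):
        bounds = (0.0, 0.0, 20_000.0, 12_000.0)
        a = tz.make_region("r", bounds, tz.strip_subregions(bounds, ["x", "y"]))
        b = tz.make_region("r", bounds, tz.strip_subregions(bounds, ["x", "y"]))
        assert a.points.equals(b.points)


class TestGaussianField:
    def test_same_seed_same_draw(self, square_region):
        p = tz.FieldParams(mean=5.0, nugget=0.1, sill=1.0, range_m=30_000)
        a = tz.simulate_gaussian_field(square_region, p, 7)
        b = tz.simulate_gaussian_field(square_region, p, 7)
        assert np.array_equal(a, b)
        c = tz.simulate_gaussian_field(square_region, p, 8)
        assert not np.array_equal(a, c)

    def test_zero_variance_gives_constant_field(self, square_region):
        p = tz.FieldParams(mean=73.0, nugget=0.0, sill=0.0, range_m=1000.0)
        v = tz.simulate_gaussian_field(square_region, p, 0)
        assert np.all(v == 73.0)

    def test_vanishing_range_behaves_iid(self, square_region):
        """Near-zero range: neighboring lattice points are uncorrelated."""
        p = tz.FieldParams(mean=0.0, nugget=0.0, sill=1.0, range_m=1.0)
        v = tz.simulate_gaussian_field(square_region, p, 123)
        grid = v.reshape(26, 26)
        r = np.corrcoef(grid[:, :-1].ravel(), grid[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_linear_trend_applied_around_center(self, square_region):
        p = tz.FieldParams(mean=10.0, sill=0.0, nugget=0.0, range_m=1.0,
                           trend=(0.1, 0.0))
        v = tz.simulate_gaussian_field(square_region, p, 0)
        x = square_region.points["x_m"].to_numpy()
        assert v[np.argmax(x)] - v[np.argmin(x)] == pytest.approx(10.0)
        assert v.mean() == pytest.approx(10.0)

    def test_dense_guard(self):
        bounds = (0.0, 0.0, 400_000.0, 400_000.0)
        reg = tz.make_region("big", bounds, tz.strip_subregions(bounds, ["a"]),
                             grid_spacing=4000.0)
        with pytest.raises(ValueError, match="dense"):
            tz.simulate_gaussian_field(
                reg, tz.FieldParams(mean=0.0, sill=1.0), 0
            )


TMAX = dict(mean=29.0, nugget=0.1, sill=1.5, range_m=50_000)
TMIN = dict(mean=19.0, nugget=0.1, sill=1.5, range_m=50_000)
WS = dict(mean=1.5, nugget=0.02, sill=0.15, range_m=40_000)


class TestClimateSeries:
    def test_row_count_and_constraints(self, square_region):
        df = tz.simulate_climate_series(
            square_region, [2010, 2011], tz.FieldParams(**TMAX),
            tz.FieldParams(**TMIN), tz.FieldParams(**WS), seed=1,
        )
        assert len(df) == 2 * 676
        assert (df["tmax_c"] > df["tmin_c"]).all()
        assert (df["ws_ms"] >= 0).all()

    def test_same_seed_byte_identical(self, square_region):
        args = (
            square_region, [2010], tz.FieldParams(**TMAX),
            tz.FieldParams(**TMIN), tz.FieldParams(**WS),
        )
        a = tz.simulate_climate_series(*args, seed=5).to_csv(index=False)
        b = tz.simulate_climate_series(*args, seed=5).to_csv(index=False)
        assert a == b

    def test_field_means_near_targets(self, square_region):
        """Spatial means stay within 3 SE of the configured field means,
        where the SE of a correlated field mean is sqrt(mean(C))."""
        df = tz.simulate_climate_series(
            square_region, [2010, 2011, 2012], tz.FieldParams(**TMAX),
            tz.FieldParams(**TMIN), tz.FieldParams(**WS), seed=11,
        )
        coords = square_region.points[["x_m", "y_m"]].to_numpy()
        from scipy.spatial.distance import pdist, squareform

        h = squareform(pdist(coords))
        for col, cfg in (("tmax_c", TMAX), ("tmin_c", TMIN)):
            cov = cfg["sill"] - tz.model_semivariance(
                "gaussian", cfg["nugget"], cfg["sill"], cfg["range_m"], h
            )
            np.fill_diagonal(cov, cfg["sill"])
            se = np.sqrt(cov.mean() / 1.0)
            for _, grp in df.groupby("year"):
                assert abs(grp[col].mean() - cfg["mean"]) < 3 * se

    def test_empty_year_list_errors(self, square_region):
        with pytest.raises(ValueError, match="empty"):
            tz.simulate_climate_series(
                square_region, [], tz.FieldParams(**TMAX),
                tz.FieldParams(**TMIN), tz.FieldParams(**WS), seed=0,
            )

    def test_inverted_means_rejected(self, square_region):
        with pytest.raises(ValueError, match="mean"):
            tz.simulate_climate_series(
                square_region, [2010], tz.FieldParams(**TMIN),
                tz.FieldParams(**TMAX), tz.FieldParams(**WS), seed=0,
            )
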