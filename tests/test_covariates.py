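"""Buffer extraction against analytic and Monte-Carlo geometry oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon, box

from pahlur.covariates import (
    CovariateTable,
    GeometryError,
    area_in_buffer,
    build_covariate_table,
    count_within_radius,
    distance_to_nearest,
    interpolate_met,
    length_in_buffer,
    raster_at_site,
)
from pahlur.geoio import AsciiGrid, Feature
from pahlur.predictors import make_spec

SITE = (10000.0, 10000.0)
BUFS = (500, 1000, 2000, 5000)


def poly_layer(geom, cls=80):
    return [Feature(geom, {"class": cls})]


class TestAreaInBuffer:
    def test_full_coverage_matches_pi_r_squared(self):
        layer = poly_layer(box(0, 0, 20000, 20000))
        for r in (500, 1000, 2000):
            a = area_in_buffer(layer, SITE, r, 80, BUFS)
            assert a == pytest.approx(np.pi * r * r, rel=5e-3)

    def test_half_plane_gives_half_disc(self):
        layer = poly_layer(box(SITE[0], 0, 30000, 20000))
        a = area_in_buffer(layer, SITE, 1000, 80, BUFS)
        assert a == pytest.approx(np.pi * 1000**2 / 2, rel=5e-3)

    def test_other_class_contributes_zero(self):
        layer = poly_layer(box(0, 0, 20000, 20000), cls=30)
        assert area_in_buffer(layer, SITE, 1000, 80, BUFS) == 0.0

    def test_unregistered_radius_rejected(self):
        layer = poly_layer(box(0, 0, 20000, 20000))
        with pytest.raises(ValueError, match="buffer set"):
            area_in_buffer(layer, SITE, 750, 80, BUFS)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(GeometryError, match="invalid"):
            area_in_buffer([Feature(bowtie, {"class": 80})], SITE, 1000, 80, BUFS)

    def test_monte_carlo_oracle_random_mosaic(self):
        """Clipped polygon area agrees with a point-in-polygon Monte-Carlo
        estimate that never calls the intersection routine."""
        rng = np.random.default_rng(42)
        feats = []
        for _ in range(12):
            cx, cy = rng.uniform(8000, 12000, 2)
            w, h = rng.uniform(300, 2500, 2)
            feats.append(Feature(box(cx - w, cy - h, cx + w, cy + h),
                                 {"class": 80}))
        r = 2000.0
        a = area_in_buffer(feats, SITE, r, 80, BUFS)

        n = 200_000
        theta = rng.uniform(0, 2 * np.pi, n)
        rad = r * np.sqrt(rng.uniform(0, 1, n))
        xs = SITE[0] + rad * np.cos(theta)
        ys = SITE[1] + rad * np.sin(theta)
        from shapely.ops import unary_union

        union = unary_union([f.geometry for f in feats])
        inside = contains_xy(union, xs, ys)
        frac = inside.mean()
        mc = frac * np.pi * r * r
        se = np.pi * r * r * np.sqrt(frac * (1 - frac) / n)
        assert abs(a - mc) <= 4 * se + 0.005 * a


class TestLengthInBuffer:
    def test_diameter_chord_is_exactly_two_radii(self):
        """The 256-gon disc has vertices on the axes, so an axis-aligned
        chord through the centre is clipped to exactly 2r."""
        road = [Feature(LineString([(0, SITE[1]), (20000, SITE[1])]),
                        {"class": 51})]
        assert length_in_buffer(road, SITE, 500, 51, BUFS) == pytest.approx(
            1000.0, abs=1e-9
        )

    def test_resampling_oracle_polyline(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(7000, 13000, 8),
                               rng.uniform(7000, 13000, 8)])
        road = [Feature(LineString(pts), {"class": 52})]
        r = 2000.0
        clipped = length_in_buffer(road, SITE, r, 52, BUFS)

        # walk the polyline in 0.1 m steps and count steps inside the disc
        step = 0.1
        total = 0.0
        centre = np.array(SITE)
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            k = max(int(seg / step), 1)
            t = (np.arange(k) + 0.5) / k
            mids = a + t[:, None] * (b - a)
            inside = np.linalg.norm(mids - centre, axis=1) <= r
            total += inside.mean() * seg
        assert clipped == pytest.approx(total, rel=2e-3)

    def test_disjoint_road_class_zero(self):
        road = [Feature(LineString([(0, 0), (100, 0)]), {"class": 51})]
        assert length_in_buffer(road, SITE, 1000, 51, BUFS) == 0.0


class TestPointOps:
    def test_count_boundary_inclusive(self):
        pts = [Feature(Point(SITE[0] + d, SITE[1]), {}) for d in
               (4999.0, 5000.0, 5001.0)]
        assert count_within_radius(pts, SITE, 5000.0) == 2

    def test_count_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            count_within_radius([], SITE, 0.0)

    def test_distance_to_nearest_is_min(self):
        pts = [Feature(Point(SITE[0] + 300, SITE[1]), {}),
               Feature(Point(SITE[0], SITE[1] - 120), {})]
        assert distance_to_nearest(pts, SITE) == pytest.approx(120.0)


class TestRasterLookup:
    def test_cell_convention(self):
        grid = AsciiGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0, 0, 10)
        # values[0] is the northern row
        assert raster_at_site(grid, (5, 15)) == 1.0
        assert raster_at_site(grid, (15, 15)) == 2.0
        assert raster_at_site(grid, (5, 5)) == 3.0
        assert raster_at_site(grid, (15, 5)) == 4.0
        # far edges clamp into the last cell
        assert raster_at_site(grid, (20, 20)) == 2.0


class TestInterpolateMet:
    def stations(self, values):
        coords = [(0, 0), (10000, 0), (0, 10000), (10000, 10000)]
        return [
            Feature(Point(*c), {"tem_windy": v})
            for c, v in zip(coords, values)
        ]

    def test_constant_field_short_circuits(self):
        st = self.stations([4.2] * 4)
        out = interpolate_met(st, [Point(3000, 4000)], "windy", "tem")
        assert out[0] == 4.2

    def test_exact_at_stations(self):
        st = self.stations([1.0, 2.0, 3.0, 4.0])
        out = interpolate_met(st, [Point(0, 0), Point(10000, 10000)],
                              "windy", "tem")
        assert out == pytest.approx([1.0, 4.0], abs=1e-8)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown met variable"):
            interpolate_met(self.stations([1] * 4), [Point(0, 0)],
                            "windy", "fog")

    def test_too_few_stations_rejected(self):
        st = self.stations([1.0, 2.0, 3.0, 4.0])[:2]
        with pytest.raises(ValueError, match=">= 3"):
            interpolate_met(st, [Point(0, 0)], "windy", "tem")


class TestCovariateTable:
    def test_long_round_trip(self, covariate_table):
        back = CovariateTable.from_long(covariate_table.to_long())
        pd.testing.assert_frame_equal(
            back.frame.sort_index(axis=1),
            covariate_table.frame.sort_index(axis=1),
            check_like=True,
        )

    def test_missing_cells_rejected(self):
        idx = pd.MultiIndex.from_product([["s1"], ["windy"]],
                                         names=["site_id", "season"])
        with pytest.raises(ValueError, match="missing"):
            CovariateTable(pd.DataFrame({"dem": [np.nan]}, index=idx))


class TestBuildCovariateTable:
    def test_column_order_follows_registry(self, covariate_table, registry30):
        assert list(covariate_table.frame.columns) == list(registry30)

    def test_static_columns_season_invariant(self, covariate_table):
        w = covariate_table.for_season("windy")
        h = covariate_table.for_season("heating")
        pd.testing.assert_frame_equal(w, h)

    def test_buffer_nesting_monotone(self, covariate_table):
        """A larger buffer can only see more of any class."""
        w = covariate_table.for_season("windy")
        for stem in ("lc{}_80", "lc{}_20", "r{}_51", "lu{}_5"):
            small = w[stem.format(1000)]
            mid = w[stem.format(3000)]
            big = w[stem.format(5000)]
            assert (small <= mid + 1e-9).all()
            assert (mid <= big + 1e-9).all()

    def test_translation_invariance(self, world_net):
        """Shifting world and site together leaves buffered values fixed."""
        from shapely.affinity import translate

        world, net = world_net
        sid, x, y, _ = net.sites[0]
        lc = world.land_cover
        shifted = [Feature(translate(f.geometry, 1234.5, -678.9),
                           f.properties) for f in lc]
        a0 = area_in_buffer(lc, (x, y), 1000, 80, BUFS)
        a1 = area_in_buffer(shifted, (x + 1234.5, y - 678.9), 1000, 80, BUFS)
        assert a1 == pytest.approx(a0, rel=1e-9, abs=1e-6)

    def test_errors_name_target_and_code(self, world_net):
        world, _ = world_net
        reg = {"dem": make_spec("dem")}
        # a site far outside the elevation raster fails the dem lookup
        with pytest.raises(ValueError, match=r"far_site/dem"):
            build_covariate_table(world, [("far_site", 1e7, 1e7)], reg)

    def test_empty_registry_rejected(self, world_net):
        world, net = world_net
        with pytest.raises(ValueError, match="empty"):
            build_covariate_table(world, [("s", 0.0, 0.0)], {})
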