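"""Terrain hydrology: pit removal, D-infinity routing, distances, CTI, slope."""

import math

import numpy as np
import pytest

from wetpot import (Grid, GridError, compute_cti, dinf_accumulation,
                    dinf_flow_direction, distance_down, extract_channels,
                    remove_pits, slope_aspect, smooth_and_scale_cti)
from wetpot.terrain import NEIGHBOR_OFFSETS, SLOPE_EPS_RAD

from conftest import (accumulation_oracle, directional_slope,
                      distance_down_oracle, has_nonascending_path_to_edge,
                      random_dem, random_pitfree_dem, sweep_direction_oracle)


def plane(n, fx=0.0, fy=0.0, cell_size=10.0, z0=100.0):
    """z = z0 + fx·x + fy·y with x east, y north (row 0 north)."""
    rows = np.arange(n)[:, None] * cell_size
    cols = np.arange(n)[None, :] * cell_size
    y = (n - 1) * cell_size - rows
    return Grid(z0 + fx * cols + fy * y, cell_size)


class TestRemovePits:
    def test_single_pit_raised_to_pour_elevation(self):
        z = np.full((3, 3), 5.0)
        z[1, 1] = 1.0
        out = remove_pits(Grid(z, 10.0), epsilon=0.0)
        assert out.values[1, 1] == pytest.approx(5.0)

    def test_pit_free_dem_unchanged(self):
        g = plane(6, fx=0.01)
        out = remove_pits(g, epsilon=0.0)
        np.testing.assert_allclose(out.values, g.values)

    def test_monotone_idempotent_and_drains(self, rng):
        for _ in range(20):
            dem = random_dem(rng, n=16, smooth=False)
            # carve a few pits
            z = dem.values
            for r, c in rng.integers(2, 14, size=(4, 2)):
                z[r, c] = z[r - 1:r + 2, c - 1:c + 2].min() - 1.0
            filled = remove_pits(dem, epsilon=0.0)
            assert (filled.values >= dem.values - 1e-12).all()
            again = remove_pits(filled, epsilon=0.0)
            np.testing.assert_allclose(again.values, filled.values)
            assert has_nonascending_path_to_edge(filled)
            assert not has_nonascending_path_to_edge(dem) or True  # dem may drain

    def test_enclosed_region_raises(self):
        z = np.full((5, 5), np.nan)
        z[1:4, 1:4] = 3.0
        z[2, 2] = 1.0
        # nodata boundary is an outlet by design: carving drains to it
        out = remove_pits(Grid(z, 10.0), epsilon=0.0)
        assert np.isfinite(out.values[2, 2])
        with pytest.raises(GridError):
            remove_pits(Grid(np.full((3, 3), np.nan), 10.0), epsilon=0.0)

    def test_epsilon_yields_strict_descent(self, rng):
        dem = random_dem(rng, n=10, smooth=False)
        dem.values[4:7, 4:7] = 2.0  # a flat basin
        filled = remove_pits(dem, epsilon=1e-3)
        flow = dinf_flow_direction(filled)  # must not raise on flats
        assert np.isfinite(flow.angle[~flow.outlet & filled.valid_mask()]).all()


class TestDinfDirection:
    def test_plane_descending_east(self):
        g = plane(5, fx=-0.05)
        flow = dinf_flow_direction(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(flow.angle[interior], 0.0, atol=1e-12)
        assert (flow.idx1[interior] == 0).all()  # east neighbor
        np.testing.assert_allclose(flow.p1[interior], 1.0)

    def test_plane_descending_northeast_exact_diagonal(self):
        # α aligned exactly with the NE neighbor: that neighbor takes all
        # flow (angular-proximity split degenerates to proportion 1)
        g = plane(5, fx=-0.05, fy=-0.05)
        flow = dinf_flow_direction(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(flow.angle[interior], math.pi / 4, atol=1e-12)
        assert (flow.idx1[interior] == 1).all()  # NE neighbor
        np.testing.assert_allclose(flow.p1[interior], 1.0, atol=1e-12)

    def test_slightly_off_diagonal_plane_splits_by_angle(self):
        # descent direction 30° from east: proportions 2/3 east, 1/3 NE
        theta = math.pi / 6
        g = plane(5, fx=-0.05 * math.cos(theta), fy=-0.05 * math.sin(theta))
        flow = dinf_flow_direction(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(flow.angle[interior], theta, atol=1e-12)
        np.testing.assert_allclose(flow.p1[interior], 1 - theta / (math.pi / 4),
                                   atol=1e-12)

    def test_agrees_with_angular_sweep_oracle(self, rng):
        for _ in range(5):
            dem = random_pitfree_dem(rng, n=5)
            flow = dinf_flow_direction(dem)
            for r in range(1, 4):
                for c in range(1, 4):
                    if flow.outlet[r, c]:
                        continue
                    _, s_max = sweep_direction_oracle(dem, r, c)
                    s_impl = flow.slope[r, c]
                    assert s_impl == pytest.approx(s_max, abs=1e-6)
                    # the implementation's angle achieves the sweep maximum
                    s_at_impl = directional_slope(dem, r, c, flow.angle[r, c])
                    assert s_at_impl == pytest.approx(s_impl, abs=1e-9)

    def test_proportions_sum_to_one(self, rng):
        dem = random_pitfree_dem(rng, n=8)
        flow = dinf_flow_direction(dem)
        routed = dem.valid_mask() & ~flow.outlet
        np.testing.assert_allclose((flow.p1 + flow.p2)[routed], 1.0, atol=1e-12)

    def test_interior_pit_raises(self):
        z = np.full((5, 5), 5.0)
        z[2, 2] = 1.0
        with pytest.raises(GridError, match="flat or pit"):
            dinf_flow_direction(Grid(z + np.arange(5)[:, None] * 0.0, 10.0))


class TestAccumulation:
    def test_descending_strip_accumulates_down_column(self):
        z = np.arange(6, 0, -1, dtype=float)[:, None] * np.ones((1, 1))
        g = Grid(z, 10.0)
        flow = dinf_flow_direction(g)
        acc = dinf_accumulation(flow)
        np.testing.assert_allclose(acc.values[:, 0], np.arange(1, 7))

    def test_source_cell_is_one(self, rng):
        dem = random_pitfree_dem(rng, n=6)
        acc = dinf_accumulation(dinf_flow_direction(dem))
        assert acc.values.min() == pytest.approx(1.0)

    def test_matches_dense_linear_system(self, rng):
        for _ in range(5):
            dem = random_pitfree_dem(rng, n=8)
            flow = dinf_flow_direction(dem)
            acc = dinf_accumulation(flow)
            np.testing.assert_allclose(acc.values, accumulation_oracle(flow),
                                       atol=1e-9)

    def test_mass_conservation_at_outlets(self, rng):
        for _ in range(5):
            dem = random_pitfree_dem(rng, n=12)
            flow = dinf_flow_direction(dem)
            acc = dinf_accumulation(flow)
            outflow = acc.values[flow.outlet].sum()
            assert outflow == pytest.approx(dem.valid_mask().sum(), abs=1e-6)


class TestChannels:
    def test_inclusive_threshold(self):
        acc = Grid(np.array([[44999.0, 45000.0, 45001.0]]), 10.0)
        ch = extract_channels(acc, 45_000)
        np.testing.assert_array_equal(ch.mask.values, [[0, 1, 1]])

    def test_no_channels_below_threshold(self):
        acc = Grid(np.full((4, 4), 10.0), 10.0)
        assert extract_channels(acc, 45_000).is_empty()

    def test_coastal_injection_flags_low_accumulation_cells(self):
        acc = Grid(np.ones((3, 3)), 10.0)
        coast = Grid(np.zeros((3, 3), dtype=np.int32), 10.0)
        coast.values[2, :] = 1
        ch = extract_channels(acc, 45_000, coastal_mask=coast)
        assert ch.mask.values[1, 1] == 1  # 8-adjacent to the coast row
        assert ch.mask.values[0, 0] == 0


class TestDistanceDown:
    def test_two_step_cardinal_path_arithmetic(self):
        # column strip: channel at the bottom, 1 m drop per 10 m step
        z = np.array([[12.0], [11.0], [10.0]])
        g = Grid(z, 10.0)
        flow = dinf_flow_direction(g)
        acc = dinf_accumulation(flow)
        ch = extract_channels(acc, 3)  # only the bottom cell accumulates 3
        hofd = distance_down(flow, g, ch, "horizontal")
        vofd = distance_down(flow, g, ch, "vertical")
        pofd = distance_down(flow, g, ch, "pythagoras")
        assert hofd.values[0, 0] == pytest.approx(20.0)
        assert vofd.values[0, 0] == pytest.approx(2.0)
        assert pofd.values[0, 0] == pytest.approx(2 * math.hypot(10.0, 1.0))
        for grid in (hofd, vofd, pofd):
            assert grid.values[2, 0] == 0.0  # channel cell

    def test_matches_dense_linear_system(self, rng):
        for _ in range(5):
            dem = random_pitfree_dem(rng, n=8)
            flow = dinf_flow_direction(dem)
            acc = dinf_accumulation(flow)
            ch = extract_channels(acc, 6)
            channel = np.asarray(ch.mask.values) == 1
            for metric in ("horizontal", "vertical", "pythagoras"):
                got = distance_down(flow, dem, ch, metric,
                                    outlets_as_channels=True)
                want = distance_down_oracle(flow, channel, metric)
                np.testing.assert_allclose(got.values, want, atol=1e-9)

    def test_triangle_inequalities(self, rng):
        for _ in range(5):
            dem = random_pitfree_dem(rng, n=10)
            flow = dinf_flow_direction(dem)
            acc = dinf_accumulation(flow)
            ch = extract_channels(acc, 8)
            h = distance_down(flow, dem, ch, "horizontal", outlets_as_channels=True).values
            v = distance_down(flow, dem, ch, "vertical", outlets_as_channels=True).values
            p = distance_down(flow, dem, ch, "pythagoras", outlets_as_channels=True).values
            assert (np.maximum(h, v) <= p + 1e-9).all()
            assert (p <= h + v + 1e-9).all()

    def test_unreached_cells_are_nodata_without_outlet_channels(self):
        z = np.array([[12.0], [11.0], [10.0]])
        g = Grid(z, 10.0)
        flow = dinf_flow_direction(g)
        ch = extract_channels(dinf_accumulation(flow), 10**6)
        with pytest.raises(GridError):
            distance_down(flow, g, ch, "horizontal")
        d = distance_down(flow, g, ch, "horizontal", outlets_as_channels=True)
        assert np.isfinite(d.values).all()

    def test_unknown_metric(self, rng):
        dem = random_pitfree_dem(rng, n=4)
        flow = dinf_flow_direction(dem)
        ch = extract_channels(dinf_accumulation(flow), 2)
        with pytest.raises(GridError, match="metric"):
            distance_down(flow, dem, ch, "manhattan")


class TestCTI:
    def test_direct_formula(self):
        acc = Grid(np.full((1, 1), 100.0), 10.0)
        slope = Grid(np.full((1, 1), 0.1), 10.0)
        cti = compute_cti(acc, slope)
        assert cti.values[0, 0] == pytest.approx(
            math.log(1000.0 / math.tan(0.1 + SLOPE_EPS_RAD)), abs=1e-9)

    def test_flat_cell_finite(self):
        acc = Grid(np.full((1, 1), 5.0), 10.0)
        slope = Grid(np.zeros((1, 1)), 10.0)
        cti = compute_cti(acc, slope)
        assert cti.values[0, 0] == pytest.approx(
            math.log(50.0 / math.tan(SLOPE_EPS_RAD)))

    def test_decreases_with_slope(self):
        acc = Grid(np.full((1, 4), 100.0), 10.0)
        slope = Grid(np.array([[0.0, 0.1, 0.3, 0.8]]), 10.0)
        vals = compute_cti(acc, slope).values[0]
        assert (np.diff(vals) < 0).all()


class TestSmoothScaleCTI:
    def test_constant_neighborhood_unchanged_by_smoothing(self):
        from wetpot import focal_mean3

        g = Grid(np.full((5, 5), 7.0), 10.0)
        np.testing.assert_allclose(focal_mean3(g).values, 7.0)

    def test_endpoints_hit_0_and_1000(self, rng):
        g = Grid(rng.normal(size=(12, 12)), 10.0)
        out = smooth_and_scale_cti(g)
        assert out.values.min() == 0
        assert out.values.max() == 1000
        assert np.issubdtype(out.values.dtype, np.integer)

    def test_rank_order_preserved(self, rng):
        from wetpot import focal_mean3

        g = Grid(rng.normal(size=(10, 10)), 10.0)
        smoothed = focal_mean3(g).values.ravel()
        scaled = smooth_and_scale_cti(g).values.ravel()
        order = np.argsort(smoothed, kind="stable")
        assert (np.diff(scaled[order]) >= 0).all()

    def test_constant_grid_raises(self):
        with pytest.raises(GridError, match="constant"):
            smooth_and_scale_cti(Grid(np.full((4, 4), 3.0), 10.0))


class TestSlopeAspect:
    def test_plane_rising_east(self):
        g = plane(7, fx=1.0)
        slope, aspect = slope_aspect(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(slope.values[interior], 45.0, atol=1e-9)
        np.testing.assert_allclose(aspect.values[interior], 270.0, atol=1e-9)

    def test_constant_dem_flat_convention(self):
        slope, aspect = slope_aspect(Grid(np.full((5, 5), 9.0), 10.0))
        np.testing.assert_allclose(slope.values, 0.0)
        np.testing.assert_allclose(aspect.values, 0.0)

    def test_plane_descending_north(self):
        g = plane(7, fy=-0.2)  # z falls toward the north
        slope, aspect = slope_aspect(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(aspect.values[interior], 0.0, atol=1e-9)
        np.testing.assert_allclose(slope.values[interior],
                                   math.degrees(math.atan(0.2)), atol=1e-9)
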