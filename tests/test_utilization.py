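"""KDE utilization distributions, volume contours, bandwidth tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

import levelcore as lc
from levelcore.grid import GridError
from levelcore.utilization import UDError, contour_area

from conftest import cluster_points


def exhaustive_minimal_prefix(density, cell_area, isopleth):
    """Oracle: walk the declared ordering (density desc, row-major ties)
    and return the first prefix length reaching the isopleth volume."""
    flat = density.ravel(order="C")
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    total = flat.sum() * cell_area
    cum = 0.0
    for k, i in enumerate(order):
        cum += flat[i] * cell_area
        if cum >= isopleth * total * (1 - 1e-12):
            return k + 1, order[: k + 1]
    raise AssertionError("isopleth never reached")


class TestGrid:
    def test_point_to_cell_floor_and_edges(self):
        g = lc.GridSpec(0, 0, 2.0, 5, 5)
        r, c = g.point_to_cell([0.0, 1.9, 2.0, 9.99, 10.0], [0.0] * 5)
        assert list(c) == [0, 0, 1, 4, 4]       # right edge -> last cell
        r, c = g.point_to_cell([0.0], [10.0])
        assert r[0] == 4                        # top edge -> last row
        with pytest.raises(GridError):
            g.point_to_cell([10.01], [0.0])


class TestKdeUD:
    def test_single_point_peak_and_mass(self):
        grid = lc.GridSpec(0, 0, 1.0, 61, 61)
        ud = lc.kde_ud(np.array([[30.5, 30.5]]), 3.0, grid)
        assert ud.is_normalized()
        assert np.unravel_index(ud.density.argmax(), grid.shape) == (30, 30)

    def test_two_distant_points_half_peak(self):
        h = 2.0
        grid = lc.GridSpec(0, 0, 0.5, 160, 160)
        one = lc.kde_ud(np.array([[40.25, 40.25]]), h, grid)
        two = lc.kde_ud(np.array([[30.25, 40.25], [50.25, 40.25]]), h, grid)
        ratio = two.density.max() / one.density.max()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_matches_closed_form_gaussian_mixture(self):
        pts = np.array([[20.0, 25.0], [32.0, 18.0], [26.0, 30.0]])
        h = 3.0
        grid = lc.GridSpec(0, 0, 1.0, 50, 52)
        ud = lc.kde_ud(pts, h, grid)
        xc, yc = np.meshgrid(grid.x_centers(), grid.y_centers())
        exact = np.zeros(grid.shape)
        for p in pts:
            exact += multivariate_normal(p, h**2 * np.eye(2)).pdf(
                np.dstack([xc, yc]))
        exact /= len(pts)
        exact /= exact.sum() * grid.cell_area
        # truncation at 5 bandwidths leaves < 1e-5 relative error
        assert np.abs(ud.density - exact).max() < 1e-5 * exact.max()

    def test_smoothing_increases_entropy(self, rng):
        pts = rng.uniform(30, 90, size=(200, 2))
        grid = lc.GridSpec(0, 0, 1.0, 120, 120)

        def entropy(h):
            m = lc.kde_ud(pts, h, grid).density * grid.cell_area
            m = m[m > 0]
            return -(m * np.log(m)).sum()

        assert entropy(8.0) > entropy(2.0)

    def test_margin_contract(self):
        grid = lc.GridSpec(0, 0, 1.0, 20, 20)
        with pytest.raises(GridError):
            lc.kde_ud(np.array([[2.0, 10.0]]), 5.0, grid)   # 3h = 15 > 2

    def test_normalization_over_many_random_sets(self, rng):
        # mass check across 50 random point sets and bandwidths
        for _ in range(50):
            pts = rng.uniform(40, 80, size=(rng.integers(1, 40), 2))
            h = rng.uniform(0.5, 8.0)
            grid = lc.GridSpec(0, 0, 2.0, 60, 60)
            assert lc.kde_ud(pts, h, grid).is_normalized(tol=1e-6)


class TestVolumeContour:
    def _uniform_ud(self, ncells=100):
        grid = lc.GridSpec(0, 0, 1.0, 10, ncells // 10)
        return lc.UDRaster(grid=grid,
                           density=np.full(grid.shape, 1.0 / ncells),
                           bandwidth=1.0)

    def test_uniform_tie_break_row_major(self):
        ud = self._uniform_ud()
        cs = lc.volume_contour(ud, 0.30)
        assert sorted(cs.members.tolist()) == list(range(30))
        assert cs.area == pytest.approx(30.0)

    def test_point_mass_single_cell(self):
        grid = lc.GridSpec(0, 0, 1.0, 5, 5)
        d = np.full(grid.shape, 1e-12)
        d[2, 3] = 1.0 - 24e-12
        ud = lc.UDRaster(grid=grid, density=d, bandwidth=1.0)
        assert len(lc.volume_contour(ud, 0.95).members) == 1

    def test_minimality_against_exhaustive_oracle(self, rng):
        for _ in range(30):
            grid = lc.GridSpec(0, 0, 1.0, rng.integers(3, 14),
                               rng.integers(3, 15))
            d = rng.random(grid.shape)
            d /= d.sum() * grid.cell_area
            ud = lc.UDRaster(grid=grid, density=d, bandwidth=1.0)
            for iso in (0.30, 0.95):
                cs = lc.volume_contour(ud, iso)
                k, members = exhaustive_minimal_prefix(
                    d, grid.cell_area, iso)
                assert len(cs.members) == k
                assert sorted(cs.members.tolist()) == sorted(members)
                # mass >= isopleth; dropping the last cell falls short
                mass = d.ravel()[cs.members].sum() * grid.cell_area
                assert mass >= iso * (1 - 1e-9)
                short = d.ravel()[cs.members[:-1]].sum() * grid.cell_area
                assert short < iso

    def test_bad_isopleth(self):
        with pytest.raises(UDError):
            lc.volume_contour(self._uniform_ud(), 1.2)

    @given(st.lists(st.floats(0.01, 10.0), min_size=6, max_size=48),
           st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_contour_mass_and_minimality_property(self, weights, iso):
        n = len(weights) - len(weights) % 2
        d = np.asarray(weights[:n]).reshape(2, -1)
        grid = lc.GridSpec(0, 0, 1.0, *d.shape)
        d = d / (d.sum() * grid.cell_area)
        ud = lc.UDRaster(grid=grid, density=d, bandwidth=1.0)
        cs = lc.volume_contour(ud, iso)
        mass = d.ravel()[cs.members].sum() * grid.cell_area
        assert mass >= iso * (1 - 1e-9)
        if len(cs.members) > 1:
            assert d.ravel()[cs.members[:-1]].sum() * grid.cell_area < iso


class TestTuneBandwidth:
    def test_immediate_stop_when_h0_suffices(self, rng):
        pts = cluster_points(rng, 40)
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        a0 = contour_area(pts, 8.0, grid, 0.95)
        h, ud, trace = lc.tune_bandwidth(pts, a0 * 0.5, grid, h0=8.0, step=1.0)
        assert h == 8.0

    def test_first_crossing_property(self, rng):
        pts = cluster_points(rng, 30)
        target = lc.mcp(pts, 0.95).area
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        h, ud, trace = lc.tune_bandwidth(pts, target, grid, h0=1.0, step=1.0)
        area_h = contour_area(pts, h, grid, 0.95)
        assert area_h >= target
        if h > 1.0:
            assert contour_area(pts, h - 1.0, grid, 0.95) < target

    def test_bisection_oracle_same_answer(self, rng):
        pts = cluster_points(rng, 30)
        target = lc.mcp(pts, 0.95).area
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        h, _, _ = lc.tune_bandwidth(pts, target, grid, h0=1.0, step=1.0)
        # bisection on the same step grid for the first k with area >= target
        lo, hi = 0, 60
        while lo < hi:
            mid = (lo + hi) // 2
            if contour_area(pts, 1.0 + mid * 1.0, grid, 0.95) >= target:
                hi = mid
            else:
                lo = mid + 1
        assert h == 1.0 + lo * 1.0

    def test_step_refinement_consistency(self, rng):
        pts = cluster_points(rng, 25)
        target = lc.mcp(pts, 0.95).area
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        h1, _, _ = lc.tune_bandwidth(pts, target, grid, h0=0.5, step=1.0)
        h2, _, _ = lc.tune_bandwidth(pts, target, grid, h0=0.5, step=0.5)
        assert abs(h1 - h2) <= 1.0

    def test_warm_start_does_not_change_answer(self, rng):
        pts = cluster_points(rng, 30)
        target = lc.mcp(pts, 0.95).area
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        cold, _, _ = lc.tune_bandwidth(pts, target, grid, h0=1.0, step=1.0)
        for warm in (2.0, cold, cold + 7.0):
            h, _, _ = lc.tune_bandwidth(pts, target, grid, h0=1.0, step=1.0,
                                        warm_start=warm)
            assert h == cold

    def test_unreachable_target_errors_with_trace(self, rng):
        pts = cluster_points(rng, 20)
        grid = lc.GridSpec.from_points(pts, 2.0, 60.0)
        with pytest.raises(UDError, match="target"):
            lc.tune_bandwidth(pts, 1e9, grid, h0=1.0, step=1.0, h_max=10.0)

    def test_contour_area_nondecreasing_in_h(self, rng):
        pts = cluster_points(rng, 30)
        grid = lc.GridSpec.from_points(pts, 2.0, 120.0)
        areas = [contour_area(pts, h, grid, 0.95) for h in range(2, 20, 2)]
        assert np.all(np.diff(areas) >= 0)


class TestSeasonAndPopulationUDs:
    def test_individual_uds_normalized_and_area_matched(self, filtered,
                                                        season_uds, run_cfg):
        assert len(season_uds) == filtered.n_seasons
        for key, ud in season_uds.items():
            assert ud.is_normalized()
            target = lc.mcp(filtered.season_points(*key),
                            run_cfg.mcp_percent).area
            cs = lc.volume_contour(ud, run_cfg.outer_isopleth)
            assert cs.area >= target
            # within one step's worth of growth of the target
            if ud.bandwidth > run_cfg.bandwidth_step:
                below = contour_area(filtered.season_points(*key),
                                     ud.bandwidth - run_cfg.bandwidth_step,
                                     ud.grid, run_cfg.outer_isopleth)
                assert below < target

    def test_tight_cluster_gets_smallest_bandwidth_unimodal(self, rng):
        import pandas as pd
        base = rng.normal(0, 0.5, size=(24, 2)) + 50.0
        rows = [{"obs_id": i, "animal_id": "A0", "season_id": "S0",
                 "repro_class": "male", "timestamp": pd.Timestamp("2016-05-01"),
                 "x": base[i, 0], "y": base[i, 1], "canopy": 50.0,
                 "cwd": 50.0, "ground_veg": 50.0, "rock": 50.0,
                 "woody_veg": 50.0} for i in range(24)]
        data = lc.TelemetryDataset(pd.DataFrame(rows))
        cfg = lc.RunConfig(seed=0)
        ud = lc.individual_uds(data, cfg)[("A0", "S0")]
        assert ud.bandwidth == cfg.bandwidth_step
        # unimodal: the peak cell's 8-neighborhood holds the next densest
        flat = np.argsort(ud.density.ravel())[::-1][:5]
        r, c = np.unravel_index(flat, ud.grid.shape)
        assert r.max() - r.min() <= 2 and c.max() - c.min() <= 2

    def test_degenerate_population_resampling(self, rng):
        import pandas as pd
        rows = []
        oid = 0
        for a in range(3):
            pts = rng.normal(0, 20, size=(25, 2)) + [70 * a, 0]
            for x, y in pts:
                rows.append({"obs_id": oid, "animal_id": f"A{a}",
                             "season_id": "S0", "repro_class": "male",
                             "timestamp": pd.Timestamp("2016-05-01"),
                             "x": x, "y": y, "canopy": 50.0, "cwd": 50.0,
                             "ground_veg": 50.0, "rock": 50.0,
                             "woody_veg": 50.0})
                oid += 1
        data = lc.TelemetryDataset(pd.DataFrame(rows))
        cfg = lc.RunConfig(seed=0)
        pop3 = lc.population_ud(data, cfg, n_iterations=3)
        pooled = lc.kde_ud(data.points(), pop3.bandwidth, pop3.grid)
        assert np.abs(pop3.density - pooled.density).max() < 1e-10

    def test_population_iterations_stable(self, filtered, run_cfg, pop_ud):
        other = lc.population_ud(filtered, run_cfg,
                                 rng=np.random.default_rng(999),
                                 n_iterations=25)
        corr = np.corrcoef(pop_ud.density.ravel(), other.density.ravel())[0, 1]
        assert corr > 0.99
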