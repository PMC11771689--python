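import numpy as np
import pytest
from shapely.geometry import Point, box

from fenceflow.circuit import (
    build_graph,
    connectivity_change,
    cumulative_current,
    identify_corridors,
    solve_pair,
)
from fenceflow.raster import Raster
from fenceflow.vectors import FocalRegion

from .helpers import dense_grid_solve


def _grid(values, cell=1.0):
    arr = np.asarray(values, float)
    return Raster(arr, cell_size=cell, origin=(0.0, arr.shape[0] * cell))


def _cell_focal(name, row, col, raster):
    x, y = raster.cell_center(row, col)
    return FocalRegion(name, Point(x, y).buffer(0.3 * raster.cell_size))


class TestBuildGraph:
    def test_conductance_is_inverse_mean_resistance(self):
        r = _grid([[2.0, 2.0]])
        g = build_graph(r, [_cell_focal("a", 0, 0, r), _cell_focal("b", 0, 1, r)])
        np.testing.assert_allclose(g.edge_g, [0.5])

    def test_lattice_edge_count(self):
        r = _grid(np.ones((10, 10)))
        g = build_graph(r, [_cell_focal("a", 0, 0, r), _cell_focal("b", 9, 9, r)])
        assert len(g.edge_g) == 2 * 10 * 9  # 180 grid edges

    def test_focal_contraction_reduces_nodes(self):
        r = _grid(np.ones((8, 8)))
        # polygon covering a 2x2 block of cells (k=4) contracts to one node
        big = FocalRegion("a", box(0.0, 6.0, 2.0, 8.0))
        g = build_graph(r, [big, _cell_focal("b", 7, 7, r)])
        assert g.n_nodes == 64 - (4 - 1)

    def test_focal_without_valid_cells_rejected(self):
        r = _grid(np.ones((5, 5)))
        outside = FocalRegion("ghost", Point(-50, -50).buffer(1.0))
        with pytest.raises(ValueError, match="ghost"):
            build_graph(r, [outside, _cell_focal("b", 0, 0, r)])


class TestSolvePair:
    def test_series_chain(self):
        """1x3 chain of uniform resistance r: R_eff = 2r, middle current 1."""
        r = _grid([[2.0, 2.0, 2.0]])
        g = build_graph(r, [_cell_focal("a", 0, 0, r), _cell_focal("b", 0, 2, r)])
        res = solve_pair(g, "a", "b")
        assert res.effective_resistance == pytest.approx(4.0)
        np.testing.assert_allclose(res.current.values, [[1.0, 1.0, 1.0]])

    def test_parallel_paths_split_evenly(self):
        """Two equal two-edge paths: each carries 0.5; R_eff is halved."""
        vals = np.array([[1.0, 1.0, 1.0], [1.0, np.nan, 1.0], [1.0, 1.0, 1.0]])
        r = _grid(vals)
        left = _cell_focal("a", 1, 0, r)
        right = _cell_focal("b", 1, 2, r)
        res = solve_pair(build_graph(r, [left, right]), "a", "b")
        assert res.current.values[0, 1] == pytest.approx(0.5)
        assert res.current.values[2, 1] == pytest.approx(0.5)
        # single path (2 edges of R=1 each, via corner cells: 4 edges of R=1)
        # doubled in parallel: R_eff = 4/2
        assert res.effective_resistance == pytest.approx(2.0)

    def test_matches_dense_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(6):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(3, 9))
            vals = rng.uniform(0.5, 50.0, (n, m))
            r = _grid(vals)
            g = build_graph(r, [_cell_focal("a", 0, 0, r), _cell_focal("b", n - 1, m - 1, r)])
            res = solve_pair(g, "a", "b")
            v_oracle = dense_grid_solve(vals, (0, 0), (n - 1, m - 1))
            v_impl = np.zeros((n, m))
            for row in range(n):
                for col in range(m):
                    v_impl[row, col] = res.voltages[g.node_of[row, col]]
            np.testing.assert_allclose(v_impl, v_oracle, atol=1e-8)
            assert res.effective_resistance == pytest.approx(v_oracle[0, 0], abs=1e-8)

    def test_kirchhoff_conservation(self, fenced_world):
        from fenceflow.resistance import suitability_to_resistance

        r = suitability_to_resistance(fenced_world.suitability_true)
        g = build_graph(r, fenced_world.focal)
        res = solve_pair(g, "west", "east")
        net = np.zeros(g.n_nodes)
        np.add.at(net, g.edge_u, -res.edge_currents)
        np.add.at(net, g.edge_v, res.edge_currents)
        focal_ids = set(g.focal_nodes.values())
        interior = np.array([i for i in range(g.n_nodes) if i not in focal_ids])
        assert np.abs(net[interior]).max() < 1e-8

    def test_disconnected_pair_flagged(self):
        vals = np.array([[1.0, np.nan, 1.0]] * 3)
        r = _grid(vals)
        g = build_graph(r, [_cell_focal("a", 1, 0, r), _cell_focal("b", 1, 2, r)])
        with pytest.warns(UserWarning, match="disconnected"):
            res = solve_pair(g, "a", "b")
        assert np.isinf(res.effective_resistance)
        assert not res.connected
        assert np.nansum(res.current.values) == 0.0

    def test_rayleigh_monotonicity(self):
        """Lowering any cell's resistance never raises effective resistance."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 100, (7, 7))
        r = _grid(vals)
        focal = [_cell_focal("a", 0, 0, r), _cell_focal("b", 6, 6, r)]
        base = solve_pair(build_graph(r, focal), "a", "b").effective_resistance
        for _ in range(5):
            row, col = rng.integers(0, 7, 2)
            lowered = vals.copy()
            lowered[row, col] = lowered[row, col] * 0.1
            r2 = _grid(lowered)
            reff = solve_pair(build_graph(r2, focal), "a", "b").effective_resistance
            assert reff <= base + 1e-12


class TestCumulativeCurrent:
    def test_two_regions_equals_single_pair(self):
        r = _grid(np.ones((5, 5)))
        focal = [_cell_focal("a", 0, 0, r), _cell_focal("b", 4, 4, r)]
        g = build_graph(r, focal)
        cm = cumulative_current(g)
        pair = solve_pair(g, "a", "b")
        np.testing.assert_allclose(cm.cumulative.values, pair.current.values)

    def test_focal_order_invariance_and_pair_count(self):
        r = _grid(np.ones((6, 6)))
        f = [_cell_focal("a", 0, 0, r), _cell_focal("b", 0, 5, r), _cell_focal("c", 5, 2, r)]
        cm1 = cumulative_current(build_graph(r, f))
        cm2 = cumulative_current(build_graph(r, f[::-1]))
        assert len(cm1.pair_maps) == 3
        np.testing.assert_allclose(cm1.cumulative.values, cm2.cumulative.values, atol=1e-10)

    def test_cell_current_bounded_by_injected_total(self):
        r = _grid(np.ones((6, 6)))
        f = [_cell_focal("a", 0, 0, r), _cell_focal("b", 0, 5, r), _cell_focal("c", 5, 2, r)]
        cm = cumulative_current(build_graph(r, f))
        assert np.nanmax(cm.cumulative.values) <= len(cm.pair_maps) + 1e-9


class TestIdentifyCorridors:
    def test_top_ten_percent_of_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(100).astype(float).reshape(10, 10)
        mask, threshold = identify_corridors(_grid(vals), top_fraction=0.10)
        assert np.nansum(mask.values) == 10
        assert np.all(vals[mask.values == 1] > threshold)

    def test_median_split(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        mask, _ = identify_corridors(_grid(vals), top_fraction=0.5)
        assert np.nansum(mask.values) == 50

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        r = _grid(rng.uniform(size=(12, 12)))
        prev = np.zeros((12, 12))
        for frac in (0.05, 0.1, 0.2, 0.4):
            mask, _ = identify_corridors(r, top_fraction=frac)
            assert np.all(mask.values >= prev)  # never deselects
            prev = mask.values

    def test_constant_map_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, _ = identify_corridors(_grid(np.full((5, 5), 3.0)), 0.1)
        assert np.nansum(mask.values) == 0


class TestConnectivityChange:
    def test_identical_inputs_zero(self, uniform_raster):
        r = uniform_raster(2.0)
        np.testing.assert_array_equal(connectivity_change(r, r).values, 0.0)

    def test_sum_linearity(self):
        rng = np.random.default_rng(5)
        a = _grid(rng.uniform(size=(8, 8)))
        b = _grid(rng.uniform(size=(8, 8)))
        delta = connectivity_change(a, b)
        assert np.nansum(delta.values) == pytest.approx(np.nansum(a.values) - np.nansum(b.values))

    def test_grid_mismatch_rejected(self):
        a = _grid(np.ones((4, 4)))
        b = _grid(np.ones((4, 4)), cell=2.0)
        with pytest.raises(ValueError, match="mismatch"):
            connectivity_change(a, b)

    def test_fence_bisecting_single_path_loses_current(self):
        """Severing the only route registers as loss along that route."""
        from fenceflow.resistance import burn_fences
        from fenceflow.vectors import FenceNetwork
        from shapely.geometry import LineString

        vals = np.full((5, 9), 50.0)
        vals[2, :] = 1.0  # one low-resistance channel
        r = _grid(vals)
        focal = [_cell_focal("a", 2, 0, r), _cell_focal("b", 2, 8, r)]
        cm_pre = cumulative_current(build_graph(r, focal))
        wall = FenceNetwork(lines=[LineString([(4.5, 0.0), (4.5, 5.0)])])
        r_fenced = burn_fences(r, wall, barrier_value=100.0)
        cm_post = cumulative_current(build_graph(r_fenced, focal))
        delta = connectivity_change(cm_post, cm_pre)
        channel = delta.values[2, 1:4]
        assert np.all(channel <= 1e-12)
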