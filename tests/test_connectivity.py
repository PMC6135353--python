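import math

import numpy as np
import pytest

from _oracles import enumerate_all_simple_paths_cost, exhaustive_cost_field
from kernelscape.connectivity import (
    allometric_max_dispersal,
    cost_distance,
    cumulative_resistant_kernel,
    factorial_least_cost_paths,
    focal_mean,
    pairwise_cost_matrix,
)
from kernelscape.raster import RasterGrid
from kernelscape.resistance import ResistanceGrid, SourcePointSet


def make_resistance(values, cell_size=1000.0):
    return ResistanceGrid(RasterGrid(np.asarray(values, dtype=float), cell_size))


def sources_at(points):
    return SourcePointSet(np.asarray(points), threshold=0.0, seed=0)


class TestCostDistance:
    def test_uniform_resistance_equals_metric_distance(self):
        r = make_resistance(np.ones((7, 7)))
        field = cost_distance(r, (3, 0))
        assert field.raster.values[3, 3] == pytest.approx(3000.0)
        assert field.raster.values[4, 1] == pytest.approx(1000.0 * math.sqrt(2))
        assert field.raster.values[3, 0] == 0.0

    def test_strip_with_varying_resistance(self):
        # edge weights: 1000*(1+5)/2 + 1000*(5+9)/2 = 10000
        r = make_resistance([[1.0, 5.0, 9.0]])
        field = cost_distance(r, (0, 0))
        assert field.raster.values[0, 2] == pytest.approx(10_000.0)

    def test_max_cost_truncates_frontier(self):
        r = make_resistance(np.ones((1, 10)))
        field = cost_distance(r, (0, 0), max_cost=3500.0)
        assert np.isfinite(field.raster.values[0, 3])
        assert np.isinf(field.raster.values[0, 5])

    def test_source_on_nodata_rejected(self):
        values = np.ones((3, 3))
        values[1, 1] = -9999.0
        r = ResistanceGrid(RasterGrid(values, 1000.0))
        with pytest.raises(ValueError, match="nodata"):
            cost_distance(r, (1, 1))

    @pytest.mark.parametrize("neighbors", [4, 8])
    def test_matches_exhaustive_enumeration_small_grids(self, neighbors, rng):
        for _ in range(25):
            rows, cols = rng.integers(2, 4, size=2)
            values = rng.uniform(1.0, 100.0, size=(rows, cols))
            src = (int(rng.integers(rows)), int(rng.integers(cols)))
            r = make_resistance(values)
            got = cost_distance(r, src, neighbors=neighbors).raster.values
            want = enumerate_all_simple_paths_cost(values, 1000.0, src, neighbors)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_symmetry_of_pairwise_costs(self, rng):
        values = rng.uniform(1.0, 50.0, size=(8, 8))
        r = make_resistance(values)
        pts = sources_at([[0, 0], [3, 5], [7, 2], [6, 7]])
        cm = pairwise_cost_matrix(r, pts)
        np.testing.assert_allclose(cm, cm.T, rtol=1e-10)
        assert (np.diag(cm) == 0).all()

    def test_scaling_resistance_scales_costs(self, rng):
        values = rng.uniform(1.0, 30.0, size=(6, 6))
        r1 = make_resistance(values)
        # gamma-scaled resistance is out of [1,100] range concerns at 3x30=90
        r3 = make_resistance(values * 3.0)
        f1 = cost_distance(r1, (0, 0)).raster.values
        f3 = cost_distance(r3, (0, 0)).raster.values
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-10)


class TestResistantKernel:
    def test_linear_decay_value(self):
        r = make_resistance(np.ones((1, 10)))
        k = cumulative_resistant_kernel(r, sources_at([[0, 0]]), bandwidth=125_000.0)
        assert k.raster.values[0, 3] == pytest.approx(1.0 - 3000.0 / 125_000.0)
        assert k.raster.values[0, 0] == pytest.approx(1.0)

    def test_zero_outside_bandwidth(self):
        r = make_resistance(np.ones((1, 10)))
        k = cumulative_resistant_kernel(r, sources_at([[0, 0]]), bandwidth=2500.0)
        assert k.raster.values[0, 3] == 0.0
        assert k.raster.values[0, 2] == pytest.approx(1.0 - 2000.0 / 2500.0)

    def test_additive_across_sources(self):
        r = make_resistance(np.ones((5, 5)))
        ka = cumulative_resistant_kernel(r, sources_at([[0, 0]]), 50_000.0)
        kb = cumulative_resistant_kernel(r, sources_at([[4, 4]]), 50_000.0)
        kab = cumulative_resistant_kernel(r, sources_at([[0, 0], [4, 4]]), 50_000.0)
        np.testing.assert_allclose(
            kab.raster.values, ka.raster.values + kb.raster.values, rtol=1e-12
        )

    def test_raising_resistance_never_raises_kernel(self, rng):
        values = rng.uniform(1.0, 20.0, size=(8, 8))
        r = make_resistance(values)
        pts = sources_at([[0, 0], [7, 7], [2, 5]])
        k0 = cumulative_resistant_kernel(r, pts, 20_000.0).raster.values
        for _ in range(5):
            bumped = values.copy()
            i, j = rng.integers(8, size=2)
            bumped[i, j] = min(bumped[i, j] + rng.uniform(5, 40), 100.0)
            k1 = cumulative_resistant_kernel(make_resistance(bumped), pts, 20_000.0)
            assert (k1.raster.values <= k0 + 1e-9).all()

    def test_bandwidth_scaling_invariance(self, rng):
        values = rng.uniform(1.0, 30.0, size=(6, 6))
        pts = sources_at([[0, 0], [5, 5]])
        k1 = cumulative_resistant_kernel(make_resistance(values), pts, 40_000.0)
        k3 = cumulative_resistant_kernel(make_resistance(values * 3.0), pts, 120_000.0)
        np.testing.assert_allclose(k1.raster.values, k3.raster.values, rtol=1e-10)


class TestFactorialLCP:
    def test_two_sources_on_strip(self):
        r = make_resistance(np.ones((1, 11)))
        d = factorial_least_cost_paths(r, sources_at([[0, 0], [0, 10]]))
        np.testing.assert_array_equal(d.raster.values, np.ones((1, 11), dtype=int))

    def test_three_collinear_sources(self):
        r = make_resistance(np.ones((1, 11)))
        d = factorial_least_cost_paths(
            r, sources_at([[0, 0], [0, 5], [0, 10]])
        ).raster.values[0]
        # paths 0-5, 0-10, 5-10; interior cells covered by two paths each,
        # the middle source is endpoint of two and interior of one
        assert d[3] == 2
        assert d[7] == 2
        assert d[5] == 3
        assert d[0] == 2 and d[10] == 2

    def test_max_cost_excludes_far_pairs(self):
        r = make_resistance(np.ones((1, 11)))
        d = factorial_least_cost_paths(
            r, sources_at([[0, 0], [0, 10]]), max_cost=5000.0
        )
        assert d.raster.values.sum() == 0

    def test_deterministic_across_runs(self, rng):
        values = rng.uniform(1.0, 40.0, size=(10, 10))
        r = make_resistance(values)
        pts = sources_at([[0, 0], [9, 9], [0, 9], [5, 4]])
        a = factorial_least_cost_paths(r, pts).raster.values
        b = factorial_least_cost_paths(r, pts).raster.values
        np.testing.assert_array_equal(a, b)

    def test_needs_two_sources(self):
        r = make_resistance(np.ones((3, 3)))
        with pytest.raises(ValueError):
            factorial_least_cost_paths(r, sources_at([[0, 0]]))


class TestFocalMean:
    def test_constant_surface_unchanged(self):
        g = RasterGrid(np.full((9, 9), 3.7), 1000.0)
        out = focal_mean(g, 2500.0)
        np.testing.assert_allclose(out.values, 3.7)

    def test_thirteen_cell_window(self):
        # radius 2 cells: |offsets| with dr^2+dc^2 <= 4 -> 13 cells
        values = np.zeros((11, 11))
        values[5, 5] = 1.0
        out = focal_mean(RasterGrid(values, 1000.0), 2000.0)
        assert out.values[5, 5] == pytest.approx(1.0 / 13.0)

    def test_interior_mean_preserved(self, rng):
        values = rng.uniform(size=(30, 30))
        out = focal_mean(RasterGrid(values, 1000.0), 2000.0)
        # away from edges the smoother redistributes mass without creating it
        assert out.values[5:25, 5:25].mean() == pytest.approx(
            values[3:27, 3:27].mean(), abs=0.02
        )

    def test_radius_below_cell_size_rejected(self):
        with pytest.raises(ValueError):
            focal_mean(RasterGrid(np.ones((3, 3)), 1000.0), 500.0)


def test_allometric_dispersal_bound():
    assert allometric_max_dispersal(16.0) == pytest.approx(160.0)
    assert allometric_max_dispersal(40.0) == pytest.approx(40.0 * math.sqrt(40.0))
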