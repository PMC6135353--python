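import numpy as np
import pytest

from kernelscape import landcover as lc
from kernelscape.experts import aggregate_ratings
from kernelscape.raster import RasterGrid
from kernelscape.resistance import (
    ResistanceGrid,
    build_resistance,
    project_future_resistance,
    reapply_threshold,
    resistance_to_suitability,
    seed_source_points,
    suitability_to_resistance,
)

# resistance of the plantations/regrowth class under the observed panel
# endpoints (class means 1.0 and 4.5, plantations mean 2.0)
R_TRANSITION = 1.0 + 99.0 * (4.5 - 2.0) / (4.5 - 1.0)  # 71.714...


class TestSuitabilityToResistance:
    def test_endpoints_and_midpoint(self):
        assert suitability_to_resistance(4.5, 1.0, 4.5) == pytest.approx(1.0)
        assert suitability_to_resistance(1.0, 1.0, 4.5) == pytest.approx(100.0)
        assert suitability_to_resistance(2.75, 1.0, 4.5) == pytest.approx(50.5)

    def test_monotone_decreasing(self):
        s = np.linspace(1.0, 4.5, 50)
        r = suitability_to_resistance(s, 1.0, 4.5)
        assert (np.diff(r) < 0).all()

    def test_inverse_roundtrip_identity(self):
        s = np.linspace(1.0, 4.5, 101)
        back = resistance_to_suitability(suitability_to_resistance(s, 1.0, 4.5), 1.0, 4.5)
        np.testing.assert_allclose(back, s, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            suitability_to_resistance(0.5, 1.0, 4.5)
        with pytest.raises(ValueError):
            suitability_to_resistance(3.0, 4.0, 2.0)  # s_min >= s_max


class TestBuildResistance:
    def test_uniform_map_invariant_under_resampling(self):
        values = np.full((8, 8), 2, dtype=np.int64)
        grid = lc.LandCoverGrid(RasterGrid(values, 500.0), lc.default_class_table())
        panel = lc.generate_expert_ratings(
            lc.DEMO_TRUE_SUITABILITY, 6, 0.0, 0.0, 0.5, 0.0, seed=0
        )
        table = aggregate_ratings(panel)
        expected = suitability_to_resistance(
            table.mean_suitability(2), table.s_min, table.s_max
        )
        for target in (500.0, 1000.0, 2000.0):
            r = build_resistance(grid, table, target)
            assert np.allclose(r.raster.values, expected)

    def test_factor_one_is_exact_lookup(self, small_scenario, small_suitability):
        t0 = small_scenario.grids[0]
        r = build_resistance(t0, small_suitability)
        lookup = {
            code: suitability_to_resistance(
                small_suitability.mean_suitability(code),
                small_suitability.s_min,
                small_suitability.s_max,
            )
            for code in small_suitability.table.index
        }
        want = np.vectorize(lookup.get)(t0.raster.values)
        np.testing.assert_allclose(r.raster.values, want)

    def test_bilinear_block_average(self):
        # a 2x2 block {1,1,100,100} coarsened x2 samples the block centre: 50.5
        values = np.array([[2, 2], [7, 7]], dtype=np.int64)
        grid = lc.LandCoverGrid(RasterGrid(values, 1000.0), lc.default_class_table())
        panel = lc.generate_expert_ratings(
            lc.DEMO_TRUE_SUITABILITY, 6, 0.0, 0.0, 0.5, 0.0, seed=0
        )
        table = aggregate_ratings(panel)
        # classes 2 and 7 are the observed extremes: resistances 1 and 100
        r = build_resistance(grid, table, 2000.0)
        assert r.raster.shape == (1, 1)
        assert r.raster.values[0, 0] == pytest.approx(50.5)

    def test_bounds_hold_after_resampling(self, small_scenario, small_suitability):
        r = build_resistance(small_scenario.grids[0], small_suitability, 2000.0)
        assert r.raster.values.min() >= 1.0
        assert r.raster.values.max() <= 100.0

    def test_non_divisible_cell_size_rejected(self, small_scenario, small_suitability):
        with pytest.raises(ValueError, match="integer multiple"):
            build_resistance(small_scenario.grids[0], small_suitability, 1500.0)


class TestProjection:
    def grid(self, value, shape=(3, 3)):
        return ResistanceGrid(RasterGrid(np.full(shape, float(value)), 1000.0))

    def risk(self, value, shape=(3, 3)):
        return RasterGrid(np.full(shape, float(value)), 1000.0)

    def test_zero_risk_identity(self):
        r = self.grid(37.0)
        out = project_future_resistance(r, self.risk(0.0), R_TRANSITION)
        np.testing.assert_array_equal(out.raster.values, r.raster.values)

    def test_literal_arithmetic(self):
        out = project_future_resistance(self.grid(1.0), self.risk(0.5), R_TRANSITION)
        assert out.raster.values[0, 0] == pytest.approx(36.857, abs=1e-3)

    def test_literal_clips_at_hundred(self):
        out = project_future_resistance(self.grid(90.0), self.risk(1.0), R_TRANSITION)
        assert (out.raster.values == 100.0).all()

    def test_expectation_mode_interpolates(self):
        out = project_future_resistance(
            self.grid(10.0), self.risk(0.5), R_TRANSITION, mode="expectation"
        )
        assert out.raster.values[0, 0] == pytest.approx((10.0 + R_TRANSITION) / 2)

    def test_bad_risk_rejected(self):
        with pytest.raises(ValueError):
            project_future_resistance(self.grid(10.0), self.risk(1.5), R_TRANSITION)


class TestSourceSeeding:
    def test_uniform_resistance_selects_largest_u(self):
        r = ResistanceGrid(RasterGrid(np.ones((20, 20)), 1000.0))
        sp = seed_source_points(r, 25, seed=5)
        u = np.random.default_rng(5).random((20, 20))
        want = set(
            map(tuple, np.column_stack(np.unravel_index(np.argsort(-u, axis=None)[:25], u.shape)))
        )
        assert set(map(tuple, sp.points)) == want

    def test_seeding_reproducible(self, small_resistance):
        a = seed_source_points(small_resistance, 40, seed=9)
        b = seed_source_points(small_resistance, 40, seed=9)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.threshold == b.threshold

    def test_reapply_own_threshold_reproduces_set(self, small_resistance):
        sp = seed_source_points(small_resistance, 40, seed=9)
        again = reapply_threshold(small_resistance, sp.threshold, seed=9)
        assert set(map(tuple, again.points)) == set(map(tuple, sp.points))

    def test_higher_resistance_never_gains_points(self, small_resistance):
        sp = seed_source_points(small_resistance, 40, seed=9)
        worse = ResistanceGrid(
            small_resistance.raster.copy(
                np.minimum(small_resistance.raster.values * 1.5, 100.0)
            )
        )
        fewer = reapply_threshold(worse, sp.threshold, seed=9)
        assert len(fewer) <= len(sp)

    def test_three_epoch_counts_strictly_decrease(self, small_scenario, small_suitability):
        r0 = build_resistance(small_scenario.grids[0], small_suitability)
        r1 = build_resistance(small_scenario.grids[1], small_suitability)
        rt = suitability_to_resistance(
            small_suitability.mean_suitability(5),
            small_suitability.s_min,
            small_suitability.s_max,
        )
        r2 = project_future_resistance(r1, small_scenario.risk, rt)
        sp0 = seed_source_points(r0, 60, seed=4)
        n1 = len(reapply_threshold(r1, sp0.threshold, seed=4))
        n2 = len(reapply_threshold(r2, sp0.threshold, seed=4))
        assert len(sp0) > n1 > n2 > 0

    def test_overlarge_target_rejected(self, small_resistance):
        with pytest.raises(ValueError):
            seed_source_points(small_resistance, 10**6, seed=0)

    def test_roundtrip_csv(self, tmp_path, small_resistance):
        from kernelscape.resistance import SourcePointSet

        sp = seed_source_points(small_resistance, 15, seed=2)
        path = str(tmp_path / "pts.csv")
        sp.to_csv(path)
        back = SourcePointSet.from_csv(path)
        np.testing.assert_array_equal(back.points, sp.points)
        assert back.threshold == sp.threshold
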