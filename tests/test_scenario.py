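import numpy as np
import pandas as pd
import pytest

from rseisim import regression as rg
from rseisim import scenario as sc
from rseisim import synthetic
from rseisim.raster_core import Raster, SceneGrid

from conftest import make_raster


def feature_state(grid, ndvi=0.8, ndisi=0.3, pb=10.0, popd=5.0, bh=4.0):
    ones = np.ones(grid.shape, bool)
    return rg.FeatureState(
        Raster(grid, np.full(grid.shape, ndvi), ones.copy()),
        Raster(grid, np.full(grid.shape, ndisi), ones.copy()),
        Raster(grid, np.full(grid.shape, pb), ones.copy()),
        Raster(grid, np.full(grid.shape, popd), ones.copy()),
        Raster(grid, np.full(grid.shape, bh), ones.copy()),
    )


class LinearStubModel:
    """Deterministic stand-in regressor: monotone up in ndvi, down in ndisi."""

    def predict(self, X):
        return np.clip(0.3 + 0.5 * X[:, 0] - 0.3 * X[:, 1], 0.0, 1.0)


class ConstantStubModel:
    def predict(self, X):
        return np.full(X.shape[0], 0.55)


class TestExtractA1:
    def test_fixed_threshold_selects_high_cells(self):
        r = make_raster([[0.2, 0.9, 0.2, 0.9]])
        a1 = sc.extract_a1(r, 0.5)
        assert a1.values.tolist() == [[0.0, 1.0, 0.0, 1.0]]

    def test_zero_threshold_selects_all_valid(self):
        r = make_raster([[0.0, 0.4, 1.0]])
        a1 = sc.extract_a1(r, 0.0)
        assert a1.values.sum() == 3

    def test_threshold_at_boundary_inclusive(self):
        r = make_raster([[0.5, 0.49]])
        a1 = sc.extract_a1(r, 0.5)
        assert a1.values.tolist() == [[1.0, 0.0]]

    def test_otsu_on_bimodal_field(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0.2, 0.04, 800)
        high = rng.normal(0.8, 0.04, 800)
        vals = np.clip(np.concatenate([low, high]), 0, 1).reshape(40, 40)
        a1 = sc.extract_a1(make_raster(vals), "otsu")
        core = a1.values != 0
        # Otsu must land between the modes and select the high-mode cells
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(vals.ravel())
        assert 0.3 < thr < 0.7
        assert np.mean(core == (vals >= thr)) == 1.0
        assert np.mean(core == (vals >= 0.5)) > 0.99

    def test_empty_core_raises(self):
        with pytest.raises(ValueError, match="core"):
            sc.extract_a1(make_raster([[0.1, 0.2]]), 0.9)


class TestBufferRings:
    def test_ring_membership_by_distance(self):
        # single A1 cell at (0, 0) of a 1x30 strip at 30 m: cell k is at 30k m
        grid = SceneGrid(1, 30, 30.0)
        a1_vals = np.zeros(grid.shape)
        a1_vals[0, 0] = 1.0
        part = sc.buffer_rings(Raster(grid, a1_vals), (200.0, 400.0, 600.0))
        regions = part.regions()
        # 150 m -> A2; 450 m -> A4; 700 m -> outside
        assert regions[1][0, 5]   # 150 m
        assert regions[3][0, 15]  # 450 m
        assert not any(reg[0, 24] for reg in regions)  # 720 m

    def test_rings_pairwise_disjoint_and_exclude_core(self):
        rng = np.random.default_rng(1)
        grid = SceneGrid(25, 25, 30.0)
        a1 = Raster(grid, (rng.random(grid.shape) < 0.1).astype(float))
        part = sc.buffer_rings(a1, (60.0, 120.0, 200.0))
        regions = part.regions()
        stacked = np.sum([r.astype(int) for r in regions], axis=0)
        assert stacked.max() <= 1

    def test_matches_brute_force_distance_oracle(self):
        rng = np.random.default_rng(2)
        grid = SceneGrid(20, 20, 30.0)
        core = rng.random(grid.shape) < 0.08
        core[0, 0] = True
        part = sc.buffer_rings(Raster(grid, core.astype(float)), (100.0, 250.0, 400.0))
        # oracle: all-pairs centre-to-centre distances
        ys, xs = np.mgrid[0:20, 0:20]
        pts = np.column_stack([ys.ravel(), xs.ravel()]) * 30.0
        core_pts = pts[core.ravel()]
        dmin = np.sqrt(((pts[:, None, :] - core_pts[None, :, :]) ** 2).sum(-1)).min(1)
        dmin = dmin.reshape(grid.shape)
        bounds = (0.0, 100.0, 250.0, 400.0)
        for k, ring in enumerate(part.rings):
            expected = (dmin > bounds[k]) & (dmin <= bounds[k + 1]) & ~core
            np.testing.assert_array_equal(ring.values != 0, expected)

    def test_non_increasing_distances_rejected(self):
        a1 = make_raster([[1.0]])
        with pytest.raises(ValueError, match="increasing"):
            sc.buffer_rings(a1, (400.0, 200.0))


class TestPerturbOnce:
    def test_multiplicative_step(self):
        grid = SceneGrid(1, 2, 30.0)
        fs = feature_state(grid, ndvi=0.5, ndisi=0.4, pb=20.0, popd=10.0, bh=6.0)
        region = np.array([[True, False]])
        out = sc.perturb_once(fs, region, sc.ScenarioSpec())
        assert out.ndvi_nor.values[0, 0] == pytest.approx(0.475)
        assert out.ndisi_nor.values[0, 0] == pytest.approx(0.42)
        assert out.pb.values[0, 0] == pytest.approx(21.0)
        assert out.popd.values[0, 0] == pytest.approx(10.5)
        assert out.bh.values[0, 0] == pytest.approx(6.3)

    def test_clamp_at_upper_bounds(self):
        grid = SceneGrid(1, 1, 30.0)
        fs = feature_state(grid, ndisi=0.98, pb=99.0)
        out = sc.perturb_once(fs, np.array([[True]]), sc.ScenarioSpec())
        assert out.ndisi_nor.values[0, 0] == 1.0
        assert out.pb.values[0, 0] == 100.0

    def test_outside_region_unchanged(self):
        grid = SceneGrid(1, 2, 30.0)
        fs = feature_state(grid)
        out = sc.perturb_once(fs, np.array([[True, False]]), sc.ScenarioSpec())
        for name in rg.FEATURE_NAMES:
            assert getattr(out, name).values[0, 1] == getattr(fs, name).values[0, 1]

    def test_additive_mode_exercises_ndvi_floor_clamp(self):
        grid = SceneGrid(1, 1, 30.0)
        fs = feature_state(grid, ndvi=0.03)
        spec = sc.ScenarioSpec(mode="additive")
        out = sc.perturb_once(fs, np.array([[True]]), spec)
        assert out.ndvi_nor.values[0, 0] == 0.0  # 0.03 - 0.05 clamped up to 0

    def test_clamp_idempotent_under_repeated_steps(self):
        grid = SceneGrid(1, 1, 30.0)
        fs = feature_state(grid, ndisi=0.99)
        spec = sc.ScenarioSpec()
        region = np.array([[True]])
        once = sc.perturb_once(fs, region, spec)
        twice = sc.perturb_once(once, region, spec)
        assert once.ndisi_nor.values[0, 0] == 1.0
        assert twice.ndisi_nor.values[0, 0] == 1.0


class TestZeroSubstitute:
    def test_both_zero_cells_get_ring_minima(self):
        grid = SceneGrid(1, 4, 30.0)
        ones = np.ones(grid.shape, bool)
        fs = rg.FeatureState(
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.zeros(grid.shape), ones.copy()),
            Raster(grid, np.array([[0.0, 0.0, 3.0, 5.0]]), ones.copy()),
            Raster(grid, np.array([[0.0, 0.0, 4.0, 6.0]]), ones.copy()),
        )
        out = sc.zero_substitute(fs, np.ones(grid.shape, bool))
        assert out.popd.values[0, 0] == 3.0 and out.bh.values[0, 0] == 4.0
        assert out.popd.values[0, 1] == 3.0 and out.bh.values[0, 1] == 4.0
        assert out.popd.values[0, 2] == 3.0  # untouched nonzero

    def test_single_zero_untouched(self):
        grid = SceneGrid(1, 2, 30.0)
        ones = np.ones(grid.shape, bool)
        fs = rg.FeatureState(
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.zeros(grid.shape), ones.copy()),
            Raster(grid, np.array([[0.0, 3.0]]), ones.copy()),
            Raster(grid, np.array([[2.0, 4.0]]), ones.copy()),
        )
        out = sc.zero_substitute(fs, np.ones(grid.shape, bool))
        assert out.popd.values[0, 0] == 0.0  # bh is 2, not both zero

    def test_ring_without_zeros_is_identity(self):
        grid = SceneGrid(1, 3, 30.0)
        fs = feature_state(grid, popd=2.0, bh=3.0)
        out = sc.zero_substitute(fs, np.ones(grid.shape, bool))
        np.testing.assert_array_equal(out.popd.values, fs.popd.values)

    def test_scene_fallback_when_ring_all_zero(self):
        grid = SceneGrid(1, 4, 30.0)
        ones = np.ones(grid.shape, bool)
        fs = rg.FeatureState(
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.full(grid.shape, 0.5), ones.copy()),
            Raster(grid, np.zeros(grid.shape), ones.copy()),
            Raster(grid, np.array([[0.0, 0.0, 7.0, 9.0]]), ones.copy()),
            Raster(grid, np.array([[0.0, 0.0, 5.0, 8.0]]), ones.copy()),
        )
        ring = np.array([[True, True, False, False]])  # no nonzero inside ring
        out = sc.zero_substitute(fs, ring)
        assert out.popd.values[0, 0] == 7.0
        assert out.bh.values[0, 0] == 5.0

    def test_no_nonzero_anywhere_raises(self):
        grid = SceneGrid(1, 2, 30.0)
        fs = feature_state(grid, popd=0.0, bh=0.0)
        with pytest.raises(ValueError, match="nonzero"):
            sc.zero_substitute(fs, np.ones(grid.shape, bool))


@pytest.fixture(scope="module")
def scenario_run():
    """Full S0..S4 run on a constant-feature scene with a stub model."""
    grid = SceneGrid(40, 40, 30.0)
    fs = feature_state(grid, ndvi=0.8, ndisi=0.3, pb=10.0, popd=5.0, bh=4.0)
    a1_vals = np.zeros(grid.shape)
    a1_vals[18:22, 18:22] = 1.0
    part = sc.buffer_rings(Raster(grid, a1_vals), (200.0, 400.0, 600.0))
    results = sc.run_scenarios(fs, part, LinearStubModel(), sc.ScenarioSpec())
    return grid, fs, part, results


class TestRunScenarios:
    def test_a1_cell_accumulates_four_steps(self, scenario_run):
        _, fs, part, results = scenario_run
        a1 = part.regions()[0]
        final = results[4].features
        np.testing.assert_allclose(
            final.ndvi_nor.values[a1], 0.8 * 0.95**4, rtol=1e-12)
        np.testing.assert_allclose(
            final.ndisi_nor.values[a1], 0.3 * 1.05**4, rtol=1e-12)

    def test_outermost_ring_gets_exactly_one_step(self, scenario_run):
        _, fs, part, results = scenario_run
        a4 = part.regions()[3]
        final = results[4].features
        np.testing.assert_allclose(final.ndvi_nor.values[a4], 0.8 * 0.95, rtol=1e-12)

    def test_cumulative_bookkeeping_per_region(self, scenario_run):
        # after S_k, region A_j has received k - j + 1 steps
        _, fs, part, results = scenario_run
        regions = part.regions()
        for k in range(1, 5):
            state = results[k].features
            for j, region in enumerate(regions, start=1):
                steps = max(0, k - j + 1)
                np.testing.assert_allclose(
                    state.ndvi_nor.values[region], 0.8 * 0.95**steps, rtol=1e-12)

    def test_outside_regions_scenario_invariant(self, scenario_run):
        _, fs, part, results = scenario_run
        outside = ~np.logical_or.reduce(part.regions())
        base = results[0].predicted_rsei.values[outside]
        for res in results[1:]:
            np.testing.assert_array_equal(res.predicted_rsei.values[outside], base)

    def test_s0_equals_baseline(self, scenario_run):
        _, fs, _, results = scenario_run
        np.testing.assert_array_equal(results[0].features.ndvi_nor.values,
                                      fs.ndvi_nor.values)

    def test_monotone_model_gives_strictly_decreasing_means(self, scenario_run):
        _, _, _, results = scenario_run
        means = [r.mean_rsei for r in results]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestScenarioMeans:
    def test_constant_model_equal_means(self):
        grid = SceneGrid(20, 20, 30.0)
        fs = feature_state(grid)
        a1_vals = np.zeros(grid.shape)
        a1_vals[9:11, 9:11] = 1.0
        part = sc.buffer_rings(Raster(grid, a1_vals), (60.0, 120.0, 180.0))
        results = sc.run_scenarios(fs, part, ConstantStubModel(),
                                   sc.ScenarioSpec(distances=(60.0, 120.0, 180.0)))
        means = sc.scenario_means(results)
        assert means.mean_rsei.nunique() == 1
        assert means.scenario.tolist() == ["S0", "S1", "S2", "S3", "S4"]

    def test_means_in_unit_interval(self, scenario_run):
        _, _, _, results = scenario_run
        means = sc.scenario_means(results)
        assert means.mean_rsei.between(0, 1).all()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no scenario"):
            sc.scenario_means([])
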