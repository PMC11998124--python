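"""Synthetic landscape generator: determinism, structure, and couplings."""

import numpy as np
import pytest

from wetpot import (GridError, SceneConfig, compute_wetness, gen_cropland,
                    gen_dem, gen_labels, gen_sar_stack, gen_soils,
                    generate_scene, pws_by_unit, sar_percentiles)
from wetpot.terrain import NEIGHBOR_OFFSETS


CFG = SceneConfig(n_rows=90, n_cols=90, seed=7)


def count_single_cell_pits(values):
    n = 0
    for r in range(1, values.shape[0] - 1):
        for c in range(1, values.shape[1] - 1):
            if all(values[r, c] < values[r + dr, c + dc]
                   for dr, dc in NEIGHBOR_OFFSETS):
                n += 1
    return n


class TestDem:
    def test_seed_determinism(self):
        np.testing.assert_array_equal(gen_dem(CFG).values, gen_dem(CFG).values)

    def test_carved_pit_count(self):
        cfg = SceneConfig(n_rows=60, n_cols=60, seed=3, n_pits=5)
        dem = gen_dem(cfg)
        assert count_single_cell_pits(dem.values) >= 5

    def test_zero_relief_leaves_pure_tilt(self):
        cfg = SceneConfig(n_rows=30, n_cols=30, seed=1, relief=0.0, n_pits=0)
        dem = gen_dem(cfg)
        col = dem.values[:, 10]
        # constant southward gradient everywhere
        np.testing.assert_allclose(np.diff(col), np.diff(col)[0], atol=1e-12)
        np.testing.assert_allclose(np.diff(dem.values, axis=1), 0.0, atol=1e-12)


@pytest.fixture(scope="module")
def soils():
    dem = gen_dem(CFG)
    wet = compute_wetness(dem, CFG)
    mu, table = gen_soils(CFG, wet)
    return mu, table, wet


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SceneConfig(n_rows=90, n_cols=90, seed=9))


class TestSoils:
    def test_percents_sum_to_100(self, soils):
        _, table, _ = soils
        sums = table.df.groupby("map_unit")["component_percent"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-9)

    def test_wet_units_have_higher_eligible_percent(self):
        cfg = SceneConfig(n_rows=120, n_cols=120, seed=5, n_map_units=60,
                          pwsl_only_fraction=0.0)
        dem = gen_dem(cfg)
        wet = compute_wetness(dem, cfg)
        mu, table = gen_soils(cfg, wet)
        pws = pws_by_unit(table)
        w = wet.values
        unit_wetness = {u: w[mu.values == u].mean() for u in pws.index}
        order = sorted(pws.index, key=unit_wetness.get)
        k = max(len(order) // 10, 1)
        driest = np.mean([pws[u] for u in order[:k]])
        wettest = np.mean([pws[u] for u in order[-k:]])
        assert wettest > driest

    def test_pwsl_only_units_exercise_fallback(self, soils):
        _, table, _ = soils
        df = table.df
        pwsl_units = df.groupby("map_unit").apply(
            lambda g: (g["drainage_class"] == "unknown").all()
            and (g["hydric"] == "unknown").all(), include_groups=False)
        assert pwsl_units.sum() == round(0.15 * CFG.n_map_units)

    def test_seed_determinism(self, soils):
        mu, table, wet = soils
        mu2, table2 = gen_soils(CFG, wet)
        np.testing.assert_array_equal(mu.values, mu2.values)
        assert table.df.equals(table2.df)


class TestSar:
    def test_noise_free_limit_collapses_percentiles(self):
        cfg = SceneConfig(n_rows=30, n_cols=30, seed=2, speckle_looks=1e9,
                          temporal_sd=0.0)
        wet = compute_wetness(gen_dem(cfg), cfg)
        stack = gen_sar_stack(cfg, wet)
        # gamma speckle at 1e9 looks has sd ~3e-5 in power: dates agree to
        # well under a millidecibel
        vv0 = stack[0][1].values
        for _, vv, _ in stack[1:]:
            np.testing.assert_allclose(vv.values, vv0, atol=1e-3)
        pct = sar_percentiles([(vv, vh) for _, vv, vh in stack])
        np.testing.assert_allclose(pct["VV10"].values, pct["VV90"].values,
                                   atol=1e-3)

    def test_wet_cells_are_darker(self):
        cfg = SceneConfig(n_rows=60, n_cols=60, seed=4)
        wet = compute_wetness(gen_dem(cfg), cfg)
        stack = gen_sar_stack(cfg, wet)
        mean_vv = np.mean([vv.values for _, vv, _ in stack], axis=0)
        w = wet.values.ravel()
        thresh_lo, thresh_hi = np.quantile(w, [0.1, 0.9])
        assert mean_vv.ravel()[w >= thresh_hi].mean() < \
            mean_vv.ravel()[w <= thresh_lo].mean()

    def test_vh_below_vv(self):
        wet = compute_wetness(gen_dem(CFG), CFG)
        stack = gen_sar_stack(CFG, wet)
        for _, vv, vh in stack:
            assert vh.values.mean() < vv.values.mean()

    def test_seed_determinism(self):
        wet = compute_wetness(gen_dem(CFG), CFG)
        a = gen_sar_stack(CFG, wet)
        b = gen_sar_stack(CFG, wet)
        for (_, vva, vha), (_, vvb, vhb) in zip(a, b):
            np.testing.assert_array_equal(vva.values, vvb.values)
            np.testing.assert_array_equal(vha.values, vhb.values)


class TestLabels:
    def test_noiseless_prevalence_is_exact(self, scene):
        cfg = SceneConfig(n_rows=90, n_cols=90, seed=9, noise_sd=0.0,
                          target_prevalence=0.25)
        t = scene.terrain_layers
        from wetpot import compute_pws

        pws = compute_pws(scene.soil_map_unit_raster, scene.soil_table)
        labels, _ = gen_labels(cfg, t["cti"], pws, t["vofd"])
        frac = (labels.values == 1).mean()
        n = labels.values.size
        assert abs(frac - 0.25) <= 1.0 / n + 1e-12

    def test_noiseless_labels_are_threshold_on_score(self, scene):
        cfg = SceneConfig(n_rows=90, n_cols=90, seed=9, noise_sd=0.0)
        t = scene.terrain_layers
        from wetpot import compute_pws

        pws = compute_pws(scene.soil_map_unit_raster, scene.soil_table)
        labels, truth = gen_labels(cfg, t["cti"], pws, t["vofd"])
        s = truth.suitability.values
        assert s[labels.values == 1].min() > s[labels.values == 0].max()

    def test_labels_deterministic(self, scene):
        cfg = scene.config
        t = scene.terrain_layers
        from wetpot import compute_pws

        pws = compute_pws(scene.soil_map_unit_raster, scene.soil_table)
        l1, _ = gen_labels(cfg, t["cti"], pws, t["vofd"])
        np.testing.assert_array_equal(l1.values, scene.labels.values)

    def test_prevalence_within_one_point_of_target(self, scene):
        frac = (scene.labels.values == 1).mean()
        assert abs(frac - scene.config.target_prevalence) < 0.01


class TestCropland:
    def test_zero_fraction_all_zeros(self):
        cfg = SceneConfig(n_rows=30, n_cols=30, seed=1, cropland_fraction=0.0)
        assert (gen_cropland(cfg).values == 0).all()

    def test_realized_fraction_close_to_target(self):
        cfg = SceneConfig(n_rows=150, n_cols=150, seed=2, cropland_fraction=0.3)
        frac = (gen_cropland(cfg).values == 1).mean()
        assert 0.28 <= frac <= 0.32

    def test_coarse_grid_geometry(self):
        g = gen_cropland(SceneConfig(n_rows=30, n_cols=30, seed=1))
        assert g.shape == (10, 10)
        assert g.cell_size == 30.0

    def test_indivisible_dimensions_rejected(self):
        with pytest.raises(GridError, match="divisible"):
            gen_cropland(SceneConfig(n_rows=31, n_cols=30, seed=1))

    def test_seed_determinism(self):
        cfg = SceneConfig(n_rows=60, n_cols=60, seed=5)
        np.testing.assert_array_equal(gen_cropland(cfg).values,
                                      gen_cropland(cfg).values)


class TestFullScene:
    def test_bundle_is_pure_function_of_config(self):
        cfg = SceneConfig(n_rows=48, n_cols=48, seed=13)
        a, b = generate_scene(cfg), generate_scene(cfg)
        np.testing.assert_array_equal(a.dem.values, b.dem.values)
        np.testing.assert_array_equal(a.labels.values, b.labels.values)
        assert a.soil_table.df.equals(b.soil_table.df)
        np.testing.assert_array_equal(a.cropland_30m.values,
                                      b.cropland_30m.values)
        assert a.truth.threshold == b.truth.threshold

    def test_all_grids_aligned_and_nodata_free(self, small_scene):
        b = small_scene
        for g in (b.soil_map_unit_raster, b.labels):
            assert g.aligned_with(b.dem)
        assert b.dem.valid_mask().all()
        assert b.labels.valid_mask().all()
        for _, vv, vh in b.sar_stack:
            assert vv.valid_mask().all() and vh.valid_mask().all()
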