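"""Scene-generator tests: leaf optics, stress trajectories, rendering,
determinism, and the segmentation recovery the scenes must support."""

import numpy as np
import pytest

from conftest import CLEAN_LAYOUT, TINY_LAYOUT
from phytoproxy import indices, segmentation
from phytoproxy import synthetic as syn


class TestLeafReflectance:
    wl = syn.default_wavelengths()

    def test_bounds(self):
        for chl in (0.0, 0.3, 1.0):
            spec = syn.leaf_reflectance(syn.PigmentState(chl, 0.5, 1.0), self.wl)
            assert spec.min() > 0 and spec.max() <= 1

    def test_chlorophyll_loss_raises_red_reflectance(self):
        healthy = syn.leaf_reflectance(syn.PigmentState(1, 1, 1), self.wl)
        degraded = syn.leaf_reflectance(syn.PigmentState(0.3, 1, 1), self.wl)
        i680 = indices.nearest_band(self.wl, 680)
        assert degraded[i680] > healthy[i680]

    def test_blue_reflectance_decreases_in_total_pigment(self):
        i470 = indices.nearest_band(self.wl, 470)
        base = syn.leaf_reflectance(syn.PigmentState(0.5, 0.5, 1.0), self.wl)[i470]
        more_chl = syn.leaf_reflectance(syn.PigmentState(0.8, 0.5, 1.0), self.wl)[i470]
        more_car = syn.leaf_reflectance(syn.PigmentState(0.5, 0.8, 1.0), self.wl)[i470]
        assert more_chl < base and more_car < base

    def test_nir_plateau(self):
        spec = syn.leaf_reflectance(syn.CONTROL_STATE, self.wl)
        nir = spec[self.wl >= 750]
        assert np.all(np.abs(nir - 0.5) < 0.06)

    @pytest.mark.parametrize("species", ["pea", "wheat"])
    def test_healthy_ndvi_plausible(self, species):
        optics = syn.SPECIES_OPTICS[species]
        spec = syn.leaf_reflectance(syn.CONTROL_STATE, self.wl, optics)
        r780 = spec[indices.nearest_band(self.wl, 780)]
        r680 = spec[indices.nearest_band(self.wl, 680)]
        ndvi = (r780 - r680) / (r780 + r680)
        assert ndvi > 0.5
        if species == "pea":  # default optics target the mid healthy range
            assert 0.6 <= ndvi <= 0.9

    def test_out_of_range_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="wavelengths"):
            syn.leaf_reflectance(syn.CONTROL_STATE, np.array([350.0, 500.0]))

    def test_pigment_state_validation(self):
        with pytest.raises(ValueError):
            syn.PigmentState(1.2, 0.5, 0.5)


class TestStressTrajectory:
    def test_control_is_pristine(self):
        for day in syn.DEFAULT_DAYS:
            state = syn.stress_trajectory(syn.StressScenario("pea", "control"), day)
            assert state == syn.CONTROL_STATE

    def test_pea_drought_day12_fvfm_near_02(self):
        state = syn.stress_trajectory(syn.StressScenario("pea", "drought"), 12)
        assert syn.FVFM_CEILING * state.vitality == pytest.approx(0.2, abs=0.02)

    def test_wheat_drought_day12_fvfm_near_01(self):
        state = syn.stress_trajectory(syn.StressScenario("wheat", "drought"), 12)
        assert syn.FVFM_CEILING * state.vitality == pytest.approx(0.1, abs=0.02)

    def test_severity_ordering_of_nacl_levels(self):
        days = syn.DEFAULT_DAYS
        for day in days:
            states = {
                t: syn.stress_trajectory(syn.StressScenario("pea", t, days), day)
                for t in ("nacl100", "nacl200", "nacl400")
            }
            assert states["nacl400"].vitality <= states["nacl200"].vitality
            assert states["nacl200"].vitality <= states["nacl100"].vitality
            assert states["nacl400"].chl <= states["nacl100"].chl

    def test_monotone_decay_in_day(self):
        scen = syn.StressScenario("wheat", "drought")
        states = [syn.stress_trajectory(scen, d) for d in scen.days]
        for a, b in zip(states, states[1:]):
            assert b.chl <= a.chl and b.vitality <= a.vitality

    def test_chl_decays_faster_than_car_under_drought_only(self):
        drought = syn.stress_trajectory(syn.StressScenario("pea", "drought"), 12)
        salt = syn.stress_trajectory(syn.StressScenario("pea", "nacl400"), 12)
        assert drought.chl < drought.car
        assert salt.chl == pytest.approx(salt.car)

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            syn.StressScenario("pea", "frost")

    def test_day_outside_scenario_rejected(self):
        with pytest.raises(ValueError, match="day"):
            syn.stress_trajectory(syn.StressScenario("pea", "drought", (1, 3)), 5)


class TestRenderRGB:
    wl = syn.default_wavelengths()

    @pytest.mark.parametrize(
        "level, expected", [(1.0, 255), (0.0, 0), (0.5, 128)]  # 127.5 rounds half-up
    )
    def test_flat_spectra(self, level, expected):
        rgb = syn.render_rgb(np.full(self.wl.size, level), self.wl)
        assert rgb.tolist() == [expected] * 3

    def test_coverage_gap_rejected(self):
        wl = np.linspace(550, 1000, 100)
        with pytest.raises(ValueError, match="cover"):
            syn.render_rgb(np.full(100, 0.5), wl)


class TestRenderScene:
    def test_deterministic_bit_identical(self):
        scen = syn.StressScenario("pea", "nacl200")
        a = syn.render_scene(scen, 5, TINY_LAYOUT, seed=3)
        b = syn.render_scene(scen, 5, TINY_LAYOUT, seed=3)
        np.testing.assert_array_equal(a.rgb, b.rgb)
        np.testing.assert_array_equal(a.cube, b.cube)
        np.testing.assert_array_equal(a.f0_map, b.f0_map)

    def test_plant_fraction_in_design_range(self, pea_control_bundle):
        frac = pea_control_bundle.truth_mask.mean()
        assert 0.10 <= frac <= 0.60

    def test_control_fvfm_near_08(self, pea_control_bundle):
        fvfm = indices.fv_fm(pea_control_bundle.f0_map, pea_control_bundle.fm_map)
        assert np.nanmean(fvfm[pea_control_bundle.truth_mask]) == pytest.approx(0.8, abs=0.01)

    def test_white_patch_saturates_rgb(self, pea_control_bundle):
        patch = pea_control_bundle.rgb[pea_control_bundle.white_patch.slices]
        assert np.all(patch == 255)

    def test_fluorescence_consistency_exact_on_noiseless_render(self):
        scen = syn.StressScenario("pea", "drought")
        bundle = syn.render_scene(scen, 10, CLEAN_LAYOUT, seed=0)
        state = syn.stress_trajectory(scen, 10)
        fvfm = indices.fv_fm(bundle.f0_map, bundle.fm_map)
        expected = syn.FVFM_CEILING * state.vitality
        np.testing.assert_allclose(fvfm[bundle.truth_mask], expected, atol=1e-12)

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.SceneLayout(height=0, width=10)

    @pytest.mark.parametrize("species", ["pea", "wheat"])
    def test_rgb_and_ndvi_masks_recover_most_plant_pixels(self, species):
        """On healthy scenes both mask families find >= 90 % of true plant
        pixels (and the soil/white background stays out)."""
        bundle = syn.render_scene(
            syn.StressScenario(species, "control"), 1, TINY_LAYOUT, seed=11
        )
        truth = bundle.truth_mask
        rgb_m = segmentation.rgb_plant_mask(bundle.rgb, species).mask
        ndvi_map = indices.ndvi(bundle.cube, bundle.wavelengths)
        ndvi_m = segmentation.ndvi_plant_mask(ndvi_map, species).mask
        for mask in (rgb_m, ndvi_m):
            recall = mask[truth].mean()
            assert recall >= 0.90
            false_pos = mask[~truth].mean()
            assert false_pos <= 0.05


class TestGenerateExperiment:
    def test_default_design_counts(self):
        config = syn.ExperimentConfig(layout=TINY_LAYOUT)
        bundles, manifest = syn.generate_experiment(config, seed=0)
        assert len(bundles) == 2 * 5 * 6 == 60
        assert len(manifest) == len(bundles)

    def test_seed_changes_pixels_not_manifest(self):
        config = syn.ExperimentConfig(
            species=("pea",), treatments=("control", "drought"), days=(1, 12),
            layout=TINY_LAYOUT,
        )
        b1, m1 = syn.generate_experiment(config, seed=1)
        b2, m2 = syn.generate_experiment(config, seed=2)
        assert m1.equals(m2)
        assert any(not np.array_equal(a.cube, b.cube) for a, b in zip(b1, b2))

    def test_draws_do_not_depend_on_arm_order(self):
        layout = TINY_LAYOUT
        cfg_a = syn.ExperimentConfig(("pea",), ("control", "drought"), (1,), layout)
        cfg_b = syn.ExperimentConfig(("pea",), ("drought", "control"), (1,), layout)
        a, _ = syn.generate_experiment(cfg_a, seed=5)
        b, _ = syn.generate_experiment(cfg_b, seed=5)
        by_arm_a = {x.treatment: x for x in a}
        by_arm_b = {x.treatment: x for x in b}
        for arm in ("control", "drought"):
            np.testing.assert_array_equal(by_arm_a[arm].cube, by_arm_b[arm].cube)

    def test_empty_treatments_rejected(self):
        with pytest.raises(ValueError):
            syn.ExperimentConfig(treatments=())


class TestSceneDirectionality:
    """Per-scene means of the RGB indices move the way stressed canopies do."""

    @pytest.mark.parametrize("treatment", ["drought", "nacl400"])
    def test_monotone_stress_direction(self, treatment):
        scen = syn.StressScenario("pea", treatment)
        series = {k: [] for k in ("r", "g", "ExG", "VEG", "VARI")}
        for day in scen.days:
            bundle = syn.render_scene(scen, day, TINY_LAYOUT, seed=2)
            white = np.asarray(
                [bundle.rgb[bundle.white_patch.slices][..., i].mean() for i in range(3)]
            )
            rn, gn, bn = (bundle.rgb[..., i] / white[i] for i in range(3))
            maps = indices.rgb_indices(rn, gn, bn)
            for k in series:
                series[k].append(np.nanmean(maps[k][bundle.truth_mask]))
        tol = 1e-3
        for k in ("g", "ExG", "VEG", "VARI"):
            assert all(b <= a + tol for a, b in zip(series[k], series[k][1:])), k
        assert all(b >= a - tol for a, b in zip(series["r"], series["r"][1:]))
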