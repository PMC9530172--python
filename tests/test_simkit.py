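"""Tests for the synthetic scene generator: kinetics, rendering, experiments."""

import numpy as np
import pytest

import starchshg as s


class TestDielKinetics:
    def test_dawn_boundary_returns_baseline(self):
        m = s.DielModel.col0(dawn_baseline=0.7)
        assert s.starch_mass_at(m, 0.0) == pytest.approx(0.7)

    def test_constant_model_stays_at_baseline(self):
        m = s.DielModel(synth_rate=0.0, degrade_rate=0.0, dawn_baseline=1.3)
        assert s.starch_mass_at(m, 12.0) == pytest.approx(1.3)

    def test_hand_evaluated_piecewise_value(self):
        # baseline 1 + 2/h * 16 h light - 4/h * 4 h dark = 17
        m = s.DielModel.col0(dawn_baseline=1.0, synth_rate=2.0, degrade_rate=4.0)
        assert s.starch_mass_at(m, 20.0) == pytest.approx(17.0)

    def test_decay_clamps_at_baseline(self):
        m = s.DielModel.col0(dawn_baseline=1.0, synth_rate=1.0, degrade_rate=100.0)
        assert s.starch_mass_at(m, 23.0) == pytest.approx(1.0)

    def test_sex1_holds_peak_through_the_night(self):
        m = s.DielModel.sex1()
        peak = s.starch_mass_at(m, m.light_hours)
        assert s.starch_mass_at(m, 24.0) == pytest.approx(peak)

    def test_out_of_domain_zt_rejected(self):
        m = s.DielModel.col0()
        for zt in (-0.1, 24.1):
            with pytest.raises(ValueError):
                s.starch_mass_at(m, zt)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            s.DielModel(light_hours=12.0, dark_hours=8.0)
        with pytest.raises(ValueError):
            s.DielModel(genotype="sex1", degrade_rate=1.0)
        with pytest.raises(ValueError):
            s.DielModel(synth_rate=-1.0)


class TestRenderScene:
    def test_fixed_seed_is_bit_identical(self, tiny_scene, optics):
        pairs = []
        for _ in range(2):
            truth = s.make_ground_truth(tiny_scene, 4.0, 8.0, np.random.default_rng(9))
            pairs.append(s.render_scene(tiny_scene, optics, truth, np.random.default_rng(9)))
        (t1, g1), (t2, g2) = pairs
        assert np.array_equal(t1.pixels, t2.pixels)
        assert np.array_equal(g1.pixels, g2.pixels)

    def test_zero_starch_means_zero_shg_expectation(self, tiny_scene, optics_clean):
        truth = s.make_ground_truth(tiny_scene, 0.0, 0.0, np.random.default_rng(1))
        _, shg_mean = s.expected_scene(tiny_scene, optics_clean, truth)
        assert not shg_mean.any()
        _, shg = s.render_scene(tiny_scene, optics_clean, truth, np.random.default_rng(2))
        assert not shg.pixels.any()

    def test_tpf_expectation_confined_to_thylakoid(self, tiny_scene, optics):
        truth = s.make_ground_truth(tiny_scene, 4.0, 8.0, np.random.default_rng(2))
        tpf_mean, _ = s.expected_scene(tiny_scene, optics, truth)
        assert np.array_equal(tpf_mean > 0, truth.thylakoid_mask)

    def test_shg_expectation_confined_to_chloroplasts(self, tiny_scene, optics):
        """Even with leakage on, every SHG-expected-positive pixel lies
        inside a chloroplast."""
        for seed in range(5):
            truth = s.make_ground_truth(tiny_scene, 6.0, 8.0, np.random.default_rng(seed))
            _, shg_mean = s.expected_scene(tiny_scene, optics, truth)
            assert not np.any((shg_mean > 0) & ~truth.chloroplast_mask)
            assert truth.granule_mask.sum() > 0
            assert not np.any(truth.granule_mask & ~truth.chloroplast_mask)

    def test_poisson_law_per_pixel(self, optics):
        """Sample mean over 1000 renders stays within 4 SE of the expected
        count on every pixel with signal."""
        cfg = s.SceneConfig(image_shape=(48, 48), n_chloroplasts=2,
                            chloroplast_axes_px=(6.0, 8.0), rng_seed=0)
        truth = s.make_ground_truth(cfg, 4.0, 8.0, np.random.default_rng(3))
        tpf_mean, shg_mean = s.expected_scene(cfg, optics, truth)
        n = 1000
        rng = np.random.default_rng(4)
        acc = np.zeros_like(shg_mean)
        for _ in range(n):
            _, shg = s.render_scene(cfg, optics, truth, rng)
            acc += shg.pixels
        sample_mean = acc / n
        se = np.sqrt(np.maximum(shg_mean, 1e-12) / n)
        sel = shg_mean > 0
        assert np.all(np.abs(sample_mean[sel] - shg_mean[sel]) <= 4 * se[sel])

    def test_granule_outside_chloroplast_rejected(self, tiny_scene):
        truth = s.make_ground_truth(tiny_scene, 4.0, 8.0, np.random.default_rng(5))
        with pytest.raises(s.simkit.InvariantError):
            s.GroundTruth(
                starch_mass=truth.starch_mass, zt_hour=truth.zt_hour,
                granule_centers=np.array([[0.0, 0.0]]),  # corner: no chloroplast
                granule_radii=np.array([2.0]),
                chloroplast_mask=truth.chloroplast_mask,
                thylakoid_mask=truth.thylakoid_mask,
                granule_mask=truth.granule_mask,
            )


class TestRenderCube:
    def test_additivity_of_components(self, tiny_scene, optics, wavelengths):
        truth = s.make_ground_truth(tiny_scene, 5.0, 8.0, np.random.default_rng(6))
        cube, comps = s.render_cube(
            tiny_scene, optics, truth, wavelengths, 2.0, return_components=True
        )
        np.testing.assert_allclose(
            cube.data, comps["chlorophyll"] + comps["leak590"] + comps["shg_line"],
            rtol=1e-12,
        )

    def test_intensity_scales_with_integration_time(
        self, tiny_scene, optics, wavelengths
    ):
        truth = s.make_ground_truth(tiny_scene, 5.0, 8.0, np.random.default_rng(7))
        c5 = s.render_cube(tiny_scene, optics, truth, wavelengths, 5.0)
        c03 = s.render_cube(tiny_scene, optics, truth, wavelengths, 0.3)
        np.testing.assert_allclose(c5.data, (5.0 / 0.3) * c03.data, rtol=1e-12)

    def test_granule_pixel_argmax_at_532(self, tiny_scene, optics_clean, wavelengths):
        truth = s.make_ground_truth(tiny_scene, 5.0, 8.0, np.random.default_rng(8))
        cube = s.render_cube(tiny_scene, optics_clean, truth, wavelengths, 1.0)
        r, c = np.argwhere(truth.granule_mask & ~truth.thylakoid_mask)[0]
        assert wavelengths[np.argmax(cube.data[r, c])] == pytest.approx(532.0)

    def test_coarse_grid_warns(self, tiny_scene, optics):
        truth = s.make_ground_truth(tiny_scene, 5.0, 8.0, np.random.default_rng(9))
        with pytest.warns(UserWarning, match="coarse"):
            s.render_cube(tiny_scene, optics, truth, np.arange(515.0, 706.0, 2.0), 1.0)

    def test_insufficient_span_rejected(self, tiny_scene, optics):
        truth = s.make_ground_truth(tiny_scene, 5.0, 8.0, np.random.default_rng(10))
        with pytest.raises(ValueError):
            s.render_cube(tiny_scene, optics, truth, np.arange(540.0, 701.0, 1.0), 1.0)


class TestSimulateExperiment:
    def test_manifest_covers_grid_and_areas(self, tiny_scene, optics):
        exp = s.simulate_experiment(
            s.DielModel.col0(), tiny_scene, optics, np.arange(0, 25, 3),
            n_areas=2, n_leaves=2, seed=0,
        )
        assert exp.manifest["zt_hour"].nunique() == 9
        assert len(exp.manifest) == 18
        assert exp.manifest["image_id"].is_unique
        assert set(exp.manifest["leaf_id"]) == {1, 2}

    def test_sex1_truth_constant_across_dark_phase_without_dispersion(
        self, tiny_scene, optics
    ):
        exp = s.simulate_experiment(
            s.DielModel.sex1(), tiny_scene, optics, [16.0, 24.0],
            n_areas=1, seed=1, dispersion_sigma=0.0,
        )
        masses = exp.truth_table.set_index("zt_hour")["true_starch_mass"]
        assert masses[16.0] == pytest.approx(masses[24.0])

    def test_col0_truth_peaks_at_lights_off(self, tiny_scene, optics):
        exp = s.simulate_experiment(
            s.DielModel.col0(), tiny_scene, optics, [0, 8, 16, 20, 24],
            n_areas=1, seed=2, dispersion_sigma=0.0,
        )
        tt = exp.truth_table.set_index("zt_hour")["true_starch_mass"]
        assert tt.idxmax() == 16.0

    def test_empty_experiment_rejected(self, tiny_scene, optics):
        with pytest.raises(ValueError, match="empty"):
            s.simulate_experiment(
                s.DielModel.col0(), tiny_scene, optics, [], n_areas=3, seed=0
            )
        with pytest.raises(ValueError, match="empty"):
            s.simulate_experiment(
                s.DielModel.col0(), tiny_scene, optics, [0.0], n_areas=0, seed=0
            )

    def test_granule_area_tracks_requested_mass(self, tiny_scene):
        # masses kept below the stroma-site capacity of the tiny scene
        masses = [1.0, 2.0, 4.0]
        areas = [
            s.make_ground_truth(tiny_scene, m, 0.0, np.random.default_rng(11)).granule_area_px
            for m in masses
        ]
        assert areas == sorted(areas)
        for m, a in zip(masses, areas):
            assert a >= m * tiny_scene.starch_area_px_per_unit  # reaches target
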