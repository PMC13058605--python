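"""Generators: seeded determinism, distributional fidelity, geometric oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from sonogold.kinetics import first_order_model
from sonogold.morphometry import measure_cell
from sonogold.synthetic import (
    CellMaskSpec,
    KineticScenario,
    SceneSpec,
    StudyConfig,
    gen_cell_mask,
    gen_group_study,
    gen_particle_diameters,
    gen_reflectance_image,
    gen_uptake_series,
)


class TestParticleDiameters:
    def test_zero_variance_collapses_to_median(self):
        s = gen_particle_diameters(5, math.log(57), 0.0)
        assert np.allclose(s.diameters, 57.0)

    def test_geometric_mean_recovers_median(self):
        # law of large numbers: exp(mean(log d)) -> exp(log_mu)
        s = gen_particle_diameters(10_000, math.log(57), 0.35, seed=1)
        gm = math.exp(np.log(s.diameters).mean())
        assert abs(gm - 57) / 57 < 0.02

    def test_empirical_median_within_2pct(self):
        s = gen_particle_diameters(10_000, math.log(57), 0.35, seed=3)
        assert abs(np.median(s.diameters) - 57) / 57 < 0.02

    def test_seeded_determinism(self):
        a = gen_particle_diameters(100, math.log(57), 0.35, seed=9)
        b = gen_particle_diameters(100, math.log(57), 0.35, seed=9)
        assert np.array_equal(a.diameters, b.diameters)

    @pytest.mark.parametrize("n,sigma", [(0, 0.3), (-1, 0.3), (5, -0.1)])
    def test_invalid_parameters_raise(self, n, sigma):
        with pytest.raises(ValueError):
            gen_particle_diameters(n, math.log(57), sigma)


class TestReflectanceScene:
    def test_empty_scene_is_constant_background(self):
        spec = SceneSpec(image_shape=(128, 128), n_clusters=0, noise_sd=0.0,
                         psf_sigma=0.0)
        img, truth = gen_reflectance_image(spec)
        assert truth.empty
        assert np.allclose(img.intensities, spec.background_level)

    def test_ground_truth_count_and_annulus(self):
        spec = SceneSpec(image_shape=(512, 512), n_clusters=50, seed=7)
        img, truth = gen_reflectance_image(spec)
        assert len(truth) == 50
        extent = 512 * spec.pixel_size
        r = np.hypot(truth.x_um - extent / 2, truth.y_um - extent / 2)
        assert (r >= spec.annulus_inner * extent - 1e-9).all()
        assert (r <= spec.annulus_outer * extent + 1e-9).all()

    def test_disk_area_matches_analytic(self):
        # one 1-um disk at 0.1 um/px: rasterized area within a 1-px-wide ring
        # of the analytic pi r^2
        spec = SceneSpec(image_shape=(256, 256), pixel_size=0.1, n_clusters=1,
                         diameter_log_mu=math.log(1.0), diameter_log_sigma=0.0,
                         psf_sigma=0.0, noise_sd=0.0, seed=3)
        img, truth = gen_reflectance_image(spec)
        fg = img.intensities > (spec.background_level + spec.foreground_level) / 2
        r_px = 0.5 / 0.1
        ring = 2 * math.pi * r_px  # 1-px tolerance band around the circumference
        assert abs(fg.sum() - math.pi * r_px**2) <= ring

    def test_seeded_determinism(self, clean_scene_spec):
        a, ta = gen_reflectance_image(clean_scene_spec)
        b, tb = gen_reflectance_image(clean_scene_spec)
        assert np.array_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(ta, tb)


class TestUptakeSeries:
    def test_noiseless_matches_closed_form(self):
        sc = KineticScenario(a_max_true=2.31, k_true=0.158,
                             sample_times=(27.0,), replicates=1, noise_sd=0.0)
        series = gen_uptake_series(sc)
        expected = 2.31 * (1 - math.exp(-0.158 * 27))
        assert series.data.c_m_mgL.iloc[0] == pytest.approx(expected, abs=1e-12)
        # direct evaluation of the saturation law: ~2.278 mg/L at 27 h
        assert expected == pytest.approx(2.2776, abs=5e-4)

    def test_zero_rate_gives_zero_uptake(self):
        sc = KineticScenario(k_true=0.0, noise_sd=0.0)
        assert np.allclose(gen_uptake_series(sc).data.c_m_mgL, 0.0)

    def test_noiseless_series_is_nondecreasing(self):
        sc = KineticScenario(k_true=0.3, noise_sd=0.0,
                             sample_times=(1.0, 2.0, 5.0, 10.0, 30.0))
        vals = gen_uptake_series(sc).data.sort_values("time_h").c_m_mgL.to_numpy()
        assert (np.diff(vals) >= 0).all()

    def test_noiseless_kinetics_exact_everywhere(self):
        # max abs deviation from the first-order law < 1e-12
        sc = KineticScenario(a_max_true=1.7, k_true=0.21, noise_sd=0.0,
                             sample_times=(0.0, 3.0, 6.0, 27.0), replicates=2)
        d = gen_uptake_series(sc).data
        model = first_order_model(d.time_h.to_numpy(), 1.7, 0.21)
        assert np.max(np.abs(d.c_m_mgL.to_numpy() - model)) < 1e-12


class TestCellMask:
    def test_sphere_volume_matches_analytic(self):
        spec = CellMaskSpec(grid_shape=(92, 92, 92), voxel_size=0.25,
                            radius=10.0, roughness_amplitude=0.0)
        vol = gen_cell_mask(spec)
        measured = vol.values.sum() * 0.25**3
        analytic = 4 / 3 * math.pi * 10**3
        assert abs(measured - analytic) / analytic < 0.03

    def test_seeded_determinism(self):
        spec = CellMaskSpec(roughness_amplitude=2.0, seed=5)
        assert np.array_equal(gen_cell_mask(spec).values, gen_cell_mask(spec).values)

    def test_roughness_increases_surface_area(self):
        smooth = gen_cell_mask(CellMaskSpec(seed=4))
        rough = gen_cell_mask(CellMaskSpec(roughness_amplitude=2.0,
                                           roughness_frequency=8, seed=4))
        assert measure_cell(rough).surface_area > measure_cell(smooth).surface_area

    def test_oversized_sphere_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            gen_cell_mask(CellMaskSpec(grid_shape=(32, 32, 32), voxel_size=0.25,
                                       radius=10.0))


@pytest.fixture(scope="module")
def tiny_config():
    return StudyConfig(
        n_images_per_group=1,
        n_cells_per_condition=2,
        scene=SceneSpec(image_shape=(128, 128), n_clusters=5),
        mask=CellMaskSpec(grid_shape=(48, 48, 48), voxel_size=0.5),
        master_seed=11,
    )


class TestGroupStudy:

    def test_study_grid_dimensions(self, tiny_config):
        bundle = gen_group_study(tiny_config)
        table = bundle.uptake_table()
        # 4 groups x 3 timepoints, 3 replicates each
        assert len(table) == 4 * 3 * 3
        assert table.groupby(["group_min", "time_h"]).size().eq(3).all()
        assert set(table.time_h) == {3.0, 6.0, 27.0}
        assert len(bundle.masks) == 12

    def test_single_condition_single_row(self):
        cfg = StudyConfig(
            groups_min=(0.0,), post_times_h=(0.0,), replicates=1,
            n_images_per_group=1, n_cells_per_condition=2,
            scene=SceneSpec(image_shape=(128, 128), n_clusters=5),
            mask=CellMaskSpec(grid_shape=(48, 48, 48), voxel_size=0.5),
        )
        assert len(gen_group_study(cfg).uptake_table()) == 1

    def test_master_seed_determinism(self, tiny_config):
        a = gen_group_study(tiny_config)
        b = gen_group_study(tiny_config)
        assert a.uptake_table().to_csv() == b.uptake_table().to_csv()
        img_a, _ = a.images[0.0][0]
        img_b, _ = b.images[0.0][0]
        assert np.array_equal(img_a.intensities, img_b.intensities)
        for key in a.masks:
            for va, vb in zip(a.masks[key], b.masks[key]):
                assert np.array_equal(va.values, vb.values)

    def test_modality_subset_matches_full_bundle(self, tiny_config):
        full = gen_group_study(tiny_config)
        only_uptake = gen_group_study(tiny_config, modalities=("uptake",))
        pd.testing.assert_frame_equal(full.uptake_table(),
                                      only_uptake.uptake_table())
        assert not only_uptake.images and not only_uptake.masks

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            StudyConfig(groups_min=())
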