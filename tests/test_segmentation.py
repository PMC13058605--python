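"""Segmentation: normalization, K-means+threshold masks, sizes, regressions."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sonogold.segmentation import (
    ReflectanceImage,
    SegmentationMask,
    exposure_regression,
    extract_clusters,
    fit_cluster_histogram,
    normalize_image,
    percent_reduction,
    segment_gnp,
    summarize_group,
)
from sonogold.sizing import UnderdeterminedFitError
from sonogold.synthetic import SceneSpec, gen_reflectance_image

PX = 0.2


def make_image(arr, pixel_size=PX):
    return ReflectanceImage(np.asarray(arr, dtype=float), pixel_size)


class TestNormalize:
    def test_constant_image_maps_to_zeros(self):
        out = normalize_image(make_image(np.full((8, 8), 3.0)))
        assert np.allclose(out.intensities, 0.0)

    def test_endpoints(self):
        img = make_image([[100.0, 4195.0], [2000.0, 300.0]])
        out = normalize_image(img).intensities
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.uniform(10, 50, (16, 16)))
        once = normalize_image(img)
        twice = normalize_image(once)
        assert np.allclose(once.intensities, twice.intensities)


class TestSegment:
    def test_recovers_injected_cluster_count(self, clean_scene_spec):
        img, truth = gen_reflectance_image(clean_scene_spec)
        seg = segment_gnp(normalize_image(img))
        assert seg.n_components == len(truth) == 20

    def test_background_only_image_is_empty(self):
        spec = SceneSpec(image_shape=(128, 128), n_clusters=0, noise_sd=0.0,
                         psf_sigma=0.0, seed=1)
        img, _ = gen_reflectance_image(spec)
        seg = segment_gnp(normalize_image(img))
        assert seg.n_components == 0

    def test_seeded_determinism(self, clean_scene_spec):
        img, _ = gen_reflectance_image(replace(clean_scene_spec, noise_sd=0.05))
        norm = normalize_image(img)
        a = segment_gnp(norm, seed=3)
        b = segment_gnp(norm, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_intensity_shift_invariance(self, clean_scene_spec):
        # adding a constant changes nothing after min-max normalization
        img, _ = gen_reflectance_image(replace(clean_scene_spec, noise_sd=0.03))
        shifted = ReflectanceImage(img.intensities + 7.5, img.pixel_size)
        a = segment_gnp(normalize_image(img))
        b = segment_gnp(normalize_image(shifted))
        assert np.array_equal(a.labels, b.labels)

    def test_cluster_count_error_monotone_in_noise(self, clean_scene_spec):
        errors = []
        for noise in (0.15, 0.05, 0.0):
            img, truth = gen_reflectance_image(replace(clean_scene_spec,
                                                       noise_sd=noise))
            seg = segment_gnp(normalize_image(img))
            errors.append(abs(seg.n_components - len(truth)))
        assert errors[0] >= errors[1] >= errors[2]

    def test_invalid_k_rejected(self, clean_scene_spec):
        img, _ = gen_reflectance_image(clean_scene_spec)
        with pytest.raises(ValueError):
            segment_gnp(normalize_image(img), k_clusters=1)

    def test_degenerate_intensities_rejected(self):
        # two intensity levels cannot support three clusters
        arr = np.zeros((16, 16))
        arr[:4] = 1.0
        with pytest.raises(ValueError, match="distinct"):
            segment_gnp(make_image(arr), k_clusters=3)


class TestExtract:
    def test_equivalent_diameter_closed_form(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[10:20, 10:20] = 1  # 100 px
        tab = extract_clusters(SegmentationMask(labels, pixel_size=0.1))
        d = tab.equivalent_diameter_um.iloc[0]
        assert d == pytest.approx(2 * math.sqrt(100 / math.pi) * 0.1, rel=1e-12)

    def test_empty_mask_empty_table(self):
        tab = extract_clusters(SegmentationMask(np.zeros((8, 8), dtype=int), PX))
        assert tab.empty

    def test_single_disk_diameter_within_5pct(self):
        spec = SceneSpec(image_shape=(128, 128), pixel_size=0.1, n_clusters=1,
                         diameter_log_mu=math.log(1.0), diameter_log_sigma=0.0,
                         psf_sigma=0.0, noise_sd=0.0, seed=2)
        img, truth = gen_reflectance_image(spec)
        # binary-valued scene: two intensity levels support exactly 2 clusters
        tab = extract_clusters(segment_gnp(normalize_image(img), k_clusters=2))
        assert len(tab) == 1
        assert abs(tab.equivalent_diameter_um.iloc[0] - 1.0) < 0.05

    def test_diameter_estimator_unbiased_over_size_range(self):
        # 100 disks, d in [0.4, 2] um, no PSF/noise: median relative error < 5%
        # frame large enough that the biggest disk stays well under the
        # 5% foreground budget implied by the 0.95 quantile threshold
        errors = []
        diameters = np.linspace(0.4, 2.0, 100)
        for i, d in enumerate(diameters):
            spec = SceneSpec(image_shape=(128, 128), pixel_size=0.1, n_clusters=1,
                             diameter_log_mu=math.log(d), diameter_log_sigma=0.0,
                             psf_sigma=0.0, noise_sd=0.0,
                             annulus_inner=0.0, annulus_outer=0.2, seed=i)
            img, _ = gen_reflectance_image(spec)
            tab = extract_clusters(segment_gnp(normalize_image(img), k_clusters=2,
                                               min_cluster_pixels=1))
            errors.append(abs(tab.equivalent_diameter_um.iloc[0] - d) / d)
        assert np.median(errors) < 0.05


class TestSummaries:
    def test_degenerate_group(self):
        tab = pd.DataFrame({"equivalent_diameter_um": [1.0, 1.0, 1.0]})
        s = summarize_group([tab], group_min=0)
        assert (s.mean, s.sd, s.max) == (1.0, 0.0, 1.0)

    def test_pooled_arithmetic(self):
        tabs = [pd.DataFrame({"equivalent_diameter_um": [0.2, 0.6]}),
                pd.DataFrame({"equivalent_diameter_um": [1.0]})]
        s = summarize_group(tabs, group_min=5)
        assert s.mean == pytest.approx(0.6)
        assert s.max == 1.0
        assert s.n_clusters == 3

    def test_lognormal_group_mean_matches_analytic(self):
        rng = np.random.default_rng(12)
        sizes = np.exp(rng.normal(math.log(0.5), 0.5, 500))
        s = summarize_group([pd.DataFrame({"equivalent_diameter_um": sizes})], 0)
        analytic = math.exp(math.log(0.5) + 0.5**2 / 2)
        assert abs(s.mean - analytic) / analytic < 0.10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([pd.DataFrame({"equivalent_diameter_um": []})], 0)

    def test_cluster_histogram_fit_recovery(self):
        rng = np.random.default_rng(3)
        sizes = np.exp(rng.normal(math.log(0.5), 0.5, 10_000))
        s = summarize_group([pd.DataFrame({"equivalent_diameter_um": sizes})], 0,
                            bin_width_um=0.05)
        fit = fit_cluster_histogram(s)
        assert abs(fit.log_mu - math.log(0.5)) < 0.02 * abs(math.log(0.5)) + 0.02

    def test_cluster_histogram_underdetermined(self):
        tab = pd.DataFrame({"equivalent_diameter_um": [0.5, 0.5, 1.5]})
        s = summarize_group([tab], 0, bin_width_um=1.0)
        with pytest.raises(UnderdeterminedFitError):
            fit_cluster_histogram(s)


class TestReductionAndRegression:
    @pytest.mark.parametrize("treated,expected", [
        (0.483, 19.10), (0.465, 22.11), (0.495, 17.09),
    ])
    def test_reported_reductions(self, treated, expected):
        assert percent_reduction(0.597, treated) == pytest.approx(expected, abs=0.005)

    def test_no_change_is_zero(self):
        assert percent_reduction(0.42, 0.42) == 0.0

    def test_invalid_control_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.4)

    def test_group_mean_regressions(self):
        x = [0, 5, 10, 20]
        y = [0.597, 0.483, 0.465, 0.495]
        lin = exposure_regression(x, y, degree=1)
        quad = exposure_regression(x, y, degree=2)
        # frozen from an independent polyfit/centered-SST computation
        assert lin.r_squared == pytest.approx(0.339444, abs=1e-4)
        assert quad.r_squared == pytest.approx(0.957524, abs=1e-4)

    def test_r_squared_is_pearson_squared(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 20, 40)
        y = 0.6 - 0.01 * x + rng.normal(0, 0.1, 40)
        r = exposure_regression(x, y, degree=1)
        assert r.r_squared == pytest.approx(r.pearson_r**2, abs=1e-12)

    def test_two_points_saturate(self):
        r = exposure_regression([0, 10], [0.6, 0.4], degree=1)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            exposure_regression([0, 5], [0.6, 0.5], degree=2)
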