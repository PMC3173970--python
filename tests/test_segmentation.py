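import math

import numpy as np
import pytest

from mraseg import (
    Image2D,
    NoiseModel,
    ParameterError,
    PhantomSpec,
    SegmentationConfig,
    add_gaussian_noise,
    area_accuracy_pct,
    diameter_error_pct,
    evaluate_denoising,
    generate_phantom,
    match_rois_to_spheres,
    measure_equivalent_diameter,
    segment,
)


class TestMeasurements:
    def test_single_pixel_equivalent_diameter(self):
        assert measure_equivalent_diameter(1, 1.0) == pytest.approx(
            2.0 / math.sqrt(math.pi), abs=1e-12
        )

    def test_rasterized_disc_recovers_diameter(self):
        h = 0.5
        r_mm = 18.5  # 37 mm disc
        n = 100
        y, x = np.mgrid[0:n, 0:n]
        cx = (n - 1) / 2.0
        inside = ((x - cx) ** 2 + (y - cx) ** 2) * h * h <= r_mm * r_mm
        d = measure_equivalent_diameter(int(inside.sum()), h)
        assert abs(d - 37.0) / 37.0 < 0.01

    def test_square_root_law(self):
        d1 = measure_equivalent_diameter(50, 1.0)
        d4 = measure_equivalent_diameter(200, 1.0)
        assert d4 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_invalid_area(self):
        with pytest.raises(ParameterError):
            measure_equivalent_diameter(0, 1.0)

    @pytest.mark.parametrize(
        "measured,actual,expected",
        [(10.0, 10.0, 0.0), (11.0, 10.0, 10.0), (8.8, 10.0, -12.0)],
    )
    def test_diameter_error_pct(self, measured, actual, expected):
        assert diameter_error_pct(measured, actual) == pytest.approx(expected, abs=1e-10)

    def test_diameter_error_antisymmetric(self):
        for delta in (0.5, 1.7, 3.0):
            up = diameter_error_pct(10.0 + delta, 10.0)
            down = diameter_error_pct(10.0 - delta, 10.0)
            assert up == pytest.approx(-down, abs=1e-12)
        with pytest.raises(ParameterError):
            diameter_error_pct(5.0, 0.0)

    @pytest.mark.parametrize(
        "measured,reference,expected",
        [(50.0, 50.0, 100.0), (0.0, 50.0, 0.0), (55.0, 50.0, 90.0), (200.0, 50.0, 0.0)],
    )
    def test_area_accuracy(self, measured, reference, expected):
        assert area_accuracy_pct(measured, reference) == pytest.approx(expected, abs=1e-10)


class TestPipeline:
    def test_empty_image_gives_no_rois(self):
        labels, rois = segment(
            Image2D(np.zeros((64, 64))), SegmentationConfig(transform="none")
        )
        assert rois == []
        assert labels.max() == 0

    def test_noise_free_phantom_six_rois(self, phantom_512, phantom_512_spec):
        labels, rois = segment(phantom_512, SegmentationConfig(transform="none"))
        assert len(rois) == 6
        matches, spurious, missed = match_rois_to_spheres(rois, phantom_512_spec)
        assert len(matches) == 6 and not spurious and not missed
        for roi, actual in matches:
            assert abs(roi.equivalent_diameter_mm - actual) <= phantom_512.pixel_size_mm

    def test_curvelet_t0_matches_transform_free(self, phantom_512):
        _, plain = segment(phantom_512, SegmentationConfig(transform="none"))
        _, through = segment(
            phantom_512, SegmentationConfig(transform="curvelet", t_coef=0.0)
        )
        assert len(plain) == len(through) == 6
        plain_d = sorted(r.equivalent_diameter_mm for r in plain)
        through_d = sorted(r.equivalent_diameter_mm for r in through)
        for a, b in zip(plain_d, through_d):
            assert abs(a - b) <= phantom_512.pixel_size_mm

    def test_raising_t_post_never_grows_rois(self, phantom_512):
        sizes = []
        for t_post in (7.0, 50.0, 150.0):
            _, rois = segment(
                phantom_512,
                SegmentationConfig(transform="none", t_post=t_post),
            )
            sizes.append(sum(r.pixel_area for r in rois))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_noisy_phantom_segmentation_finds_spheres(self, phantom_512, phantom_512_spec):
        noisy = add_gaussian_noise(phantom_512, NoiseModel(0.2, 9))
        sigma = 0.2 * phantom_512.pixels.max()
        # the post threshold must clear the rectified-noise floor left by
        # pre-thresholding Gaussian noise of this strength (≈ 11 here)
        _, rois = segment(
            noisy,
            SegmentationConfig(
                transform="curvelet", t_coef=3.0 * sigma, t_post=20.0
            ),
        )
        matches, _, missed = match_rois_to_spheres(rois, phantom_512_spec)
        assert len(matches) >= 5
        assert len(missed) <= 1

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            SegmentationConfig(transform="shearlet")
        with pytest.raises(ParameterError):
            SegmentationConfig(t_pre=-1.0)


class TestMatching:
    def test_spurious_and_missed(self, phantom_512, phantom_512_spec):
        _, rois = segment(phantom_512, SegmentationConfig(transform="none"))
        # an extra blob far from every sphere centre is spurious
        from dataclasses import replace

        fake = replace(rois[0], label=99, centroid=(5.0, 5.0))
        matches, spurious, missed = match_rois_to_spheres(
            rois + [fake], phantom_512_spec
        )
        assert len(matches) == 6
        assert [r.label for r in spurious] == [99]
        assert not missed
        # dropping one ROI leaves its sphere missed
        matches, spurious, missed = match_rois_to_spheres(rois[1:], phantom_512_spec)
        assert len(matches) == 5
        assert len(missed) == 1

    def test_matched_rois_are_annotated(self, phantom_512, phantom_512_spec):
        _, rois = segment(phantom_512, SegmentationConfig(transform="none"))
        matches, _, _ = match_rois_to_spheres(rois, phantom_512_spec)
        for roi, actual in matches:
            assert roi.matched_actual_diameter_mm == actual
            assert roi.error_pct == pytest.approx(
                diameter_error_pct(roi.equivalent_diameter_mm, actual), abs=1e-12
            )


class TestEvaluation:
    def test_perfect_denoising(self, phantom_128):
        noisy = add_gaussian_noise(phantom_128, NoiseModel(0.2, 0))
        report = evaluate_denoising(phantom_128, noisy, phantom_128)
        assert report.denoised_mse == 0.0
        assert report.denoised_psnr_db == math.inf
        assert not report.data_loss_high

    def test_identity_denoising_equals_baseline(self, phantom_128):
        noisy = add_gaussian_noise(phantom_128, NoiseModel(0.2, 0))
        report = evaluate_denoising(phantom_128, noisy, noisy)
        assert report.denoised_mse == report.noisy_mse
        assert report.denoised_psnr_db == report.noisy_psnr_db

    def test_transform_quality_ordering(self, phantom_128):
        """Median over five noise seeds: curvelet MSE ≤ wavelet MSE against
        the clean phantom, and both beat the noisy baseline."""
        from mraseg.curvelet import denoise_curvelet, plan
        from mraseg.wavelet import denoise_wavelet

        sigma = 0.2 * phantom_128.pixels.max()
        system = plan(128, 128)
        curvelet_mse, wavelet_mse, baseline_mse = [], [], []
        for seed in range(5):
            noisy = add_gaussian_noise(phantom_128, NoiseModel(0.2, seed))
            c = evaluate_denoising(
                phantom_128, noisy, denoise_curvelet(noisy, system, 3.0 * sigma)
            )
            w = evaluate_denoising(
                phantom_128, noisy, denoise_wavelet(noisy, "haar", 3, 3.0 * sigma)
            )
            curvelet_mse.append(c.denoised_mse)
            wavelet_mse.append(w.denoised_mse)
            baseline_mse.append(c.noisy_mse)
        assert np.median(curvelet_mse) <= np.median(wavelet_mse)
        assert np.median(wavelet_mse) < np.median(baseline_mse)

    def test_shape_mismatch(self, phantom_128):
        from mraseg import ShapeMismatchError

        small = Image2D(np.zeros((10, 10)))
        with pytest.raises(ShapeMismatchError):
            evaluate_denoising(phantom_128, small, small)
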