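import math

import numpy as np
import pytest

from mraseg import Image2D, ParameterError
from mraseg.curvelet import (
    CurveletCoefficients,
    angular_window,
    coefficient_display,
    denoise_curvelet,
    fdct_forward,
    fdct_inverse,
    load_coefficients,
    meyer_nu,
    plan,
    radial_window,
    save_coefficients,
    threshold_curvelet,
    wedge_window,
)


class TestWindows:
    def test_meyer_complementarity(self):
        x = np.linspace(0.0, 1.0, 1001)
        assert np.max(np.abs(meyer_nu(x) + meyer_nu(1.0 - x) - 1.0)) < 1e-12

    def test_radial_admissibility(self):
        """Σ_j W²(2^j r) = 1 on the covered radial range, sampled densely."""
        r = np.linspace(0.75, 1.5, 10000, endpoint=False)
        total = sum(radial_window(2.0**j * r) ** 2 for j in range(-60, 61))
        assert np.max(np.abs(total - 1.0)) < 1e-10

    def test_angular_admissibility(self):
        """Σ_l V²(t − l) = 1 on (−1/2, 1/2), sampled densely."""
        t = np.linspace(-0.5, 0.5, 10000)
        total = sum(angular_window(t - l) ** 2 for l in range(-3, 4))
        assert np.max(np.abs(total - 1.0)) < 1e-10

    def test_windows_bounded_and_compact(self):
        assert np.all(radial_window(np.linspace(0, 4, 400)) <= 1.0 + 1e-15)
        assert np.all(angular_window(np.linspace(-2, 2, 400)) <= 1.0 + 1e-15)
        assert angular_window(1.5) == 0.0
        assert radial_window(8.0) == 0.0


class TestPlan:
    def test_512_default_has_five_scales(self):
        assert plan(512, 512).nscales == 5

    def test_second_coarsest_angle_constraint(self):
        for shape in ((64, 64), (128, 128), (512, 512)):
            system = plan(*shape)
            n2 = system.angles_per_scale[1]
            assert n2 >= 8 and n2 % 4 == 0

    def test_coarsest_is_single_nondirectional_band(self):
        system = plan(64, 64, nscales=2)
        assert system.angles_per_scale[0] == 1
        tile = wedge_window(system, 1, 0)
        mask = tile.full_mask()
        # no angular modulation: on a square grid the band is exactly
        # symmetric under axis exchange
        assert np.max(np.abs(mask - mask.T)) < 1e-12
        with pytest.raises(ParameterError):
            wedge_window(system, 1, 1)

    def test_angles_double_every_other_scale(self):
        n = plan(512, 512).angles_per_scale
        assert n == [1, 16, 16, 32, 32]

    def test_invalid_angle_count(self):
        with pytest.raises(ParameterError):
            plan(64, 64, nangles_coarse=6)
        with pytest.raises(ParameterError):
            plan(64, 64, nangles_coarse=18)

    def test_too_deep_plan_rejected(self):
        with pytest.raises(ParameterError):
            plan(64, 64, nscales=5)

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            plan(16, 16)

    def test_partition_of_unity_128(self):
        dev = np.abs(plan(128, 128).partition_of_unity() - 1.0)
        assert np.max(dev) < 1e-10

    def test_parabolic_elongation_toward_fine_scales(self):
        """Axis-aligned wrapped rectangles get more anisotropic with scale
        (compared two scales apart, matching the every-other-scale angle
        doubling)."""
        system = plan(512, 512)
        aspect = {}
        for sc in range(2, system.nscales + 1):
            h, w = wedge_window(system, sc, 0).rect_shape
            aspect[sc] = max(h, w) / min(h, w)
        assert aspect[4] > aspect[2]
        assert aspect[5] > aspect[3]
        assert aspect[system.nscales] > aspect[2]

    def test_wrapping_map_is_collision_free(self):
        system = plan(128, 128)
        for tile in system.tiles.values():
            flat = tile.wrapped_rows * tile.rect_shape[1] + tile.wrapped_cols
            assert np.unique(flat).size == flat.size


class TestTransform:
    def test_zero_image_zero_coefficients(self):
        system = plan(64, 64)
        coeffs = fdct_forward(Image2D(np.zeros((64, 64))), system)
        assert coeffs.energy() == 0.0
        rec = fdct_inverse(coeffs)
        assert np.all(rec.pixels == 0.0)

    @pytest.mark.parametrize("n", [64, 100, 128])
    def test_tight_frame_energy(self, rng, n):
        img = Image2D(rng.normal(size=(n, n)))
        coeffs = fdct_forward(img, plan(n, n))
        e = float(np.sum(img.pixels**2))
        assert abs(coeffs.energy() - e) / e < 1e-6

    @pytest.mark.parametrize("n", [64, 128])
    def test_round_trip(self, rng, n):
        img = Image2D(rng.normal(size=(n, n)))
        rec = fdct_inverse(fdct_forward(img, plan(n, n)), max_imag_residue=1e-9)
        rel = np.linalg.norm(rec.pixels - img.pixels) / np.linalg.norm(img.pixels)
        assert rel < 1e-6

    def test_round_trip_phantom(self, phantom_128):
        rec = fdct_inverse(
            fdct_forward(phantom_128, plan(128, 128)), max_imag_residue=1e-9
        )
        rel = np.linalg.norm(rec.pixels - phantom_128.pixels) / np.linalg.norm(
            phantom_128.pixels
        )
        assert rel < 1e-6

    def test_odd_dimensions_accepted(self, rng):
        img = Image2D(rng.normal(size=(65, 97)))
        rec = fdct_inverse(fdct_forward(img, plan(65, 97)))
        rel = np.linalg.norm(rec.pixels - img.pixels) / np.linalg.norm(img.pixels)
        assert rel < 1e-6

    def test_linearity(self, rng):
        system = plan(64, 64)
        x = Image2D(rng.normal(size=(64, 64)))
        y = Image2D(rng.normal(size=(64, 64)))
        z = Image2D(2.0 * x.pixels - 0.5 * y.pixels)
        cx, cy, cz = (fdct_forward(i, system) for i in (x, y, z))
        for key in cz.bands:
            combo = 2.0 * cx.bands[key] - 0.5 * cy.bands[key]
            denom = max(np.max(np.abs(combo)), 1.0)
            assert np.max(np.abs(cz.bands[key] - combo)) / denom < 1e-10

    def test_shape_mismatch(self, rng):
        from mraseg import ShapeMismatchError

        with pytest.raises(ShapeMismatchError):
            fdct_forward(Image2D(rng.normal(size=(64, 64))), plan(128, 128))


class TestThresholdAndDenoise:
    def test_zero_threshold_identity(self, rng):
        coeffs = fdct_forward(Image2D(rng.normal(size=(64, 64))), plan(64, 64))
        out = threshold_curvelet(coeffs, 0.0)
        for key in coeffs.bands:
            assert np.array_equal(out.bands[key], coeffs.bands[key])

    def test_huge_threshold_keeps_only_coarse(self, rng):
        coeffs = fdct_forward(Image2D(rng.normal(size=(64, 64))), plan(64, 64))
        big = 1.0 + max(
            np.max(np.abs(b)) for k, b in coeffs.bands.items() if k[0] != 1
        )
        out = threshold_curvelet(coeffs, big)
        for key, band in out.bands.items():
            if key[0] == 1:
                assert np.array_equal(band, coeffs.bands[key])
            else:
                assert np.all(band == 0.0)

    def test_survivor_count_monotone_in_t(self, rng):
        coeffs = fdct_forward(Image2D(rng.normal(size=(64, 64))), plan(64, 64))
        grid = np.linspace(0.0, 2.0, 9)
        counts = [
            sum(
                int(np.count_nonzero(b))
                for k, b in threshold_curvelet(coeffs, t).bands.items()
            )
            for t in grid
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_threshold(self, rng):
        coeffs = fdct_forward(Image2D(rng.normal(size=(64, 64))), plan(64, 64))
        with pytest.raises(ParameterError):
            threshold_curvelet(coeffs, -0.5)

    def test_denoise_t0_round_trip(self, rng):
        img = Image2D(rng.normal(size=(64, 64)))
        out = denoise_curvelet(img, plan(64, 64), 0.0)
        rel = np.linalg.norm(out.pixels - img.pixels) / np.linalg.norm(img.pixels)
        assert rel < 1e-6

    def test_denoise_improves_psnr_on_noisy_phantom(self, phantom_128):
        from mraseg import NoiseModel, add_gaussian_noise, psnr

        noisy = add_gaussian_noise(phantom_128, NoiseModel(0.2, 5))
        sigma = 0.2 * phantom_128.pixels.max()
        out = denoise_curvelet(noisy, plan(128, 128), 3.0 * sigma)
        assert psnr(phantom_128, out) > psnr(phantom_128, noisy)


class TestDisplayAndSerialization:
    def test_zero_coefficients_zero_mosaic(self):
        system = plan(64, 64)
        coeffs = fdct_forward(Image2D(np.zeros((64, 64))), system)
        mosaic = coefficient_display(coeffs)
        assert np.all(mosaic.pixels == 0.0)

    def test_layout_disjoint_and_capacious(self, rng):
        coeffs = fdct_forward(Image2D(rng.normal(size=(128, 128))), plan(128, 128))
        mosaic, layout = coefficient_display(coeffs, return_layout=True)
        assert mosaic.pixels.size >= coeffs.coefficient_count()
        used = np.zeros(mosaic.shape, dtype=int)
        for r, c, h, w in layout.values():
            used[r : r + h, c : c + w] += 1
        assert used.max() == 1

    def test_container_round_trip(self, rng, tmp_path):
        img = Image2D(rng.normal(size=(64, 64)))
        coeffs = fdct_forward(img, plan(64, 64))
        save_coefficients(coeffs, tmp_path / "co")
        back = load_coefficients(tmp_path / "co")
        for key in coeffs.bands:
            assert np.array_equal(back.bands[key], coeffs.bands[key])
        rec = fdct_inverse(back)
        rel = np.linalg.norm(rec.pixels - img.pixels) / np.linalg.norm(img.pixels)
        assert rel < 1e-6
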