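"""Fourier-domain degradation operators: conventions, oracles, invariants."""

import numpy as np
import pytest

from lowfield_sr.kspace import (
    DegradationConfig,
    KSpaceDegrader,
    add_complex_noise,
    central_crop,
    degrade,
    fft2c,
    ifft2c,
    resize_via_kspace,
    zero_fill_sr,
    zero_pad,
)

from conftest import dft2c_oracle, idft2c_oracle


class TestCenteredFFT:
    def test_constant_image_concentrates_at_dc(self):
        N, c = 16, 0.7
        k = fft2c(np.full((N, N), c))
        assert abs(k[N // 2, N // 2] - c * N) < 1e-10
        k[N // 2, N // 2] = 0
        assert np.abs(k).max() < 1e-10

    def test_centered_impulse_is_flat(self):
        N = 12
        img = np.zeros((N, N))
        img[N // 2, N // 2] = 1.0
        k = fft2c(img)
        assert np.allclose(np.abs(k), 1.0 / N, atol=1e-12)

    def test_matches_direct_sum_dft_oracle(self, rng):
        x = rng.random((8, 8))
        assert np.abs(fft2c(x) - dft2c_oracle(x)).max() < 1e-10

    def test_inverse_matches_direct_sum_oracle(self, rng):
        k = rng.random((8, 8)) + 1j * rng.random((8, 8))
        assert np.abs(ifft2c(k) - idft2c_oracle(k)).max() < 1e-10

    def test_round_trip(self, rng):
        x = rng.random((24, 20))
        assert np.abs(ifft2c(fft2c(x)) - x).max() < 1e-10

    def test_single_dc_coefficient_gives_constant(self):
        N, c = 10, 0.3
        k = np.zeros((N, N), dtype=complex)
        k[N // 2, N // 2] = c * N
        assert np.allclose(ifft2c(k).real, c, atol=1e-12)

    def test_parseval_energy_preservation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            H = int(rng.integers(8, 24))
            W = int(rng.integers(8, 24))
            x = rng.standard_normal((H, W))
            e_img = np.sum(x**2)
            e_k = np.sum(np.abs(fft2c(x)) ** 2)
            assert abs(e_img - e_k) / e_img < 1e-8

    def test_nonfinite_input_rejected(self):
        bad = np.full((8, 8), np.nan)
        with pytest.raises(ValueError):
            fft2c(bad)
        with pytest.raises(ValueError):
            ifft2c(bad.astype(complex))


class TestCropPad:
    def test_crop_convention_keeps_rows_32_to_95(self):
        marker = np.zeros((128, 128), dtype=complex)
        marker[32:96, 32:96] = 1.0
        cropped = central_crop(marker, (64, 64))
        assert cropped.shape == (64, 64)
        assert np.all(cropped == 1.0)
        # anything outside that window is discarded
        marker[31, :] = 99.0
        assert np.all(central_crop(marker, (64, 64))[0] == 1.0)

    def test_crop_same_size_is_identity(self, rng):
        k = rng.random((16, 16)) + 1j * rng.random((16, 16))
        out = central_crop(k, (16, 16))
        assert np.array_equal(out, k)

    def test_dc_preserved_bit_exactly(self, rng):
        k = rng.random((32, 32)) + 1j * rng.random((32, 32))
        c = central_crop(k, (16, 16))
        assert c[8, 8] == k[16, 16]

    def test_pad_support_and_energy(self, rng):
        k = rng.random((64, 64)) + 1j * rng.random((64, 64))
        p = zero_pad(k, (128, 128))
        assert np.array_equal(p[32:96, 32:96], k)
        mask = np.ones((128, 128), dtype=bool)
        mask[32:96, 32:96] = False
        assert np.all(p[mask] == 0)
        # zeros contribute no energy (summation order may differ in the last ulp)
        assert np.sum(np.abs(p) ** 2) == pytest.approx(np.sum(np.abs(k) ** 2), rel=1e-12)

    def test_pad_same_size_is_identity(self, rng):
        k = rng.random((12, 12)) + 1j * rng.random((12, 12))
        assert np.array_equal(zero_pad(k, (12, 12)), k)

    @pytest.mark.parametrize("small,big", [((8, 8), (16, 16)), ((10, 14), (20, 20)), ((64, 64), (128, 128))])
    def test_crop_of_pad_is_bit_exact_identity(self, rng, small, big):
        k = rng.random(small) + 1j * rng.random(small)
        assert np.array_equal(central_crop(zero_pad(k, big), small), k)

    def test_invalid_sizes_rejected(self, rng):
        k = rng.random((16, 16)).astype(complex)
        with pytest.raises(ValueError):
            central_crop(k, (32, 16))
        with pytest.raises(ValueError):
            zero_pad(k, (8, 16))


class TestComplexNoise:
    def test_zero_sigma_is_identity(self, rng):
        k = rng.random((16, 16)).astype(complex)
        assert np.array_equal(add_complex_noise(k, 0.0, seed=1), k)

    def test_noise_power_matches_sigma(self):
        k = np.zeros((64, 64), dtype=complex)
        noisy = add_complex_noise(k, 1.0, seed=3)
        assert np.mean(np.abs(noisy) ** 2) == pytest.approx(1.0, rel=0.05)

    def test_seed_determinism(self, rng):
        k = rng.random((16, 16)).astype(complex)
        a = add_complex_noise(k, 0.5, seed=9)
        b = add_complex_noise(k, 0.5, seed=9)
        c = add_complex_noise(k, 0.5, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            add_complex_noise(rng.random((8, 8)).astype(complex), -0.1, seed=0)


class TestDegrade:
    def test_output_size_is_half(self, rng):
        hr = rng.random((128, 128))
        assert degrade(hr, DegradationConfig(), seed=0).shape == (64, 64)

    def test_constant_maps_to_same_constant(self):
        hr = np.full((128, 128), 0.4)
        lr = degrade(hr, DegradationConfig(), seed=0, rho=0.0)
        assert np.abs(lr - 0.4).max() < 1e-10

    def test_band_limited_images_are_fixed_points(self, band_limited_pair):
        pair = band_limited_pair
        rec = zero_fill_sr(degrade(pair.hr, DegradationConfig(), seed=0, rho=0.0), (128, 128))
        assert np.abs(rec - pair.hr).max() < 1e-10

    def test_linearity_before_magnitude(self, rng):
        cfg = DegradationConfig()
        x1, x2 = rng.random((128, 128)), rng.random((128, 128))
        a, b = 0.6, -1.3
        lhs = degrade(a * x1 + b * x2, cfg, seed=0, rho=0.0, _complex_output=True)
        rhs = a * degrade(x1, cfg, seed=0, rho=0.0, _complex_output=True) + b * degrade(
            x2, cfg, seed=0, rho=0.0, _complex_output=True
        )
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_determinism(self, rng):
        hr = rng.random((128, 128))
        assert np.array_equal(degrade(hr, seed=5), degrade(hr, seed=5))
        assert not np.array_equal(degrade(hr, seed=5), degrade(hr, seed=6))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            degrade(rng.random((64, 64)), DegradationConfig(), seed=0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DegradationConfig(lr_size=(256, 256), hr_size=(128, 128))
        with pytest.raises(ValueError):
            DegradationConfig(noise_rho_range=(0.3, 0.1))


class TestZeroFillSR:
    def test_output_size(self, rng):
        assert zero_fill_sr(rng.random((64, 64)), (128, 128)).shape == (128, 128)

    def test_constant_preserved(self):
        out = zero_fill_sr(np.full((64, 64), 0.25), (128, 128))
        assert np.abs(out - 0.25).max() < 1e-10

    def test_target_smaller_rejected(self, rng):
        with pytest.raises(ValueError):
            zero_fill_sr(rng.random((64, 64)), (32, 32))


class TestResizeViaKspace:
    def test_identity_at_same_size(self, rng):
        x = rng.random((32, 32))
        assert np.abs(resize_via_kspace(x, (32, 32)) - x).max() < 1e-10

    def test_mixed_crop_and_pad(self, rng):
        out = resize_via_kspace(rng.random((160, 120)), (128, 128))
        assert out.shape == (128, 128)

    def test_mixed_resize_preserves_constants(self):
        out = resize_via_kspace(np.full((160, 120), 0.5), (128, 128))
        assert np.abs(out - 0.5).max() < 1e-9

    def test_down_up_composition_equals_zero_fill_of_degrade(self, rng):
        x = rng.random((128, 128))
        via_resize = resize_via_kspace(resize_via_kspace(x, (64, 64)), (128, 128))
        via_degrade = zero_fill_sr(degrade(x, DegradationConfig(), seed=0, rho=0.0), (128, 128))
        assert np.array_equal(via_resize, via_degrade)


class TestKSpaceDegraderTransformer:
    def test_transform_shapes_and_determinism(self, rng):
        X = rng.random((3, 128, 128))
        deg = KSpaceDegrader(random_state=4)
        out1 = deg.fit_transform(X)
        out2 = KSpaceDegrader(random_state=4).transform(X)
        assert out1.shape == (3, 64, 64)
        assert np.array_equal(out1, out2)

    def test_params_round_trip(self):
        deg = KSpaceDegrader()
        params = deg.get_params()
        deg.set_params(**params)
        assert deg.get_params() == params
        with pytest.raises(ValueError):
            deg.set_params(not_a_param=1)
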