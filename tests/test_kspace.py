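import numpy as np
import pytest

from asdlmri import (
    KSpaceGrid,
    SamplingMask,
    fft2c,
    ifft2c,
    kspace_data_update,
    make_sampling_mask,
    psnr,
    undersample,
    zero_filled_recon,
)


class TestCenteredFFT:
    def test_constant_image_concentrates_at_dc(self):
        H = 16
        spec = fft2c(np.full((H, H), 3.0))
        assert spec[H // 2, H // 2] == pytest.approx(3.0 * H)
        off_dc = spec.copy()
        off_dc[H // 2, H // 2] = 0
        assert np.abs(off_dc).max() < 1e-10

    def test_round_trip_and_parseval(self, rng):
        x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        assert np.abs(ifft2c(fft2c(x)) - x).max() < 1e-10
        y = rng.standard_normal((16, 16))
        assert np.linalg.norm(fft2c(y)) == pytest.approx(
            np.linalg.norm(y), abs=1e-10
        )

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            fft2c(np.zeros(8))


class TestSamplingMasks:
    def test_factor_one_is_full(self):
        for kind in ("variable_density_2d", "cartesian_lines", "uniform_random"):
            mask = make_sampling_mask(32, 32, 1.0, kind, seed=0)
            assert mask.grid.all()

    def test_sampled_fraction_within_band(self):
        for factor in (2.5, 4.0, 10.0, 20.0):
            mask = make_sampling_mask(128, 128, factor, "variable_density_2d", seed=1)
            assert 0.8 / factor <= mask.sampled_fraction <= 1.2 / factor

    def test_variable_density_concentrates_near_dc(self):
        vd = make_sampling_mask(128, 128, 4.0, "variable_density_2d", seed=0)
        uni = make_sampling_mask(128, 128, 4.0, "uniform_random", seed=0)
        assert 0.20 <= vd.sampled_fraction <= 0.30

        def mean_radius(mask):
            ii, jj = np.nonzero(mask.grid)
            return np.hypot(ii - 64, jj - 64).mean()

        assert mean_radius(vd) < mean_radius(uni)

    def test_cartesian_lines_row_count(self):
        mask = make_sampling_mask(128, 128, 10.0, "cartesian_lines", seed=4)
        full_rows = mask.grid.all(axis=1)
        assert full_rows.sum() in (12, 13)
        assert (~mask.grid[~full_rows]).all()

    def test_dc_always_sampled_and_deterministic(self):
        for kind in ("variable_density_2d", "cartesian_lines", "uniform_random"):
            a = make_sampling_mask(64, 64, 6.0, kind, seed=9)
            b = make_sampling_mask(64, 64, 6.0, kind, seed=9)
            assert a.grid[32, 32]
            np.testing.assert_array_equal(a.grid, b.grid)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            make_sampling_mask(32, 32, 0.5, "uniform_random", seed=0)


class TestUndersample:
    def test_full_mask_equals_spectrum(self, phantom64):
        mask = make_sampling_mask(64, 64, 1.0, "full", seed=0)
        y = undersample(phantom64, mask)
        np.testing.assert_allclose(y.values, fft2c(phantom64), atol=1e-12)

    def test_zero_outside_omega_and_norm_bound(self, phantom64, rng):
        mask = make_sampling_mask(64, 64, 4.0, "uniform_random", seed=2)
        y = undersample(phantom64, mask)
        assert (y.values[~mask.grid] == 0).all()
        x = rng.standard_normal((64, 64))
        assert np.linalg.norm(undersample(x, mask).values) <= np.linalg.norm(
            fft2c(x)
        ) + 1e-12

    def test_shape_mismatch_rejected(self, phantom64):
        mask = make_sampling_mask(32, 32, 2.0, "uniform_random", seed=0)
        with pytest.raises(ValueError):
            undersample(phantom64, mask)


class TestZeroFilled:
    def test_full_sampling_recovers_image(self, phantom64):
        mask = make_sampling_mask(64, 64, 1.0, "full", seed=0)
        recon = zero_filled_recon(undersample(phantom64, mask))
        assert np.abs(recon - phantom64).max() < 1e-10

    def test_empty_mask_gives_zero_image(self):
        mask = SamplingMask(np.zeros((16, 16), bool), 1e9, "uniform_random", 0)
        y = KSpaceGrid(np.zeros((16, 16), complex), mask)
        assert (zero_filled_recon(y) == 0).all()

    def test_undersampling_degrades_psnr(self, phantom128):
        full = make_sampling_mask(128, 128, 1.0, "full", seed=0)
        four = make_sampling_mask(128, 128, 4.0, "variable_density_2d", seed=0)
        p_full = psnr(phantom128, zero_filled_recon(undersample(phantom128, full)))
        p_four = psnr(phantom128, zero_filled_recon(undersample(phantom128, four)))
        assert p_four < p_full


class TestKSpaceDataUpdate:
    def test_v_zero_keeps_current_estimate(self, rng):
        mask = make_sampling_mask(16, 16, 2.0, "uniform_random", seed=1)
        M = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        M0 = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        np.testing.assert_array_equal(kspace_data_update(M, M0, mask, 0.0), M)

    def test_hand_computed_value_on_sampled_bin(self):
        mask = SamplingMask(np.ones((1, 1), bool), 1.0, "full", 0)
        out = kspace_data_update(
            np.array([[2.0 + 0j]]), np.array([[8.0 + 0j]]), mask, 3.0
        )
        assert out[0, 0] == pytest.approx(6.5)

    def test_large_v_pins_measurements(self, rng):
        mask = make_sampling_mask(16, 16, 2.0, "uniform_random", seed=5)
        M = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        M0 = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        out = kspace_data_update(M, M0, mask, 1e6)
        assert np.abs(out[mask.grid] - M0[mask.grid]).max() < 1e-5
        np.testing.assert_array_equal(out[~mask.grid], M[~mask.grid])

    def test_convex_combination_on_omega(self, rng):
        # updated value lies on the segment joining M and M0 in the plane
        mask = make_sampling_mask(16, 16, 2.0, "uniform_random", seed=3)
        M = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        M0 = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        for v in (0.5, 3.0, 10.0):
            out = kspace_data_update(M, M0, mask, v)
            t = v / (1.0 + v)
            np.testing.assert_allclose(
                out[mask.grid], (1 - t) * M[mask.grid] + t * M0[mask.grid], atol=1e-12
            )

    def test_idempotent_when_consistent(self, rng):
        mask = make_sampling_mask(16, 16, 2.0, "uniform_random", seed=8)
        M = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        M0 = M.copy()
        np.testing.assert_allclose(kspace_data_update(M, M0, mask, 7.0), M, atol=1e-12)

    def test_negative_v_rejected(self, rng):
        mask = make_sampling_mask(8, 8, 2.0, "uniform_random", seed=0)
        M = np.zeros((8, 8), complex)
        with pytest.raises(ValueError):
            kspace_data_update(M, M, mask, -1.0)
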