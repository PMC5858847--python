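"""Calibration, noise regression, band crop/average, normalization, chain."""

import numpy as np
import pytest

import hsibrain as hb
from hsibrain.errors import ConfigError, DegenerateInputError


def _cube(data, stage="calibrated"):
    B = data.shape[2]
    return hb.HSCube(data, np.linspace(400, 1000, B), stage=stage)


def _refs(shape, white=2.0, dark=1.0):
    return hb.ReferenceFrames(white=np.full(shape, white), dark=np.full(shape, dark))


class TestCalibrate:
    @pytest.mark.parametrize("raw_value, expected", [(1.0, 0.0), (2.0, 1.0), (1.5, 0.5)])
    def test_endpoints_and_midpoint(self, raw_value, expected):
        """raw==dark -> 0, raw==white -> 1, halfway -> 0.5."""
        shape = (3, 4, 5)
        refs = _refs(shape)
        out = hb.calibrate(_cube(np.full(shape, raw_value), stage="raw"), refs)
        np.testing.assert_allclose(out.data, expected)
        assert out.stage == "calibrated"

    def test_dead_band_guarded(self):
        shape = (2, 2, 3)
        white = np.full(shape, 2.0)
        white[:, :, 1] = 1.0  # white == dark on band 1
        refs = hb.ReferenceFrames(white=white, dark=np.ones(shape))
        with pytest.warns(UserWarning, match="white==dark"):
            out = hb.calibrate(_cube(np.full(shape, 1.5), stage="raw"), refs)
        assert np.all(out.data[:, :, 1] == 0)
        assert out.metadata["dead_reference_entries"] == 4

    def test_clipping_bound(self):
        shape = (2, 2, 2)
        out = hb.calibrate(_cube(np.full(shape, 100.0), stage="raw"), _refs(shape),
                           clip_max=1.5)
        assert out.data.max() == 1.5


class TestNoiseEstimation:
    def test_exact_linear_dependence_gives_zero_noise(self):
        """Bands that are exact linear combinations of the others leave no
        residual for the per-band regression."""
        rng = np.random.default_rng(0)
        base = rng.random((8 * 8, 2))
        mix = rng.random((2, 6))
        X = base @ mix  # rank-2 spectra, 6 bands
        _, noise = hb.estimate_and_filter_noise(_cube(X.reshape(8, 8, 6)))
        assert np.abs(noise).max() < 1e-8

    @pytest.mark.parametrize("sigma", [0.005, 0.01, 0.02])
    def test_noise_sd_recovery(self, sigma):
        """Low-rank signal + iid Gaussian noise: estimated per-band noise sd
        within 20% of the injected sd, averaged over 10 seeds."""
        B, n = 20, 64 * 64
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            signal = rng.random((n, 3)) @ rng.random((3, B))
            noisy = signal + rng.normal(0, sigma, (n, B))
            _, noise = hb.estimate_and_filter_noise(_cube(noisy.reshape(64, 64, B)))
            ratios.append(noise.reshape(n, B).std(axis=0).mean() / sigma)
        assert abs(np.mean(ratios) - 1) < 0.2

    def test_noise_variance_tracks_injected_monotonically(self):
        B, n = 20, 32 * 32
        rng = np.random.default_rng(3)
        signal = rng.random((n, 3)) @ rng.random((3, B))
        est = []
        for sigma in (0.005, 0.01, 0.02):
            noisy = signal + np.random.default_rng(1).normal(0, sigma, (n, B))
            _, noise = hb.estimate_and_filter_noise(_cube(noisy.reshape(32, 32, B)))
            est.append(noise.var())
        assert est[0] < est[1] < est[2]

    def test_single_pixel_cube_rejected(self):
        with pytest.raises(DegenerateInputError):
            hb.estimate_and_filter_noise(_cube(np.ones((1, 1, 4))))


class TestCropAverage:
    def test_default_crop_keeps_699_of_826(self):
        """Open-interval convention: removing bands 0..50 and 750..825 keeps
        crop_high - crop_low - 1 = 699 bands."""
        cube = _cube(np.ones((2, 2, 826)))
        out = hb.crop_bands(cube, 50, 750)
        assert out.n_bands == 699
        np.testing.assert_array_equal(out.wavelengths_nm, cube.wavelengths_nm[51:750])

    def test_crop_identity_and_empty(self):
        cube = _cube(np.ones((2, 2, 10)))
        assert hb.crop_bands(cube, -1, 10).n_bands == 10
        with pytest.raises(ConfigError):
            hb.crop_bands(cube, 5, 5)

    def test_average_699_to_129(self):
        cube = _cube(np.ones((2, 2, 699)), stage="cropped")
        assert hb.average_bands(cube, 129).n_bands == 129

    def test_average_identity_and_constant_preservation(self):
        rng = np.random.default_rng(0)
        cube = _cube(rng.random((3, 3, 12)), stage="cropped")
        np.testing.assert_allclose(hb.average_bands(cube, 12).data, cube.data)
        const = _cube(np.full((2, 2, 10), 0.37), stage="cropped")
        np.testing.assert_allclose(hb.average_bands(const, 4).data, 0.37)

    def test_average_group_sizes_near_equal(self):
        # 10 bands into 4 groups: sizes 3,3,2,2 -> group means of arange
        data = np.arange(10, dtype=float).reshape(1, 1, 10)
        out = hb.average_bands(_cube(data, stage="cropped"), 4)
        np.testing.assert_allclose(out.data[0, 0], [1.0, 4.0, 6.5, 8.5])

    def test_bad_target_rejected(self):
        cube = _cube(np.ones((2, 2, 10)), stage="cropped")
        with pytest.raises(ConfigError):
            hb.average_bands(cube, 0)


class TestNormalize:
    def test_scale_invariance_idempotence_zero_guard(self):
        rng = np.random.default_rng(1)
        base = rng.random((4, 4, 6)) + 0.1
        a = hb.normalize_pixels(_cube(base))
        b = hb.normalize_pixels(_cube(base * 7))
        np.testing.assert_allclose(a.data, b.data)
        np.testing.assert_allclose(hb.normalize_pixels(a).data, a.data)
        z = hb.normalize_pixels(_cube(np.zeros((2, 2, 3))))
        assert np.all(z.data == 0)

    def test_unit_norms(self):
        rng = np.random.default_rng(2)
        out = hb.normalize_pixels(_cube(rng.random((5, 5, 8)) + 0.01))
        np.testing.assert_allclose(np.linalg.norm(out.pixels(), axis=1), 1.0)


class TestChain:
    def test_chain_outputs_and_determinism(self, small_phantom, small_ppcfg,
                                           small_chain):
        raw, refs, _ = small_phantom
        reduced, fullband = small_chain
        assert reduced.n_bands == small_ppcfg.target_bands
        assert fullband.n_bands == small_ppcfg.crop_high - small_ppcfg.crop_low - 1
        again = hb.run_chain(raw, refs, small_ppcfg)
        np.testing.assert_array_equal(again[0].data, reduced.data)
        np.testing.assert_array_equal(again[1].data, fullband.data)

    def test_chain_unit_norm_outputs(self, small_chain):
        for cube in small_chain:
            norms = np.linalg.norm(cube.pixels(), axis=1)
            nz = norms > 0
            np.testing.assert_allclose(norms[nz], 1.0)

    def test_noise_filter_switch(self, small_phantom, small_ppcfg):
        import dataclasses
        raw, refs, _ = small_phantom
        cfg_off = dataclasses.replace(small_ppcfg, noise_filter=False)
        reduced, _ = hb.run_chain(raw, refs, cfg_off)
        cal = hb.calibrate(raw, refs)
        manual = hb.normalize_pixels(hb.average_bands(
            hb.crop_bands(cal, cfg_off.crop_low, cfg_off.crop_high),
            cfg_off.target_bands))
        np.testing.assert_allclose(reduced.data, manual.data)

    def test_chain_invariant_to_multiplicative_illumination(self, small_ppcfg):
        """Per-pixel scaling (illumination) cancels out after normalization:
        average_bands commutes with scaling and the final step divides it off."""
        rng = np.random.default_rng(5)
        H, W, B = 8, 8, 30
        refl = rng.random((H, W, B)) + 0.2
        illum = 0.6 + 0.6 * rng.random((H, W, 1))  # keeps refl*illum under clip_max
        refs = _refs((H, W, B))
        cfg = hb.PreprocessConfig(crop_low=2, crop_high=28, target_bands=10,
                                  noise_filter=False)
        mk = lambda r: hb.HSCube(r * (refs.white - refs.dark) + refs.dark,
                                 np.linspace(400, 1000, B), stage="raw")
        flat, _ = hb.run_chain(mk(refl), refs, cfg)
        lit, _ = hb.run_chain(mk(refl * illum), refs, cfg)
        np.testing.assert_allclose(lit.data, flat.data, atol=1e-9)
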