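"""Overlay composition, tissue-map thresholding, specular detection, denoising."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endospec import enhance, phantom, spectral
from endospec.enhance import (
    compose_overlay,
    compute_tissue_map,
    detect_specular,
    fourier_denoise,
)
from endospec.errors import ParameterError


def iou(pred, truth):
    union = (pred | truth).sum()
    return float((pred & truth).sum() / union) if union else 1.0


class TestFourierDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.37)
        np.testing.assert_allclose(fourier_denoise(img, 0.25), img, atol=1e-12)

    def test_checkerboard_strongly_attenuated(self):
        yy, xx = np.mgrid[0:64, 0:64]
        checker = ((yy + xx) % 2).astype(float)  # energy at Nyquist
        out = fourier_denoise(checker, 0.25)
        residual = out - out.mean()
        assert np.abs(residual).max() < 0.05 * 0.5  # input amplitude 0.5 about its mean

    def test_band_separation(self):
        x = np.arange(128)
        low = np.sin(2 * np.pi * 0.05 * 0.5 * x)  # 0.05 x Nyquist
        high = np.sin(2 * np.pi * 0.9 * 0.5 * x)  # 0.9 x Nyquist
        img = np.tile(low + high, (128, 1))
        out = fourier_denoise(img, 0.25)
        corr = np.corrcoef(out.ravel(), np.tile(low, (128, 1)).ravel())[0, 1]
        assert corr > 0.99

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (48, 48))
        out = fourier_denoise(img, 0.3)
        assert abs(out.mean() - img.mean()) <= 1e-9 * abs(img.mean())

    @pytest.mark.parametrize("cutoff", [0.0, -0.5, 1.5])
    def test_invalid_cutoff_rejected(self, cutoff):
        with pytest.raises(ParameterError):
            fourier_denoise(np.zeros((8, 8)), cutoff)


class TestTissueMap:
    def test_direct_ratio_evaluation(self):
        out = compute_tissue_map(np.full((4, 4), 0.6), np.ones((4, 4)), t=0.5)
        np.testing.assert_allclose(out.values, 0.6)

    def test_subthreshold_forced_to_zero(self):
        out = compute_tissue_map(np.full((4, 4), 0.2), np.ones((4, 4)), t=0.5)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_identity_when_unthresholded(self):
        rng = np.random.default_rng(1)
        refl = rng.uniform(0, 1, (16, 16))
        out = compute_tissue_map(refl, np.ones_like(refl), t=0.0)
        np.testing.assert_allclose(out.values, refl)

    def test_zero_correction_yields_zero(self):
        out = compute_tissue_map(np.full((4, 4), 0.8), np.zeros((4, 4)), t=0.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            compute_tissue_map(np.zeros((4, 4)), np.zeros((5, 5)), t=0.5)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_threshold_monotonicity(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(5)
        refl = rng.uniform(0, 1, (12, 12))
        v_lo = compute_tissue_map(refl, None, t=lo).values
        v_hi = compute_tissue_map(refl, None, t=hi).values
        assert np.all(v_hi <= v_lo)

    def test_threshold_one_keeps_only_full_response(self):
        refl = np.array([[1.0, 0.999], [0.5, 1.0]])
        out = compute_tissue_map(refl, None, t=1.0)
        np.testing.assert_array_equal(out.values > 0, refl == 1.0)


class TestDetectSpecular:
    def test_pure_white_is_specular(self):
        mask = detect_specular(np.ones((2, 2, 3)))
        assert mask.all()

    def test_mid_gray_is_not_specular(self):
        mask = detect_specular(np.full((2, 2, 3), 0.5))
        assert not mask.any()

    def test_second_branch_hand_case(self):
        # (0.9, 0.95, 0.85): B+R < 2G, I = 0.9, S = 1.5*(0.9-0.85) = 0.075
        px = np.array([[[0.9, 0.95, 0.85]]])
        assert detect_specular(px)[0, 0]

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            detect_specular(np.zeros((2, 2, 3)), i_threshold=1.2)
        with pytest.raises(ParameterError):
            detect_specular(np.zeros((2, 2, 3)), s_threshold=-0.1)


class TestComposeOverlay:
    def _broadband(self):
        bb = np.zeros((4, 4, 3))
        bb[..., 0], bb[..., 1], bb[..., 2] = 0.4, 0.6, 0.2
        bb[0, 0, 0] = 0.8  # channel maxima (0.8, 0.6, 0.4)
        bb[0, 1, 2] = 0.4
        return bb

    def test_zero_tissue_map_gives_normalized_broadband(self):
        bb = self._broadband()
        tm = compute_tissue_map(np.zeros((4, 4)), None, t=0.0)
        out = compose_overlay(bb, tm, mask_specular=False)
        assert out.rgb[1, 1] == pytest.approx((0.5, 1.0, 0.5))

    def test_tissue_value_added_to_blue_and_clipped(self):
        bb = self._broadband()
        tissue = np.full((4, 4), 0.6)
        tm = compute_tissue_map(tissue, None, t=0.0)
        out = compose_overlay(bb, tm, mask_specular=False)
        assert out.rgb[1, 1, 2] == 1.0  # 0.5 + 0.6 clipped
        assert out.rgb[1, 1, 0] == pytest.approx(0.5)

    def test_red_green_bit_identical_to_normalization(self):
        rng = np.random.default_rng(2)
        bb = rng.uniform(0, 1, (16, 16, 3))
        tm = compute_tissue_map(rng.uniform(0, 1, (16, 16)), None, t=0.0)
        out = compose_overlay(bb, tm, mask_specular=False)
        np.testing.assert_array_equal(out.rgb[..., 0], bb[..., 0] / bb[..., 0].max())
        np.testing.assert_array_equal(out.rgb[..., 1], bb[..., 1] / bb[..., 1].max())

    def test_specular_masking_never_increases_blue(self):
        rng = np.random.default_rng(3)
        bb = rng.uniform(0, 1, (16, 16, 3))
        bb[4:6, 4:6] = 0.98  # bright colourless highlight
        tm = compute_tissue_map(rng.uniform(0, 1, (16, 16)), None, t=0.0)
        masked = compose_overlay(bb, tm, mask_specular=True)
        tissue_masked = np.where(masked.specular_mask, 0.0, tm.values)
        unmasked_blue = np.clip(
            bb[..., 2] / bb[..., 2][~masked.specular_mask].max() + tm.values, 0, 1
        )
        masked_ref = np.clip(
            bb[..., 2] / bb[..., 2][~masked.specular_mask].max() + tissue_masked, 0, 1
        )
        np.testing.assert_array_equal(masked.rgb[..., 2], np.clip(masked_ref, 0, 1))
        assert np.all(masked.rgb[..., 2] <= unmasked_blue + 1e-12)

    def test_all_zero_channel_uses_unit_divisor(self):
        bb = np.zeros((4, 4, 3))
        bb[..., 1] = 0.5
        tm = compute_tissue_map(np.zeros((4, 4)), None, t=0.0)
        with pytest.warns(UserWarning, match="all-zero"):
            out = compose_overlay(bb, tm, mask_specular=False)
        np.testing.assert_array_equal(out.rgb[..., 0], 0.0)

    def test_size_mismatch_rejected(self):
        tm = compute_tissue_map(np.zeros((5, 5)), None, t=0.0)
        with pytest.raises(ParameterError):
            compose_overlay(np.zeros((4, 4, 3)), tm)


class TestParameterRecovery:
    def test_auto_threshold_recovers_labels(self, small_scene, small_render, calibration):
        """Otsu auto-threshold on a noise-free 420 nm render segments cholesteatoma."""
        band = small_render.left.band(420)
        raw = spectral.select_analysis_channel(small_render.left.narrowband[band], band)
        refl = spectral.flat_field_correct(raw, calibration.dark, calibration.white[band])
        tm = compute_tissue_map(refl, None, t="auto")
        truth = small_scene.label_map == phantom.Tissue.CHOLESTEATOMA
        assert iou(tm.values > 0, truth) >= 0.90
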