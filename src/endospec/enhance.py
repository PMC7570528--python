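"""Augmented cholesteatoma overlay.

The enhancement adds calibrated narrow-band tissue information to the blue
channel of the broad-band surgical image only, so that cholesteatoma turns
bluish while the red/green content — and with it the familiar colour balance
of the surgical view — is untouched:

    R_res = R_bb / max(R_bb)
    G_res = G_bb / max(G_bb)
    B_res = B_bb / max(B_bb) + B_nb_cal

where ``B_nb_cal`` is the calibrated narrow-band map after ratio
normalisation and thresholding: ``y = B_nb / B_cor`` kept where ``y >= t``
and zeroed below.  Specular highlights (high intensity, low saturation) are
detected with an intensity/saturation threshold pair and excluded from the
added tissue information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ParameterError
from .spectral import BandDefinition, MultispectralSequence, ReflectanceImage

__all__ = [
    "TissueMap",
    "OverlayImage",
    "fourier_denoise",
    "compute_tissue_map",
    "detect_specular",
    "compose_overlay",
]


@dataclass
class TissueMap:
    """Thresholded, calibrated narrow-band tissue response in [0, 1]."""

    values: np.ndarray
    band: BandDefinition | None
    threshold_used: float


@dataclass
class OverlayImage:
    """Augmented RGB overlay; R and G equal the max-normalised broad-band channels."""

    rgb: np.ndarray
    source_view: str
    specular_mask: np.ndarray


def fourier_denoise(image: np.ndarray, cutoff: float = 0.25) -> np.ndarray:
    """Frequency-domain low-pass denoising.

    The image is Fourier transformed and multiplied with a radial Gaussian
    attenuation ``exp(-0.5 (rho / rho_c)^2)`` with ``rho_c = cutoff * Nyquist``
    — a soft roll-off that avoids the ringing of an ideal brick-wall filter.
    The DC component is untouched, so the image mean is preserved.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ParameterError(f"cutoff must lie in (0, 1], got {cutoff}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("fourier_denoise expects a single-channel image")
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    rho = np.hypot(fy, fx)
    rho_c = cutoff * 0.5  # Nyquist is 0.5 cycles/px
    attenuation = np.exp(-0.5 * (rho / rho_c) ** 2)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * attenuation))


def compute_tissue_map(
    reflectance: ReflectanceImage | np.ndarray,
    correction: ReflectanceImage | np.ndarray | None = None,
    t: float | str = "auto",
) -> TissueMap:
    """Ratio-normalise and threshold a narrow-band image.

    Per pixel ``y = B_nb / B_cor``; the output is ``y`` where ``y >= t`` and 0
    elsewhere, clipped to [0, 1].  Pixels where the correction image is 0
    yield 0.  ``correction=None`` means the input is already calibrated
    (divisor 1).  ``t="auto"`` chooses a scene-specific threshold from the
    intensity distribution: Otsu's split of the non-zero ratio histogram,
    matching the bright-cholesteatoma / dark-bone bimodality.
    """
    band = reflectance.band if isinstance(reflectance, ReflectanceImage) else None
    nb = np.asarray(
        reflectance.values if isinstance(reflectance, ReflectanceImage) else reflectance,
        dtype=float,
    )
    if correction is None:
        cor = np.ones_like(nb)
    else:
        cor = np.asarray(
            correction.values if isinstance(correction, ReflectanceImage) else correction,
            dtype=float,
        )
    if cor.shape != nb.shape:
        raise ParameterError(f"size mismatch: narrow-band {nb.shape} vs correction {cor.shape}")
    ratio = np.zeros_like(nb)
    np.divide(nb, cor, out=ratio, where=cor > 0)
    np.clip(ratio, 0.0, 1.0, out=ratio)

    if isinstance(t, str):
        if t != "auto":
            raise ParameterError(f"threshold must be a scalar in [0, 1] or 'auto', got {t!r}")
        nonzero = ratio[ratio > 0]
        if nonzero.size < 2 or np.ptp(nonzero) < 1e-12:
            t_val = 0.0
        else:
            t_val = float(threshold_otsu(nonzero))
    else:
        t_val = float(t)
        if not 0.0 <= t_val <= 1.0:
            raise ParameterError(f"threshold must lie in [0, 1], got {t_val}")
    out = np.where(ratio >= t_val, ratio, 0.0) if t_val > 0 else ratio
    return TissueMap(values=out, band=band, threshold_used=t_val)


def detect_specular(
    rgb: np.ndarray, i_threshold: float = 0.8, s_threshold: float = 0.1
) -> np.ndarray:
    """Classify specular highlight pixels.

    Specular reflections are hue independent, very bright and colourless:
    with intensity ``I = (R+G+B)/3`` and saturation
    ``S = 3/2 (R - I)`` if ``(B + R) >= 2G`` else ``3/2 (I - B)``,
    a pixel is specular when ``I >= i_threshold`` and ``S < s_threshold``.
    """
    for name, v in (("i_threshold", i_threshold), ("s_threshold", s_threshold)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError(f"expected an RGB image (H, W, 3), got shape {rgb.shape}")
    r, g, b = rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2]
    intensity = (r + g + b) / 3.0
    saturation = np.where(b + r >= 2.0 * g, 1.5 * (r - intensity), 1.5 * (intensity - b))
    return (intensity >= i_threshold) & (saturation < s_threshold)


def compose_overlay(
    sequence: MultispectralSequence | np.ndarray,
    tissue_map: TissueMap,
    mask_specular: bool = True,
    specular_dilate_px: int = 1,
    i_threshold: float = 0.8,
    s_threshold: float = 0.1,
) -> OverlayImage:
    """Blend the tissue map into the blue channel of the broad-band frame.

    Each broad-band channel is divided by its own image maximum; the tissue
    map is then added to the normalised blue channel and the sum clipped to 1.
    With ``mask_specular`` the channel maxima are computed outside the
    (dilated) specular mask and the tissue contribution is zeroed on it, so
    highlights neither dim the overlay nor get falsely enhanced.
    """
    if isinstance(sequence, MultispectralSequence):
        broadband = sequence.broadband
        view = sequence.view_id
    else:
        broadband = np.asarray(sequence, dtype=float)
        view = "unknown"
    if broadband.ndim != 3 or broadband.shape[2] != 3:
        raise ParameterError("broadband frame must be (H, W, 3)")
    if tissue_map.values.shape != broadband.shape[:2]:
        raise ParameterError(
            f"size mismatch: broadband {broadband.shape[:2]} vs tissue map "
            f"{tissue_map.values.shape}"
        )
    specular = detect_specular(broadband, i_threshold, s_threshold)
    if mask_specular and specular_dilate_px > 0 and specular.any():
        specular = ndimage.binary_dilation(specular, iterations=specular_dilate_px)

    out = np.empty_like(broadband)
    for c in range(3):
        channel = broadband[:, :, c]
        pool = channel[~specular] if (mask_specular and (~specular).any()) else channel
        peak = float(pool.max()) if pool.size else 0.0
        if peak <= 0.0:
            warnings.warn(f"all-zero broadband channel {c}; using divisor 1", stacklevel=2)
            peak = 1.0
        out[:, :, c] = channel / peak
    tissue = tissue_map.values
    if mask_specular:
        tissue = np.where(specular, 0.0, tissue)
    out[:, :, 2] = np.clip(out[:, :, 2] + tissue, 0.0, 1.0)
    np.clip(out, 0.0, 1.0, out=out)
    return OverlayImage(rgb=out, source_view=view, specular_mask=specular)
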