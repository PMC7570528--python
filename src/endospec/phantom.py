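"""Synthetic middle-ear phantom generator.

Produces every input the processing pipeline consumes, with ground truth:

* stereo multispectral sequences of a depth-varying tissue surface in which
  cholesteatoma reflects markedly more than bone across 400-575 nm,
* per-band dark/white calibration frames,
* sharpness test charts (sinusoidal line charts and concentric-circle charts)
  with exact spatial-frequency annotations.

The renderer is analytic rather than physically based: Lambertian shading
with the light co-located at the reference camera (endoscope coaxial
illumination), a Phong-like specular lobe added equally to all colour
channels, multiplicative albedo texture, and additive Gaussian read noise
plus Poisson shot noise.  Surfaces are height fields over the left-camera
pixel grid, so true disparity and per-camera label maps are available in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .rig import CameraRig
from .spectral import BandDefinition, DEFAULT_BANDS, MultispectralSequence

__all__ = [
    "Tissue",
    "TissueSpectrum",
    "default_spectra",
    "SceneConfig",
    "PhantomScene",
    "make_scene",
    "SensorModel",
    "NoiseModel",
    "StereoRender",
    "render_sequence",
    "apply_distortion",
    "CalibrationFrames",
    "render_calibration_frames",
    "ChartRegion",
    "ChartImage",
    "render_chart",
]


class Tissue(IntEnum):
    BONE = 0
    CHOLESTEATOMA = 1
    SOFT_TISSUE = 2


@dataclass(frozen=True)
class TissueSpectrum:
    """Tabulated diffuse reflectance of one tissue class.

    Reflectance is interpolated piecewise-linearly between the tabulated
    wavelengths and must lie in [0, 1].
    """

    tissue: Tissue
    wavelengths_nm: tuple[float, ...]
    reflectance: tuple[float, ...]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, float)
        r = np.asarray(self.reflectance, float)
        if wl.size != r.size or wl.size < 2:
            raise ParameterError("spectrum needs >= 2 matching wavelength/reflectance samples")
        if np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if r.min() < 0.0 or r.max() > 1.0:
            raise ParameterError("reflectance values must lie in [0, 1]")

    def at(self, wavelength_nm) -> np.ndarray:
        """Reflectance at the given wavelength(s), linear interpolation."""
        return np.interp(wavelength_nm, self.wavelengths_nm, self.reflectance)


def default_spectra(separation_margin: float = 0.15) -> dict[Tissue, TissueSpectrum]:
    """Default per-tissue reflectance curves.

    Only the ordering is constrained by the underlying tissue optics:
    cholesteatoma reflects more than bone throughout 400-575 nm (by at least
    ``separation_margin``), and soft tissue absorbs strongly in the blue.
    Absolute levels are plausible placeholders, not measured values.
    """
    spectra = {
        Tissue.CHOLESTEATOMA: TissueSpectrum(
            Tissue.CHOLESTEATOMA,
            (380, 400, 450, 500, 575, 650, 700),
            (0.52, 0.58, 0.62, 0.66, 0.70, 0.72, 0.72),
        ),
        Tissue.BONE: TissueSpectrum(
            Tissue.BONE,
            (380, 400, 450, 500, 575, 650, 700),
            (0.24, 0.27, 0.31, 0.35, 0.40, 0.46, 0.50),
        ),
        Tissue.SOFT_TISSUE: TissueSpectrum(
            Tissue.SOFT_TISSUE,
            (380, 400, 450, 500, 575, 600, 700),
            (0.07, 0.08, 0.10, 0.12, 0.18, 0.35, 0.45),
        ),
    }
    wl = np.linspace(400.0, 575.0, 176)
    gap = spectra[Tissue.CHOLESTEATOMA].at(wl) - spectra[Tissue.BONE].at(wl)
    if gap.min() < separation_margin:
        raise ParameterError(
            f"cholesteatoma/bone separation {gap.min():.3f} below margin {separation_margin}"
        )
    return spectra


#: Broad-band (white light) RGB albedo per tissue: cholesteatoma and bone both
#: appear white; soft tissue is reddish.
BROADBAND_ALBEDO = {
    Tissue.BONE: (0.88, 0.85, 0.78),
    Tissue.CHOLESTEATOMA: (0.92, 0.90, 0.86),
    Tissue.SOFT_TISSUE: (0.70, 0.32, 0.28),
}


# --------------------------------------------------------------------- scene

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one phantom scene (all randomness derives from ``seed``)."""

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    cholesteatoma_fraction: float = 0.3
    soft_tissue_fraction: float = 0.1
    working_distance_mm: tuple[float, float] = (20.0, 60.0)
    base_distance_mm: float = 40.0
    relief_amplitude_mm: float = 0.4
    relief_scale_px: float = 48.0
    label_scale_px: float = 24.0
    texture_strength: float = 0.05
    texture_scale_px: float = 5.0
    specular_fraction: float = 0.01
    specular_strength: float = 0.5
    sphere_diameter_mm: float | None = None
    sphere_center_px: tuple[float, float] | None = None  # (row, col), default image centre


@dataclass
class PhantomScene:
    """Ground-truth scene: geometry, tissue labels, optics, all on the left grid."""

    height_map: np.ndarray  # (H, W) depth in mm from the reference camera
    label_map: np.ndarray  # (H, W) int, values from Tissue
    spectra: dict[Tissue, TissueSpectrum]
    specular_map: np.ndarray  # (H, W) in [0, 1]
    texture_map: np.ndarray  # (H, W) multiplicative albedo jitter around 1
    rng_seed: int
    config: SceneConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.height_map.shape

    def cholesteatoma_fraction(self) -> float:
        return float(np.mean(self.label_map == Tissue.CHOLESTEATOMA))


def _smooth_field(rng: np.random.Generator, shape, scale_px: float) -> np.ndarray:
    """Zero-mean smooth random field, normalised to unit max absolute value."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale_px, mode="wrap")
    f -= f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_scene(config: SceneConfig = SceneConfig()) -> PhantomScene:
    """Generate a phantom scene; identical config (incl. seed) => identical scene."""
    h, w = config.shape
    if h < 32 or w < 32:
        raise ParameterError(f"image size must be >= 32x32, got {config.shape}")
    frac = config.cholesteatoma_fraction
    if not 0.0 <= frac <= 1.0:
        raise ParameterError(f"cholesteatoma fraction must lie in [0, 1], got {frac}")
    lo, hi = config.working_distance_mm
    if not 0 < lo < hi:
        raise ParameterError(f"invalid working-distance interval {config.working_distance_mm}")
    if not lo <= config.base_distance_mm <= hi:
        raise ParameterError("base_distance_mm outside the working-distance interval")

    rng = np.random.default_rng(config.seed)
    n = h * w

    # Geometry: smooth relief around the base working distance, clipped inside
    # the working-distance interval with a small inset.
    relief = _smooth_field(rng, (h, w), config.relief_scale_px)
    height = config.base_distance_mm + config.relief_amplitude_mm * relief
    inset = 1e-3 * (hi - lo)
    height = np.clip(height, lo + inset, hi - inset)

    if config.sphere_diameter_mm is not None:
        height = _embed_sphere(height, config)

    # Labels: exact top-k thresholding of a smooth field gives blob-shaped
    # regions whose realised pixel fraction matches the request exactly
    # (up to the 1-pixel rounding of k).
    labels = np.full((h, w), int(Tissue.BONE), dtype=np.int8)
    chol_field = _smooth_field(rng, (h, w), config.label_scale_px)
    k = int(round(frac * n))
    if k > 0:
        order = np.argsort(chol_field, axis=None, kind="stable")[::-1]
        labels.flat[order[:k]] = int(Tissue.CHOLESTEATOMA)
    soft_field = _smooth_field(rng, (h, w), config.label_scale_px)
    k_soft = int(round(config.soft_tissue_fraction * n))
    if k_soft > 0:
        free = np.flatnonzero(labels.ravel() == int(Tissue.BONE))
        if free.size:
            order = free[np.argsort(soft_field.ravel()[free], kind="stable")[::-1]]
            labels.flat[order[: min(k_soft, free.size)]] = int(Tissue.SOFT_TISSUE)

    # Specular lobes: smooth bumps rescaled so about `specular_fraction` of
    # pixels carry a non-zero lobe of up to `specular_strength`.
    specular = np.zeros((h, w))
    if config.specular_fraction > 0 and config.specular_strength > 0:
        bump = _smooth_field(rng, (h, w), 4.0)
        thresh = np.quantile(bump, 1.0 - config.specular_fraction)
        lobe = np.clip(bump - thresh, 0.0, None)
        if lobe.max() > 0:
            specular = config.specular_strength * lobe / lobe.max()

    texture = 1.0 + config.texture_strength * _smooth_field(rng, (h, w), config.texture_scale_px)
    np.clip(texture, 0.05, None, out=texture)

    return PhantomScene(
        height_map=height,
        label_map=labels,
        spectra=default_spectra(),
        specular_map=specular,
        texture_map=texture,
        rng_seed=config.seed,
        config=config,
    )


def _embed_sphere(height: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Carve a sphere (front hemisphere toward the camera) into the height field.

    Exact ray-sphere intersection per pixel, using the default rig's focal
    length in pixels so the sphere subtends physically correct pixel extents.
    """
    h, w = height.shape
    rig = CameraRig()
    f_px = rig.f_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0, c0 = config.sphere_center_px if config.sphere_center_px else (cy, cx)
    radius = config.sphere_diameter_mm / 2.0
    zc = config.base_distance_mm
    rows, cols = np.mgrid[0:h, 0:w]
    # Ray through pixel: P(t) = t * (a, b, 1); sphere centre on the ray through
    # (r0, c0) at depth zc.
    a = (cols - cx) / f_px
    b = (rows - cy) / f_px
    xc = (c0 - cx) / f_px * zc
    yc = (r0 - cy) / f_px * zc
    A = a * a + b * b + 1.0
    B = -2.0 * (a * xc + b * yc + zc)
    C = xc * xc + yc * yc + zc * zc - radius * radius
    disc = B * B - 4.0 * A * C
    hit = disc >= 0.0
    t = np.where(hit, (-B - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * A), np.inf)
    return np.minimum(height, np.where(hit, t, np.inf))


# ------------------------------------------------------------------- sensors

@dataclass(frozen=True)
class SensorModel:
    """Linear sensor: code = offset + gain * radiometric signal, clipped to [0, 1]."""

    dark_offset: float = 0.02
    gain: float = 0.75


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise plus Poisson shot noise.

    ``full_well_electrons = 0`` disables shot noise; ``read_sigma = 0``
    disables read noise.  Noise realisations derive from ``seed`` only.
    """

    read_sigma: float = 0.0
    full_well_electrons: float = 0.0
    seed: int = 0

    @property
    def enabled(self) -> bool:
        return self.read_sigma > 0 or self.full_well_electrons > 0


def _apply_noise(img: np.ndarray, noise: NoiseModel | None, rng: np.random.Generator) -> np.ndarray:
    if noise is None or not noise.enabled:
        return np.clip(img, 0.0, 1.0)
    out = np.clip(img, 0.0, 1.0)
    if noise.full_well_electrons > 0:
        out = rng.poisson(out * noise.full_well_electrons) / noise.full_well_electrons
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


# Sensor channel sensitivity vs wavelength: within 400-500 nm only the blue
# channel responds notably; green picks up from ~480 nm, red from ~550 nm.
_SENS_TABLES = {
    "r": ((380, 540, 560, 600, 700), (0.0, 0.0, 0.15, 0.9, 0.9)),
    "g": ((380, 475, 480, 500, 540, 600, 700), (0.0, 0.0, 0.05, 0.30, 0.9, 0.2, 0.0)),
    "b": ((380, 500, 520, 560, 700), (1.0, 1.0, 0.7, 0.05, 0.0)),
}


def channel_sensitivity(wavelength_nm: float) -> tuple[float, float, float]:
    """(R, G, B) relative sensor sensitivity at a narrow-band wavelength."""
    return tuple(
        float(np.interp(wavelength_nm, *_SENS_TABLES[c])) for c in ("r", "g", "b")
    )


# ------------------------------------------------------------------- render

@dataclass
class StereoRender:
    """Rendered stereo multispectral pair plus ground truth (left reference)."""

    left: MultispectralSequence
    right: MultispectralSequence
    true_disparity: np.ndarray  # (H, W) px on the left grid
    labels: dict[str, np.ndarray]  # per camera; -1 marks pixels with no scene content
    shading: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    scene: PhantomScene
    rig: CameraRig


def _sample(field_arr: np.ndarray, rows, cols, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(field_arr, [rows, cols], order=order, mode="nearest")


def _shading_map(height: np.ndarray, f_px: float) -> np.ndarray:
    """Lambertian shading for a light co-located with the camera.

    cos(angle between surface normal and view) for a fronto-parallel-ish
    height field; gradients in mm per mm of image plane at the local depth.
    """
    gy_px, gx_px = np.gradient(height)
    mm_per_px = height / f_px
    gx = gx_px / mm_per_px
    gy = gy_px / mm_per_px
    return 1.0 / np.sqrt(1.0 + gx * gx + gy * gy)


def render_sequence(
    scene: PhantomScene,
    rig: CameraRig,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    noise: NoiseModel | None = None,
    sensor: SensorModel = SensorModel(),
    view_id: str = "phantom",
) -> StereoRender:
    """Render left/right multispectral sequences of a scene with ground truth.

    Narrow-band pixel value before noise is
    ``offset + gain * sens_c(lambda) * radiance * (reflectance * texture * shading
    + specular)``; the broad-band frame uses per-tissue RGB albedos instead of
    the spectra.  The right view is generated by exact inverse warping through
    the true disparity field, so stereo geometry is consistent to numerical
    precision.
    """
    if not bands:
        raise ParameterError("band list must not be empty")
    h, w = scene.shape
    f_px = rig.f_px
    d_true = rig.disparity_for_depth(scene.height_map)
    shading_l = _shading_map(scene.height_map, f_px)

    # Per-camera sample coordinates on the left grid.
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    views: dict[str, dict] = {
        "left": dict(rows=rows, cols=cols, valid=np.ones((h, w), bool))
    }
    # Right view: solve x_l = x_r + d(y, x_l) by fixed-point iteration
    # (d is smooth, the map contracts quickly).
    xl = cols + _sample(d_true, rows, cols)
    for _ in range(25):
        xl = cols + _sample(d_true, rows, np.clip(xl, 0, w - 1))
    valid_r = (xl >= 0) & (xl <= w - 1)
    views["right"] = dict(rows=rows, cols=np.clip(xl, 0, w - 1), valid=valid_r)

    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    sequences: dict[str, MultispectralSequence] = {}
    labels_out: dict[str, np.ndarray] = {}
    shading_out: dict[str, np.ndarray] = {}
    valid_out: dict[str, np.ndarray] = {}

    refl_by_label = {
        band: np.array([scene.spectra[t].at(band.center_nm) for t in Tissue])
        for band in bands
    }
    albedo = np.array([BROADBAND_ALBEDO[t] for t in Tissue])  # (3 labels, 3 channels)

    for cam, v in views.items():
        r_s, c_s, valid = v["rows"], v["cols"], v["valid"]
        label = _sample(scene.label_map.astype(float), r_s, c_s, order=0).astype(int)
        texture = _sample(scene.texture_map, r_s, c_s)
        shading = _sample(shading_l, r_s, c_s)
        specular = _sample(scene.specular_map, r_s, c_s)
        label[~valid] = -1

        def _to_code(radiometric):
            img = sensor.dark_offset + sensor.gain * radiometric
            img[~valid] = sensor.dark_offset
            return img

        bb = np.empty((h, w, 3))
        for c in range(3):
            diffuse = albedo[label, c] * texture * shading
            bb[:, :, c] = _to_code(diffuse + specular)
        bb = _apply_noise(bb, noise, rng)

        nb: dict[BandDefinition, np.ndarray] = {}
        for band in bands:
            sens = channel_sensitivity(band.center_nm)
            refl = refl_by_label[band][label]
            radiometric = band.relative_radiance * (refl * texture * shading + specular)
            frame = np.empty((h, w, 3))
            for c in range(3):
                frame[:, :, c] = _to_code(sens[c] * radiometric)
            nb[band] = _apply_noise(frame, noise, rng)

        sequences[cam] = MultispectralSequence(
            broadband=bb, narrowband=nb, view_id=view_id, camera_id=cam
        )
        labels_out[cam] = label
        shading_out[cam] = shading
        valid_out[cam] = valid

    return StereoRender(
        left=sequences["left"],
        right=sequences["right"],
        true_disparity=d_true,
        labels=labels_out,
        shading=shading_out,
        valid=valid_out,
        scene=scene,
        rig=rig,
    )


def apply_distortion(image: np.ndarray, rig: CameraRig, camera: str) -> np.ndarray:
    """Simulate lens distortion: resample an ideal pinhole image onto the
    distorted pixel grid (the observed image of a real lens)."""
    h, w = image.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    ideal = rig.undistort_points(
        np.stack([cols, rows], axis=-1), camera, image_shape=(h, w)
    )
    coords = [ideal[..., 1], ideal[..., 0]]
    if image.ndim == 2:
        return ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(image[..., c], coords, order=1, mode="nearest")
    return out


# -------------------------------------------------------- calibration frames

@dataclass
class CalibrationFrames:
    dark: np.ndarray
    white: dict[BandDefinition, np.ndarray]


def render_calibration_frames(
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    shape: tuple[int, int] = (256, 256),
    sensor: SensorModel = SensorModel(),
    noise: NoiseModel | None = None,
) -> CalibrationFrames:
    """Dark frame (sensor offset) and per-band white frames (ideal uniform
    reflector, blue channel) for flat-field correction."""
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    dark = _apply_noise(np.full(shape, sensor.dark_offset), noise, rng)
    white = {}
    for band in bands:
        sens_b = channel_sensitivity(band.center_nm)[2]
        level = sensor.dark_offset + sensor.gain * sens_b * band.relative_radiance
        white[band] = _apply_noise(np.full(shape, level), noise, rng)
    return CalibrationFrames(dark=dark, white=white)


# --------------------------------------------------------------------- charts

@dataclass(frozen=True)
class ChartRegion:
    """One annotated chart region at a single spatial frequency."""

    frequency_lpmm: float
    rows: tuple[int, int] | None = None  # bar regions: half-open row bounds
    cols: tuple[int, int] | None = None
    annulus: tuple[float, float, float, float] | None = None  # (cy, cx, r_in, r_out) px


@dataclass
class ChartImage:
    image: np.ndarray
    regions: tuple[ChartRegion, ...]
    kind: str
    pixel_pitch_mm: float
    blur_sigma_mm: float


def render_chart(
    kind: str,
    frequencies: tuple[float, ...],
    blur_sigma: float = 0.0,
    pixel_pitch: float = 0.0025,
    profile: str = "sine",
    width: int = 512,
    region_height: int = 64,
    gap: int = 16,
) -> ChartImage:
    """Render a resolution test chart.

    ``kind`` is ``"line_bars"`` (stacked horizontal regions of vertical
    gratings, one per frequency) or ``"circle_putora"`` (concentric radial
    gratings, finest group innermost).  Frequencies are in lp/mm; the optional
    Gaussian point-spread blur ``blur_sigma`` is in mm.  The default
    ``profile="sine"`` renders full-modulation sinusoidal gratings (as on
    sine-modulated resolution charts); ``profile="square"`` renders binary
    bars.  Gratings are cosine-phase-aligned to their region origin, so at
    frequencies whose period is an even integer number of pixels the sampled
    extrema are exact.
    """
    if not frequencies:
        raise ParameterError("frequency list must not be empty")
    if pixel_pitch <= 0:
        raise ParameterError("pixel_pitch must be positive")
    nyquist = 1.0 / (2.0 * pixel_pitch)
    for f in frequencies:
        if f <= 0:
            raise ParameterError(f"frequency must be positive, got {f}")
        if f >= nyquist:
            raise ParameterError(
                f"frequency {f} lp/mm at or above Nyquist {nyquist:g} lp/mm for "
                f"pixel pitch {pixel_pitch} mm"
            )
    if profile not in ("sine", "square"):
        raise ParameterError(f"unknown profile {profile!r}")
    if kind == "line_bars":
        chart = _render_line_chart(frequencies, pixel_pitch, profile, width, region_height, gap)
    elif kind == "circle_putora":
        chart = _render_circle_chart(frequencies, pixel_pitch, profile)
    else:
        raise ParameterError(f"unknown chart kind {kind!r}")
    image, regions = chart
    if blur_sigma < 0:
        raise ParameterError("blur_sigma must be >= 0")
    if blur_sigma > 0:
        image = ndimage.gaussian_filter(image, blur_sigma / pixel_pitch)
    return ChartImage(
        image=image,
        regions=regions,
        kind=kind,
        pixel_pitch_mm=pixel_pitch,
        blur_sigma_mm=blur_sigma,
    )


def _grating(phase_cycles: np.ndarray, profile: str) -> np.ndarray:
    wave = np.cos(2.0 * np.pi * phase_cycles)
    if profile == "square":
        wave = np.where(wave >= 0, 1.0, -1.0)
    return 0.5 + 0.5 * wave


def _render_line_chart(frequencies, pixel_pitch, profile, width, region_height, gap):
    n = len(frequencies)
    height = n * region_height + (n + 1) * gap
    image = np.full((height, width), 0.5)
    x_mm = np.arange(width) * pixel_pitch
    regions = []
    row = gap
    for f in frequencies:
        image[row : row + region_height, :] = _grating(f * x_mm, profile)[None, :]
        regions.append(
            ChartRegion(frequency_lpmm=float(f), rows=(row, row + region_height), cols=(0, width))
        )
        row += region_height + gap
    return image, tuple(regions)


def _render_circle_chart(frequencies, pixel_pitch, profile):
    freqs = sorted(frequencies, reverse=True)  # finest innermost
    gap_px = 6
    bounds = []
    r = 10.0
    for f in freqs:
        period_px = 1.0 / (f * pixel_pitch)
        width_px = max(3.0 * period_px, 12.0)
        bounds.append((f, r, r + width_px))
        r += width_px + gap_px
    size = int(np.ceil(2 * (r + 8)))
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rad = np.hypot(yy - cy, xx - cx)
    image = np.full((size, size), 0.5)
    regions = []
    for f, r_in, r_out in bounds:
        mask = (rad >= r_in) & (rad < r_out)
        image[mask] = _grating(f * (rad[mask] - r_in) * pixel_pitch, profile)
        regions.append(ChartRegion(frequency_lpmm=float(f), annulus=(cy, cx, r_in, r_out)))
    return image, tuple(regions)
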