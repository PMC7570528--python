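"""Narrow-band reflectance calibration.

The imaging protocol records, per surgical view and per camera, one broad-band
(white light) RGB frame plus one RGB frame per narrow-band illumination
(~20 nm FWHM filters from 400 to 500 nm).  Within 400-500 nm the red channel
of the RGB sensor has no notable sensitivity and the green channel only starts
responding around 480 nm, so the quantitative analysis uses the blue channel
only.  Each raw narrow-band blue image is flat-field corrected with a dark
frame and a per-band white reference: ``(raw - dark) / (white - dark)``,
yielding reflectance in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ParameterError, SequenceLoadError, UnsupportedBandError

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "MultispectralSequence",
    "ReflectanceImage",
    "select_analysis_channel",
    "flat_field_correct",
    "save_sequence",
    "load_sequence",
    "save_reflectance",
]

#: Wavelength range (nm) within which the blue-channel-only analysis is defined.
ANALYSIS_RANGE_NM = (400.0, 500.0)


@dataclass(frozen=True)
class BandDefinition:
    """One narrow-band illumination filter.

    relative_radiance expresses the band's illumination strength relative to
    the brightest band; the short wavelengths (400-440 nm) have markedly lower
    luminous efficiency than 460-500 nm.
    """

    center_nm: float
    fwhm_nm: float = 20.0
    relative_radiance: float = 1.0

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ParameterError("fwhm_nm must be positive")
        if not 0.0 < self.relative_radiance <= 1.0:
            raise ParameterError("relative_radiance must lie in (0, 1]")


#: Default filter set: 400..500 nm in 20 nm steps, FWHM 20 nm, with
#: radiances that fall off toward the deep blue.
DEFAULT_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(center_nm=c, fwhm_nm=20.0, relative_radiance=r)
    for c, r in [(400, 0.25), (420, 0.35), (440, 0.50), (460, 0.70), (480, 0.85), (500, 1.00)]
)


@dataclass
class MultispectralSequence:
    """One broad-band RGB frame plus per-band narrow-band frames of one view."""

    broadband: np.ndarray  # (H, W, 3) float in [0, 1]
    narrowband: dict[BandDefinition, np.ndarray]  # band -> (H, W, 3) float in [0, 1]
    view_id: str = "view0"
    camera_id: str = "left"

    def __post_init__(self):
        shape = self.broadband.shape[:2]
        frames = [("broadband", self.broadband)] + [
            (f"{b.center_nm:g} nm", f) for b, f in self.narrowband.items()
        ]
        for name, f in frames:
            if f.shape[:2] != shape:
                raise ParameterError(f"frame {name} has shape {f.shape[:2]}, expected {shape}")
            if float(f.min()) < 0.0 or float(f.max()) > 1.0:
                raise ParameterError(f"frame {name} has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.broadband.shape[:2]

    @property
    def bands(self) -> list[BandDefinition]:
        return sorted(self.narrowband, key=lambda b: b.center_nm)

    def band(self, center_nm: float) -> BandDefinition:
        """Look a band up by its centre wavelength."""
        for b in self.narrowband:
            if abs(b.center_nm - center_nm) < 1e-9:
                return b
        raise ParameterError(f"no band centred at {center_nm} nm in sequence {self.view_id!r}")


@dataclass
class ReflectanceImage:
    """Calibrated single-channel narrow-band reflectance in [0, 1].

    valid_mask is False wherever the white reference does not exceed the dark
    frame (no usable calibration signal); values are forced to 0 there.
    """

    values: np.ndarray
    band: BandDefinition | None = None
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ParameterError("valid_mask shape differs from values")


def select_analysis_channel(
    frame: np.ndarray, band: BandDefinition, use_green_above_480: bool = False
) -> np.ndarray:
    """Extract the analysis channel of a narrow-band RGB frame.

    For all supported bands (centre in 400-500 nm) this is the blue channel;
    red and green carry no usable signal under these illuminations and are
    discarded.  The green channel does become sensitive from ~480 nm; setting
    ``use_green_above_480`` averages G and B for such bands, but the default
    keeps the blue-channel-only rule.
    """
    lo, hi = ANALYSIS_RANGE_NM
    if not lo <= band.center_nm <= hi:
        raise UnsupportedBandError(
            f"band centre {band.center_nm:g} nm outside supported analysis range "
            f"{lo:g}-{hi:g} nm"
        )
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ParameterError(f"expected an RGB frame (H, W, 3), got shape {frame.shape}")
    blue = frame[:, :, 2]
    if use_green_above_480 and band.center_nm >= 480.0:
        return 0.5 * (frame[:, :, 1] + blue)
    return blue.copy()


def flat_field_correct(
    raw: np.ndarray,
    dark: np.ndarray,
    white: np.ndarray,
    band: BandDefinition | None = None,
    normalize: bool = False,
) -> ReflectanceImage:
    """Dark/white flat-field correction: ``(raw - dark) / (white - dark)``.

    Output is clipped to [0, 1].  Pixels where ``white <= dark`` carry no
    calibration information; they are flagged invalid and set to 0.  With
    ``normalize=True`` the result is additionally scaled by its maximum over
    the valid pixels (per-image max normalization), default off.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    if not raw.shape == dark.shape == white.shape:
        raise ParameterError(
            f"size mismatch: raw {raw.shape}, dark {dark.shape}, white {white.shape}"
        )
    denom = white - dark
    valid = denom > 0
    out = np.zeros_like(raw)
    np.divide(raw - dark, denom, out=out, where=valid)
    np.clip(out, 0.0, 1.0, out=out)
    out[~valid] = 0.0
    if normalize:
        peak = out[valid].max() if valid.any() else 0.0
        if peak > 0:
            out = np.clip(out / peak, 0.0, 1.0)
            out[~valid] = 0.0
    return ReflectanceImage(values=out, band=band, valid_mask=valid)


# ----------------------------------------------------------------------- i/o

def _encode16(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 65535.0).astype(np.uint16)


def save_sequence(seq: MultispectralSequence, directory, stem: str | None = None) -> Path:
    """Write a sequence as 16-bit TIFFs plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{seq.view_id}_{seq.camera_id}"
    bb_name = f"{stem}_broadband.tiff"
    tifffile.imwrite(directory / bb_name, _encode16(seq.broadband))
    entries = []
    for b in seq.bands:
        name = f"{stem}_nb{int(round(b.center_nm)):03d}.tiff"
        tifffile.imwrite(directory / name, _encode16(seq.narrowband[b]))
        entries.append(
            {
                "file": name,
                "center_nm": b.center_nm,
                "fwhm_nm": b.fwhm_nm,
                "relative_radiance": b.relative_radiance,
            }
        )
    manifest = {
        "view_id": seq.view_id,
        "camera_id": seq.camera_id,
        "broadband": bb_name,
        "bands": entries,
    }
    path = directory / f"{stem}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _load_frame(directory: Path, name: str, what: str) -> np.ndarray:
    path = directory / name
    if not path.exists():
        raise SequenceLoadError(f"{what}: frame file not found: {path}")
    img = iio.imread(path)
    if img.dtype == np.uint8:
        scale = 255.0
    elif img.dtype == np.uint16:
        scale = 65535.0
    else:
        raise SequenceLoadError(f"{what}: unsupported dtype {img.dtype} in {path}")
    return img.astype(float) / scale


def load_sequence(manifest_path) -> MultispectralSequence:
    """Load a sequence from its JSON manifest (see :func:`save_sequence`)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise SequenceLoadError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    if "broadband" not in manifest:
        raise SequenceLoadError(f"manifest {manifest_path.name}: missing 'broadband' entry")
    broadband = _load_frame(directory, manifest["broadband"], "broadband")
    bands_meta = manifest.get("bands", [])
    if not bands_meta:
        raise SequenceLoadError(f"manifest {manifest_path.name}: no narrow-band entries")
    narrowband: dict[BandDefinition, np.ndarray] = {}
    for i, entry in enumerate(bands_meta):
        for key in ("file", "center_nm"):
            if key not in entry:
                raise SequenceLoadError(
                    f"manifest {manifest_path.name}: band entry {i} missing {key!r}"
                )
        band = BandDefinition(
            center_nm=float(entry["center_nm"]),
            fwhm_nm=float(entry.get("fwhm_nm", 20.0)),
            relative_radiance=float(entry.get("relative_radiance", 1.0)),
        )
        frame = _load_frame(directory, entry["file"], f"band {band.center_nm:g} nm")
        if frame.shape[:2] != broadband.shape[:2]:
            raise SequenceLoadError(
                f"band {band.center_nm:g} nm: dimensions {frame.shape[:2]} differ "
                f"from broadband {broadband.shape[:2]}"
            )
        narrowband[band] = frame
    return MultispectralSequence(
        broadband=broadband,
        narrowband=narrowband,
        view_id=manifest.get("view_id", manifest_path.stem),
        camera_id=manifest.get("camera_id", "left"),
    )


def save_reflectance(image: ReflectanceImage, path) -> None:
    """Write a reflectance image as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), image.values.astype(np.float32))
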