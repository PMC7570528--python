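"""Stereo camera rig model.

A two-camera pinhole rig with Brown radial-tangential lens distortion and
per-camera rectifying rotations.  The rig is the metric bridge between pixel
coordinates and millimetres: with focal length ``f`` (mm), pixel pitch ``p``
(mm/px) and baseline ``B`` (mm), a scene point at depth ``z`` produces a
horizontal disparity ``d = f/p * B / z`` pixels between the rectified views.

Default constants follow the reference 3D-endoscope: focal length 4.63 mm and
inter-axial distance 4.16 mm.  The sensor pixel pitch is not published for
that device; the default of 0.002 mm is an assumption and is mandatory to
override for metric output on other hardware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ParameterError

__all__ = ["CameraRig", "DEFAULT_FOCAL_LENGTH_MM", "DEFAULT_BASELINE_MM", "DEFAULT_PIXEL_PITCH_MM"]

DEFAULT_FOCAL_LENGTH_MM = 4.63
DEFAULT_BASELINE_MM = 4.16
DEFAULT_PIXEL_PITCH_MM = 0.002

_CAMERAS = ("left", "right")


def _as_dist(coeffs) -> np.ndarray:
    c = np.zeros(5, dtype=float)
    a = np.asarray(coeffs, dtype=float).ravel()
    if a.size > 5:
        raise ParameterError("distortion supports at most 5 coefficients (k1,k2,p1,p2,k3)")
    c[: a.size] = a
    return c


@dataclass
class CameraRig:
    """Calibrated stereo rig (left camera is the reference).

    Coordinate convention: 0-based pixel indices, x right, y down, z forward
    from the left camera; disparity = x_left - x_right >= 0.
    """

    focal_length_mm: float = DEFAULT_FOCAL_LENGTH_MM
    baseline_mm: float = DEFAULT_BASELINE_MM
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    #: (cx, cy) in px per camera; ``None`` means "use the image centre".
    principal_point_left: tuple[float, float] | None = None
    principal_point_right: tuple[float, float] | None = None
    #: Brown coefficients (k1, k2, p1, p2, k3) per camera.
    distortion_left: np.ndarray = field(default_factory=lambda: np.zeros(5))
    distortion_right: np.ndarray = field(default_factory=lambda: np.zeros(5))
    #: Rectifying rotation applied to each camera (3x3, identity = already rectified).
    rect_rotation_left: np.ndarray = field(default_factory=lambda: np.eye(3))
    rect_rotation_right: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        for name in ("focal_length_mm", "baseline_mm", "pixel_pitch_mm"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)!r}")
        self.distortion_left = _as_dist(self.distortion_left)
        self.distortion_right = _as_dist(self.distortion_right)
        self.rect_rotation_left = np.asarray(self.rect_rotation_left, dtype=float).reshape(3, 3)
        self.rect_rotation_right = np.asarray(self.rect_rotation_right, dtype=float).reshape(3, 3)

    # ------------------------------------------------------------------ basic
    @property
    def f_px(self) -> float:
        """Focal length in pixels: focal_length_mm / pixel_pitch_mm."""
        return self.focal_length_mm / self.pixel_pitch_mm

    def principal_point(self, camera: str, image_shape=None) -> tuple[float, float]:
        if camera not in _CAMERAS:
            raise ParameterError(f"camera must be one of {_CAMERAS}, got {camera!r}")
        pp = self.principal_point_left if camera == "left" else self.principal_point_right
        if pp is not None:
            return float(pp[0]), float(pp[1])
        if image_shape is None:
            raise ConfigurationError("principal point unset and no image shape supplied")
        h, w = image_shape[:2]
        return (w - 1) / 2.0, (h - 1) / 2.0

    def distortion(self, camera: str) -> np.ndarray:
        return self.distortion_left if camera == "left" else self.distortion_right

    def rect_rotation(self, camera: str) -> np.ndarray:
        return self.rect_rotation_left if camera == "left" else self.rect_rotation_right

    def has_distortion(self, camera: str) -> bool:
        return bool(np.any(self.distortion(camera)))

    # --------------------------------------------------------------- geometry
    def disparity_for_depth(self, z_mm) -> np.ndarray:
        """True disparity (px) of a point at depth z (mm)."""
        z = np.asarray(z_mm, dtype=float)
        return self.f_px * self.baseline_mm / z

    def depth_for_disparity(self, d_px) -> np.ndarray:
        """Depth z (mm) for disparity d (px); inverse of :meth:`disparity_for_depth`."""
        d = np.asarray(d_px, dtype=float)
        return self.f_px * self.baseline_mm / d

    def project(self, points_mm: np.ndarray, camera: str, image_shape=None) -> np.ndarray:
        """Project Nx3 points (mm, left-camera frame) to ideal pixel coords (x, y)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        cx, cy = self.principal_point(camera, image_shape)
        x = pts[:, 0] - (self.baseline_mm if camera == "right" else 0.0)
        u = self.f_px * x / pts[:, 2] + cx
        v = self.f_px * pts[:, 1] / pts[:, 2] + cy
        return np.stack([u, v], axis=1)

    def back_project(self, cols, rows, z_mm, image_shape=None) -> np.ndarray:
        """Left-camera pixel (col,row) + depth -> 3D point (mm), Nx3."""
        cx, cy = self.principal_point("left", image_shape)
        z = np.asarray(z_mm, dtype=float)
        x = (np.asarray(cols, dtype=float) - cx) * z / self.f_px
        y = (np.asarray(rows, dtype=float) - cy) * z / self.f_px
        return np.stack([x, y, z], axis=-1)

    # ------------------------------------------------------------- distortion
    def distort_points(self, xy_px: np.ndarray, camera: str, image_shape=None) -> np.ndarray:
        """Map ideal (undistorted) pixel coords to observed (distorted) coords."""
        cx, cy = self.principal_point(camera, image_shape)
        k1, k2, p1, p2, k3 = self.distortion(camera)
        xy = np.asarray(xy_px, dtype=float)
        xn = (xy[..., 0] - cx) / self.f_px
        yn = (xy[..., 1] - cy) / self.f_px
        r2 = xn * xn + yn * yn
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
        return np.stack([xd * self.f_px + cx, yd * self.f_px + cy], axis=-1)

    def undistort_points(
        self, xy_px: np.ndarray, camera: str, image_shape=None, iterations: int = 12
    ) -> np.ndarray:
        """Invert :meth:`distort_points` by fixed-point iteration."""
        cx, cy = self.principal_point(camera, image_shape)
        k1, k2, p1, p2, k3 = self.distortion(camera)
        xy = np.asarray(xy_px, dtype=float)
        xd = (xy[..., 0] - cx) / self.f_px
        yd = (xy[..., 1] - cy) / self.f_px
        xn, yn = xd.copy(), yd.copy()
        for _ in range(iterations):
            r2 = xn * xn + yn * yn
            radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
            dx = 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
            dy = p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
            xn = (xd - dx) / radial
            yn = (yd - dy) / radial
        return np.stack([xn * self.f_px + cx, yn * self.f_px + cy], axis=-1)

    # -------------------------------------------------------------------- i/o
    def to_dict(self) -> dict:
        return {
            "focal_length_mm": self.focal_length_mm,
            "baseline_mm": self.baseline_mm,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "principal_point_left": list(self.principal_point_left) if self.principal_point_left else None,
            "principal_point_right": list(self.principal_point_right) if self.principal_point_right else None,
            "distortion_left": self.distortion_left.tolist(),
            "distortion_right": self.distortion_right.tolist(),
            "rect_rotation_left": self.rect_rotation_left.tolist(),
            "rect_rotation_right": self.rect_rotation_right.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        kwargs = dict(d)
        for key in ("principal_point_left", "principal_point_right"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CameraRig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"calibration profile not found: {p}")
        return cls.from_dict(json.loads(p.read_text()))
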