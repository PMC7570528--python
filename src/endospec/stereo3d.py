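"""Stereo reconstruction: rectification, dense sub-pixel disparity, triangulation.

Disparity estimation follows a propagation/random-search scheme (PatchMatch
family): every pixel starts from a random disparity hypothesis; each
iteration lets pixels adopt their neighbours' best hypotheses and try a
random perturbation with an exponentially shrinking radius; hypotheses are
scored with zero-mean normalised cross-correlation (ZNCC) over a local
window.  A final parabola fit over the cost at d-1, d, d+1 refines the
winner to sub-pixel precision, and a left-right consistency check marks
inconsistent (occluded/unmatched) pixels invalid.

Triangulation of a rectified rig is closed form: ``z = f_px * B / d``,
``x = (col - cx) z / f_px``, ``y = (row - cy) z / f_px`` in the left-camera
frame, millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .enhance import OverlayImage, TissueMap
from .errors import ConfigurationError, MeasurementError, ParameterError
from .rig import CameraRig

__all__ = [
    "DisparityMap",
    "SpectralPointCloud",
    "rectify_pair",
    "estimate_disparity",
    "triangulate",
    "measure_distance",
    "attach_spectral",
    "write_ply",
]


@dataclass
class DisparityMap:
    """Dense left-reference disparity in px; NaN marks invalid pixels."""

    values: np.ndarray
    min_disparity: float = 0.0
    search_range: float = 0.0
    reference: str = "left"

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SpectralPointCloud:
    """Triangulated points (mm, left-camera frame) with optional spectral attributes."""

    points: np.ndarray  # (N, 3) float
    pixels: np.ndarray  # (N, 2) int (row, col) source pixel
    colors: np.ndarray | None = None  # (N, 3) float in [0, 1]
    tissue: np.ndarray | None = None  # (N,) float
    index_map: np.ndarray | None = field(default=None, repr=False)  # (H, W) int, -1 invalid

    def __len__(self) -> int:
        return self.points.shape[0]

    def point_at(self, pixel: tuple[int, int]) -> np.ndarray:
        if self.index_map is None:
            raise MeasurementError("point cloud carries no pixel index map")
        row, col = int(pixel[0]), int(pixel[1])
        h, w = self.index_map.shape
        if not (0 <= row < h and 0 <= col < w):
            raise MeasurementError(f"pixel {(row, col)} outside the image")
        idx = self.index_map[row, col]
        if idx < 0:
            raise MeasurementError(f"pixel {(row, col)} has no valid 3D point")
        return self.points[idx]


# -------------------------------------------------------------- rectification

def _warp(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    coords = [ys, xs]
    if image.ndim == 2:
        return ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(image[..., c], coords, order=1, mode="nearest")
    return out


def _rectify_one(image: np.ndarray, rig: CameraRig, camera: str) -> np.ndarray:
    h, w = image.shape[:2]
    cx, cy = rig.principal_point(camera, (h, w))
    f = rig.f_px
    rot = rig.rect_rotation(camera)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if np.allclose(rot, np.eye(3)):
        xs, ys = cols, rows
    else:
        # Destination (rectified) pixel -> ray in rectified frame -> rotate back.
        rays = np.stack(
            [(cols - cx) / f, (rows - cy) / f, np.ones_like(cols)], axis=-1
        )
        back = rays @ rot  # rot^T applied to each ray
        xs = back[..., 0] / back[..., 2] * f + cx
        ys = back[..., 1] / back[..., 2] * f + cy
    if rig.has_distortion(camera):
        dist = rig.distort_points(np.stack([xs, ys], axis=-1), camera, (h, w))
        xs, ys = dist[..., 0], dist[..., 1]
    if np.array_equal(xs, cols) and np.array_equal(ys, rows):
        return image.copy()
    return _warp(image, xs, ys)


def rectify_pair(
    left: np.ndarray, right: np.ndarray, rig: CameraRig
) -> tuple[np.ndarray, np.ndarray]:
    """Undistort and rectify a stereo pair so epipolar lines are horizontal.

    Consumes the rig's calibration (distortion coefficients and rectifying
    rotations); with zero distortion and identity rotations the images pass
    through unchanged.
    """
    if rig is None:
        raise ConfigurationError("rectification requires a calibrated rig")
    if left.shape != right.shape:
        raise ParameterError(f"left/right shape mismatch: {left.shape} vs {right.shape}")
    return _rectify_one(left, rig, "left"), _rectify_one(right, rig, "right")


# ------------------------------------------------------------------ disparity

def _gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return img.mean(axis=2) if img.ndim == 3 else img


_BAD_COST = 4.0


def _shift_cost(left: np.ndarray, right: np.ndarray, d: int, window: int) -> np.ndarray:
    """Per-pixel ``1 - ZNCC`` window cost of the constant disparity hypothesis d.

    The right image is shifted by the integer disparity so every pixel's
    window is compared against a window warped with the *same* hypothesis.
    Pixels whose correspondence falls outside the right image get _BAD_COST.
    """
    h, w = left.shape
    warped = np.empty_like(right)
    if d > 0:
        warped[:, d:] = right[:, :-d]
        warped[:, :d] = right[:, :1]
    elif d < 0:
        warped[:, :d] = right[:, -d:]
        warped[:, d:] = right[:, -1:]
    else:
        warped = right
    m_l = ndimage.uniform_filter(left, window)
    m_w = ndimage.uniform_filter(warped, window)
    m_lw = ndimage.uniform_filter(left * warped, window)
    var_l = np.clip(ndimage.uniform_filter(left * left, window) - m_l * m_l, 0.0, None)
    var_w = np.clip(ndimage.uniform_filter(warped * warped, window) - m_w * m_w, 0.0, None)
    ncc = (m_lw - m_l * m_w) / (np.sqrt(var_l * var_w) + 1e-12)
    cost = (1.0 - np.clip(ncc, -1.0, 1.0)).astype(np.float32)
    if d > 0:
        cost[:, :d] = _BAD_COST
    elif d < 0:
        cost[:, d:] = _BAD_COST
    return cost


def _patchmatch(
    left: np.ndarray,
    right: np.ndarray,
    search_range: int,
    min_disparity: int,
    iterations: int,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer propagation/random-search matching + parabolic sub-pixel refinement.

    Candidate hypotheses are scored against per-disparity constant-shift ZNCC
    cost images (precomputed over the search window, which is moderate by
    construction); the iteration itself is the PatchMatch scheme: random
    initialisation, adoption of neighbour hypotheses, and a random
    perturbation with exponentially shrinking radius.
    """
    h, w = left.shape
    lo, hi = min_disparity, min_disparity + search_range
    # Cost volume over the integer search window (+1 on both sides for the
    # final parabola fit).
    ds = np.arange(lo - 1, hi + 2)
    volume = np.stack([_shift_cost(left, right, int(d), window) for d in ds])

    rows, cols = np.mgrid[0:h, 0:w]

    def cost_of(field: np.ndarray) -> np.ndarray:
        return volume[field - (lo - 1), rows, cols]

    disp = rng.integers(lo, hi + 1, size=(h, w))
    cost = cost_of(disp)
    shifts = [(0, 1), (0, -1), (1, 0), (-1, 0), (0, 3), (0, -3)]
    for it in range(iterations):
        candidates = [np.roll(disp, (dy, dx), axis=(0, 1)) for dy, dx in shifts]
        radius = max(1, int(round(search_range * 0.5**it)))
        candidates.append(
            np.clip(disp + rng.integers(-radius, radius + 1, size=(h, w)), lo, hi)
        )
        for cand in candidates:
            c_cost = cost_of(cand)
            better = c_cost < cost
            disp[better] = cand[better]
            cost[better] = c_cost[better]

    # Parabola through the cost at d-1, d, d+1.
    cm = cost_of(disp - 1)
    cp = cost_of(disp + 1)
    denom = cm - 2.0 * cost + cp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = 0.5 * (cm - cp) / denom
    offset = np.where((denom > 1e-12) & np.isfinite(offset), offset, 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    return disp.astype(float) + offset, np.asarray(cost, dtype=float)


def estimate_disparity(
    left: np.ndarray,
    right: np.ndarray,
    search_range: int = 64,
    iterations: int = 10,
    seed: int = 0,
    window: int = 9,
    min_disparity: int = 0,
    lr_check: bool = True,
    lr_tolerance: float = 1.0,
    max_cost: float = 0.5,
) -> DisparityMap:
    """Dense sub-pixel disparity between a rectified pair (left reference).

    Searches ``[min_disparity, min_disparity + search_range]``; for a rig with
    a large standoff disparity, set ``min_disparity`` near the disparity of
    the expected working distance.  Fixed ``seed`` gives identical results.
    Pixels failing the left-right consistency check (tolerance
    ``lr_tolerance`` px) or whose best matching cost exceeds ``max_cost``
    (texture-free or saturated windows, where ZNCC carries no signal) are NaN.
    """
    gl, gr = _gray(left), _gray(right)
    if gl.shape != gr.shape:
        raise ParameterError(f"left/right shape mismatch: {gl.shape} vs {gr.shape}")
    if search_range <= 0:
        raise ParameterError("search_range must be positive")
    if min_disparity + search_range >= gl.shape[1]:
        raise ParameterError(
            f"search range [{min_disparity}, {min_disparity + search_range}] exceeds "
            f"image width {gl.shape[1]}"
        )
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be an odd integer >= 3")

    rng = np.random.default_rng(seed)
    disp, cost = _patchmatch(gl, gr, search_range, min_disparity, iterations, window, rng)
    values = np.where(cost <= max_cost, disp, np.nan)

    if lr_check:
        # Right-reference disparity via the mirrored problem: flipping both
        # images horizontally and swapping roles turns right-reference
        # matching into the same left-reference computation.
        rng_r = np.random.default_rng(seed + 1)
        disp_r, _ = _patchmatch(
            gr[:, ::-1], gl[:, ::-1], search_range, min_disparity, iterations, window, rng_r
        )
        disp_r = disp_r[:, ::-1]
        h, w = gl.shape
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        xr = np.clip(cols - values, 0, w - 1)
        d_r_at_match = ndimage.map_coordinates(disp_r, [rows, xr], order=1, mode="nearest")
        inconsistent = np.abs(values - d_r_at_match) > lr_tolerance
        values = np.where(inconsistent, np.nan, values)

    return DisparityMap(
        values=values,
        min_disparity=float(min_disparity),
        search_range=float(search_range),
    )


# -------------------------------------------------------------- triangulation

def triangulate(
    disparity: DisparityMap,
    rig: CameraRig,
    min_valid_disparity: float = 0.5,
) -> SpectralPointCloud:
    """Triangulate a disparity map to a metric point cloud (left-camera frame).

    ``z = f_px * B / d``; pixels with ``d <= min_valid_disparity`` (depth
    diverges) or invalid disparity are dropped.
    """
    d = disparity.values
    h, w = d.shape
    keep = np.isfinite(d) & (d > min_valid_disparity)
    if not keep.any():
        warnings.warn("all disparities invalid; returning empty point cloud", stacklevel=2)
        return SpectralPointCloud(
            points=np.empty((0, 3)),
            pixels=np.empty((0, 2), dtype=int),
            index_map=np.full((h, w), -1, dtype=np.int64),
        )
    rows, cols = np.nonzero(keep)
    z = rig.f_px * rig.baseline_mm / d[rows, cols]
    pts = rig.back_project(cols, rows, z, image_shape=(h, w))
    index_map = np.full((h, w), -1, dtype=np.int64)
    index_map[rows, cols] = np.arange(rows.size)
    return SpectralPointCloud(
        points=pts,
        pixels=np.stack([rows, cols], axis=1),
        index_map=index_map,
    )


def measure_distance(
    cloud: SpectralPointCloud, pixel_a: tuple[int, int], pixel_b: tuple[int, int]
) -> float:
    """Euclidean distance in mm between the 3D points under two pixels."""
    pa = cloud.point_at(pixel_a)
    pb = cloud.point_at(pixel_b)
    return float(np.linalg.norm(pa - pb))


def attach_spectral(
    cloud: SpectralPointCloud,
    overlay: OverlayImage | np.ndarray,
    tissue_map: TissueMap | np.ndarray,
    only_cholesteatoma: bool = False,
) -> SpectralPointCloud:
    """Sample overlay colour and tissue value at each point's source pixel.

    ``only_cholesteatoma`` keeps only points whose tissue value is positive
    (masking out non-relevant tissue areas in the 3D view).
    """
    rgb = overlay.rgb if isinstance(overlay, OverlayImage) else np.asarray(overlay)
    tissue = tissue_map.values if isinstance(tissue_map, TissueMap) else np.asarray(tissue_map)
    if cloud.index_map is None:
        raise ParameterError("point cloud carries no pixel index map")
    shape = cloud.index_map.shape
    if rgb.shape[:2] != shape or tissue.shape != shape:
        raise ParameterError(
            f"size mismatch: cloud {shape}, overlay {rgb.shape[:2]}, tissue {tissue.shape}"
        )
    rows, cols = cloud.pixels[:, 0], cloud.pixels[:, 1]
    colors = rgb[rows, cols]
    tvals = tissue[rows, cols]
    if not only_cholesteatoma:
        return SpectralPointCloud(
            points=cloud.points,
            pixels=cloud.pixels,
            colors=colors,
            tissue=tvals,
            index_map=cloud.index_map,
        )
    keep = tvals > 0
    index_map = np.full(shape, -1, dtype=np.int64)
    index_map[rows[keep], cols[keep]] = np.arange(int(keep.sum()))
    return SpectralPointCloud(
        points=cloud.points[keep],
        pixels=cloud.pixels[keep],
        colors=colors[keep],
        tissue=tvals[keep],
        index_map=index_map,
    )


# ------------------------------------------------------------------------ ply

def write_ply(cloud: SpectralPointCloud, path) -> None:
    """Write a binary little-endian PLY: xyz float32 (mm), RGB uint8, tissue float32."""
    n = len(cloud)
    colors = cloud.colors if cloud.colors is not None else np.ones((n, 3))
    tissue = cloud.tissue if cloud.tissue is not None else np.zeros(n)
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "property float tissue\n"
        "end_header\n"
    )
    rgb8 = np.round(np.clip(colors, 0.0, 1.0) * 255.0).astype(np.uint8)
    rec = np.empty(
        n,
        dtype=np.dtype(
            [
                ("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                ("red", "u1"), ("green", "u1"), ("blue", "u1"),
                ("tissue", "<f4"),
            ]
        ),
    )
    rec["x"], rec["y"], rec["z"] = (cloud.points[:, i].astype("<f4") for i in range(3))
    rec["red"], rec["green"], rec["blue"] = (rgb8[:, i] for i in range(3))
    rec["tissue"] = tissue.astype("<f4")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())
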