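"""Rectification, disparity estimation, triangulation, measurement, PLY export."""

import numpy as np
import pytest
from scipy import ndimage

from endospec import phantom, stereo3d
from endospec.errors import MeasurementError, ParameterError
from endospec.phantom import SceneConfig, make_scene, render_sequence
from endospec.rig import CameraRig
from endospec.stereo3d import (
    DisparityMap,
    estimate_disparity,
    measure_distance,
    rectify_pair,
    triangulate,
    write_ply,
)


class TestRig:
    def test_focal_length_in_pixels(self, rig):
        assert rig.f_px == pytest.approx(4.63 / 0.002)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            CameraRig(baseline_mm=-1.0)

    def test_json_round_trip(self, tmp_path, rig):
        path = tmp_path / "rig.json"
        rig.save(path)
        loaded = CameraRig.load(path)
        assert loaded.focal_length_mm == rig.focal_length_mm
        np.testing.assert_array_equal(loaded.distortion_left, rig.distortion_left)


class TestRectification:
    def test_identity_rig_passes_images_through(self, rig):
        rng = np.random.default_rng(0)
        left = rng.uniform(0, 1, (32, 32))
        right = rng.uniform(0, 1, (32, 32))
        out_l, out_r = rectify_pair(left, right, rig)
        np.testing.assert_array_equal(out_l, left)
        np.testing.assert_array_equal(out_r, right)

    @staticmethod
    def _line_centroids(image, cols):
        """Sub-pixel row position of dark horizontal lines, per sampled column."""
        rows = []
        for c in cols:
            profile = 1.0 - image[:, c]
            r = np.argmax(profile)
            window = profile[max(0, r - 3) : r + 4]
            offs = np.arange(max(0, r - 3), r + 4)
            rows.append((window * offs).sum() / window.sum())
        return np.array(rows)

    def test_distorted_lines_straight_after_rectification(self):
        # A wide-angle rig (large pixel pitch -> small f_px) with barrel distortion.
        rig = CameraRig(pixel_pitch_mm=0.02, distortion_left=[-0.25, 0.0, 0.0, 0.0, 0.0])
        h = w = 256
        ideal = np.ones((h, w))
        ideal[60, :] = 0.0  # a straight scene line off-centre
        ideal = ndimage.gaussian_filter(ideal, 1.0)
        observed = phantom.apply_distortion(ideal, rig, "left")
        cols = np.arange(16, w - 16, 8)
        curved = self._line_centroids(observed, cols)
        assert curved.max() - curved.min() > 2.0  # distortion clearly bends the line
        rectified, _ = rectify_pair(observed, observed, rig)
        straight = self._line_centroids(rectified, cols)
        assert straight.max() - straight.min() < 0.5

    def test_vertical_disparity_removed_by_rectifying_rotation(self):
        # Right camera rotated slightly about the optical axis.
        angle = np.deg2rad(0.8)
        rot = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0.0],
                [np.sin(angle), np.cos(angle), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rig = CameraRig(pixel_pitch_mm=0.02, rect_rotation_right=rot)
        h = w = 256
        cx = cy = (w - 1) / 2.0
        f = rig.f_px
        rng = np.random.default_rng(1)
        dots = np.stack([rng.uniform(40, 216, 12), rng.uniform(40, 216, 12)], axis=1)
        ideal = np.zeros((h, w))
        for x, y in dots:
            yy, xx = np.mgrid[0:h, 0:w]
            ideal += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / 4.0)
        # Simulated observed image: the inverse warp of what rectification applies.
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        rays = np.stack([(cols - cx) / f, (rows - cy) / f, np.ones_like(cols)], axis=-1)
        fwd = rays @ rot.T
        xs = fwd[..., 0] / fwd[..., 2] * f + cx
        ys = fwd[..., 1] / fwd[..., 2] * f + cy
        observed = ndimage.map_coordinates(ideal, [ys, xs], order=1, mode="nearest")
        _, rectified = rectify_pair(observed, observed, rig)
        for x, y in dots:
            patch = rectified[int(y) - 5 : int(y) + 6, int(x) - 5 : int(x) + 6]
            yy = np.mgrid[int(y) - 5 : int(y) + 6, 0:11][0]
            y_centroid = (patch.sum(axis=1) * yy[:, 0]).sum() / patch.sum()
            assert abs(y_centroid - y) < 0.5


class TestEstimateDisparity:
    def test_identical_pair_zero_disparity(self):
        rng = np.random.default_rng(2)
        img = ndimage.gaussian_filter(rng.standard_normal((64, 96)), 1.5)
        img = 0.5 + 0.4 * img / np.abs(img).max()
        dm = estimate_disparity(img, img, search_range=8, seed=0)
        assert np.nanmedian(np.abs(dm.values[dm.valid])) < 0.1

    def test_subpixel_shift_recovered(self):
        rng = np.random.default_rng(3)
        tex = ndimage.gaussian_filter(rng.standard_normal((96, 256)), 2.0)
        tex = 0.5 + 0.4 * tex / np.abs(tex).max()
        rows, cols = np.mgrid[0:96, 0:256].astype(float)
        right = ndimage.map_coordinates(tex, [rows, cols + 7.25], order=3, mode="nearest")
        dm = estimate_disparity(tex, right, search_range=16, seed=1)
        assert np.nanmedian(dm.values[dm.valid]) == pytest.approx(7.25, abs=0.2)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        tex = ndimage.gaussian_filter(rng.standard_normal((48, 96)), 1.5)
        a = estimate_disparity(tex, tex, search_range=8, seed=9)
        b = estimate_disparity(tex, tex, search_range=8, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_search_range_exceeding_width_rejected(self):
        with pytest.raises(ParameterError):
            estimate_disparity(np.zeros((16, 32)), np.zeros((16, 32)), search_range=40)


class TestTriangulate:
    def test_closed_form_depth(self):
        rig = CameraRig(focal_length_mm=2.0, pixel_pitch_mm=0.002, baseline_mm=4.16)
        assert rig.f_px == 1000.0
        d = np.full((8, 8), 104.0)
        cloud = triangulate(DisparityMap(values=d), rig)
        np.testing.assert_allclose(cloud.points[:, 2], 40.0)

    def test_small_disparity_dropped(self, rig):
        d = np.full((4, 4), 10.0)
        d[0, 0] = 0.5
        d[0, 1] = 0.2
        d[0, 2] = np.nan
        cloud = triangulate(DisparityMap(values=d), rig)
        assert len(cloud) == 13
        assert cloud.index_map[0, 0] == -1

    def test_all_invalid_gives_empty_cloud_with_warning(self, rig):
        with pytest.warns(UserWarning, match="invalid"):
            cloud = triangulate(DisparityMap(values=np.full((4, 4), np.nan)), rig)
        assert len(cloud) == 0

    def test_projection_triangulation_round_trip(self, rig):
        rng = np.random.default_rng(5)
        pts = np.stack(
            [rng.uniform(-3, 3, 20), rng.uniform(-2, 2, 20), rng.uniform(25, 55, 20)], axis=1
        )
        uv_l = rig.project(pts, "left", (128, 128))
        uv_r = rig.project(pts, "right", (128, 128))
        assert np.allclose(uv_l[:, 1], uv_r[:, 1])  # rectified: same rows
        disp = uv_l[:, 0] - uv_r[:, 0]
        z = rig.depth_for_disparity(disp)
        rec = rig.back_project(uv_l[:, 0], uv_l[:, 1], z, (128, 128))
        np.testing.assert_allclose(rec, pts, atol=1e-6)

    def test_depth_disparity_product_invariant(self, rig):
        rng = np.random.default_rng(6)
        d = rng.uniform(150, 400, (16, 16))
        cloud = triangulate(DisparityMap(values=d), rig)
        rows, cols = cloud.pixels[:, 0], cloud.pixels[:, 1]
        np.testing.assert_allclose(
            cloud.points[:, 2] * d[rows, cols], rig.f_px * rig.baseline_mm, rtol=1e-12
        )

    def test_larger_disparity_means_smaller_depth(self, rig):
        z1 = rig.depth_for_disparity(200.0)
        z2 = rig.depth_for_disparity(250.0)
        assert z2 < z1


class TestMeasureDistance:
    def _cloud(self, rig):
        d = np.full((8, 8), 200.0)
        return triangulate(DisparityMap(values=d), rig)

    def test_same_pixel_zero(self, rig):
        cloud = self._cloud(rig)
        assert measure_distance(cloud, (2, 2), (2, 2)) == 0.0

    def test_three_four_five_triangle(self):
        cloud = stereo3d.SpectralPointCloud(
            points=np.array([[0.0, 0.0, 40.0], [3.0, 4.0, 40.0]]),
            pixels=np.array([[0, 0], [0, 1]]),
            index_map=np.array([[0, 1]]),
        )
        assert measure_distance(cloud, (0, 0), (0, 1)) == pytest.approx(5.0)

    def test_invalid_pixel_named_in_error(self, rig):
        d = np.full((8, 8), 200.0)
        d[3, 3] = np.nan
        cloud = triangulate(DisparityMap(values=d), rig)
        with pytest.raises(MeasurementError, match=r"\(3, 3\)"):
            measure_distance(cloud, (0, 0), (3, 3))


class TestAttachSpectral:
    def _setup(self, rig):
        d = np.full((8, 8), 200.0)
        cloud = triangulate(DisparityMap(values=d), rig)
        tissue = np.zeros((8, 8))
        tissue[:, 4:] = 0.7
        overlay = np.random.default_rng(7).uniform(0, 1, (8, 8, 3))
        return cloud, overlay, tissue

    def test_attachment_preserves_point_count(self, rig):
        cloud, overlay, tissue = self._setup(rig)
        out = stereo3d.attach_spectral(cloud, overlay, tissue)
        assert len(out) == len(cloud)
        np.testing.assert_array_equal(out.colors, overlay.reshape(-1, 3))

    def test_filter_keeps_only_tissue_points(self, rig):
        cloud, overlay, tissue = self._setup(rig)
        out = stereo3d.attach_spectral(cloud, overlay, tissue, only_cholesteatoma=True)
        assert len(out) == 32
        assert np.all(out.tissue > 0)

    def test_filter_on_empty_tissue_map_gives_empty_cloud(self, rig):
        cloud, overlay, _ = self._setup(rig)
        out = stereo3d.attach_spectral(
            cloud, overlay, np.zeros((8, 8)), only_cholesteatoma=True
        )
        assert len(out) == 0

    def test_kept_fraction_matches_label_fraction(self, small_render, rig):
        """On a phantom, filtered point share tracks the cholesteatoma pixel share."""
        labels = small_render.labels["left"]
        d = small_render.true_disparity.copy()
        d[:, :260] = np.nan  # only the stereo-visible part
        cloud = triangulate(DisparityMap(values=d), rig)
        tissue = (labels == phantom.Tissue.CHOLESTEATOMA).astype(float)
        out = stereo3d.attach_spectral(cloud, np.zeros(labels.shape + (3,)), tissue,
                                       only_cholesteatoma=True)
        valid = np.isfinite(d)
        expected = (tissue[valid] > 0).mean()
        assert len(out) / len(cloud) == pytest.approx(expected, abs=0.05)


class TestPly:
    def test_written_ply_parses_back(self, tmp_path, rig):
        d = np.full((4, 4), 200.0)
        cloud = triangulate(DisparityMap(values=d), rig)
        cloud = stereo3d.attach_spectral(
            cloud, np.full((4, 4, 3), 0.5), np.full((4, 4), 0.25)
        )
        path = tmp_path / "cloud.ply"
        write_ply(cloud, path)
        blob = path.read_bytes()
        header, _, body = blob.partition(b"end_header\n")
        assert b"element vertex 16" in header
        rec = np.frombuffer(
            body,
            dtype=np.dtype(
                [
                    ("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                    ("red", "u1"), ("green", "u1"), ("blue", "u1"),
                    ("tissue", "<f4"),
                ]
            ),
        )
        assert rec.shape[0] == 16
        np.testing.assert_allclose(rec["z"], cloud.points[:, 2].astype(np.float32))
        assert np.all(rec["red"] == 128)
        np.testing.assert_allclose(rec["tissue"], 0.25)


class TestEndToEndGeometry:
    def test_sphere_chord_measurement(self, rig):
        """A 10 mm phantom sphere: the 9 mm symmetric chord is recovered to 0.1 mm."""
        wd = 40.0
        cfg = SceneConfig(
            seed=21,
            shape=(192, 896),
            cholesteatoma_fraction=0.3,
            base_distance_mm=wd,
            relief_amplitude_mm=0.2,
            texture_strength=0.2,
            texture_scale_px=3.0,
            sphere_diameter_mm=10.0,
            sphere_center_px=(95.5, 580.0),
            specular_fraction=0.0,
        )
        scene = make_scene(cfg)
        render = render_sequence(scene, rig)
        d_lo = int(np.floor(rig.disparity_for_depth(wd + 1.0)))
        d_hi = int(np.ceil(rig.disparity_for_depth(wd - 6.0)))
        dm = estimate_disparity(
            render.left.broadband,
            render.right.broadband,
            search_range=d_hi - d_lo + 4,
            min_disparity=d_lo - 2,
            seed=3,
        )
        cloud = triangulate(dm, rig)
        # Chord endpoints at radius 4.5 mm on the sphere's centre row.
        # Chord endpoints: project the two sphere-surface points at
        # x = xc -+ 4.5 mm, y = yc, z = zc - sqrt(r^2 - 4.5^2) into the left view.
        h, w = cfg.shape
        cx, cy = rig.principal_point("left", (h, w))
        r0, c0 = cfg.sphere_center_px
        xc = (c0 - cx) / rig.f_px * wd
        yc = (r0 - cy) / rig.f_px * wd
        z_chord = wd - np.sqrt(5.0**2 - 4.5**2)
        ends = np.array([[xc - 4.5, yc, z_chord], [xc + 4.5, yc, z_chord]])
        uv = rig.project(ends, "left", (h, w))

        def valid_pixel(u, inward):
            col = int(round(u[0]))
            for dc in range(6):  # nudge inwards off occasional invalidated pixels
                candidate = (int(round(u[1])), col + inward * dc)
                if cloud.index_map[candidate] >= 0:
                    return candidate
            raise AssertionError(f"no valid disparity near column {col}")

        a = valid_pixel(uv[0], +1)
        b = valid_pixel(uv[1], -1)
        measured = measure_distance(cloud, a, b)
        truth = np.linalg.norm(
            rig.back_project(a[1], a[0], scene.height_map[a], cfg.shape)
            - rig.back_project(b[1], b[0], scene.height_map[b], cfg.shape)
        )
        assert truth == pytest.approx(9.0, abs=0.2)  # chord geometry, up to pixel nudges
        assert measured == pytest.approx(truth, abs=0.1)
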