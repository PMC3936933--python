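"""Software rasterization, cameras, stereo compositing, labels."""

import numpy as np
import pytest

from molcanvas import (
    Camera,
    build_primary,
    default_camera,
    draw_labels,
    project,
    rasterize,
    render_anaglyph,
)
from molcanvas.errors import BehindCameraError
from molcanvas.representations import GeometryBatch


def ortho_camera(half_height=10.0):
    return Camera(kind="orthographic", eye=np.array([0.0, 0.0, 50.0]),
                  target=np.zeros(3), half_height=half_height,
                  near=0.1, far=200.0)


def triangle_batch(vertices, color=(1.0, 0.0, 0.0)):
    vertices = np.asarray(vertices, dtype=float)
    return GeometryBatch(
        kind="triangles", positions=vertices,
        colors=np.tile(color, (len(vertices), 1)),
        indices=np.arange(len(vertices)).reshape(-1, 3),
        source_atoms=np.zeros(len(vertices), dtype=np.int64),
        normals=np.tile([0.0, 0.0, 1.0], (len(vertices), 1)))


class TestProject:
    def test_target_projects_to_center(self):
        x, y, _ = project(ortho_camera(), np.zeros(3), (200, 100))
        assert (x, y) == pytest.approx((99.5, 49.5))

    def test_half_height_offset_reaches_top_edge(self):
        cam = ortho_camera(half_height=10.0)
        _, y, _ = project(cam, np.array([0.0, 10.0, 0.0]), (200, 100))
        assert y == pytest.approx(0.0)

    def test_orthographic_depth_linear(self):
        cam = ortho_camera()
        depths = [project(cam, np.array([0.0, 0.0, z]), (100, 100))[2]
                  for z in (40.0, 0.0, -40.0)]
        diffs = np.diff(depths)
        assert diffs[0] == pytest.approx(diffs[1])
        assert depths[0] < depths[1] < depths[2]

    def test_point_behind_perspective_eye_raises(self):
        cam = Camera(kind="perspective", eye=np.array([0.0, 0.0, 10.0]),
                     target=np.zeros(3))
        with pytest.raises(BehindCameraError):
            project(cam, np.array([0.0, 0.0, 20.0]), (100, 100))


class TestRasterize:
    def test_empty_scene_is_background(self):
        img = rasterize([], ortho_camera(), 32, 24, background="white")
        assert np.all(img.pixels == 255)
        grey = rasterize([], ortho_camera(), 8, 8, background="grey")
        assert np.all(grey.pixels == 128)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            rasterize([], ortho_camera(), 8, 8, background="mauve")

    def test_triangle_fill_matches_halfplane_oracle(self):
        cam = ortho_camera(half_height=10.0)
        batch = triangle_batch([[-5, -5, 0], [5, -5, 0], [0, 6, 0]])
        img = rasterize(batch, cam, 100, 100, background="white")
        filled = np.count_nonzero(np.any(img.pixels != 255, axis=2))
        # oracle: count pixel centers inside the projected triangle
        pts = np.array([project(cam, v, (100, 100))[:2]
                        for v in batch.positions])
        gx, gy = np.meshgrid(np.arange(100), np.arange(100))

        def half(p, q):
            return ((q[0] - p[0]) * (gy - p[1])
                    - (gx - p[0]) * (q[1] - p[1]))

        s0, s1, s2 = half(pts[0], pts[1]), half(pts[1], pts[2]), \
            half(pts[2], pts[0])
        inside = ((s0 >= 0) & (s1 >= 0) & (s2 >= 0)) | \
            ((s0 <= 0) & (s1 <= 0) & (s2 <= 0))
        oracle = int(inside.sum())
        perimeter = sum(np.linalg.norm(pts[i] - pts[(i + 1) % 3])
                        for i in range(3))
        assert abs(filled - oracle) <= perimeter

    def test_nearer_triangle_wins_overlap(self):
        cam = ortho_camera()
        far_tri = triangle_batch([[-5, -5, -5], [5, -5, -5], [0, 5, -5]],
                                 color=(0.0, 0.0, 1.0))
        near_tri = triangle_batch([[-5, -5, 5], [5, -5, 5], [0, 5, 5]],
                                  color=(1.0, 0.0, 0.0))
        for order in ([far_tri, near_tri], [near_tri, far_tri]):
            img = rasterize(order, cam, 64, 64, background="black")
            center = img.pixels[32, 31]
            assert center[0] > center[2]  # red (near, z=+5) in front

    def test_translucent_blends_with_background(self):
        cam = ortho_camera()
        tri = triangle_batch([[-8, -8, 0], [8, -8, 0], [0, 8, 0]],
                             color=(1.0, 0.0, 0.0))
        tri.opacity = 0.5
        img = rasterize(tri, cam, 64, 64, background="white")
        center = img.pixels[40, 31]
        assert 0 < center[1] < 255  # white shows through the red triangle

    def test_deterministic_png_bytes(self, helix_structure):
        batch = build_primary(helix_structure, "sphere")
        cam = default_camera(helix_structure.coords())
        a = rasterize(batch, cam, 120, 90).png_bytes()
        b = rasterize(batch, cam, 120, 90).png_bytes()
        assert a == b


class TestAnaglyph:
    def test_zero_separation_channels_identical(self, helix_structure):
        batch = build_primary(helix_structure, "sphere")
        cam = default_camera(helix_structure.coords())
        img = render_anaglyph(batch, cam, 0.0, 100, 80)
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 1])
        assert np.array_equal(img.pixels[..., 1], img.pixels[..., 2])

    @staticmethod
    def _channel_centroid(channel, background=0):
        mask = channel != background
        ys, xs = np.nonzero(mask)
        return xs.mean()

    def test_disparity_monotone_in_separation(self, single_atom):
        # the sphere sits 12 A in front of the convergence plane: disparity
        # vanishes only at the target depth
        s = single_atom(2.0)
        batch = build_primary(s, "sphere")
        cam = Camera(kind="orthographic", eye=np.array([0.0, 0.0, 30.0]),
                     target=np.array([0.0, 0.0, -12.0]), half_height=4.0,
                     near=0.1, far=100.0)
        disparities = []
        for sep in (0.0, 1.0, 2.0, 4.0):
            img = render_anaglyph(batch, cam, sep, 160, 120)
            left = self._channel_centroid(img.pixels[..., 0])
            right = self._channel_centroid(img.pixels[..., 2])
            disparities.append(left - right)
        assert disparities[0] == pytest.approx(0.0, abs=1e-9)
        assert all(b > a for a, b in zip(disparities, disparities[1:]))

    def test_sphere_disparity_matches_projection(self, single_atom):
        s = single_atom(2.0)
        batch = build_primary(s, "sphere")
        cam = Camera(kind="orthographic", eye=np.array([0.0, 0.0, 30.0]),
                     target=np.array([0.0, 0.0, -12.0]), half_height=4.0,
                     near=0.1, far=100.0)
        sep = 3.0
        img = render_anaglyph(batch, cam, sep, 200, 150)
        left = self._channel_centroid(img.pixels[..., 0])
        right = self._channel_centroid(img.pixels[..., 2])
        # projection oracle: shift of the atom center between the two views
        right_vec, _, _ = cam.basis()
        cam_l = Camera(kind=cam.kind, eye=cam.eye - right_vec * sep / 2,
                       target=cam.target, half_height=cam.half_height,
                       near=cam.near, far=cam.far)
        cam_r = Camera(kind=cam.kind, eye=cam.eye + right_vec * sep / 2,
                       target=cam.target, half_height=cam.half_height,
                       near=cam.near, far=cam.far)
        x_l = project(cam_l, s.atoms[0].position, (200, 150))[0]
        x_r = project(cam_r, s.atoms[0].position, (200, 150))[0]
        assert (left - right) == pytest.approx(x_l - x_r, abs=1.0)

    def test_empty_scene_background_only(self):
        img = render_anaglyph([], ortho_camera(), 2.0, 40, 30,
                              background="black")
        assert np.all(img.pixels == 0)


class TestLabels:
    def test_label_at_target_draws_near_center(self):
        cam = ortho_camera()
        img = rasterize([], cam, 100, 100, background="black")
        out = draw_labels(img, [("CA", np.zeros(3))], cam)
        changed = np.argwhere(np.any(out.pixels != 0, axis=2))
        assert len(changed) > 0
        ys, xs = changed[:, 0], changed[:, 1]
        assert abs(ys.mean() - 49.5) < 15 and abs(xs.mean() - 49.5) < 30

    def test_offscreen_anchor_skipped(self):
        cam = ortho_camera()
        img = rasterize([], cam, 50, 50, background="black")
        out = draw_labels(img, [("FAR", np.array([500.0, 0.0, 0.0]))], cam)
        assert np.array_equal(out.pixels, img.pixels)

    def test_behind_camera_anchor_skipped(self):
        cam = Camera(kind="perspective", eye=np.array([0.0, 0.0, 10.0]),
                     target=np.zeros(3))
        img = rasterize([], cam, 50, 50, background="black")
        out = draw_labels(img, [("X", np.array([0.0, 0.0, 30.0]))], cam)
        assert np.array_equal(out.pixels, img.pixels)

    def test_two_labels_deterministic(self):
        cam = ortho_camera()
        img = rasterize([], cam, 100, 100, background="black")
        labels = [("B", np.array([2.0, 0.0, 0.0])),
                  ("A", np.array([-2.0, 0.0, 0.0]))]
        out1 = draw_labels(img, labels, cam)
        out2 = draw_labels(img, list(reversed(labels)), cam)
        assert np.array_equal(out1.pixels, out2.pixels)
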