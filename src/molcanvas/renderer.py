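"""Headless software rendering: cameras, z-buffer rasterization, labels,
and anaglyph stereo compositing.

Rendering is deterministic by construction: fixed-function z-buffered
triangle fill with Gouraud shading from a single headlight at the eye
(Lambert, ambient 0.2), 1-px lines and points, no antialiasing. Repeated
renders of the same scene produce byte-identical PNG files.

The anaglyph composites a left and a right view, eyes displaced by half
the eye separation along the camera right vector and both converging on
the target; the red channel carries the left view's luminance and the
green/blue channels the right view's (gray anaglyph, which avoids
retinal rivalry between strongly colored regions).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image as PILImage
from PIL import ImageDraw, ImageFont

from .errors import BehindCameraError
from .representations import GeometryBatch
from .surface_engine import TriangleMesh

__all__ = [
    "Camera",
    "Image",
    "default_camera",
    "project",
    "rasterize",
    "render_anaglyph",
    "draw_labels",
]

BACKGROUNDS = {
    "black": (0, 0, 0),
    "grey": (128, 128, 128),
    "white": (255, 255, 255),
}

AMBIENT = 0.2
_EPS = 1e-9


@dataclass
class Camera:
    """Perspective or orthographic camera (all lengths in Angstrom)."""

    kind: str = "perspective"           # perspective | orthographic
    eye: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 50.0]))
    target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    fov_deg: float = 40.0               # perspective vertical field of view
    half_height: float = 10.0           # orthographic half view height
    near: float = 0.1
    far: float = 1000.0

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, up, forward) orthonormal camera basis."""
        forward = np.asarray(self.target, float) - np.asarray(self.eye, float)
        norm = np.linalg.norm(forward)
        if norm < _EPS:
            raise ValueError("camera eye and target coincide")
        forward = forward / norm
        right = np.cross(forward, np.asarray(self.up, float))
        norm = np.linalg.norm(right)
        if norm < _EPS:
            raise ValueError("camera up is parallel to the view direction")
        right = right / norm
        true_up = np.cross(right, forward)
        return right, true_up, forward


@dataclass
class Image:
    width: int
    height: int
    pixels: np.ndarray  # (height, width, 3) uint8

    def to_pil(self) -> PILImage.Image:
        return PILImage.fromarray(self.pixels, mode="RGB")

    def save_png(self, path) -> None:
        self.to_pil().save(path, format="PNG")

    def png_bytes(self) -> bytes:
        buffer = io.BytesIO()
        self.to_pil().save(buffer, format="PNG")
        return buffer.getvalue()


def default_camera(points: np.ndarray, kind: str = "perspective",
                   width: int = 800, height: int = 600) -> Camera:
    """Eye on +z at twice the bounding-sphere radius from the centroid."""
    points = np.atleast_2d(points)
    center = points.mean(axis=0)
    radius = float(np.linalg.norm(points - center, axis=1).max()) or 1.0
    distance = 2.0 * radius + 1.0
    return Camera(kind=kind,
                  eye=center + np.array([0.0, 0.0, distance]),
                  target=center.copy(),
                  half_height=1.2 * radius,
                  fov_deg=40.0,
                  near=max(distance - 4.0 * radius, 0.05),
                  far=distance + 4.0 * radius)


def _view_coords(camera: Camera, points: np.ndarray) -> np.ndarray:
    right, up, forward = camera.basis()
    d = np.atleast_2d(points) - np.asarray(camera.eye, float)
    return np.column_stack([d @ right, d @ up, d @ forward])


def _ndc_depth(camera: Camera, view: np.ndarray, aspect: float
               ) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = view[:, 0], view[:, 1], view[:, 2]
    if camera.kind == "orthographic":
        half_h = camera.half_height
        ndc = np.column_stack([x / (half_h * aspect), y / half_h])
        depth = (z - camera.near) / (camera.far - camera.near)
    else:
        tan_half = np.tan(np.deg2rad(camera.fov_deg) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ndc = np.column_stack([x / (z * tan_half * aspect),
                                   y / (z * tan_half)])
            depth = ((camera.far + camera.near) / (camera.far - camera.near)
                     - 2.0 * camera.far * camera.near
                     / ((camera.far - camera.near) * z) + 1.0) / 2.0
    return ndc, depth


def project(camera: Camera, point, viewport: tuple[int, int]
            ) -> tuple[float, float, float]:
    """Project one world point to (x_px, y_px, depth).

    Raises :class:`BehindCameraError` for a perspective camera when the
    point lies at or behind the eye plane.
    """
    width, height = viewport
    view = _view_coords(camera, np.asarray(point, float))
    if camera.kind == "perspective" and view[0, 2] <= _EPS:
        raise BehindCameraError("point at or behind the eye plane")
    ndc, depth = _ndc_depth(camera, view, width / height)
    x_px = (ndc[0, 0] + 1.0) / 2.0 * (width - 1)
    y_px = (1.0 - (ndc[0, 1] + 1.0) / 2.0) * (height - 1)
    return float(x_px), float(y_px), float(depth[0])


def _project_array(camera: Camera, points: np.ndarray,
                   width: int, height: int):
    """Vectorized projection; returns (xy pixels, depth, valid mask)."""
    view = _view_coords(camera, points)
    valid = np.ones(len(view), dtype=bool)
    if camera.kind == "perspective":
        valid = view[:, 2] > _EPS
    ndc, depth = _ndc_depth(camera, view, width / height)
    xy = np.column_stack([(ndc[:, 0] + 1.0) / 2.0 * (width - 1),
                          (1.0 - (ndc[:, 1] + 1.0) / 2.0) * (height - 1)])
    return xy, depth, valid


def _as_batches(scene) -> list[GeometryBatch]:
    if isinstance(scene, (GeometryBatch, TriangleMesh)):
        scene = [scene]
    batches = []
    for item in scene:
        if isinstance(item, TriangleMesh):
            colors = item.vertex_color
            if colors is None:
                colors = np.full((item.n_vertices, 3), 0.7)
            batches.append(GeometryBatch(
                kind="triangles", positions=item.vertices, colors=colors,
                indices=item.triangles,
                source_atoms=(item.vertex_atom if item.vertex_atom is not None
                              else np.zeros(item.n_vertices, dtype=np.int64)),
                normals=item.normals))
        else:
            batches.append(item)
    return batches


def _lit_colors(batch: GeometryBatch, camera: Camera) -> np.ndarray:
    """Per-vertex Lambert shading with a headlight at the eye."""
    if batch.kind != "triangles" or len(batch.positions) == 0:
        return batch.colors
    normals = batch.normals
    if normals is None:
        normals = _mesh_vertex_normals(batch.positions, batch.indices)
    to_eye = np.asarray(camera.eye, float) - batch.positions
    to_eye /= np.maximum(np.linalg.norm(to_eye, axis=1, keepdims=True), _EPS)
    lambert = np.abs(np.sum(normals * to_eye, axis=1))  # two-sided
    intensity = AMBIENT + (1.0 - AMBIENT) * lambert
    return np.clip(batch.colors * intensity[:, None], 0.0, 1.0)


def _mesh_vertex_normals(vertices, triangles):
    normals = np.zeros_like(vertices)
    if len(triangles):
        cross = np.cross(vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
                         vertices[triangles[:, 2]] - vertices[triangles[:, 0]])
        for k in range(3):
            np.add.at(normals, triangles[:, k], cross)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def _fill_triangles(color_buf, z_buf, xy, depth, colors, triangles,
                    opacity: float, z_write: bool = True):
    height, width, _ = color_buf.shape
    for tri in triangles:
        p = xy[tri]
        z = depth[tri]
        c = colors[tri]
        x_min = max(int(np.floor(p[:, 0].min())), 0)
        x_max = min(int(np.ceil(p[:, 0].max())), width - 1)
        y_min = max(int(np.floor(p[:, 1].min())), 0)
        y_max = min(int(np.ceil(p[:, 1].max())), height - 1)
        if x_min > x_max or y_min > y_max:
            continue
        area = ((p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1]))
        if abs(area) < _EPS:
            continue
        gx, gy = np.meshgrid(np.arange(x_min, x_max + 1),
                             np.arange(y_min, y_max + 1))
        w0 = ((p[1, 0] - p[0, 0]) * (gy - p[0, 1])
              - (gx - p[0, 0]) * (p[1, 1] - p[0, 1])) / area
        w1 = ((gx - p[0, 0]) * (p[2, 1] - p[0, 1])
              - (p[2, 0] - p[0, 0]) * (gy - p[0, 1])) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z_pix = w2 * z[0] + w1 * z[1] + w0 * z[2]
        rows, cols = gy[inside], gx[inside]
        z_vals = z_pix[inside]
        closer = z_vals < z_buf[rows, cols]
        rows, cols, z_vals = rows[closer], cols[closer], z_vals[closer]
        if len(rows) == 0:
            continue
        rgb = (w2[inside][closer, None] * c[0]
               + w1[inside][closer, None] * c[1]
               + w0[inside][closer, None] * c[2])
        rgb = np.clip(rgb, 0.0, 1.0) * 255.0
        if opacity >= 1.0:
            color_buf[rows, cols] = rgb
        else:
            color_buf[rows, cols] = (opacity * rgb
                                     + (1.0 - opacity)
                                     * color_buf[rows, cols])
        if z_write:
            z_buf[rows, cols] = z_vals


def _draw_lines(color_buf, z_buf, xy, depth, colors, segments):
    height, width, _ = color_buf.shape
    for a, b in segments:
        pa, pb = xy[a], xy[b]
        steps = int(max(abs(pb[0] - pa[0]), abs(pb[1] - pa[1]))) + 1
        t = np.linspace(0.0, 1.0, steps + 1)
        cols = np.rint(pa[0] + t * (pb[0] - pa[0])).astype(int)
        rows = np.rint(pa[1] + t * (pb[1] - pa[1])).astype(int)
        z = depth[a] + t * (depth[b] - depth[a])
        rgb = (colors[a][None, :] * (1 - t[:, None])
               + colors[b][None, :] * t[:, None]) * 255.0
        keep = (cols >= 0) & (cols < width) & (rows >= 0) & (rows < height)
        cols, rows, z, rgb = cols[keep], rows[keep], z[keep], rgb[keep]
        closer = z < z_buf[rows, cols]
        color_buf[rows[closer], cols[closer]] = rgb[closer]
        z_buf[rows[closer], cols[closer]] = z[closer]


def rasterize(scene, camera: Camera, width: int = 800, height: int = 600,
              background: str = "white") -> Image:
    """Render geometry batches / meshes to an RGB image.

    Opaque batches draw with full z-buffering; translucent batches
    (opacity < 1) are composited afterwards back-to-front against the
    opaque depth buffer.
    """
    if background not in BACKGROUNDS:
        raise ValueError(f"background must be one of {tuple(BACKGROUNDS)}")
    color_buf = np.empty((height, width, 3), dtype=float)
    color_buf[:] = BACKGROUNDS[background]
    z_buf = np.full((height, width), np.inf)
    batches = _as_batches(scene)

    opaque = [b for b in batches if b.opacity >= 1.0]
    translucent = [b for b in batches if b.opacity < 1.0]
    for batch in opaque + translucent:
        if len(batch.positions) == 0 or batch.is_empty:
            continue
        xy, depth, valid = _project_array(camera, batch.positions,
                                          width, height)
        colors = _lit_colors(batch, camera)
        if batch.kind == "triangles":
            tris = batch.indices[valid[batch.indices].all(axis=1)]
            if batch.opacity < 1.0:
                order = np.argsort(-depth[tris].mean(axis=1), kind="stable")
                tris = tris[order]
            _fill_triangles(color_buf, z_buf, xy, depth, colors, tris,
                            batch.opacity, z_write=batch.opacity >= 1.0)
        elif batch.kind == "lines":
            segs = batch.indices[valid[batch.indices].all(axis=1)]
            _draw_lines(color_buf, z_buf, xy, depth, colors, segs)
        else:  # points
            idx = batch.indices.ravel()
            idx = idx[valid[idx]]
            cols = np.rint(xy[idx, 0]).astype(int)
            rows = np.rint(xy[idx, 1]).astype(int)
            keep = ((cols >= 0) & (cols < width)
                    & (rows >= 0) & (rows < height))
            cols, rows, idx = cols[keep], rows[keep], idx[keep]
            closer = depth[idx] < z_buf[rows, cols]
            color_buf[rows[closer], cols[closer]] = \
                colors[idx[closer]] * 255.0
            z_buf[rows[closer], cols[closer]] = depth[idx][closer]
    return Image(width=width, height=height,
                 pixels=np.clip(np.rint(color_buf), 0, 255).astype(np.uint8))


_LUMA = np.array([0.299, 0.587, 0.114])


def render_anaglyph(scene, camera: Camera, eye_separation: float,
                    width: int = 800, height: int = 600,
                    background: str = "black") -> Image:
    """Gray-anaglyph stereo render.

    Left/right eyes are displaced by +/- eye_separation/2 along the camera
    right vector, both looking at the target; the red channel encodes the
    left view's luminance and the green/blue channels the right view's.
    At zero separation the channels are identical.
    """
    right, _, _ = camera.basis()
    views = []
    for sign in (-1.0, +1.0):
        shifted = Camera(kind=camera.kind,
                         eye=np.asarray(camera.eye, float)
                         + sign * (eye_separation / 2.0) * right,
                         target=np.asarray(camera.target, float),
                         up=np.asarray(camera.up, float),
                         fov_deg=camera.fov_deg,
                         half_height=camera.half_height,
                         near=camera.near, far=camera.far)
        views.append(rasterize(scene, shifted, width, height, background))
    left, right_img = views
    luma_left = np.clip(left.pixels @ _LUMA, 0, 255).astype(np.uint8)
    luma_right = np.clip(right_img.pixels @ _LUMA, 0, 255).astype(np.uint8)
    pixels = np.stack([luma_left, luma_right, luma_right], axis=-1)
    return Image(width=width, height=height, pixels=pixels)


def draw_labels(image: Image, labels, camera: Camera,
                offset: tuple[int, int] = (5, -10),
                color: tuple[int, int, int] = (255, 220, 50)) -> Image:
    """Annotate projected anchor positions with text labels.

    ``labels`` holds (text, anchor) pairs or the (ref, text, anchor)
    triples emitted by :func:`molcanvas.interactions.make_labels`.
    Off-screen and behind-camera anchors are skipped; draws happen in a
    deterministic order (atom serial when refs are present).
    """
    items = []
    for item in labels:
        if len(item) == 3:
            ref, text, anchor = item
            items.append((getattr(ref, "serial", 0), text, anchor))
        else:
            text, anchor = item
            items.append((0, text, anchor))
    items.sort(key=lambda it: (it[0], it[1]))
    pil = image.to_pil()
    draw = ImageDraw.Draw(pil)
    font = ImageFont.load_default()
    for _, text, anchor in items:
        try:
            x, y, _ = project(camera, anchor, (image.width, image.height))
        except BehindCameraError:
            continue
        if not (0 <= x < image.width and 0 <= y < image.height):
            continue
        draw.text((x + offset[0], y + offset[1]), text, fill=color, font=font)
    return Image(width=image.width, height=image.height,
                 pixels=np.asarray(pil, dtype=np.uint8).copy())
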