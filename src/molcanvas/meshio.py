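"""Mesh and geometry export: Wavefront OBJ and binary PLY.

OBJ carries v/vn/f records (and `l` line elements for wireframes); PLY is
binary little-endian with per-vertex uchar RGB when colors are present.
"""

from __future__ import annotations

import struct

import numpy as np

from .surface_engine import TriangleMesh

__all__ = ["write_obj", "write_ply", "wireframe_edges"]


def wireframe_edges(mesh: TriangleMesh) -> np.ndarray:
    """Unique undirected edges of a triangle mesh, sorted for determinism."""
    t = mesh.triangles
    if len(t) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def write_obj(mesh: TriangleMesh, path, wireframe: bool = False) -> None:
    """Write an OBJ file; wireframe=True emits line elements, not faces."""
    lines = []
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    if mesh.normals is not None and not wireframe:
        for n in mesh.normals:
            lines.append(f"vn {n[0]:.6f} {n[1]:.6f} {n[2]:.6f}")
    if wireframe:
        for a, b in wireframe_edges(mesh):
            lines.append(f"l {a + 1} {b + 1}")
    else:
        has_normals = mesh.normals is not None
        for a, b, c in mesh.triangles + 1:
            if has_normals:
                lines.append(f"f {a}//{a} {b}//{b} {c}//{c}")
            else:
                lines.append(f"f {a} {b} {c}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_ply(mesh: TriangleMesh, path) -> None:
    """Write a binary little-endian PLY with optional per-vertex RGB."""
    has_color = mesh.vertex_color is not None
    has_normals = mesh.normals is not None
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {mesh.n_vertices}",
              "property float x", "property float y", "property float z"]
    if has_normals:
        header += ["property float nx", "property float ny",
                   "property float nz"]
    if has_color:
        header += ["property uchar red", "property uchar green",
                   "property uchar blue"]
    header += [f"element face {mesh.n_triangles}",
               "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as handle:
        handle.write(("\n".join(header) + "\n").encode("ascii"))
        colors = None
        if has_color:
            colors = np.clip(mesh.vertex_color * 255.0, 0, 255).astype(np.uint8)
        for i in range(mesh.n_vertices):
            handle.write(struct.pack("<3f", *mesh.vertices[i]))
            if has_normals:
                handle.write(struct.pack("<3f", *mesh.normals[i]))
            if has_color:
                handle.write(struct.pack("<3B", *colors[i]))
        for tri in mesh.triangles:
            handle.write(struct.pack("<B3i", 3, *tri))
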