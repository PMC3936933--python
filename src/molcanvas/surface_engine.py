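"""Triangulated macromolecular surfaces on a capped voxel grid.

The four surface kinds are all derived from Euclidean distance fields on
an axis-aligned grid whose dimensions never exceed a cap (default
180x180x180); when a molecule is too large for the requested resolution
the grid is uniformly coarsened, never cropped.

* ``vdw`` - zero level set of the minimum signed distance to the atom
  spheres at their van der Waals radii.
* ``sas`` - same field with every radius inflated by the probe radius.
* ``ses`` - erosion route: the solvent-excluded solid is the SAS solid
  eroded by the probe ball, realized as the level set where the inward
  Euclidean distance from the SAS exterior equals the probe radius.
* ``ms``  - closing route: the van der Waals solid united with the
  SAS-interior voxels no probe center can reach, i.e. the morphological
  closing of the VdW solid by the probe ball.

SES and MS describe the same mathematical surface; the two derivations
differ only by discretization (at most a one-voxel shell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import NoAtomsError, NoFeaturesError
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ScalarField",
    "TriangleMesh",
    "build_grid",
    "min_signed_distance_field",
    "exact_edt",
    "extract_isosurface",
    "compute_surface",
    "smooth_mesh",
    "mesh_area_volume",
]

GRID_CAP = 180          # per-dimension voxel cap
GRID_MARGIN_VOXELS = 2  # empty voxels kept around the inflated atoms
DEGENERATE_AREA = 1e-12


@dataclass
class GridSpec:
    """Axis-aligned isotropic voxel grid (origin in Angstrom)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def voxel_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D voxel-center coordinate arrays along each axis."""
        return tuple(self.origin[k] + self.spacing * np.arange(self.dims[k])
                     for k in range(3))


@dataclass
class ScalarField:
    grid: GridSpec
    values: np.ndarray
    nearest_atom: np.ndarray | None = None


@dataclass
class TriangleMesh:
    """Indexed triangle surface with per-vertex attributes."""

    vertices: np.ndarray                      # (n, 3) Angstrom
    triangles: np.ndarray                     # (m, 3) int
    normals: np.ndarray | None = None         # (n, 3) unit
    vertex_color: np.ndarray | None = None    # (n, 3) RGB in [0, 1]
    vertex_atom: np.ndarray | None = None     # (n,) int

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


def _atom_arrays(atoms) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(atoms, Structure):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise NoAtomsError("surface computation requires at least one atom")
    centers = np.array([a.position for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius if a.vdw_radius > 0 else 1.7
                      for a in atoms], dtype=float)
    return centers, radii


def build_grid(atoms, probe_radius: float = 0.0,
               target_resolution: float = 4.0, cap: int = GRID_CAP) -> GridSpec:
    """Grid enclosing all atoms inflated by (vdw + probe) plus a margin.

    spacing starts at 1/target_resolution and is uniformly coarsened until
    every dimension fits under ``cap``; the box is never cropped.
    """
    centers, radii = _atom_arrays(atoms)
    inflated = radii + probe_radius
    lo = (centers - inflated[:, None]).min(axis=0)
    hi = (centers + inflated[:, None]).max(axis=0)
    spacing = 1.0 / float(target_resolution)
    extent = hi - lo
    # dims = extent/spacing + 1 + 2*margin must stay <= cap on every axis
    usable = cap - 1 - 2 * GRID_MARGIN_VOXELS
    if usable < 1:
        raise ValueError(f"cap {cap} too small for the fixed margin")
    needed = float(extent.max()) / usable
    if needed > spacing:
        spacing = needed
        logger.debug("grid coarsened to spacing %.4f A to honor cap %d",
                     spacing, cap)
    dims = tuple(int(np.ceil(extent[k] / spacing)) + 1 + 2 * GRID_MARGIN_VOXELS
                 for k in range(3))
    dims = tuple(min(d, cap) for d in dims)
    origin = lo - GRID_MARGIN_VOXELS * spacing
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


def min_signed_distance_field(atoms, grid: GridSpec,
                              inflation: float = 0.0) -> ScalarField:
    """Minimum over atoms of ||v - center|| - (vdw_radius + inflation).

    Negative inside the union of (inflated) atom spheres. ``nearest_atom``
    is the argmin atom index; ties break to the lowest index.
    """
    centers, radii = _atom_arrays(atoms)
    xs, ys, zs = grid.voxel_coordinates()
    values = np.full(grid.dims, np.inf)
    nearest = np.zeros(grid.dims, dtype=np.int32)
    dx2_all = (xs[:, None] - centers[None, :, 0]) ** 2
    for i in range(len(centers)):
        dy2 = (ys - centers[i, 1]) ** 2
        dz2 = (zs - centers[i, 2]) ** 2
        dist = np.sqrt(dx2_all[:, i][:, None, None]
                       + dy2[None, :, None] + dz2[None, None, :])
        signed = dist - (radii[i] + inflation)
        closer = signed < values  # strict: earlier (lower) index wins ties
        values[closer] = signed[closer]
        nearest[closer] = i
    return ScalarField(grid=grid, values=values, nearest_atom=nearest)


def exact_edt(mask: ScalarField | np.ndarray,
              grid: GridSpec | None = None) -> ScalarField:
    """Exact Euclidean distance (in voxels) to the nearest feature voxel.

    ``mask`` is boolean (True = feature), given directly or as a
    ScalarField whose values are truthy on features. ``nearest_atom`` of the
    input, when present, is propagated from the nearest feature voxel.
    """
    atom_ids = None
    if isinstance(mask, ScalarField):
        grid = mask.grid
        atom_ids = mask.nearest_atom
        feature = mask.values.astype(bool)
    else:
        feature = np.asarray(mask, dtype=bool)
    if not feature.any():
        raise NoFeaturesError("distance transform needs >= 1 feature voxel")
    distances, indices = ndimage.distance_transform_edt(
        ~feature, return_indices=True)
    nearest = None
    if atom_ids is not None:
        nearest = atom_ids[tuple(indices)]
    if grid is None:
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, dims=feature.shape)
    return ScalarField(grid=grid, values=distances, nearest_atom=nearest)


def extract_isosurface(fieldobj: ScalarField, isovalue: float = 0.0,
                       ) -> TriangleMesh:
    """Marching-cubes mesh of the isovalue level set.

    Vertices are linearly interpolated along voxel edges and mapped into
    Angstrom coordinates; normals come from the field gradient. A uniform
    field (level set absent) yields an empty mesh. Each vertex is
    attributed to the nearest-atom id of the voxel-edge endpoint with the
    smaller absolute field value, when the field carries atom ids.
    """
    values = fieldobj.values
    grid = fieldobj.grid
    vmin, vmax = float(values.min()), float(values.max())
    if not (vmin < isovalue < vmax):
        return _empty_mesh()
    if np.any(values == isovalue):
        # nudge the level off exact grid values so no cell corner lies on
        # the surface (exact hits duplicate vertices and open the mesh)
        isovalue += 1e-9 * max(abs(vmin), abs(vmax), 1.0)
    verts, faces, normals, _ = measure.marching_cubes(
        values, level=isovalue, spacing=(1.0, 1.0, 1.0))
    vertex_atom = None
    if fieldobj.nearest_atom is not None:
        lo = np.floor(verts).astype(int)
        hi = np.minimum(np.ceil(verts).astype(int),
                        np.array(values.shape) - 1)
        pick_hi = np.abs(values[tuple(hi.T)]) < np.abs(values[tuple(lo.T)])
        idx = np.where(pick_hi[:, None], hi, lo)
        vertex_atom = fieldobj.nearest_atom[tuple(idx.T)].astype(np.int32)
    vertices = grid.origin[None, :] + verts * grid.spacing
    mesh = TriangleMesh(vertices=vertices, triangles=faces.astype(np.int64),
                        normals=_normalize(normals), vertex_atom=vertex_atom)
    mesh = _weld_vertices(mesh)
    return _drop_degenerate(mesh)


def _weld_vertices(mesh: TriangleMesh, decimals: int = 7) -> TriangleMesh:
    """Merge coincident vertices so shared edges are truly shared."""
    rounded = np.round(mesh.vertices, decimals)
    _, first, inverse = np.unique(rounded, axis=0, return_index=True,
                                  return_inverse=True)
    if len(first) == len(mesh.vertices):
        return mesh
    remap = inverse.astype(np.int64)
    mesh.triangles = remap[mesh.triangles]
    keep = first
    # np.unique sorts; build vertex arrays in the new (sorted) order
    mesh.vertices = mesh.vertices[keep]
    if mesh.normals is not None:
        mesh.normals = _normalize(mesh.normals[keep])
    if mesh.vertex_atom is not None:
        mesh.vertex_atom = mesh.vertex_atom[keep]
    if mesh.vertex_color is not None:
        mesh.vertex_color = mesh.vertex_color[keep]
    return mesh


def _empty_mesh() -> TriangleMesh:
    return TriangleMesh(vertices=np.zeros((0, 3)),
                        triangles=np.zeros((0, 3), dtype=np.int64),
                        normals=np.zeros((0, 3)))


def _normalize(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vectors / norms


def _drop_degenerate(mesh: TriangleMesh) -> TriangleMesh:
    if mesh.n_triangles == 0:
        return mesh
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    mesh.triangles = t[areas > DEGENERATE_AREA]
    return mesh


def solvent_fields(atoms, grid: GridSpec, probe_radius: float):
    """Distance fields shared by the SES/MS derivations.

    Returns (sdf_vdw, sdf_sas, depth) where depth approximates the inward
    Angstrom distance from the SAS boundary: the exact EDT to the nearest
    exterior voxel center minus that voxel's own (positive) signed
    distance to the SAS surface. The correction removes the half-voxel
    outward bias of a center-to-center transform while preserving the
    voxelwise guarantee that van der Waals interior voxels keep
    depth >= probe_radius. Nearest-atom ids are propagated inward.
    """
    sdf_vdw = min_signed_distance_field(atoms, grid, inflation=0.0)
    sdf_sas = min_signed_distance_field(atoms, grid,
                                        inflation=probe_radius)
    exterior = sdf_sas.values > 0.0
    if not exterior.any():
        # molecule fills the whole grid; treat boundary as exterior
        exterior = np.zeros_like(exterior)
        exterior[0, :, :] = exterior[-1, :, :] = True
    edt, indices = ndimage.distance_transform_edt(~exterior,
                                                  return_indices=True)
    surface_offset = np.maximum(sdf_sas.values[tuple(indices)], 0.0)
    depth = ScalarField(grid=grid,
                        values=edt * grid.spacing - surface_offset,
                        nearest_atom=sdf_sas.nearest_atom)
    return sdf_vdw, sdf_sas, depth


def compute_surface(s, kind: str = "ses", probe_radius: float = 1.4,
                    target_resolution: float = 4.0, cap: int = GRID_CAP,
                    smooth_iterations: int = 0,
                    swap_ses_ms: bool = False) -> TriangleMesh:
    """Triangulated surface of a structure.

    kind: ``vdw`` | ``sas`` | ``ses`` (erosion route) | ``ms`` (closing
    route). ``swap_ses_ms`` exchanges which derivation the two labels use.
    """
    if kind not in ("vdw", "sas", "ses", "ms"):
        raise ValueError(f"unknown surface kind {kind!r}")
    if swap_ses_ms and kind in ("ses", "ms"):
        kind = "ms" if kind == "ses" else "ses"
    grid = build_grid(s, probe_radius if kind != "vdw" else 0.0,
                      target_resolution, cap)
    if kind == "vdw":
        mesh = extract_isosurface(
            min_signed_distance_field(s, grid, 0.0), 0.0)
    elif kind == "sas":
        mesh = extract_isosurface(
            min_signed_distance_field(s, grid, probe_radius), 0.0)
    else:
        sdf_vdw, _, depth = solvent_fields(s, grid, probe_radius)
        # negative inside the solvent-excluded solid
        eroded = probe_radius - depth.values
        if kind == "ses":
            values = eroded
        else:  # ms: union of the VdW solid with the unreachable interior
            values = np.minimum(sdf_vdw.values, eroded)
        mesh = extract_isosurface(
            ScalarField(grid=grid, values=values,
                        nearest_atom=depth.nearest_atom), 0.0)
    if smooth_iterations > 0:
        mesh = smooth_mesh(mesh, smooth_iterations)
    return mesh


def surface_solids(s, probe_radius: float = 1.4,
                   target_resolution: float = 4.0, cap: int = GRID_CAP):
    """Boolean voxel solids for the four surface kinds on a shared grid.

    Exposed for nesting/consistency checks: vdw subset-of ses/ms subset-of
    sas holds voxelwise by construction of the exact EDT at voxel centers.
    """
    grid = build_grid(s, probe_radius, target_resolution, cap)
    sdf_vdw, sdf_sas, depth = solvent_fields(s, grid, probe_radius)
    vdw = sdf_vdw.values <= 0.0
    sas = sdf_sas.values <= 0.0
    ses = depth.values >= probe_radius
    ms = vdw | ses
    return grid, {"vdw": vdw, "sas": sas, "ses": ses, "ms": ms}


def _vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    neighbors: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    return [np.fromiter(n, dtype=np.int64) for n in neighbors]


def smooth_mesh(mesh: TriangleMesh, iterations: int = 1,
                weight: float = 0.5) -> TriangleMesh:
    """Laplacian smoothing: v <- v + w * (neighborhood mean - v).

    Topology (triangle indices) is unchanged; normals are re-derived from
    the smoothed geometry by area-weighted face-normal averaging.
    """
    if iterations <= 0 or mesh.n_triangles == 0:
        return mesh
    adjacency = _vertex_adjacency(mesh)
    vertices = mesh.vertices.copy()
    for _ in range(iterations):
        means = np.array([vertices[n].mean(axis=0) if len(n) else vertices[i]
                          for i, n in enumerate(adjacency)])
        vertices = vertices + weight * (means - vertices)
    out = TriangleMesh(vertices=vertices, triangles=mesh.triangles,
                       vertex_color=mesh.vertex_color,
                       vertex_atom=mesh.vertex_atom)
    out.normals = _vertex_normals(vertices, mesh.triangles)
    return out


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    normals = np.zeros_like(vertices)
    cross = np.cross(vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
                     vertices[triangles[:, 2]] - vertices[triangles[:, 0]])
    for k in range(3):
        np.add.at(normals, triangles[:, k], cross)
    return _normalize(normals)


def mesh_area_volume(mesh: TriangleMesh) -> tuple[float, float]:
    """Total triangle area (A^2) and enclosed volume (A^3).

    Volume is the absolute sum of signed tetrahedra from the origin;
    meaningful for closed meshes only.
    """
    if mesh.n_triangles == 0:
        return 0.0, 0.0
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    cross = np.cross(b - a, c - a)
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    volume = float(abs((a * np.cross(b, c)).sum() / 6.0))
    return area, volume
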