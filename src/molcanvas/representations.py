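"""Renderable geometry for molecular representations and color schemes.

Primary-structure representations: line, stick, ball & stick, sphere,
dot. Secondary-structure representations: ribbon, strand, C-alpha trace,
B-factor tube, cylinder & plate. Color schemes: atom spectrum, chain,
secondary structure, B factor, residue name, residue polarity, atom
(CPK).

Backbone curves are uniform Catmull-Rom splines through consecutive
C-alpha atoms with duplicated endpoints (the curve interpolates every
control point), 8 subdivisions per residue by default.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .errors import UnknownRepresentationError, UnknownSchemeError
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryBatch",
    "atom_colors",
    "derive_bonds",
    "build_primary",
    "build_secondary",
    "catmull_rom",
    "icosphere",
]

COLOR_SCHEMES = ("spectrum", "chain", "secondary", "bfactor", "residue",
                 "polarity", "atom")

SPECTRUM_HUE_RANGE = (240.0, 0.0)   # degrees, blue -> red over residue rank
RIBBON_WIDTH = 1.6                  # Angstrom
SPLINE_SUBDIVISIONS = 8             # points per residue along the backbone
STICK_RADIUS = 0.25                 # Angstrom
BALL_SCALE = 0.4                    # ball & stick sphere = 0.4 x VdW
BOND_TOLERANCE = 1.2                # bond iff d < 1.2 x (covalent sum)

CHAIN_PALETTE = [
    (0.20, 0.50, 0.90), (0.95, 0.55, 0.15), (0.25, 0.75, 0.30),
    (0.85, 0.25, 0.25), (0.60, 0.40, 0.80), (0.55, 0.35, 0.20),
    (0.90, 0.50, 0.75), (0.50, 0.50, 0.50),
]

SECONDARY_PALETTE = {
    "helix": (1.00, 0.00, 0.50),
    "sheet": (1.00, 0.78, 0.00),
    "coil": (0.78, 0.78, 0.78),
}

CPK_COLORS = {
    "H": (1.00, 1.00, 1.00), "C": (0.56, 0.56, 0.56),
    "N": (0.19, 0.31, 0.97), "O": (1.00, 0.05, 0.05),
    "S": (1.00, 1.00, 0.19), "P": (1.00, 0.50, 0.00),
    "F": (0.56, 0.88, 0.31), "CL": (0.12, 0.94, 0.12),
    "BR": (0.65, 0.16, 0.16), "I": (0.58, 0.00, 0.58),
    "FE": (0.88, 0.40, 0.20), "ZN": (0.49, 0.50, 0.69),
    "MG": (0.54, 1.00, 0.00), "CA": (0.24, 1.00, 0.00),
    "NA": (0.67, 0.36, 0.95), "K": (0.56, 0.25, 0.83),
}
CPK_DEFAULT = (1.00, 0.08, 0.58)

RESIDUE_PALETTE = {
    "ALA": (0.78, 0.78, 0.78), "ARG": (0.08, 0.35, 1.00),
    "ASN": (0.00, 0.86, 0.86), "ASP": (0.90, 0.04, 0.04),
    "CYS": (0.90, 0.90, 0.00), "GLN": (0.00, 0.86, 0.86),
    "GLU": (0.90, 0.04, 0.04), "GLY": (0.92, 0.92, 0.92),
    "HIS": (0.51, 0.51, 0.82), "ILE": (0.06, 0.51, 0.06),
    "LEU": (0.06, 0.51, 0.06), "LYS": (0.08, 0.35, 1.00),
    "MET": (0.90, 0.90, 0.00), "PHE": (0.20, 0.20, 0.67),
    "PRO": (0.86, 0.59, 0.51), "SER": (0.98, 0.59, 0.00),
    "THR": (0.98, 0.59, 0.00), "TRP": (0.71, 0.35, 0.71),
    "TYR": (0.20, 0.20, 0.67), "VAL": (0.06, 0.51, 0.06),
}
RESIDUE_DEFAULT = (0.74, 0.63, 0.43)

POLAR_RESIDUES = {"ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "LYS",
                  "SER", "THR", "TYR", "CYS", "TRP"}
POLAR_COLOR = (0.15, 0.70, 0.25)
NONPOLAR_COLOR = (0.85, 0.80, 0.25)


@dataclass
class GeometryBatch:
    """One drawable batch: points, line segments, or triangles."""

    kind: str                                  # points | lines | triangles
    positions: np.ndarray                      # (n, 3) Angstrom
    colors: np.ndarray                         # (n, 3) RGB in [0, 1]
    indices: np.ndarray                        # (m, 1|2|3) int
    source_atoms: np.ndarray                   # (n,) int atom index
    normals: np.ndarray | None = None          # (n, 3), triangles only
    opacity: float = 1.0

    @property
    def is_empty(self) -> bool:
        return len(self.indices) == 0


def _empty_batch(kind: str) -> GeometryBatch:
    width = {"points": 1, "lines": 2, "triangles": 3}[kind]
    return GeometryBatch(kind=kind, positions=np.zeros((0, 3)),
                         colors=np.zeros((0, 3)),
                         indices=np.zeros((0, width), dtype=np.int64),
                         source_atoms=np.zeros(0, dtype=np.int64))


# -- color schemes ------------------------------------------------------------

def _spectrum_colors(s: Structure, n: int) -> np.ndarray:
    colors = np.zeros((n, 3))
    i = 0
    for chain in s.chains:
        n_res = max(len(chain.residues) - 1, 1)
        for rank, residue in enumerate(chain.residues):
            t = rank / n_res
            hue = (SPECTRUM_HUE_RANGE[0]
                   + t * (SPECTRUM_HUE_RANGE[1] - SPECTRUM_HUE_RANGE[0]))
            rgb = colorsys.hsv_to_rgb((hue % 360.0) / 360.0, 1.0, 1.0)
            for _ in residue.atoms:
                colors[i] = rgb
                i += 1
    return colors


def atom_colors(s: Structure, scheme: str = "atom") -> np.ndarray:
    """Per-atom RGB (in [0,1]) for one of the seven color schemes."""
    if scheme not in COLOR_SCHEMES:
        raise UnknownSchemeError(
            f"unknown color scheme {scheme!r}; choose from {COLOR_SCHEMES}")
    atoms = s.atoms
    n = len(atoms)
    if scheme == "spectrum":
        return _spectrum_colors(s, n)
    colors = np.zeros((n, 3))
    if scheme == "chain":
        chain_rgb = {c.id: CHAIN_PALETTE[k % len(CHAIN_PALETTE)]
                     for k, c in enumerate(s.chains)}
        for i, a in enumerate(atoms):
            colors[i] = chain_rgb[a.chain_id]
    elif scheme == "secondary":
        i = 0
        for residue in s.residues():
            for _ in residue.atoms:
                colors[i] = SECONDARY_PALETTE[residue.ss]
                i += 1
    elif scheme == "bfactor":
        b = np.array([a.b_factor for a in atoms], dtype=float)
        span = b.max() - b.min()
        t = (b - b.min()) / span if span > 0 else np.full(n, 0.5)
        colors[:, 0] = t            # cold (blue) -> hot (red), monotone
        colors[:, 2] = 1.0 - t
    elif scheme == "residue":
        for i, a in enumerate(atoms):
            colors[i] = RESIDUE_PALETTE.get(a.res_name.strip().upper(),
                                            RESIDUE_DEFAULT)
    elif scheme == "polarity":
        for i, a in enumerate(atoms):
            polar = a.res_name.strip().upper() in POLAR_RESIDUES
            colors[i] = POLAR_COLOR if polar else NONPOLAR_COLOR
    else:  # atom (CPK)
        for i, a in enumerate(atoms):
            colors[i] = CPK_COLORS.get(a.element.upper(), CPK_DEFAULT)
    return colors


# -- connectivity -------------------------------------------------------------

def derive_bonds(s: Structure) -> list[tuple[int, int]]:
    """Covalent bonds by the distance rule, plus explicit CONECT pairs.

    Bond iff d < 1.2 x (sum of covalent radii), found with a KD-tree;
    CONECT records are honored additively even beyond the threshold.
    """
    atoms = s.atoms
    if len(atoms) < 2:
        return []
    positions = np.array([a.position for a in atoms])
    radii = np.array([chem.covalent_radius(a.element) for a in atoms])
    tree = cKDTree(positions)
    max_cut = BOND_TOLERANCE * 2.0 * radii.max()
    bonds: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(max_cut):
        d = np.linalg.norm(positions[i] - positions[j])
        if d < BOND_TOLERANCE * (radii[i] + radii[j]) and d > 1e-6:
            bonds.add((min(i, j), max(i, j)))
    if s.conect:
        by_serial = {a.serial: i for i, a in enumerate(atoms)}
        for sa, sb in s.conect:
            i, j = by_serial.get(sa), by_serial.get(sb)
            if i is not None and j is not None and i != j:
                bonds.add((min(i, j), max(i, j)))
    return sorted(bonds)


# -- geometric primitives -----------------------------------------------------

def icosphere(subdivisions: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: 20 * 4**s faces, evenly tessellated."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.array(verts[i]) + np.array(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc),
                          (ab, bc, ca)]
        faces = new_faces
    return np.array(verts), np.array(faces, dtype=np.int64)


def _cylinder(p0: np.ndarray, p1: np.ndarray, radius: float, n_sides: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open cylinder between two points: 2n vertices, 2n side triangles."""
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        return np.zeros((0, 3)), np.zeros((0, 3), np.int64), np.zeros((0, 3))
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    angles = 2 * np.pi * np.arange(n_sides) / n_sides
    ring = (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
    verts = np.concatenate([p0 + radius * ring, p1 + radius * ring])
    normals = np.concatenate([ring, ring])
    faces = []
    for k in range(n_sides):
        k2 = (k + 1) % n_sides
        faces += [(k, k2, n_sides + k), (k2, n_sides + k2, n_sides + k)]
    return verts, np.array(faces, dtype=np.int64), normals


class _BatchBuilder:
    def __init__(self, kind: str):
        self.kind = kind
        self.positions: list[np.ndarray] = []
        self.colors: list[np.ndarray] = []
        self.indices: list[np.ndarray] = []
        self.source: list[np.ndarray] = []
        self.normals: list[np.ndarray] = []
        self._offset = 0

    def add(self, positions, indices, color, atom_index, normals=None):
        positions = np.atleast_2d(positions)
        n = len(positions)
        if n == 0:
            return
        self.positions.append(positions)
        color = np.atleast_2d(color)
        self.colors.append(np.broadcast_to(color, (n, 3)).copy()
                           if len(color) != n else color)
        self.indices.append(np.atleast_2d(indices) + self._offset)
        atom_index = np.atleast_1d(atom_index)
        self.source.append(np.broadcast_to(atom_index, (n,)).copy()
                           if len(atom_index) != n else atom_index)
        if normals is not None:
            self.normals.append(np.atleast_2d(normals))
        self._offset += n

    def build(self) -> GeometryBatch:
        if not self.positions:
            return _empty_batch(self.kind)
        normals = (np.concatenate(self.normals)
                   if self.normals and sum(map(len, self.normals)) == self._offset
                   else None)
        return GeometryBatch(
            kind=self.kind,
            positions=np.concatenate(self.positions),
            colors=np.concatenate(self.colors),
            indices=np.concatenate(self.indices).astype(np.int64),
            source_atoms=np.concatenate(self.source).astype(np.int64),
            normals=normals)


# -- primary structure --------------------------------------------------------

PRIMARY_REPRESENTATIONS = ("line", "stick", "ball_stick", "sphere", "dot")


def build_primary(s: Structure, rep: str = "line",
                  color_scheme: str = "atom",
                  colors: np.ndarray | None = None,
                  stick_radius: float = STICK_RADIUS,
                  n_sides: int = 12,
                  subdivisions: int = 2) -> GeometryBatch:
    """Geometry for a primary-structure representation.

    line - one bicolor segment pair per bond (split at the midpoint);
    stick - two half-cylinders per bond; ball_stick - sticks plus spheres
    at 0.4 x VdW; sphere - one icosphere per atom at full VdW radius;
    dot - one point per atom.
    """
    if rep not in PRIMARY_REPRESENTATIONS:
        raise UnknownRepresentationError(f"unknown representation {rep!r}")
    atoms = s.atoms
    if colors is None:
        colors = atom_colors(s, color_scheme)
    positions = np.array([a.position for a in atoms]) if atoms \
        else np.zeros((0, 3))

    if rep == "dot":
        builder = _BatchBuilder("points")
        for i in range(len(atoms)):
            builder.add(positions[i], np.array([[0]]), colors[i], i)
        return builder.build()

    if rep == "sphere" or rep == "ball_stick":
        sphere_scale = 1.0 if rep == "sphere" else BALL_SCALE
        tri = _BatchBuilder("triangles")
        unit_v, unit_f = icosphere(subdivisions)
        for i, atom in enumerate(atoms):
            r = sphere_scale * (atom.vdw_radius or chem.vdw_radius(atom.element))
            tri.add(positions[i] + r * unit_v, unit_f, colors[i], i,
                    normals=unit_v)
        if rep == "sphere":
            return tri.build()
    else:
        tri = _BatchBuilder("triangles")

    bonds = derive_bonds(s)
    if rep == "line":
        builder = _BatchBuilder("lines")
        for i, j in bonds:
            mid = (positions[i] + positions[j]) / 2.0
            builder.add(np.array([positions[i], mid]), np.array([[0, 1]]),
                        colors[i], i)
            builder.add(np.array([mid, positions[j]]), np.array([[0, 1]]),
                        colors[j], j)
        return builder.build()

    # stick / ball_stick cylinders
    for i, j in bonds:
        mid = (positions[i] + positions[j]) / 2.0
        for a_idx, (p0, p1) in ((i, (positions[i], mid)),
                                (j, (mid, positions[j]))):
            verts, faces, normals = _cylinder(p0, p1, stick_radius, n_sides)
            tri.add(verts, faces, colors[a_idx], a_idx, normals=normals)
    return tri.build()


# -- secondary structure ------------------------------------------------------

SECONDARY_REPRESENTATIONS = ("ribbon", "strand", "ca_trace", "tube_b",
                             "cylinder_plate")


def catmull_rom(control: np.ndarray,
                subdivisions: int = SPLINE_SUBDIVISIONS) -> np.ndarray:
    """Uniform Catmull-Rom spline through all control points.

    Endpoints are duplicated so the curve starts and ends exactly on the
    first and last control point; every control point lies on the curve.
    """
    control = np.asarray(control, dtype=float)
    if len(control) < 2:
        return control.copy()
    padded = np.concatenate([control[:1], control, control[-1:]])
    t = np.linspace(0.0, 1.0, subdivisions, endpoint=False)
    points = []
    for k in range(len(control) - 1):
        p0, p1, p2, p3 = padded[k], padded[k + 1], padded[k + 2], padded[k + 3]
        tt, tt2, tt3 = t[:, None], (t ** 2)[:, None], (t ** 3)[:, None]
        seg = 0.5 * ((2 * p1) + (-p0 + p2) * tt
                     + (2 * p0 - 5 * p1 + 4 * p2 - p3) * tt2
                     + (-p0 + 3 * p1 - 3 * p2 + p3) * tt3)
        points.append(seg)
    points.append(control[-1:])
    return np.concatenate(points)


def _chain_traces(s: Structure):
    """Per chain: (ca atoms global indices, positions, residues)."""
    atoms = s.atoms
    index_of = {id(a): i for i, a in enumerate(atoms)}
    for chain in s.chains:
        ca, residues = [], []
        for residue in chain.residues:
            for atom in residue.atoms:
                if atom.name.strip().upper() == "CA" and not atom.is_hetero:
                    ca.append(index_of[id(atom)])
                    residues.append(residue)
                    break
        yield chain, ca, residues


def _transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported (normal, binormal) frames along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True),
                           1e-12)
    normals = np.zeros_like(points)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normals[0] = np.cross(tangents[0], ref)
    normals[0] /= np.linalg.norm(normals[0])
    for k in range(1, len(points)):
        n = normals[k - 1] - (normals[k - 1] @ tangents[k]) * tangents[k]
        norm = np.linalg.norm(n)
        normals[k] = n / norm if norm > 1e-12 else normals[k - 1]
    binormals = np.cross(tangents, normals)
    return normals, binormals


def _spline_colors(colors, ca_indices, subdivisions, n_points):
    """Per-spline-point color/atom attribution from the nearest residue."""
    owner = np.minimum(np.arange(n_points) // subdivisions,
                       len(ca_indices) - 1)
    atom_idx = np.array([ca_indices[o] for o in owner], dtype=np.int64)
    return colors[atom_idx], atom_idx


def build_secondary(s: Structure, rep: str = "ribbon",
                    color_scheme: str = "spectrum",
                    colors: np.ndarray | None = None,
                    subdivisions: int = SPLINE_SUBDIVISIONS,
                    width: float = RIBBON_WIDTH,
                    tube_scale: float = 0.3,
                    n_sides: int = 8) -> GeometryBatch:
    """Geometry for a secondary-structure representation.

    ribbon - flat extrusion of the backbone spline; strand - the bare
    spline polyline; ca_trace - straight polyline through C-alpha atoms;
    tube_b - tube whose radius tracks per-residue B factor
    (radius = tube_scale x B / mean(B)); cylinder_plate - one cylinder per
    helix (least-squares axis through its C-alphas), a flat plate per
    sheet run, a thin tube elsewhere. Chains with fewer than two C-alpha
    atoms contribute nothing (logged warning).
    """
    if rep not in SECONDARY_REPRESENTATIONS:
        raise UnknownRepresentationError(f"unknown representation {rep!r}")
    if colors is None:
        colors = atom_colors(s, color_scheme)
    kind = "lines" if rep in ("strand", "ca_trace") else "triangles"
    builder = _BatchBuilder(kind)
    atoms = s.atoms
    positions = np.array([a.position for a in atoms]) if atoms \
        else np.zeros((0, 3))

    for chain, ca_indices, residues in _chain_traces(s):
        if len(ca_indices) < 2:
            if chain.residues:
                logger.warning("chain %r has < 2 C-alpha atoms; skipped",
                               chain.id)
            continue
        control = positions[ca_indices]
        if rep == "ca_trace":
            idx = np.column_stack([np.arange(len(control) - 1),
                                   np.arange(1, len(control))])
            builder.add(control, idx, colors[ca_indices],
                        np.array(ca_indices))
            continue
        spline = catmull_rom(control, subdivisions)
        pt_colors, pt_atoms = _spline_colors(colors, ca_indices,
                                             subdivisions, len(spline))
        if rep == "strand":
            idx = np.column_stack([np.arange(len(spline) - 1),
                                   np.arange(1, len(spline))])
            builder.add(spline, idx, pt_colors, pt_atoms)
        elif rep == "ribbon":
            _add_ribbon(builder, spline, pt_colors, pt_atoms, width)
        elif rep == "tube_b":
            b = np.array([np.mean([a.b_factor for a in r.atoms])
                          for r in residues])
            mean_b = b.mean() if b.mean() > 0 else 1.0
            radii_ctrl = tube_scale * b / mean_b
            owner = np.minimum(np.arange(len(spline)) // subdivisions,
                               len(ca_indices) - 1)
            _add_tube(builder, spline, radii_ctrl[owner], pt_colors,
                      pt_atoms, n_sides)
        else:  # cylinder_plate
            _add_cylinder_plate(builder, control, residues, ca_indices,
                                colors, subdivisions, width, n_sides)
    return builder.build()


def _add_ribbon(builder, spline, pt_colors, pt_atoms, width):
    normals, binormals = _transport_frames(spline)
    half = 0.5 * width * binormals
    left, right = spline - half, spline + half
    n = len(spline)
    verts = np.empty((2 * n, 3))
    verts[0::2], verts[1::2] = left, right
    vcolors = np.repeat(pt_colors, 2, axis=0)
    vatoms = np.repeat(pt_atoms, 2)
    vnormals = np.repeat(normals, 2, axis=0)
    faces = []
    for k in range(n - 1):
        a, b, c, d = 2 * k, 2 * k + 1, 2 * k + 2, 2 * k + 3
        faces += [(a, b, c), (b, d, c)]
    builder.add(verts, np.array(faces, dtype=np.int64), vcolors, vatoms,
                normals=vnormals)


def _add_tube(builder, spline, radii, pt_colors, pt_atoms, n_sides):
    normals, binormals = _transport_frames(spline)
    angles = 2 * np.pi * np.arange(n_sides) / n_sides
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    n = len(spline)
    verts = np.empty((n * n_sides, 3))
    vnormals = np.empty_like(verts)
    for k in range(n):
        ring_dir = np.outer(cos_a, normals[k]) + np.outer(sin_a, binormals[k])
        verts[k * n_sides:(k + 1) * n_sides] = spline[k] + radii[k] * ring_dir
        vnormals[k * n_sides:(k + 1) * n_sides] = ring_dir
    faces = []
    for k in range(n - 1):
        for m in range(n_sides):
            m2 = (m + 1) % n_sides
            a, b = k * n_sides + m, k * n_sides + m2
            c, d = (k + 1) * n_sides + m, (k + 1) * n_sides + m2
            faces += [(a, b, c), (b, d, c)]
    builder.add(verts, np.array(faces, dtype=np.int64),
                np.repeat(pt_colors, n_sides, axis=0),
                np.repeat(pt_atoms, n_sides), normals=vnormals)


def _ss_runs(residues):
    runs = []
    start = 0
    for k in range(1, len(residues) + 1):
        if k == len(residues) or residues[k].ss != residues[start].ss:
            runs.append((residues[start].ss, start, k))
            start = k
    return runs


def _add_cylinder_plate(builder, control, residues, ca_indices, colors,
                        subdivisions, width, n_sides):
    for ss, start, end in _ss_runs(residues):
        pts = control[start:end]
        idx = ca_indices[start:end]
        mid_atom = idx[len(idx) // 2]
        color = colors[idx]
        if ss == "helix" and len(pts) >= 2:
            centroid = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centroid)
            axis = vt[0]
            proj = (pts - centroid) @ axis
            p0 = centroid + proj.min() * axis
            p1 = centroid + proj.max() * axis
            verts, faces, normals = _cylinder(p0, p1, 2.3, max(n_sides, 12))
            builder.add(verts, faces, colors[mid_atom], mid_atom,
                        normals=normals)
        elif ss == "sheet" and len(pts) >= 2:
            spline = catmull_rom(pts, subdivisions)
            owner = np.minimum(np.arange(len(spline)) // subdivisions,
                               len(idx) - 1)
            _add_ribbon(builder, spline, color[owner],
                        np.array(idx)[owner], width)
        elif len(pts) >= 2:
            spline = catmull_rom(pts, subdivisions)
            owner = np.minimum(np.arange(len(spline)) // subdivisions,
                               len(idx) - 1)
            _add_tube(builder, spline, np.full(len(spline), 0.2),
                      color[owner], np.array(idx)[owner], n_sides)
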