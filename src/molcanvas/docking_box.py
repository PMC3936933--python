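"""Automatic cubic docking-box determination and containment checks.

The binding site is detected from the largest co-crystallized ligand
(most atoms among non-water, non-ion HETATM groups). The box is the
smallest cube covering the ligand, then extended by 50% in all three
dimensions to leave room for conformational sampling. Without a
co-crystallized ligand the box defaults to the geometric center of the
protein with a default edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ION_NAMES, WATER_NAMES
from .structure_io import Residue, Structure

__all__ = ["Box", "find_largest_ligand", "auto_box", "box_contains"]

MIN_EDGE = 10.0       # Angstrom floor for degenerate (e.g. 1-atom) ligands
DEFAULT_EDGE = 20.0   # Angstrom edge when no ligand exists


@dataclass
class Box:
    """Axis-aligned binding-site region: cubic by default.

    ``edge`` may be a scalar (cube) or a per-axis 3-vector after manual
    adjustment.
    """

    center: np.ndarray
    edge: float | np.ndarray

    @property
    def half_extent(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.edge, dtype=float),
                               (3,)) / 2.0


def find_largest_ligand(s: Structure,
                        exclude: set[str] | None = None) -> Residue | None:
    """Largest eligible hetero residue group, ties broken by file order.

    Waters (HOH/WAT/DOD) and common ions / crystallization additives are
    excluded; the exclusion list is overridable.
    """
    excluded = WATER_NAMES | (ION_NAMES if exclude is None else exclude)
    best: Residue | None = None
    for residue in s.residues():
        if not residue.atoms or not residue.atoms[0].is_hetero:
            continue
        if residue.name.strip().upper() in excluded:
            continue
        if best is None or len(residue.atoms) > len(best.atoms):
            best = residue
    return best


def _protein_coords(s: Structure) -> np.ndarray:
    coords = [a.position for a in s.atoms if not a.is_hetero]
    if not coords:
        coords = [a.position for a in s.atoms]
    return np.array(coords, dtype=float)


def auto_box(s: Structure, expand_fraction: float = 0.5,
             min_edge: float = MIN_EDGE, default_edge: float = DEFAULT_EDGE,
             cubic: bool = True) -> Box:
    """Binding-site box from the largest ligand, or the protein centroid.

    With a ligand: center = midpoint of the ligand coordinate extremes;
    edge = (1 + expand_fraction) x the largest per-axis extent (the tight
    covering cube expanded), floored at ``min_edge``. ``cubic=False``
    expands each axis independently instead (rectangular box). Without a
    ligand: center = unweighted protein centroid, edge = ``default_edge``.
    """
    ligand = find_largest_ligand(s)
    if ligand is None:
        coords = _protein_coords(s)
        return Box(center=coords.mean(axis=0), edge=float(default_edge))
    coords = np.array([a.position for a in ligand.atoms], dtype=float)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    center = (lo + hi) / 2.0
    if cubic:
        edge = float(max((1.0 + expand_fraction) * float((hi - lo).max()),
                         min_edge))
        return Box(center=center, edge=edge)
    edge = np.maximum((1.0 + expand_fraction) * (hi - lo), min_edge)
    return Box(center=center, edge=edge)


def box_contains(box: Box, m: Structure | np.ndarray) -> tuple[bool, int]:
    """Whether every atom lies inside the (closed) box.

    Returns (all_inside, number_of_atoms_outside).
    """
    coords = m.coords() if isinstance(m, Structure) else np.asarray(m, float)
    if coords.size == 0:
        return True, 0
    half = box.half_extent
    inside = np.all(np.abs(coords - box.center[None, :]) <= half[None, :],
                    axis=1)
    outside = int((~inside).sum())
    return outside == 0, outside
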