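"""Geometric intermolecular hydrogen-bond detection.

A putative hydrogen bond is a receptor/ligand donor-acceptor pair whose
heavy-atom separation is at most the cutoff (default 3.5 A). Distance is
measured donor-to-acceptor; no angular criterion is applied.

Donor/acceptor chemistry:

* PDBQT route (AutoDock types present): acceptors are type OA/NA/SA;
  donors are N or O with a covalently attached polar hydrogen (type HD
  within 1.3 A).
* PDB route (typically no hydrogens): donors are backbone N, side-chain N
  of Lys/Arg/His/Trp/Asn/Gln and hydroxyl O of Ser/Thr/Tyr; acceptors are
  every O plus side-chain N of His. Hetero-group N/O take both roles.

These tables are documented defaults, overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import AUTODOCK_ACCEPTOR_TYPES
from .structure_io import Atom, Structure

__all__ = [
    "HydrogenBond",
    "AtomRef",
    "assign_donors_acceptors",
    "detect_hbonds",
    "make_labels",
]

DEFAULT_CUTOFF = 3.5        # heavy-atom donor-acceptor distance, Angstrom
COVALENT_H_CUTOFF = 1.3     # N/O-H attachment distance, Angstrom

_SIDECHAIN_N_DONORS = {"LYS", "ARG", "HIS", "TRP", "ASN", "GLN"}
_HYDROXYL_O_DONORS = {"SER", "THR", "TYR"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomRef:
    """Stable reference to one atom of one molecule."""

    molecule: str       # 'receptor' or 'ligand'
    chain_id: str
    res_name: str
    res_seq: int
    atom_name: str
    serial: int
    position: tuple[float, float, float]

    @property
    def label(self) -> str:
        return (f"{self.chain_id.strip() or '_'}:{self.res_name} "
                f"{self.res_seq}:{self.atom_name.strip()}")


@dataclass(frozen=True)
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef
    length: float


def _is_pdbqt(atoms: list[Atom]) -> bool:
    return any(a.pdbqt_type for a in atoms)


def _assign_pdbqt(atoms: list[Atom]) -> None:
    positions = np.array([a.position for a in atoms])
    hd_positions = np.array([a.position for a in atoms
                             if (a.pdbqt_type or "").upper() == "HD"])
    hd_tree = cKDTree(hd_positions) if len(hd_positions) else None
    for i, atom in enumerate(atoms):
        ad_type = (atom.pdbqt_type or "").upper()
        atom.is_acceptor = ad_type in AUTODOCK_ACCEPTOR_TYPES
        atom.is_donor = False
        if atom.element.upper() in ("N", "O") and hd_tree is not None:
            near = hd_tree.query_ball_point(positions[i], COVALENT_H_CUTOFF)
            atom.is_donor = len(near) > 0


def _assign_pdb(atoms: list[Atom]) -> None:
    for atom in atoms:
        element = atom.element.upper()
        name = atom.name.strip().upper()
        res = atom.res_name.strip().upper()
        atom.is_donor = atom.is_acceptor = False
        if element not in ("N", "O"):
            continue
        if atom.is_hetero:
            atom.is_donor = atom.is_acceptor = True
            continue
        if element == "O":
            atom.is_acceptor = True
            if res in _HYDROXYL_O_DONORS and name not in _BACKBONE_NAMES:
                atom.is_donor = True
        else:  # nitrogen
            if name == "N":
                atom.is_donor = True
            elif res in _SIDECHAIN_N_DONORS:
                atom.is_donor = True
            if res == "HIS" and name != "N":
                atom.is_acceptor = True


def assign_donors_acceptors(s: Structure) -> Structure:
    """Flag hydrogen-bond donors and acceptors in place (and return s)."""
    atoms = s.atoms
    if not atoms:
        return s
    if _is_pdbqt(atoms):
        _assign_pdbqt(atoms)
    else:
        _assign_pdb(atoms)
    return s


def _ref(atom: Atom, molecule: str) -> AtomRef:
    return AtomRef(molecule=molecule, chain_id=atom.chain_id,
                   res_name=atom.res_name, res_seq=atom.res_seq,
                   atom_name=atom.name, serial=atom.serial,
                   position=tuple(float(x) for x in atom.position))


def detect_hbonds(receptor: Structure, ligand: Structure,
                  cutoff: float = DEFAULT_CUTOFF,
                  annotate: bool = True) -> list[HydrogenBond]:
    """All cross-molecule donor-acceptor pairs within the distance cutoff.

    Both (receptor-donor, ligand-acceptor) and (receptor-acceptor,
    ligand-donor) directions are searched; each unordered atom pair is
    reported once, sorted by length ascending.
    """
    if annotate:
        assign_donors_acceptors(receptor)
        assign_donors_acceptors(ligand)
    rec_atoms = receptor.atoms
    lig_atoms = ligand.atoms
    if not rec_atoms or not lig_atoms:
        return []
    bonds: dict[tuple[int, int], HydrogenBond] = {}

    def _scan(donors, acceptors, donor_mol, acceptor_mol):
        if not donors or not acceptors:
            return
        tree = cKDTree(np.array([a.position for a in acceptors]))
        for donor in donors:
            for j in tree.query_ball_point(donor.position, cutoff):
                acceptor = acceptors[j]
                length = float(np.linalg.norm(donor.position
                                              - acceptor.position))
                key = ((0, donor.serial), (1, acceptor.serial)) \
                    if donor_mol == "receptor" \
                    else ((0, acceptor.serial), (1, donor.serial))
                bond = HydrogenBond(donor=_ref(donor, donor_mol),
                                    acceptor=_ref(acceptor, acceptor_mol),
                                    length=length)
                prev = bonds.get(key)
                if prev is None or length < prev.length:
                    bonds[key] = bond

    _scan([a for a in rec_atoms if a.is_donor],
          [a for a in lig_atoms if a.is_acceptor], "receptor", "ligand")
    _scan([a for a in lig_atoms if a.is_donor],
          [a for a in rec_atoms if a.is_acceptor], "ligand", "receptor")
    return sorted(bonds.values(),
                  key=lambda b: (b.length, b.donor.serial, b.acceptor.serial))


def make_labels(bonds: list[HydrogenBond]
                ) -> list[tuple[AtomRef, str, np.ndarray]]:
    """One label per distinct atom participating in at least one bond.

    Text format is ``chain:resname resseq:atomname``; the anchor is the
    atom position. Deterministic order: molecule then serial.
    """
    seen: dict[tuple[str, int], AtomRef] = {}
    for bond in bonds:
        for ref in (bond.donor, bond.acceptor):
            seen.setdefault((ref.molecule, ref.serial), ref)
    refs = sorted(seen.values(), key=lambda r: (r.molecule, r.serial))
    return [(r, r.label, np.array(r.position)) for r in refs]
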