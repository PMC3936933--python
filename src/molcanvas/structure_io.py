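"""PDB / PDBQT parsing into a chain -> residue -> atom domain model.

The PDB reader follows wwPDB v3.3 fixed columns; the PDBQT reader handles
the AutoDock docking dialect (MODEL blocks carrying poses, partial charge
and atom-type columns, ROOT/BRANCH/TORSDOF torsion-tree records, REMARK
lines with predicted binding energies). Malformed atom lines are skipped
with a logged warning; parsing only fails if nothing survives.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .errors import (
    EmptyInputError,
    InconsistentModelsError,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "DockedEnsemble",
    "parse_pdb",
    "parse_pdbqt",
    "assign_elements_and_radii",
    "assign_secondary_structure",
    "fetch",
]


@dataclass
class Atom:
    """One ATOM/HETATM record.

    ``position`` is in Angstrom, right-handed axes as stored in the file.
    ``element`` and ``vdw_radius`` are filled by
    :func:`assign_elements_and_radii`; ``pdbqt_type``/``partial_charge``
    only exist for PDBQT input. ``is_donor``/``is_acceptor`` are set by
    :func:`molcanvas.interactions.assign_donors_acceptors`.
    """

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    vdw_radius: float = 0.0
    pdbqt_type: str | None = None
    partial_charge: float | None = None
    is_hetero: bool = False
    is_donor: bool = False
    is_acceptor: bool = False


@dataclass
class Residue:
    name: str
    seq: int
    insertion_code: str
    atoms: list[Atom] = field(default_factory=list)
    ss: str = "coil"  # one of helix / sheet / coil

    @property
    def is_water(self) -> bool:
        return self.name.strip().upper() in chem.WATER_NAMES


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """Hierarchical molecule model: chains -> residues -> atoms."""

    id: str = ""
    chains: list[Chain] = field(default_factory=list)
    conect: list[tuple[int, int]] = field(default_factory=list)
    ss_records: list[tuple[str, str, int, int]] = field(default_factory=list)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    @property
    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        atoms = self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass
class DockedEnsemble:
    """Ordered ligand conformations from a multi-MODEL PDBQT file.

    ``energies`` holds one value (kcal/mol) or None per model;
    ``energy_remarks`` records which REMARK line each energy came from.
    """

    models: list[Structure] = field(default_factory=list)
    energies: list[float | None] = field(default_factory=list)
    energy_remarks: list[str | None] = field(default_factory=list)


# -- low-level record readers -------------------------------------------------

def _safe_float(text: str, default: float = 0.0) -> float:
    try:
        return float(text)
    except ValueError:
        return default


def _parse_atom_line(line: str, pdbqt: bool) -> Atom | None:
    """Parse one ATOM/HETATM line; None when mandatory columns are missing."""
    if len(line.rstrip("\n")) < 54:
        logger.warning("skipping short atom record: %r", line.rstrip())
        return None
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        logger.warning("skipping unparseable coordinates: %r", line.rstrip())
        return None
    if not np.all(np.isfinite([x, y, z])):
        logger.warning("skipping non-finite coordinates: %r", line.rstrip())
        return None
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    element_col = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element_col.isalpha():
        element_col = ""
    atom = Atom(
        serial=serial,
        name=line[12:16],
        alt_loc=line[16:17],
        res_name=line[17:20].strip(),
        chain_id=line[21:22],
        res_seq=int(line[22:26]) if line[22:26].strip() else 0,
        insertion_code=line[26:27],
        position=np.array([x, y, z], dtype=float),
        occupancy=_safe_float(line[54:60].strip() or "1", 1.0),
        b_factor=_safe_float(line[60:66].strip() or "0", 0.0),
        element="" if pdbqt else element_col,
        is_hetero=line.startswith("HETATM"),
    )
    if pdbqt:
        tail = line[66:].rstrip()
        pdbqt_type = line[77:79].strip() if len(line) >= 78 else ""
        charge_text = line[70:76].strip() if len(line) >= 76 else ""
        if not pdbqt_type or not charge_text:
            tokens = tail.split()
            if tokens:
                pdbqt_type = pdbqt_type or tokens[-1]
                if not charge_text and len(tokens) >= 2:
                    charge_text = tokens[-2]
        if pdbqt_type:
            atom.pdbqt_type = pdbqt_type.upper()
        if charge_text:
            try:
                atom.partial_charge = float(charge_text)
            except ValueError:
                pass
    return atom


def _keep_altloc(atom: Atom) -> bool:
    return atom.alt_loc in (" ", "A")


def _build_structure(atoms: list[Atom], struct_id: str = "") -> Structure:
    """Group a flat atom list into chains and residues, preserving order."""
    structure = Structure(id=struct_id)
    chain: Chain | None = None
    residue: Residue | None = None
    for atom in atoms:
        if chain is None or atom.chain_id != chain.id:
            chain = next((c for c in structure.chains if c.id == atom.chain_id), None)
            if chain is None:
                chain = Chain(id=atom.chain_id)
                structure.chains.append(chain)
            residue = chain.residues[-1] if chain.residues else None
        key = (atom.res_seq, atom.insertion_code, atom.res_name)
        if residue is None or (residue.seq, residue.insertion_code, residue.name) != key:
            residue = Residue(name=atom.res_name, seq=atom.res_seq,
                              insertion_code=atom.insertion_code)
            chain.residues.append(residue)
        residue.atoms.append(atom)
    return structure


def _parse_ss_record(line: str) -> tuple[str, str, int, int] | None:
    try:
        if line.startswith("HELIX") and len(line) >= 38:
            return ("helix", line[19], int(line[21:25]), int(line[33:37]))
        if line.startswith("SHEET") and len(line) >= 38:
            return ("sheet", line[21], int(line[22:26]), int(line[33:37]))
    except ValueError:
        logger.warning("skipping malformed secondary-structure record: %r",
                       line.rstrip())
    return None


# -- public parsers -----------------------------------------------------------

def parse_pdb(text: str, struct_id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Keeps alt-locs ' '/'A' only; for multi-model (NMR) files only MODEL 1
    is retained. HELIX/SHEET records are captured for
    :func:`assign_secondary_structure`; CONECT pairs are kept for bond
    derivation.
    """
    if not text.strip():
        raise EmptyInputError("no records in PDB input")
    atoms: list[Atom] = []
    ss_records = []
    conect: list[tuple[int, int]] = []
    saw_record = False
    skipped = 0
    model_no = 0
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            model_no += 1
            continue
        if rec in ("ATOM", "HETATM"):
            saw_record = True
            if model_no > 1:
                continue
            atom = _parse_atom_line(line, pdbqt=False)
            if atom is None:
                skipped += 1
            elif _keep_altloc(atom):
                atoms.append(atom)
        elif rec in ("HELIX", "SHEET"):
            ss = _parse_ss_record(line)
            if ss is not None:
                ss_records.append(ss)
        elif rec == "CONECT":
            try:
                serials = [int(line[i:i + 5]) for i in (6, 11, 16, 21, 26)
                           if len(line) > i and line[i:i + 5].strip()]
            except ValueError:
                continue
            conect.extend((serials[0], s) for s in serials[1:])
    if not saw_record:
        raise EmptyInputError("no ATOM/HETATM records in PDB input")
    if not atoms:
        raise MalformedRecordError(
            f"all {skipped} atom records were malformed; nothing parsed")
    structure = _build_structure(atoms, struct_id)
    structure.ss_records = ss_records
    structure.conect = conect
    return structure


_ENERGY_TOKENS = ("RESULT", "ENERGY", "AFFINITY", "KCAL")
_FLOAT_RE = re.compile(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?")


def _remark_energy(line: str) -> float | None:
    upper = line.upper()
    if not any(tok in upper for tok in _ENERGY_TOKENS):
        return None
    for match in _FLOAT_RE.finditer(line[6:]):
        text = match.group()
        # skip bare integers that are just remark numbering
        if "." in text or "e" in text.lower():
            return float(text)
    return None


def parse_pdbqt(text: str, struct_id: str = "") -> DockedEnsemble:
    """Parse PDBQT text into a :class:`DockedEnsemble`.

    One model per MODEL/ENDMDL block (the whole file is a single model when
    no MODEL lines occur). Per-model energy is taken from the first REMARK
    line carrying a recognizable energy token and a float; torsion-tree
    records (ROOT/BRANCH/ENDBRANCH/TORSDOF) are tolerated and ignored.
    """
    if not text.strip():
        raise EmptyInputError("no records in PDBQT input")
    blocks: list[list[str]] = []
    current: list[str] = []
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            if current:
                blocks.append(current)
            current = []
        elif rec == "ENDMDL":
            blocks.append(current)
            current = []
        else:
            current.append(line)
    if current or not blocks:
        blocks.append(current)
    if saw_model:
        blocks = [b for b in blocks if any(
            ln[:6].strip() in ("ATOM", "HETATM") for ln in b)]

    ensemble = DockedEnsemble()
    saw_record = False
    for i, block in enumerate(blocks):
        atoms: list[Atom] = []
        energy = None
        remark_used = None
        for line in block:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                saw_record = True
                atom = _parse_atom_line(line, pdbqt=True)
                if atom is not None and _keep_altloc(atom):
                    atoms.append(atom)
            elif rec == "REMARK" and energy is None:
                value = _remark_energy(line)
                if value is not None:
                    energy = value
                    remark_used = line.strip()
        if not atoms:
            continue
        model = _build_structure(atoms, struct_id=f"{struct_id}|model{i + 1}")
        ensemble.models.append(model)
        ensemble.energies.append(energy)
        ensemble.energy_remarks.append(remark_used)
    if not saw_record:
        raise EmptyInputError("no ATOM/HETATM records in PDBQT input")
    if not ensemble.models:
        raise MalformedRecordError("all atom records were malformed")

    names = [[a.name for a in m.atoms] for m in ensemble.models]
    if any(n != names[0] for n in names[1:]):
        raise InconsistentModelsError(
            "models differ in atom count or atom ordering")
    for model in ensemble.models:
        assign_elements_and_radii(model)
    return ensemble


def assign_elements_and_radii(s: Structure) -> Structure:
    """Infer elements and assign van der Waals radii in place.

    Precedence: PDB element columns 77-78, then the AutoDock type map for
    PDBQT atoms, then an atom-name heuristic. Unknown elements get the
    default radius with a logged warning. Idempotent.
    """
    for atom in s.atoms:
        if not atom.element:
            element = None
            if atom.pdbqt_type:
                element = chem.AUTODOCK_ELEMENTS.get(atom.pdbqt_type.upper())
            if element is None:
                element = chem.element_from_name(
                    atom.name, atom.res_name, atom.is_hetero)
            if element is None:
                letters = "".join(c for c in atom.name if c.isalpha()).upper()
                element = (letters[:2] or "X")
                logger.warning(
                    "unknown element for atom %r; default radius applied",
                    atom.name.strip())
            atom.element = element
        if atom.vdw_radius <= 0:
            atom.vdw_radius = chem.vdw_radius(atom.element)
    return s


def assign_secondary_structure(s: Structure) -> Structure:
    """Apply captured HELIX/SHEET ranges to per-residue ss flags.

    Residues not covered by any record stay 'coil'. Ranges referencing
    unknown chains/residues are ignored with a warning.
    """
    by_chain = {c.id: c for c in s.chains}
    for kind, chain_id, start, end in s.ss_records:
        chain = by_chain.get(chain_id)
        if chain is None:
            logger.warning("ss record references unknown chain %r", chain_id)
            continue
        hit = False
        for residue in chain.residues:
            if start <= residue.seq <= end:
                residue.ss = kind
                hit = True
        if not hit:
            logger.warning("ss record %s %s %d-%d matched no residues",
                           kind, chain_id, start, end)
    return s


def fetch(pdb_id: str, timeout: float = 30.0) -> str:
    """Download PDB text for an entry id from the wwPDB REST endpoint."""
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as response:
        return response.read().decode("utf-8", errors="replace")
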