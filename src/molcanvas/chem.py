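"""Chemical reference tables shared across modules.

One van der Waals radii table (Bondi-style) is used everywhere: surfaces,
sphere representations, ball & stick scaling. Covalent radii drive the
distance-based bond rule in :mod:`molcanvas.representations`.
"""

from __future__ import annotations

# Bondi-style van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "FE": 2.00,
    "MN": 2.00,
    "CU": 1.40,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

# Covalent radii (single bond), Angstrom.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "SE": 1.20,
    "FE": 1.32,
    "ZN": 1.22,
    "MG": 1.41,
}
DEFAULT_COVALENT_RADIUS = 0.76

# AutoDock atom type -> chemical element.
AUTODOCK_ELEMENTS: dict[str, str] = {
    "H": "H", "HD": "H", "HS": "H",
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "P": "P",
    "F": "F", "CL": "CL", "BR": "BR", "I": "I",
    "MG": "MG", "MN": "MN", "ZN": "ZN", "CA": "CA", "FE": "FE",
    "SE": "SE", "CU": "CU", "NI": "NI", "K": "K",
}

# AutoDock acceptor types; HD marks polar (donatable) hydrogens.
AUTODOCK_ACCEPTOR_TYPES = {"OA", "NA", "SA"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Monoatomic ions and common crystallization additives excluded from
# ligand detection; documented, overridable.
ION_NAMES = {
    "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "CO", "NI",
    "CD", "HG", "SO4", "PO4",
}

# Two-letter element symbols recognized by the name heuristic (upper case).
_TWO_LETTER = {
    "CL", "BR", "MG", "ZN", "MN", "FE", "CU", "NI", "SE", "NA", "CA",
    "CD", "HG", "CO",
}
_ONE_LETTER = {"H", "C", "N", "O", "S", "P", "F", "K", "I"}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), DEFAULT_COVALENT_RADIUS)


def element_from_name(name: str, res_name: str, is_hetero: bool) -> str | None:
    """Infer a chemical element from a PDB atom name.

    Standard-residue atoms use the organic one-letter set (so `` CA `` in
    ALA is carbon); hetero atoms may resolve to two-letter metals (CA in a
    calcium site). Returns None when nothing matches.
    """
    stripped = name.strip().upper()
    if not stripped:
        return None
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if not letters:
        return None
    if res_name.strip().upper() in STANDARD_AMINO_ACIDS or not is_hetero:
        # Organic residue naming: first alphabetic character is the element,
        # except explicit two-letter halogens at the name start.
        if letters[:2] in {"CL", "BR"} and name[:1] != " ":
            return letters[:2]
        if letters[0] in _ONE_LETTER:
            return letters[0]
    # Hetero atoms: prefer a two-letter symbol, then one-letter.
    if letters[:2] in _TWO_LETTER:
        return letters[:2]
    if letters[0] in _ONE_LETTER:
        return letters[0]
    return None
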