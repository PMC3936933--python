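"""Deterministic synthetic PDB/PDBQT generators.

Every test-facing input is produced here, closed-form where possible, so
the whole suite runs without downloads and the same spec + seed always
yields byte-identical text. The only seeded randomness is the interior
jitter of ``ligand_blob``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

__all__ = ["FixtureSpec", "synth_pdb", "synth_pdbqt"]

# ideal alpha-helix backbone geometry for C-alpha traces
HELIX_RISE = 1.5          # Angstrom per residue
HELIX_TWIST_DEG = 100.0   # degrees per residue
HELIX_RADIUS = 2.3        # Angstrom

PDB_KINDS = {"diatomic", "mini_helix", "ligand_blob", "sphere_cluster"}
PDBQT_KINDS = {"docked_ensemble", "diatomic"}


@dataclass
class FixtureSpec:
    """Description of a synthetic structure: a kind plus its parameters."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _fmt_name(name: str) -> str:
    """PDB atom-name column convention: 1-2 char element starts at col 14."""
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def _atom_line(record: str, serial: int, name: str, res_name: str,
               chain: str, res_seq: int, pos, occupancy: float = 1.0,
               b: float = 0.0, element: str = "",
               pdbqt: tuple[float, str] | None = None) -> str:
    line = (f"{record:<6}{serial:>5} {_fmt_name(name)} {res_name:<3} "
            f"{chain}{res_seq:>4}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{occupancy:6.2f}{b:6.2f}")
    if pdbqt is not None:
        charge, ad_type = pdbqt
        line += f"    {charge:6.3f} {ad_type:<2}"
    else:
        line += f"          {element:>2}"
    return line


def _helix_record(chain: str, start: int, end: int, res: str = "ALA") -> str:
    return (f"HELIX  {1:>3} {'H1':>3} {res:>3} {chain} {start:>4}  "
            f"{res:>3} {chain} {end:>4} {1:>2}{'':>30}{end - start + 1:>6}")


def _sheet_record(chain: str, start: int, end: int, res: str = "ALA") -> str:
    return (f"SHEET  {1:>3} {'S1':>3}{1:>2} {res:>3} {chain}{start:>4}  "
            f"{res:>3} {chain}{end:>4}{0:>2}")


def helix_ca_positions(n: int) -> np.ndarray:
    """Ideal alpha-helix C-alpha coordinates (closed form)."""
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    return np.column_stack([HELIX_RADIUS * np.cos(theta),
                            HELIX_RADIUS * np.sin(theta),
                            HELIX_RISE * i])


def _synth_diatomic_pdb(p: dict) -> str:
    separation = float(p.get("separation", 3.4))
    elements = p.get("elements", ("N", "O"))
    res_names = p.get("res_names", ("LIG", "LIG"))
    hetero = bool(p.get("hetero", False))
    chain = p.get("chain", "A")
    record = "HETATM" if hetero else "ATOM"
    lines = [
        _atom_line(record, 1, elements[0], res_names[0], chain, 1,
                   (0.0, 0.0, 0.0), element=elements[0]),
        _atom_line(record, 2, elements[1], res_names[1], chain,
                   1 if res_names[0] == res_names[1] else 2,
                   (separation, 0.0, 0.0), element=elements[1]),
        "END",
    ]
    return "\n".join(lines) + "\n"


def _synth_mini_helix(p: dict) -> str:
    n = int(p.get("n", 12))
    if n < 2:
        raise InvalidSpecError("mini_helix needs n >= 2")
    chain = p.get("chain", "A")
    sheet_range = p.get("sheet_range")  # optional (start, end) strand span
    helix_range = p.get("helix_range", (1, n))
    positions = helix_ca_positions(n)
    lines = [_helix_record(chain, *helix_range)]
    if sheet_range is not None:
        lines.append(_sheet_record(chain, *sheet_range))
    b_factors = p.get("b_factors", [10.0] * n)
    for i, pos in enumerate(positions):
        lines.append(_atom_line("ATOM", i + 1, "CA", "ALA", chain, i + 1,
                                pos, b=float(b_factors[i]), element="C"))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _synth_ligand_blob(p: dict, seed: int) -> str:
    extents = np.asarray(p.get("extents", (10.0, 6.0, 4.0)), dtype=float)
    center = np.asarray(p.get("center", (0.0, 0.0, 0.0)), dtype=float)
    n = int(p.get("n", 12))
    if n < 2:
        raise InvalidSpecError("ligand_blob needs n >= 2 atoms")
    if np.any(extents < 0):
        raise InvalidSpecError("extents must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = center - extents / 2.0, center + extents / 2.0
    # two corner atoms pin the exact per-axis extents; the rest jitter inside
    positions = [lo, hi]
    for _ in range(n - 2):
        positions.append(lo + rng.random(3) * extents)
    elements = ["C"] * n
    if n >= 3:
        elements[2] = "O"
    if n >= 4:
        elements[3] = "N"
    lines = []
    for i, (pos, el) in enumerate(zip(positions, elements)):
        name = f"{el}{i + 1}"
        lines.append(_atom_line("HETATM", i + 1, name, "LIG", "L", 1,
                                np.round(pos, 3), element=el))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _synth_sphere_cluster(p: dict) -> str:
    centers = p.get("centers")
    if not centers:
        raise InvalidSpecError("sphere_cluster needs at least one center")
    elements = p.get("elements", ["C"] * len(centers))
    hetero = bool(p.get("hetero", False))
    record = "HETATM" if hetero else "ATOM"
    res_name = p.get("res_name", "UNK" if not hetero else "LIG")
    lines = []
    for i, (pos, el) in enumerate(zip(centers, elements)):
        lines.append(_atom_line(record, i + 1, f"{el}{i + 1}", res_name, "A",
                                i + 1, pos, element=el))
    lines.append("END")
    return "\n".join(lines) + "\n"


def synth_pdb(spec: FixtureSpec) -> str:
    """Render a synthetic PDB text for the given spec (byte-deterministic)."""
    if spec.kind == "diatomic":
        return _synth_diatomic_pdb(spec.params)
    if spec.kind == "mini_helix":
        return _synth_mini_helix(spec.params)
    if spec.kind == "ligand_blob":
        return _synth_ligand_blob(spec.params, spec.seed)
    if spec.kind == "sphere_cluster":
        return _synth_sphere_cluster(spec.params)
    raise InvalidSpecError(f"unknown PDB fixture kind {spec.kind!r}")


# default rigid ligand used by docked_ensemble: C-C-N(-HD)-OA skeleton,
# polar atoms present so hydrogen-bond tests have donors and acceptors
_LIGAND_TEMPLATE = [
    # name, autodock type, charge, position
    ("C1", "C", 0.05, (0.0, 0.0, 0.0)),
    ("C2", "C", 0.10, (1.5, 0.0, 0.0)),
    ("N1", "N", -0.35, (2.2, 1.2, 0.0)),
    ("H1", "HD", 0.16, (2.2, 2.21, 0.0)),
    ("O1", "OA", -0.40, (-0.7, 1.2, 0.0)),
]


def _synth_docked_ensemble(p: dict) -> str:
    k = int(p.get("k", 1))
    if k < 1:
        raise InvalidSpecError("docked_ensemble needs k >= 1 models")
    energies = p.get("energies")
    if energies is not None and len(energies) != k:
        raise InvalidSpecError("energies length must equal k")
    if p.get("permute_models"):
        raise InvalidSpecError(
            "atom ordering must be identical across models of an ensemble")
    template = p.get("atoms", _LIGAND_TEMPLATE)
    shift = float(p.get("model_shift", 0.5))
    lines = []
    for m in range(k):
        lines.append(f"MODEL {m + 1:>8}")
        if energies is not None and energies[m] is not None:
            lines.append("REMARK     NORMALIZED FREE ENERGY PREDICTED BY "
                         f"DOCKING: {energies[m]:8.2f} KCAL/MOL")
        lines.append("ROOT")
        offset = np.array([shift * m, 0.0, 0.0])
        for i, (name, ad_type, charge, pos) in enumerate(template):
            lines.append(_atom_line("ATOM", i + 1, name, "LIG", "L", 1,
                                    np.asarray(pos) + offset,
                                    pdbqt=(charge, ad_type)))
        lines.append("ENDROOT")
        lines.append("TORSDOF 0")
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def _synth_diatomic_pdbqt(p: dict) -> str:
    separation = float(p.get("separation", 3.4))
    types = p.get("types", ("N", "OA"))
    charges = p.get("charges", (-0.35, -0.40))
    chain = p.get("chain", "A")
    element_names = [t[0] + "1" for t in types]
    lines = [
        _atom_line("ATOM", 1, element_names[0], "RES", chain, 1,
                   (0.0, 0.0, 0.0), pdbqt=(charges[0], types[0])),
        _atom_line("ATOM", 2, element_names[1], "RES", chain, 2,
                   (separation, 0.0, 0.0), pdbqt=(charges[1], types[1])),
        "TORSDOF 0",
    ]
    return "\n".join(lines) + "\n"


def synth_pdbqt(spec: FixtureSpec) -> str:
    """Render synthetic PDBQT text (docking-dialect, byte-deterministic)."""
    if spec.kind == "docked_ensemble":
        return _synth_docked_ensemble(spec.params)
    if spec.kind == "diatomic":
        return _synth_diatomic_pdbqt(spec.params)
    raise InvalidSpecError(f"unknown PDBQT fixture kind {spec.kind!r}")
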