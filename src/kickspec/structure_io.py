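"""Molecular structure containers and PDB/XYZ input/output.

Coordinates are carried in Angstrom throughout the structure layer; the
integral layer converts to bohr. PDB parsing is delegated to gemmi; on top
of it this module applies a deterministic alternate-location policy (keep
the highest-occupancy conformer, ties broken toward blank/'A') and an
element-inference fallback for files with a missing element column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .elements import (
    ATOMIC_NUMBER,
    atomic_number,
    covalent_radius,
    normalize_symbol,
)

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "read_pdb",
    "write_pdb",
    "format_pdb",
    "read_xyz",
    "write_xyz",
    "select_ligand",
]

#: Residue name used to flag capping hydrogens in written PDB files.
CAP_RESIDUE_NAME = "CAP"

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HOH",
}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: element, position (Angstrom) and PDB provenance."""

    element: str
    position: np.ndarray
    serial: int = 0
    residue_name: str = ""
    residue_seq: int | None = None
    chain_id: str = ""
    alt_loc: str = ""
    is_cap: bool = False

    def __post_init__(self):
        sym = normalize_symbol(self.element)
        if sym not in ATOMIC_NUMBER:
            raise ValueError(f"unrecognized element symbol: {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "element", sym)
        object.__setattr__(self, "position", pos)

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBER[self.element]

    @property
    def covalent_radius(self) -> float:
        return covalent_radius(self.element)

    def moved_to(self, position) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class MolecularSystem:
    """An ordered collection of atoms with a total charge.

    ``n_electrons`` is always derived from the composition and the charge
    (sum of atomic numbers minus total charge); it is not stored.
    """

    atoms: list[AtomRecord]
    total_charge: int | None = None
    label: str = ""

    def __post_init__(self):
        self.atoms = list(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def nuclear_charge(self) -> int:
        return int(sum(a.atomic_number for a in self.atoms))

    @property
    def n_electrons(self) -> int:
        if self.total_charge is None:
            raise ValueError(
                f"total charge of system {self.label!r} has not been assigned"
            )
        n = self.nuclear_charge - self.total_charge
        if n < 0:
            raise ValueError("negative electron count")
        return n

    def positions(self) -> np.ndarray:
        """(n_atoms, 3) array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=int)

    def translated(self, shift) -> "MolecularSystem":
        shift = np.asarray(shift, dtype=float)
        return MolecularSystem(
            [a.moved_to(a.position + shift) for a in self.atoms],
            total_charge=self.total_charge,
            label=self.label,
        )

    def rotated(self, rotation) -> "MolecularSystem":
        """Apply a 3x3 rotation matrix about the origin."""
        R = np.asarray(rotation, dtype=float)
        return MolecularSystem(
            [a.moved_to(R @ a.position) for a in self.atoms],
            total_charge=self.total_charge,
            label=self.label,
        )


_TWO_LETTER = sorted((s for s in ATOMIC_NUMBER if len(s) == 2), key=str.upper)


def _element_from_atom_name(name: str) -> str | None:
    """Infer the element from a PDB atom name (fallback heuristic).

    Two-letter symbols (FE, CL, ...) are checked before one-letter ones so
    that e.g. ' FE1' resolves to iron, while 'CA ' in a standard residue
    context (alpha carbon) still resolves correctly because PDB format puts
    one-letter elements in column 14, not 13.
    """
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        return None
    # Names starting in column 13 with two alphabetic chars may be a
    # two-letter element; honour that reading first.
    if len(name) >= 2 and name[0] != " " and len(letters) >= 2:
        cand = normalize_symbol(letters[:2])
        if cand in _TWO_LETTER:
            return cand
    cand = normalize_symbol(letters[0])
    if cand in ATOMIC_NUMBER:
        return cand
    return None


def read_pdb(path) -> list[AtomRecord]:
    """Read ATOM/HETATM records from a PDB file.

    For alternate locations only the highest-occupancy conformer of each
    (chain, residue, atom name) is kept; occupancy ties are broken in favour
    of a blank altLoc, then 'A', then alphabetically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc

    records: list[AtomRecord] = []
    best: dict[tuple, tuple] = {}  # site key -> (rank, list index)
    if len(structure) == 0:
        raise ValueError(f"no coordinate records parsed from {path}")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                elem = atom.element.name if not atom.element.is_metal else atom.element.name
                if atom.element == gemmi.Element("X") or not elem:
                    elem = _element_from_atom_name(atom.name) or ""
                if not elem:
                    raise ValueError(
                        f"cannot determine element for atom {atom.name!r} "
                        f"in residue {residue.name} of {path}"
                    )
                rec = AtomRecord(
                    element=elem,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    serial=atom.serial,
                    residue_name=residue.name.strip(),
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name.strip(),
                    alt_loc=(atom.altloc or "").strip(),
                )
                key = (chain.name, residue.seqid.num, residue.name, atom.name)
                alt = (atom.altloc or "").strip()
                # lower rank wins; occupancy dominates, then blank < 'A' < ...
                rank = (-float(atom.occ), 0 if alt == "" else 1, alt)
                if key not in best:
                    best[key] = (rank, len(records))
                    records.append(rec)
                elif rank < best[key][0]:
                    records[best[key][1]] = rec
                    best[key] = (rank, best[key][1])
    if not records:
        raise ValueError(f"no coordinate records parsed from {path}")
    if not any(r.element == "H" for r in records):
        warnings.warn(
            f"{path} contains no hydrogens; protonate externally before "
            "carving/propagation (heavy-atom-only structures give wrong "
            "electron counts)",
            stacklevel=2,
        )
    return records


def format_pdb(system: MolecularSystem | Sequence[AtomRecord]) -> str:
    """Render atoms as minimal PDB text.

    Capping hydrogens (``is_cap``) are emitted with residue name ``CAP`` so
    downstream tools (and re-reads) can identify them.
    """
    atoms = system.atoms if isinstance(system, MolecularSystem) else list(system)
    lines = []
    if isinstance(system, MolecularSystem) and system.total_charge is not None:
        lines.append(f"REMARK 250 TOTAL CHARGE {system.total_charge:+d}")
    counters: dict[tuple, int] = {}
    for i, a in enumerate(atoms, start=1):
        resname = CAP_RESIDUE_NAME if a.is_cap else (a.residue_name or "UNK")
        record = "ATOM  " if resname in _STANDARD_RESIDUES else "HETATM"
        seq = a.residue_seq if a.residue_seq is not None else 1
        # atom names must be unique within a residue or readers merge them
        key = (a.chain_id, resname, seq, a.element)
        counters[key] = counters.get(key, 0) + 1
        tag = f"{a.element}{counters[key]}"[:4]
        name = tag if len(a.element) == 2 else f" {tag}"[:4]
        x, y, z = a.position
        lines.append(
            f"{record}{i:5d} {name:<4s}{resname:>4s} {a.chain_id or 'A':1s}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(system: MolecularSystem | Sequence[AtomRecord], path) -> None:
    """Write atoms as a minimal PDB file (see :func:`format_pdb`)."""
    Path(path).write_text(format_pdb(system))


def read_xyz(path) -> list[AtomRecord]:
    """Read an XYZ file (count line, comment line, `El x y z` in Angstrom)."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValueError(f"empty XYZ file: {path}")
    try:
        n = int(text[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"XYZ header of {path} is not an atom count") from None
    body = [ln for ln in text[2:] if ln.strip()]
    if len(body) < n:
        raise ValueError(
            f"XYZ file {path} declares {n} atoms but lists {len(body)}"
        )
    records = []
    for i, line in enumerate(body[:n], start=1):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ line in {path}: {line!r}")
        records.append(
            AtomRecord(
                element=parts[0],
                position=np.array([float(parts[1]), float(parts[2]), float(parts[3])]),
                serial=i,
            )
        )
    return records


def write_xyz(atoms: MolecularSystem | Sequence[AtomRecord], path, comment: str = "") -> None:
    if isinstance(atoms, MolecularSystem):
        comment = comment or atoms.label
        atoms = atoms.atoms
    atoms = list(atoms)
    lines = [str(len(atoms)), comment.replace("\n", " ")]
    for a in atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def select_ligand(
    atoms: Sequence[AtomRecord],
    residue_names: Iterable[str],
    chain_id: str | None = None,
    bond_scale: float = 1.3,
) -> list[int]:
    """Indices of all atoms belonging to the named residues.

    Includes hydrogens geometrically bonded to a matching atom even when
    their own residue name differs (some protonation tools re-label added
    hydrogens). ``chain_id`` restricts the match to one chain when the
    structure holds several copies of the ligand.
    """
    names = {n.strip().upper() for n in residue_names}
    base = [
        i
        for i, a in enumerate(atoms)
        if a.residue_name.upper() in names
        and (chain_id is None or a.chain_id == chain_id)
    ]
    if not base:
        raise ValueError(
            f"no atoms with residue name in {sorted(names)}"
            + (f" on chain {chain_id!r}" if chain_id else "")
        )
    selected = set(base)
    base_pos = np.array([atoms[i].position for i in base])
    base_rad = np.array([atoms[i].covalent_radius for i in base])
    for i, a in enumerate(atoms):
        if i in selected or a.element != "H":
            continue
        d = np.linalg.norm(base_pos - a.position, axis=1)
        if np.any(d <= bond_scale * (base_rad + a.covalent_radius)):
            selected.add(i)
    return sorted(selected)
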