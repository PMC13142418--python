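"""Quantum-region carving: ligand + distance cutoff + bond-safe growth + caps.

The quantum region is seeded with the ligand and every atom whose distance
to any ligand atom (hydrogens included) is at most the cutoff. Because a
plain distance cut severs bonds arbitrarily, the region is then grown over
the inferred bond graph until the only bonds crossing the boundary are
carbon-carbon single bonds; each of those is cut and the inside carbon is
capped with a hydrogen placed on the original bond vector.

Bond character is purely geometric: a pair is bonded when its distance is
below a scale factor times the sum of covalent radii, and a C-C bond counts
as *single* when it is longer than ``cc_single_min`` (single bonds sit near
1.50-1.54 A, aromatic/double ones near 1.34-1.40 A, so a threshold of
1.45 A separates them cleanly in crystallographic coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomRecord, MolecularSystem

__all__ = ["BondRecord", "EnvironmentSpec", "detect_bonds", "carve"]

#: Interatomic distances below this (Angstrom) are treated as a clash.
CLASH_DISTANCE = 0.4


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    length: float
    character: str  # "single_CC" or "other"

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("bond indices must satisfy i < j")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Carving parameters (Angstrom). ``cutoff=0`` means ligand only."""

    cutoff: float = 3.0
    cap_bond_length: float = 1.09
    bond_detect_scale: float = 1.3
    cc_single_min: float = 1.45

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")
        if not 0.8 < self.cap_bond_length < 1.3:
            raise ValueError("cap_bond_length outside the plausible C-H range")


def detect_bonds(
    atoms: Sequence[AtomRecord],
    bond_detect_scale: float = 1.3,
    cc_single_min: float = 1.45,
) -> list[BondRecord]:
    """Geometric bond perception over all atom pairs.

    A pair (i, j) is bonded iff ``d_ij <= scale * (r_cov_i + r_cov_j)``;
    the bond is classified ``single_CC`` iff both atoms are carbon and the
    bond is at least ``cc_single_min`` long.
    """
    if len(atoms) < 2:
        return []
    pos = np.array([a.position for a in atoms])
    rad = np.array([a.covalent_radius for a in atoms])
    is_c = np.array([a.element == "C" for a in atoms])
    dist = cdist(pos, pos)
    iu, ju = np.triu_indices(len(atoms), k=1)
    d = dist[iu, ju]
    clash = d < CLASH_DISTANCE
    if np.any(clash):
        k = int(np.argmin(d))
        raise ValueError(
            f"atoms {iu[k]} and {ju[k]} are {d[k]:.3f} A apart (< "
            f"{CLASH_DISTANCE} A): clashing geometry"
        )
    bonded = d <= bond_detect_scale * (rad[iu] + rad[ju])
    bonds = []
    for i, j, dij in zip(iu[bonded], ju[bonded], d[bonded]):
        single_cc = bool(is_c[i] and is_c[j] and dij >= cc_single_min)
        bonds.append(
            BondRecord(int(i), int(j), float(dij), "single_CC" if single_cc else "other")
        )
    return bonds


def carve(
    atoms: Sequence[AtomRecord],
    ligand_indices: Sequence[int],
    spec: EnvironmentSpec = EnvironmentSpec(),
) -> MolecularSystem:
    """Extract the quantum region around a ligand.

    Returns a system whose atoms are, in original input order, the ligand,
    every atom within ``spec.cutoff`` of it, and all atoms pulled in by the
    growth rule, followed by the capping hydrogens (``is_cap=True``). The
    total charge of the returned system is left unassigned; it is selected
    later by the charge-scan protocol.
    """
    atoms = list(atoms)
    n = len(atoms)
    ligand = sorted(set(int(i) for i in ligand_indices))
    if not ligand:
        raise ValueError("ligand_indices is empty")
    if ligand[0] < 0 or ligand[-1] >= n:
        raise ValueError("ligand index outside the structure")

    pos = np.array([a.position for a in atoms])
    inside = set(ligand)
    if spec.cutoff > 0 and n > len(ligand):
        dmin = cdist(pos, pos[ligand]).min(axis=1)
        inside |= set(np.nonzero(dmin <= spec.cutoff)[0].tolist())

    bonds = detect_bonds(atoms, spec.bond_detect_scale, spec.cc_single_min)
    adjacency: dict[int, list[BondRecord]] = {i: [] for i in range(n)}
    for b in bonds:
        adjacency[b.i].append(b)
        adjacency[b.j].append(b)

    # Grow: pull in the outside partner of every boundary bond that is not a
    # carbon-carbon single bond, until closure. Frontier processed in sorted
    # order for determinism (the resulting set is order-independent anyway).
    frontier = sorted(inside)
    while frontier:
        new: set[int] = set()
        for i in frontier:
            for b in adjacency[i]:
                j = b.j if b.i == i else b.i
                if j not in inside and b.character != "single_CC":
                    new.add(j)
        inside |= new
        frontier = sorted(new)

    if len(inside) == n:
        if n > len(ligand) and spec.cutoff > 0:
            warnings.warn(
                "carve growth consumed the entire structure; returning it "
                "uncut (cutoff too large for the cutting rule)",
                stacklevel=2,
            )
        kept = [atoms[i] for i in range(n)]
        return MolecularSystem(kept, label="carved")

    # Remaining boundary bonds are all single_CC by construction: cap them.
    caps: list[tuple[tuple, AtomRecord]] = []
    for b in bonds:
        ins, out = None, None
        if b.i in inside and b.j not in inside:
            ins, out = b.i, b.j
        elif b.j in inside and b.i not in inside:
            ins, out = b.j, b.i
        if ins is None:
            continue
        assert b.character == "single_CC", "growth left a non-C-C-single boundary bond"
        vec = pos[out] - pos[ins]
        cap_pos = pos[ins] + spec.cap_bond_length * vec / np.linalg.norm(vec)
        cap = AtomRecord(
            element="H",
            position=cap_pos,
            residue_name="CAP",
            chain_id=atoms[ins].chain_id,
            is_cap=True,
        )
        caps.append((tuple(np.round(cap_pos, 6)), cap))
    caps.sort(key=lambda t: t[0])

    kept = [atoms[i] for i in sorted(inside)]
    return MolecularSystem(kept + [c for _, c in caps], label="carved")
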