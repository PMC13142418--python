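"""Synthetic structures with known ground truth.

Two kinds of fixtures are provided. ``toy_geometry`` returns small
molecules: diatomics and rigid textbook geometries are hardcoded, larger
organics (glycine, tryptophan, oxidized FAD) are built at run time from
SMILES with RDKit's deterministic distance-geometry embedding followed by
an MMFF94 relaxation — idealized gas-phase template geometries rather than
any particular crystal structure.

``make_mini_protein`` emits a fake ligand (a methylated six-ring) plus
alanine-like residues placed at controlled minimum distances, together
with a bundle of ground-truth facts (bond list, per-cutoff carve sets and
cap positions) computed at generation time by deliberately naive
brute-force routines, so the production carver can be checked against an
independent implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .elements import covalent_radius
from .structure_io import AtomRecord, MolecularSystem, format_pdb

__all__ = [
    "toy_geometry",
    "make_mini_protein",
    "FixtureBundle",
    "brute_force_bonds",
    "brute_force_carve",
    "TOY_NAMES",
]

_SMILES = {
    "glycine": "NCC(=O)O",
    "tryptophan": "c1ccc2c(c1)c(c[nH]2)C[C@@H](C(=O)O)N",
    "FAD_oxidized": (
        "Cc1cc2nc3c(=O)[nH]c(=O)nc-3n(C[C@H](O)[C@H](O)[C@H](O)COP(=O)([O-])"
        "OP(=O)([O-])OC[C@H]3O[C@@H](n4cnc5c(N)ncnc54)[C@H](O)[C@@H]3O)c2cc1C"
    ),
}

_EMBED_SEED = 20210 + 7  # fixed: the geometry is part of the fixture definition

TOY_NAMES = (
    "H2",
    "He",
    "HeH+",
    "H2O",
    "CH4",
    "ethane",
    "benzene",
    "glycine",
    "tryptophan",
    "FAD_oxidized",
)


def _atoms(spec):
    return [AtomRecord(element=e, position=np.array(p), serial=i + 1)
            for i, (e, p) in enumerate(spec)]


def _tetrahedral(scale):
    d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    return scale * d


@lru_cache(maxsize=None)
def _rdkit_geometry(name: str, n_confs: int = 10):
    """Deterministic gas-phase template geometry from SMILES.

    A small ETKDGv3 conformer ensemble is embedded with a fixed seed,
    MMFF94-relaxed, and the lowest-energy conformer is taken — the
    standard recipe for "the" gas-phase geometry of a flexible molecule.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(_SMILES[name])
    if mol is None:
        raise RuntimeError(f"bad SMILES for fixture {name}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(cids) == 0:
        raise RuntimeError(f"3-D embedding failed for fixture {name}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    energies = [e if conv == 0 else float("inf") for conv, e in results]
    if not any(np.isfinite(energies)):
        energies = [e for _conv, e in results]
    conf = mol.GetConformer(cids[int(np.argmin(energies))])
    charge = Chem.GetFormalCharge(mol)
    spec = [
        (atom.GetSymbol(), tuple(conf.GetAtomPosition(i)))
        for i, atom in enumerate(mol.GetAtoms())
    ]
    return spec, charge


def toy_geometry(name: str) -> MolecularSystem:
    """Fixed toy molecule by name (coordinates in Angstrom)."""
    if name == "H2":
        atoms = _atoms([("H", (0, 0, 0)), ("H", (0, 0, 0.74))])
        return MolecularSystem(atoms, total_charge=0, label="H2")
    if name == "He":
        return MolecularSystem(_atoms([("He", (0, 0, 0))]), total_charge=0, label="He")
    if name == "HeH+":
        atoms = _atoms([("He", (0, 0, 0)), ("H", (0, 0, 0.772))])
        return MolecularSystem(atoms, total_charge=1, label="HeH+")
    if name == "H2O":
        r, half = 0.9572, np.deg2rad(104.52 / 2)
        atoms = _atoms(
            [
                ("O", (0.0, 0.0, 0.0)),
                ("H", (r * np.sin(half), 0.0, r * np.cos(half))),
                ("H", (-r * np.sin(half), 0.0, r * np.cos(half))),
            ]
        )
        return MolecularSystem(atoms, total_charge=0, label="H2O")
    if name == "CH4":
        spec = [("C", (0.0, 0.0, 0.0))] + [("H", tuple(p)) for p in _tetrahedral(1.089)]
        return MolecularSystem(_atoms(spec), total_charge=0, label="CH4")
    if name == "ethane":
        cc = 1.536
        c1 = np.zeros(3)
        c2 = np.array([0.0, 0.0, cc])
        spec = [("C", tuple(c1)), ("C", tuple(c2))]
        for base, sign, phase in ((c1, -1.0, 0.0), (c2, 1.0, np.pi / 3)):
            for k in range(3):
                ang = phase + 2 * np.pi * k / 3
                d = np.array(
                    [np.cos(ang) * np.sin(np.deg2rad(70.5)),
                     np.sin(ang) * np.sin(np.deg2rad(70.5)),
                     sign * np.cos(np.deg2rad(70.5))]
                )
                spec.append(("H", tuple(base + 1.091 * d)))
        return MolecularSystem(_atoms(spec), total_charge=0, label="ethane")
    if name == "benzene":
        rc, rh = 1.39, 1.39 + 1.08
        spec = []
        for k in range(6):
            a = np.pi * k / 3
            spec.append(("C", (rc * np.cos(a), rc * np.sin(a), 0.0)))
        for k in range(6):
            a = np.pi * k / 3
            spec.append(("H", (rh * np.cos(a), rh * np.sin(a), 0.0)))
        return MolecularSystem(_atoms(spec), total_charge=0, label="benzene")
    if name in _SMILES:
        spec, charge = _rdkit_geometry(name)
        return MolecularSystem(_atoms(spec), total_charge=charge, label=name)
    raise ValueError(f"unknown toy geometry {name!r}; choose from {TOY_NAMES}")


# ----------------------------------------------------------------------
# brute-force ground-truth routines (intentionally naive)
# ----------------------------------------------------------------------

def brute_force_bonds(atoms, scale=1.3, cc_single_min=1.45):
    """All bonded pairs with character, by exhaustive pair scan."""
    out = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if d <= scale * (covalent_radius(atoms[i].element) + covalent_radius(atoms[j].element)):
                single_cc = (
                    atoms[i].element == "C"
                    and atoms[j].element == "C"
                    and d >= cc_single_min
                )
                out.append((i, j, d, "single_CC" if single_cc else "other"))
    return out


def brute_force_carve(atoms, ligand_indices, cutoff, cap_bond_length=1.09):
    """Reference carve: seed by distance, grow over non-C-C-single bonds to
    a fixed point by full rescanning, then cap every boundary bond.

    Returns (sorted kept indices, sorted list of cap positions)."""
    bonds = brute_force_bonds(atoms)
    inside = set(int(i) for i in ligand_indices)
    for k, a in enumerate(atoms):
        best = min(
            np.linalg.norm(a.position - atoms[i].position) for i in ligand_indices
        )
        if cutoff > 0 and best <= cutoff:
            inside.add(k)
    changed = True
    while changed:
        changed = False
        for i, j, _, char in bonds:
            if char == "single_CC":
                continue
            if (i in inside) != (j in inside):
                inside.add(i)
                inside.add(j)
                changed = True
    caps = []
    if len(inside) < len(atoms):
        for i, j, d, char in bonds:
            ins, out = None, None
            if i in inside and j not in inside:
                ins, out = i, j
            elif j in inside and i not in inside:
                ins, out = j, i
            if ins is None:
                continue
            assert char == "single_CC"
            vec = atoms[out].position - atoms[ins].position
            caps.append(tuple(atoms[ins].position + cap_bond_length * vec / d))
    return sorted(inside), sorted(caps)


# ----------------------------------------------------------------------
# mini-protein generator
# ----------------------------------------------------------------------

@dataclass
class FixtureBundle:
    name: str
    atoms: list
    ligand_indices: list
    expected: dict = field(default_factory=dict)


def _ring_ligand():
    """Methylated C4N2 six-ring: aromatic-length ring bonds (never cut)
    plus one in-ligand C-C single bond to the methyl group."""
    ring_elems = ["C", "N", "C", "C", "N", "C"]
    spec = []
    r = 1.39
    for k in range(6):
        a = np.pi * k / 3
        spec.append((ring_elems[k], np.array([r * np.cos(a), r * np.sin(a), 0.0])))
    # ring hydrogens on the carbons except index 0 (methyl site)
    for k in (2, 3, 5):
        a = np.pi * k / 3
        spec.append(("H", np.array([(r + 1.08) * np.cos(a), (r + 1.08) * np.sin(a), 0.0])))
    cm = np.array([r + 1.50, 0.0, 0.0])
    spec.append(("C", cm))
    for k in range(3):
        ang = 2 * np.pi * k / 3
        d = np.array(
            [np.cos(np.deg2rad(70.5)),
             np.cos(ang) * np.sin(np.deg2rad(70.5)),
             np.sin(ang) * np.sin(np.deg2rad(70.5))]
        )
        spec.append(("H", cm + 1.09 * d))
    return spec


def _spread_directions(axis, n, angle_deg):
    """n unit vectors at a fixed angle from ``axis``, spread azimuthally."""
    axis = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.3, -0.2])
    e1 = np.cross(axis, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    a = np.deg2rad(angle_deg)
    return [
        np.cos(a) * axis
        + np.sin(a) * (np.cos(2 * np.pi * k / n) * e1 + np.sin(2 * np.pi * k / n) * e2)
        for k in range(n)
    ]


def _alanine_like():
    """Idealized CH3-CH(NH2)-COOH residue template (13 atoms)."""
    t = _tetrahedral(1.0)
    ca = np.zeros(3)
    n = 1.47 * t[0]
    c = 1.52 * t[1]
    cb = 1.53 * t[2]
    ha = 1.09 * t[3]
    spec = [("N", n), ("C", ca), ("C", c), ("C", cb), ("H", ha)]
    # angles below are measured from the *outward* bond axis, i.e. a
    # substituent at tetrahedral geometry sits 180 - 109.5 = 70.5 deg away
    for d in _spread_directions(n - ca, 2, 73.0):
        spec.append(("H", n + 1.01 * d))
    # carboxyl: sp2 oxygens at ~120 deg O-C-CA, i.e. 60 deg from outward axis
    d1, d2 = _spread_directions(c - ca, 2, 60.0)
    o_dbl = c + 1.23 * d1
    o_sng = c + 1.36 * d2
    spec.append(("O", o_dbl))
    spec.append(("O", o_sng))
    spec.append(("H", o_sng + 0.97 * (o_sng - c) / np.linalg.norm(o_sng - c)))
    for d in _spread_directions(cb - ca, 3, 70.5):
        spec.append(("H", cb + 1.09 * d))
    return spec


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_mini_protein(
    seed: int,
    n_residues: int = 2,
    ligand_offsets=(2.5, 6.0),
    cutoffs=(0.0, 3.0, 5.0),
) -> tuple[str, FixtureBundle]:
    """Deterministic fake-protein PDB with ground-truth carve answers.

    Each residue is a rigid alanine-like molecule rotated randomly and
    translated so its *minimum* atom distance to the ligand equals the
    requested offset. The returned bundle records, per cutoff, the kept
    original-atom set and the cap positions computed by the brute-force
    reference carver.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    offsets = [float(ligand_offsets[k % len(ligand_offsets)]) for k in range(n_residues)]

    lig_spec = _ring_ligand()
    lig_pos = np.array([p for _, p in lig_spec])
    placed: list[tuple[str, np.ndarray, int]] = [
        (e, p, 1) for e, p in lig_spec
    ]

    res_template = _alanine_like()
    res_pos0 = np.array([p for _, p in res_template])

    for k, off in enumerate(offsets):
        for _attempt in range(200):
            R = _random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = res_pos0 @ R.T
            pos -= pos.mean(axis=0)
            # slide along `direction` until min distance to ligand == off
            radius = off + 4.0
            for _ in range(60):
                trial = pos + radius * direction
                dmin = np.min(
                    np.linalg.norm(trial[:, None, :] - lig_pos[None, :, :], axis=2)
                )
                if abs(dmin - off) < 1e-9:
                    break
                radius += off - dmin
            trial = pos + radius * direction
            other = np.array(
                [p for e, p, seq in placed if seq > 1] or np.zeros((0, 3))
            )
            if other.size:
                sep = np.min(
                    np.linalg.norm(trial[:, None, :] - other[None, :, :], axis=2)
                )
                if sep < 2.2:
                    continue  # perturbed retry with fresh rotation/direction
            for (e, _p0), p in zip(res_template, trial):
                placed.append((e, p, k + 2))
            break
        else:
            raise RuntimeError("could not place residue without clashes")

    atoms = []
    for i, (e, p, seq) in enumerate(placed):
        atoms.append(
            AtomRecord(
                element=e,
                position=np.asarray(p, dtype=float),
                serial=i + 1,
                residue_name="LIG" if seq == 1 else "ALA",
                residue_seq=seq,
                chain_id="A",
            )
        )
    ligand_indices = [i for i, a in enumerate(atoms) if a.residue_name == "LIG"]
    expected = {
        "bonds": brute_force_bonds(atoms),
        "carve": {
            float(c): dict(
                zip(("kept", "caps"), brute_force_carve(atoms, ligand_indices, c))
            )
            for c in cutoffs
        },
        "offsets": offsets,
    }
    bundle = FixtureBundle(
        name=f"mini_protein_seed{seed}",
        atoms=atoms,
        ligand_indices=ligand_indices,
        expected=expected,
    )
    pdb_text = format_pdb(MolecularSystem(atoms, total_charge=0, label=bundle.name))
    return pdb_text, bundle
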