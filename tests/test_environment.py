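"""Bond perception and quantum-region carving."""

import numpy as np
import pytest

from kickspec import AtomRecord, detect_bonds, carve, toy_geometry
from kickspec.environment import EnvironmentSpec
from kickspec.fixtures import make_mini_protein, brute_force_bonds


def _bond_set(bonds):
    return {(b.i, b.j, b.character) for b in bonds}


def test_ethane_has_one_cc_single_bond_and_six_ch_bonds():
    atoms = toy_geometry("ethane").atoms
    bonds = detect_bonds(atoms)
    singles = [b for b in bonds if b.character == "single_CC"]
    others = [b for b in bonds if b.character == "other"]
    assert len(singles) == 1
    assert singles[0].length == pytest.approx(1.536, abs=1e-6)
    assert len(others) == 6
    assert all(
        {atoms[b.i].element, atoms[b.j].element} == {"C", "H"} for b in others
    )


def test_benzene_aromatic_cc_bonds_are_never_single():
    atoms = toy_geometry("benzene").atoms
    bonds = detect_bonds(atoms)
    cc = [
        b for b in bonds if atoms[b.i].element == "C" and atoms[b.j].element == "C"
    ]
    assert len(cc) == 6
    assert all(b.character == "other" for b in cc)


def test_bond_detection_matches_brute_force_on_fixtures():
    for name in ("CH4", "ethane", "benzene", "glycine", "tryptophan"):
        atoms = toy_geometry(name).atoms
        got = _bond_set(detect_bonds(atoms))
        ref = {(i, j, c) for i, j, _, c in brute_force_bonds(atoms)}
        assert got == ref, name


def test_single_atom_and_clash_handling():
    assert detect_bonds([AtomRecord("He", (0, 0, 0))]) == []
    pair = [AtomRecord("H", (0, 0, 0)), AtomRecord("H", (0, 0, 0.2))]
    with pytest.raises(ValueError, match="clash"):
        detect_bonds(pair)


def test_carve_cutoff_zero_returns_exactly_the_ligand():
    _, bundle = make_mini_protein(seed=5)
    system = carve(bundle.atoms, bundle.ligand_indices, EnvironmentSpec(cutoff=0.0))
    assert len(system) == len(bundle.ligand_indices)
    assert not any(a.is_cap for a in system.atoms)
    assert system.total_charge is None


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
@pytest.mark.parametrize("cutoff", [3.0, 5.0])
def test_carve_matches_brute_force_oracle(seed, cutoff):
    _, bundle = make_mini_protein(seed=seed)
    system = carve(bundle.atoms, bundle.ligand_indices, EnvironmentSpec(cutoff=cutoff))
    expected = bundle.expected["carve"][cutoff]
    kept = [a for a in system.atoms if not a.is_cap]
    caps = [a for a in system.atoms if a.is_cap]
    pos_to_idx = {
        tuple(np.round(a.position, 8)): i for i, a in enumerate(bundle.atoms)
    }
    kept_idx = sorted(pos_to_idx[tuple(np.round(a.position, 8))] for a in kept)
    assert kept_idx == expected["kept"]
    got_caps = sorted(tuple(np.round(a.position, 6)) for a in caps)
    want_caps = sorted(tuple(np.round(np.asarray(c), 6)) for c in expected["caps"])
    assert got_caps == want_caps


def test_caps_lie_on_the_original_bond_vector():
    _, bundle = make_mini_protein(seed=3)
    spec = EnvironmentSpec(cutoff=3.0)
    system = carve(bundle.atoms, bundle.ligand_indices, spec)
    caps = [a for a in system.atoms if a.is_cap]
    assert caps, "fixture should produce at least one cap"
    bonds = detect_bonds(bundle.atoms)
    carbons = [
        (bundle.atoms[b.i].position, bundle.atoms[b.j].position)
        for b in bonds
        if b.character == "single_CC"
    ]
    for cap in caps:
        dists = []
        for pi, pj in carbons:
            for a, b in ((pi, pj), (pj, pi)):
                u = (b - a) / np.linalg.norm(b - a)
                dists.append(np.linalg.norm(a + spec.cap_bond_length * u - cap.position))
        assert min(dists) < 1e-6
        assert cap.element == "H" and cap.residue_name == "CAP"


def test_carve_is_invariant_under_atom_reordering(rng):
    _, bundle = make_mini_protein(seed=7)
    ref = carve(bundle.atoms, bundle.ligand_indices, EnvironmentSpec(cutoff=3.0))
    perm = rng.permutation(len(bundle.atoms))
    shuffled = [bundle.atoms[i] for i in perm]
    lig = [int(np.nonzero(perm == i)[0][0]) for i in bundle.ligand_indices]
    out = carve(shuffled, lig, EnvironmentSpec(cutoff=3.0))

    def key(system):
        return sorted(
            (a.element, a.is_cap, tuple(np.round(a.position, 6))) for a in system.atoms
        )

    assert key(out) == key(ref)


def test_growth_consuming_everything_warns_and_returns_all():
    atoms = toy_geometry("tryptophan").atoms
    # ligand = the whole indole ring region; huge cutoff swallows everything
    with pytest.warns(UserWarning, match="entire structure"):
        system = carve(atoms, [0], EnvironmentSpec(cutoff=50.0))
    assert len(system) == len(atoms)


def test_carve_input_validation():
    _, bundle = make_mini_protein(seed=1)
    with pytest.raises(ValueError):
        carve(bundle.atoms, [], EnvironmentSpec(cutoff=3.0))
    with pytest.raises(ValueError):
        carve(bundle.atoms, [len(bundle.atoms) + 4], EnvironmentSpec(cutoff=3.0))
    with pytest.raises(ValueError):
        EnvironmentSpec(cutoff=-1.0)
    with pytest.raises(ValueError):
        EnvironmentSpec(cap_bond_length=2.0)
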