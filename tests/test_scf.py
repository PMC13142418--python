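"""Hartree-Fock ground state vs. the naive-SCF oracle, Mulliken analysis,
and the total-charge selection protocol."""

import numpy as np
import pytest

from kickspec import (
    build_basis,
    compute_integrals,
    mulliken,
    run_rhf,
    select_charge,
    toy_geometry,
)
from kickspec.basis import atom_of_basis
from kickspec.structure_io import AtomRecord, MolecularSystem

from . import oracles


def _oracle_energy(integrals, n_electrons):
    E, P, C, eps = oracles.naive_rhf(
        integrals.S,
        integrals.hcore,
        integrals.eri.dense(),
        integrals.nuclear_repulsion,
        n_electrons,
    )
    return E


def test_h2_energy_matches_oracle_and_literature(h2_integrals, h2_scf):
    assert h2_scf.energy == pytest.approx(_oracle_energy(h2_integrals, 2), abs=1e-6)
    # canonical STO-3G value at 1.4 bohr
    assert h2_scf.energy == pytest.approx(-1.116714, abs=1e-5)


def test_he_energy_matches_oracle(he_integrals):
    res = run_rhf(he_integrals, 2)
    assert res.energy == pytest.approx(_oracle_energy(he_integrals, 2), abs=1e-6)
    assert res.energy == pytest.approx(-2.807784, abs=1e-5)


def test_h2o_energy_matches_oracle(h2o_integrals, h2o_scf):
    assert h2o_scf.energy == pytest.approx(_oracle_energy(h2o_integrals, 10), abs=1e-6)


def test_converged_density_invariants(h2o_integrals, h2o_scf):
    P, S = h2o_scf.density, h2o_integrals.S
    assert np.trace(P @ S) == pytest.approx(10.0, abs=1e-8)
    assert np.abs(P @ S @ P - 2.0 * P).max() < 1e-6
    F = h2o_integrals.fock(P)
    comm = F @ P @ S - S @ P @ F
    assert np.abs(comm).max() < 1e-5


def test_odd_electron_count_rejected(h2o_integrals):
    with pytest.raises(ValueError, match="even"):
        run_rhf(h2o_integrals, 9)


def test_energy_invariant_under_rigid_motions(h2o_system, h2o_scf):
    from scipy.spatial.transform import Rotation

    moved = h2o_system.translated([3.0, -2.0, 1.0]).rotated(
        Rotation.from_euler("zyx", [40, 25, 70], degrees=True).as_matrix()
    )
    res = run_rhf(compute_integrals(moved), 10)
    assert res.energy == pytest.approx(h2o_scf.energy, abs=1e-8)


def test_screened_vs_unscreened_energy(h2o_system):
    e_screened = run_rhf(compute_integrals(h2o_system, screen_threshold=1e-6), 10).energy
    e_full = run_rhf(compute_integrals(h2o_system, screen_threshold=0.0), 10).energy
    assert abs(e_screened - e_full) < 1e-6


def test_mulliken_symmetry_conservation_and_oracle(h2_integrals, h2_scf,
                                                   h2o_integrals, h2o_scf):
    counts = mulliken(h2_scf.density, h2_integrals.S, atom_of_basis(h2_integrals.basis))
    np.testing.assert_allclose(counts, [1.0, 1.0], atol=1e-10)

    amap = atom_of_basis(h2o_integrals.basis)
    counts = mulliken(h2o_scf.density, h2o_integrals.S, amap)
    assert counts.sum() == pytest.approx(10.0, abs=1e-10)
    # explicit-summation oracle: q_A = sum_{mu in A} (PS)_{mu mu}
    PS = h2o_scf.density @ h2o_integrals.S
    ref = np.zeros(3)
    for mu in range(len(amap)):
        ref[amap[mu]] += PS[mu, mu]
    np.testing.assert_allclose(counts, ref, atol=1e-12)


def test_select_charge_ligand_is_whole_system(h2o_system):
    chosen, results = select_charge(
        h2o_system, range(3), candidates=[-2, 0, 2], target_electrons=10.0,
        test_steps=5,
    )
    assert chosen == 0
    assert [r.accepted for r in results] == [False, True, False]


def test_select_charge_two_fragment_toy():
    """He and H2 far apart: asking for 2 electrons on He must pick the
    neutral total charge (scan table cross-checked with the naive SCF)."""
    atoms = [
        AtomRecord("He", (0, 0, 0)),
        AtomRecord("H", (0, 0, 20.0)),
        AtomRecord("H", (0, 0, 20.74)),
    ]
    system = MolecularSystem(atoms, label="He+H2")
    chosen, results = select_charge(
        system, [0], candidates=[-2, 0], target_electrons=2.0, test_steps=5
    )
    assert chosen == 0
    integrals = compute_integrals(system)
    for r in results:
        n_e = system.nuclear_charge - r.candidate_charge
        E, P, C, eps = oracles.naive_rhf(
            integrals.S, integrals.hcore, integrals.eri.dense(),
            integrals.nuclear_repulsion, n_e,
        )
        he_count = sum((P @ integrals.S)[mu, mu] for mu in [0])
        assert r.ligand_electrons == pytest.approx(he_count, abs=1e-3)
        assert r.accepted == (1.5 <= he_count <= 2.0)


def test_select_charge_no_acceptable_candidate(h2o_system):
    with pytest.raises(ValueError, match="no candidate"):
        select_charge(
            h2o_system, range(3), candidates=[0], target_electrons=4.0, test_steps=2
        )


def test_select_charge_skips_odd_counts(h2o_system):
    with pytest.warns(UserWarning, match="odd electron count"):
        chosen, results = select_charge(
            h2o_system, range(3), candidates=[-1, 0], target_electrons=10.0,
            test_steps=2,
        )
    assert [r.candidate_charge for r in results] == [0]
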