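"""Restricted Hartree-Fock ground state, Mulliken analysis, charge scan.

The density convention is doubly-occupied: P = 2 C_occ C_occ^T, so
Tr(PS) equals the electron count and the idempotency relation reads
P S P = 2 P. DIIS (Pulay mixing of Fock matrices on the commutator error
F P S - S P F in the orthonormal representation) accelerates convergence
from a core-Hamiltonian guess.

The total-charge selection protocol mirrors the preparation of carved
protein systems: the physically correct total charge is not obvious after
capping, so candidate charges are scanned; each candidate is accepted when
the Mulliken electron count of the ligand lands in a window just below its
nominal value, and among accepted candidates the numerically most stable
one (smallest idempotency drift over a short field-free propagation) wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .integrals import IntegralSet
from .structure_io import MolecularSystem

__all__ = [
    "SCFResult",
    "ChargeScanResult",
    "run_rhf",
    "mulliken",
    "select_charge",
]


@dataclass
class SCFResult:
    density: np.ndarray          # AO density, Tr(PS) = n_electrons
    orbitals: np.ndarray         # AO coefficients, columns
    orbital_energies: np.ndarray
    energy: float                # electronic + nuclear, Hartree
    converged: bool
    iterations: int
    n_electrons: int


class SCFConvergenceError(RuntimeError):
    pass


def run_rhf(
    integrals: IntegralSet,
    n_electrons: int,
    conv_energy: float = 1e-8,
    conv_density: float = 1e-6,
    max_iter: int = 200,
    diis_size: int = 8,
) -> SCFResult:
    """Closed-shell SCF. Converged when the energy change drops below
    ``conv_energy`` (Hartree) and max|dP| below ``conv_density``."""
    if n_electrons % 2 != 0:
        raise ValueError(
            f"closed-shell RHF requires an even electron count, got {n_electrons}"
        )
    X = integrals.X
    nocc = n_electrons // 2
    if nocc > X.shape[1]:
        raise ValueError("more electron pairs than independent basis functions")
    H = integrals.hcore
    S = integrals.S

    def diagonalize(F):
        Ft = X.T @ F @ X
        eps, Ct = np.linalg.eigh(Ft)
        C = X @ Ct
        P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        return eps, C, P

    eps, C, P = diagonalize(H)
    energy = 0.0
    fock_hist: list[np.ndarray] = []
    err_hist: list[np.ndarray] = []
    converged = False
    it = 0
    delta_e = np.inf
    for it in range(1, max_iter + 1):
        F = integrals.fock(P)
        new_energy = 0.5 * np.einsum("ij,ij->", P, H + F) + integrals.nuclear_repulsion
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        fock_hist.append(F)
        err_hist.append(err)
        if len(fock_hist) > diis_size:
            fock_hist.pop(0)
            err_hist.pop(0)
        if len(fock_hist) > 1:
            m = len(fock_hist)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = np.einsum("ij,ij->", err_hist[a], err_hist[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, fock_hist))
            except np.linalg.LinAlgError:
                pass
        eps, C, P_new = diagonalize(F)
        delta_e = new_energy - energy
        delta_p = np.abs(P_new - P).max()
        energy = new_energy
        P = P_new
        if abs(delta_e) < conv_energy and delta_p < conv_density:
            converged = True
            break
    if not converged:
        raise SCFConvergenceError(
            f"SCF did not converge in {max_iter} iterations "
            f"(last dE = {delta_e:.3e} Ha)"
        )
    return SCFResult(
        density=P,
        orbitals=C,
        orbital_energies=eps,
        energy=float(energy),
        converged=converged,
        iterations=it,
        n_electrons=n_electrons,
    )


def mulliken(P, S, basis_atoms, n_atoms: int | None = None) -> np.ndarray:
    """Per-atom Mulliken electron counts: q_A = sum_{mu in A} (P S)_{mu mu}.

    Accepts real or complex (propagated) densities; the diagonal of PS is
    real for Hermitian P. The counts sum exactly to Tr(PS).
    """
    basis_atoms = np.asarray(basis_atoms, dtype=int)
    diag = np.einsum("ij,ji->i", P, S).real
    if n_atoms is None:
        n_atoms = int(basis_atoms.max()) + 1
    counts = np.zeros(n_atoms)
    np.add.at(counts, basis_atoms, diag)
    return counts


@dataclass
class ChargeScanResult:
    candidate_charge: int
    ligand_electrons: float
    trace_drift: float
    stable: bool
    scf_energy: float
    accepted: bool


def select_charge(
    system: MolecularSystem,
    ligand_indices,
    candidates,
    target_electrons: float,
    test_steps: int = 50,
    dt: float = 0.25,
    window: float = 0.5,
    stable_drift_max: float = 1e-6,
    integrals: IntegralSet | None = None,
    screen_threshold: float = 1e-6,
) -> tuple[int, list[ChargeScanResult]]:
    """Scan candidate total charges and pick the physical one.

    A candidate is accepted when the ligand's Mulliken electron count after
    ``test_steps`` field-free propagation steps lies in
    [target - window, target]. Among accepted candidates the smallest
    trace drift wins; exact ties prefer the charge closest to zero, then
    the negative one. Integrals do not depend on the charge and are
    computed once.
    """
    from .basis import atom_of_basis
    from .dynamics import propagate, trace_drift
    from .integrals import compute_integrals

    ligand_indices = sorted(set(int(i) for i in ligand_indices))
    if integrals is None:
        integrals = compute_integrals(system, screen_threshold=screen_threshold)
    basis_atoms = atom_of_basis(integrals.basis)
    nuclear = system.nuclear_charge
    results: list[ChargeScanResult] = []
    for q in sorted(int(c) for c in set(candidates)):
        n_e = nuclear - q
        if n_e < 0:
            warnings.warn(f"charge {q:+d} gives a negative electron count; skipped")
            continue
        if n_e % 2 != 0:
            warnings.warn(
                f"charge {q:+d} gives an odd electron count ({n_e}); "
                "skipped (closed-shell treatment only)"
            )
            continue
        try:
            scf = run_rhf(integrals, n_e)
        except SCFConvergenceError as exc:
            warnings.warn(f"charge {q:+d}: SCF failed ({exc}); skipped")
            continue
        trace = propagate(
            scf.density.astype(complex),
            integrals,
            dt=dt,
            n_steps=test_steps,
            record_per_basis=False,
        )
        drift = trace_drift(trace)
        P_final = trace.final_density
        lig_e = float(
            mulliken(P_final, integrals.S, basis_atoms, len(system))[ligand_indices].sum()
        )
        eps = 1e-9  # guard the window edges against rounding
        accepted = target_electrons - window - eps <= lig_e <= target_electrons + eps
        results.append(
            ChargeScanResult(
                candidate_charge=q,
                ligand_electrons=lig_e,
                trace_drift=drift,
                stable=drift <= stable_drift_max,
                scf_energy=scf.energy,
                accepted=accepted,
            )
        )
    accepted = [r for r in results if r.accepted]
    if not accepted:
        table = "\n".join(
            f"  charge {r.candidate_charge:+d}: ligand e = {r.ligand_electrons:.3f}, "
            f"drift = {r.trace_drift:.2e}"
            for r in results
        )
        raise ValueError(
            "no candidate charge gives a ligand electron count in "
            f"[{target_electrons - window}, {target_electrons}]:\n{table}"
        )
    # drifts below the stability threshold are equivalent ("stable"); the
    # tie-break then prefers the charge closest to zero, negative first
    best = min(
        accepted,
        key=lambda r: (
            0.0 if r.stable else r.trace_drift,
            abs(r.candidate_charge),
            r.candidate_charge > 0,
        ),
    )
    return best.candidate_charge, results
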