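"""Delta kick and real-time propagation: conservation laws, stability,
linear response, and agreement with explicit TDHF diagonalization."""

import numpy as np
import pytest

from kickspec import (
    FieldSpec,
    absorption,
    apply_kick,
    default_energy_grid,
    load_trace,
    propagate,
    save_trace,
    trace_drift,
)


def _kick_and_run(integrals, scf, n_steps, dt=0.25, kick=2e-4, axis="z", **kw):
    field = FieldSpec.along(axis, kick)
    P = apply_kick(scf.density, integrals, field)
    tr = propagate(P, integrals, dt=dt, n_steps=n_steps, **kw)
    tr.kick = field
    return tr


def test_zero_strength_kick_is_identity(h2_integrals, h2_scf):
    tiny = FieldSpec.along("z", 1e-300)
    P = apply_kick(h2_scf.density, h2_integrals, tiny)
    np.testing.assert_allclose(P, h2_scf.density.astype(complex), atol=1e-12)
    with pytest.raises(ValueError):
        FieldSpec(kick_strength=0.0)


def test_kick_conserves_trace_and_idempotency(h2o_integrals, h2o_scf):
    field = FieldSpec.along("x", 5e-3)
    P = apply_kick(h2o_scf.density, h2o_integrals, field)
    S = h2o_integrals.S
    assert np.trace(P @ S).real == pytest.approx(10.0, abs=1e-10)
    assert np.abs(P @ S @ P - 2.0 * P).max() < 1e-9


def test_first_step_response_linear_in_kick_strength(h2_integrals, h2_scf):
    responses = []
    for kappa in (1e-4, 2e-4):
        tr = _kick_and_run(h2_integrals, h2_scf, n_steps=20, kick=kappa)
        mu = tr.total_dipole[:, 2] - tr.total_dipole[0, 2]
        responses.append(mu[10] / kappa)
    assert responses[1] == pytest.approx(responses[0], rel=1e-2)


def test_stationary_ground_state_is_stationary(h2o_integrals, h2o_scf):
    tr = propagate(h2o_scf.density.astype(complex), h2o_integrals, n_steps=500)
    spread = np.abs(tr.total_dipole - tr.total_dipole[0]).max()
    assert spread < 1e-8
    assert trace_drift(tr) < 1e-10


def test_default_schedule_duration(h2_integrals, h2_scf):
    tr = propagate(h2_scf.density.astype(complex), h2_integrals, n_steps=10, dt=0.25)
    assert tr.dt == 0.25
    scaled = tr.duration_fs * (10_000 / tr.n_steps)
    assert scaled == pytest.approx(60.5, abs=0.05)


def test_energy_conserved_after_kick(h2o_integrals, h2o_scf):
    tr = _kick_and_run(h2o_integrals, h2o_scf, n_steps=2000, axis="y")
    e = tr.energy_series
    assert np.abs(e - e[0]).max() < 1e-6


def test_trace_drift_small_and_decreasing_with_dt(h2_integrals, h2_scf):
    tr1 = _kick_and_run(h2_integrals, h2_scf, n_steps=1000, dt=0.25, kick=5e-3)
    assert trace_drift(tr1) < 1e-7
    tr2 = _kick_and_run(h2_integrals, h2_scf, n_steps=2000, dt=0.125, kick=5e-3)
    assert trace_drift(tr2) <= trace_drift(tr1) + 1e-12


def test_ao_and_orthonormal_drift_metrics_agree(h2o_integrals, h2o_scf):
    t1 = _kick_and_run(h2o_integrals, h2o_scf, n_steps=50, drift_metric="orthonormal")
    t2 = _kick_and_run(h2o_integrals, h2o_scf, n_steps=50, drift_metric="ao")
    np.testing.assert_allclose(
        t1.trace_drift_series, t2.trace_drift_series, atol=1e-12
    )


def test_per_basis_dipole_sums_to_total(h2o_integrals, h2o_scf):
    tr = _kick_and_run(h2o_integrals, h2o_scf, n_steps=100)
    total = tr.per_basis_dipole.sum(axis=1)
    np.testing.assert_allclose(total, tr.total_dipole, atol=1e-10)


@pytest.mark.parametrize("fixture_name", ["h2", "heh"])
def test_rt_peaks_match_linear_response_tdhf(fixture_name, request):
    """Spectrum peaks of the real-time run must sit at the RPA excitation
    energies of the same Hamiltonian (within discretization error)."""
    from kickspec import run_rhf
    from . import oracles

    integrals = request.getfixturevalue(f"{fixture_name}_integrals")
    scf = run_rhf(integrals, 2)
    ref = oracles.tdhf_excitations(
        scf.orbitals, scf.orbital_energies, integrals.eri.dense(), 2
    )
    tr = _kick_and_run(integrals, scf, n_steps=8000, dt=0.125)
    grid = default_energy_grid(5.0, 40.0, 0.002)
    sp = absorption([tr], energies=grid)
    k = int(np.argmax(sp.isotropic))
    peak = sp.energies[k]
    # nearest dipole-allowed RPA root
    nearest = ref[np.argmin(np.abs(ref - peak))]
    assert peak == pytest.approx(nearest, abs=5e-3)


def test_batched_propagation_matches_single(h2o_integrals, h2o_scf):
    kicks = [FieldSpec.along(a) for a in "xy"]
    P = np.stack([apply_kick(h2o_scf.density, h2o_integrals, k) for k in kicks])
    pair = propagate(P, h2o_integrals, n_steps=40, kicks=kicks)
    solo = propagate(P[1], h2o_integrals, n_steps=40)
    np.testing.assert_allclose(
        pair[1].total_dipole, solo.total_dipole, atol=1e-10
    )


def test_trace_round_trip(tmp_path, h2_integrals, h2_scf):
    tr = _kick_and_run(h2_integrals, h2_scf, n_steps=25)
    path = tmp_path / "trace.npz"
    save_trace(tr, path)
    back = load_trace(path)
    np.testing.assert_allclose(back.total_dipole, tr.total_dipole)
    np.testing.assert_allclose(back.per_basis_dipole, tr.per_basis_dipole)
    assert back.kick.direction == tr.kick.direction
    assert back.n_steps == tr.n_steps and back.dt == tr.dt
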