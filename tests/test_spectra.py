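"""Spectral post-processing: baseline, damped Fourier transform, peak
finding, shift calibration, atom maps, averaging."""

import numpy as np
import pytest

from kickspec import (
    FieldSpec,
    Spectrum,
    absorption,
    apply_kick,
    atom_map,
    baseline_correct,
    calibrate_shift,
    damped_ft,
    default_energy_grid,
    find_peaks,
    mean_spectrum,
    propagate,
)
from kickspec.elements import NM_PER_HARTREE


def _lorentzian_spectrum(centers_ha, gamma=0.005, heights=None, grid=None):
    grid = default_energy_grid(1.0, 10.0, 0.002) if grid is None else grid
    heights = heights or [1.0] * len(centers_ha)
    y = np.zeros_like(grid)
    for c, h in zip(centers_ha, heights):
        y += h * gamma**2 / ((grid - c) ** 2 + gamma**2)
    return Spectrum(
        energies=grid, strength={"x": y}, isotropic=y,
        attenuation=gamma, kick_strength=1.0,
    )


def test_baseline_constant_series_goes_to_zero():
    series = np.full((100, 3), 2.5)
    np.testing.assert_allclose(baseline_correct(series), 0.0, atol=1e-14)


def test_baseline_offset_invariance():
    rng = np.random.default_rng(0)
    series = rng.normal(size=(200, 3))
    shifted = baseline_correct(series + np.array([1.0, -2.0, 0.5]))
    np.testing.assert_allclose(shifted, baseline_correct(series), atol=1e-12)


def test_baseline_leaves_zero_tail_mean_cosine_untouched():
    dt = 0.25
    t = dt * np.arange(1, 4001)
    gamma, w0 = 0.02, 0.5
    mu = np.exp(-gamma * t) * np.cos(w0 * t)
    ntail = 3600
    tail_mean = mu[-ntail:].mean()
    out = baseline_correct(mu, tail_fraction=0.9)
    assert np.abs(out - mu).max() <= abs(tail_mean) + 1e-15


def test_damped_ft_of_cosine_is_lorentzian_at_w0():
    dt, w0, gamma = 0.1, 0.2, 0.01
    t = dt * np.arange(1, 60001)
    mu = np.cos(w0 * t)
    grid = np.linspace(0.1, 0.4, 3001)
    F = damped_ft(mu, dt, gamma, grid)
    mag = np.abs(F)
    # the negative-frequency component displaces the |F| maximum slightly
    assert grid[np.argmax(mag)] == pytest.approx(w0, abs=5e-4)
    # the absorptive (real, for a cosine input) part is a Lorentzian of
    # half width gamma; |F| itself has half width sqrt(3) gamma
    absorptive = F.real
    half = absorptive.max() / 2
    above = grid[absorptive >= half]
    hwhm = (above.max() - above.min()) / 2
    assert hwhm == pytest.approx(gamma, rel=0.05)
    np.testing.assert_allclose(damped_ft(np.zeros_like(mu), dt, gamma, grid), 0.0)


def test_doubling_attenuation_doubles_line_width():
    dt, w0 = 0.1, 0.2
    t = dt * np.arange(1, 60001)
    mu = np.cos(w0 * t)
    grid = np.linspace(0.1, 0.4, 6001)

    def width(gamma):
        mag = np.abs(damped_ft(mu, dt, gamma, grid))
        above = grid[mag >= mag.max() / 2]
        return above.max() - above.min()

    assert width(0.02) == pytest.approx(2 * width(0.01), rel=0.05)


def test_absorption_identical_traces_give_isotropic_equal_to_each(
    h2o_integrals, h2o_scf
):
    kicks = [FieldSpec.along(a) for a in "xyz"]
    P = np.stack([apply_kick(h2o_scf.density, h2o_integrals, k) for k in kicks])
    traces = propagate(P, h2o_integrals, n_steps=400, kicks=kicks)
    sp = absorption(traces)
    for axis in "xyz":
        assert axis in sp.strength
    # H2O is anisotropic; isotropic must be the exact mean of the three
    np.testing.assert_allclose(
        sp.isotropic,
        (sp.strength["x"] + sp.strength["y"] + sp.strength["z"]) / 3.0,
        atol=1e-12,
    )


def test_wavelength_axis_unit_conversion():
    # 0.1 Ha corresponds to 455.63 nm on the axis
    assert NM_PER_HARTREE / 0.1 == pytest.approx(455.63, abs=0.05)
    sp = _lorentzian_spectrum([0.1])
    k = int(np.argmin(np.abs(sp.energies - 0.1)))
    assert sp.wavelength[k] == pytest.approx(NM_PER_HARTREE / sp.energies[k], abs=1e-9)
    assert np.all(np.diff(sp.wavelength) < 0)  # decreasing with energy


def test_absorption_rejects_mismatched_schedules(h2_integrals, h2_scf):
    kx = FieldSpec.along("x")
    Px = apply_kick(h2_scf.density, h2_integrals, kx)
    t1 = propagate(Px, h2_integrals, n_steps=50, kicks=None)
    t2 = propagate(Px, h2_integrals, n_steps=60, kicks=None)
    t1.kick, t2.kick = kx, FieldSpec.along("y")
    with pytest.raises(ValueError, match="schedule"):
        absorption([t1, t2])


def test_find_peaks_single_lorentzian_center():
    sp = _lorentzian_spectrum([0.15])
    pk = find_peaks(sp, (250, 350))
    assert len(pk.peaks) == 1
    assert pk.peaks[0][0] == pytest.approx(NM_PER_HARTREE / 0.15, abs=0.2)


def test_find_peaks_resolves_two_lines_and_ignores_monotone():
    c1 = NM_PER_HARTREE / 310.0
    c2 = NM_PER_HARTREE / 330.0
    sp = _lorentzian_spectrum([c1, c2], gamma=0.002)
    pk = find_peaks(sp, (290, 350))
    assert len(pk.peaks) == 2
    got = [round(w) for w, _ in pk.peaks]
    assert got == [310, 330]
    # a monotone window segment has no strict local maxima
    mono = find_peaks(sp, (360, 450))
    assert mono.peaks == []


def test_find_peaks_empty_window():
    sp = _lorentzian_spectrum([0.15])
    with pytest.raises(ValueError):
        find_peaks(sp, (2000.0, 3000.0))


def test_calibrate_shift_recovers_known_offsets():
    assert calibrate_shift([370.0, 450.0], [370.0, 450.0]) == 0.0
    assert calibrate_shift([333.0, 413.0], [370.0, 450.0]) == 37.0
    with pytest.raises(ValueError):
        calibrate_shift([], [370.0])


def test_shift_metadata_recorded():
    sp = _lorentzian_spectrum([0.15]).shifted(140.0)
    assert sp.shift_applied == 140.0
    pk = find_peaks(sp, (380, 500))
    assert pk.peaks[0][0] == pytest.approx(NM_PER_HARTREE / 0.15 + 140.0, abs=0.2)


def test_atom_map_single_atom_equals_total(he_integrals):
    from kickspec import run_rhf

    scf = run_rhf(he_integrals, 2)
    kick = FieldSpec.along("z", 5e-3)
    P = apply_kick(scf.density, he_integrals, kick)
    tr = propagate(P, he_integrals, n_steps=200)
    tr.kick = kick
    amap = atom_map(tr, 60.0)
    assert amap.magnitude.shape == (1,)
    assert amap.magnitude[0] == pytest.approx(
        np.linalg.norm(np.abs(amap.total_response)), abs=1e-12
    )


def test_atom_map_additivity(h2o_integrals, h2o_scf):
    kick = FieldSpec.along("x")
    P = apply_kick(h2o_scf.density, h2o_integrals, kick)
    tr = propagate(P, h2o_integrals, n_steps=300)
    tr.kick = kick
    amap = atom_map(tr, 120.0)
    mu = baseline_correct(tr.total_dipole)
    ref = damped_ft(mu, tr.dt, 0.015, np.array([NM_PER_HARTREE / 120.0]))[0]
    np.testing.assert_allclose(amap.complex_response.sum(axis=0), ref, atol=1e-8)


def test_atom_map_localizes_on_the_resonant_unit(h2_integrals, h2_scf):
    """Two H2 molecules far apart along perpendicular orientations: kicking
    along one bond lights up only that molecule's atoms."""
    from kickspec import compute_integrals, run_rhf
    from kickspec.structure_io import AtomRecord, MolecularSystem

    atoms = [
        AtomRecord("H", (0, 0, 0)),
        AtomRecord("H", (0, 0, 0.74)),
        AtomRecord("H", (30.0, 0, 0.37)),
        AtomRecord("H", (30.74, 0, 0.37)),
    ]
    pair = MolecularSystem(atoms, total_charge=0, label="2xH2")
    I = compute_integrals(pair)
    scf = run_rhf(I, 4)
    kick = FieldSpec.along("z", 1e-3)
    P = apply_kick(scf.density, I, kick)
    tr = propagate(P, I, n_steps=2000)
    tr.kick = kick
    sp = absorption([tr], energies=default_energy_grid(20, 30, 0.005))
    peak_nm = find_peaks(sp, (40, 60)).peaks[-1][0]
    amap = atom_map(tr, peak_nm)
    on = amap.magnitude[:2].sum()
    off = amap.magnitude[2:].sum()
    assert on > 50 * off


def test_mean_spectrum_identity_and_bimodality():
    a = _lorentzian_spectrum([0.12])
    assert np.allclose(mean_spectrum([a]).isotropic, a.isotropic)
    same = mean_spectrum([a, a])
    np.testing.assert_allclose(same.isotropic, a.isotropic, atol=1e-14)
    b = _lorentzian_spectrum([0.18])
    mixed = mean_spectrum([a, b], scale=4.0)
    pk = find_peaks(mixed, (200, 450))
    assert len(pk.peaks) == 2
    with pytest.raises(ValueError):
        mean_spectrum([])
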