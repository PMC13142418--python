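import numpy as np
import pytest

from kickspec import compute_integrals, run_rhf, toy_geometry
from kickspec.elements import BOHR_IN_ANGSTROM
from kickspec.structure_io import AtomRecord, MolecularSystem


def h2_at(r_bohr: float) -> MolecularSystem:
    d = r_bohr * BOHR_IN_ANGSTROM
    return MolecularSystem(
        [AtomRecord("H", (0, 0, 0)), AtomRecord("H", (0, 0, d))],
        total_charge=0,
        label=f"H2@{r_bohr}",
    )


def heh_plus() -> MolecularSystem:
    return toy_geometry("HeH+")


@pytest.fixture(scope="session")
def h2_system():
    return h2_at(1.4)


@pytest.fixture(scope="session")
def h2_integrals(h2_system):
    return compute_integrals(h2_system)


@pytest.fixture(scope="session")
def h2_scf(h2_integrals):
    return run_rhf(h2_integrals, 2)


@pytest.fixture(scope="session")
def he_integrals():
    return compute_integrals(toy_geometry("He"))


@pytest.fixture(scope="session")
def heh_integrals():
    return compute_integrals(heh_plus())


@pytest.fixture(scope="session")
def h2o_system():
    return toy_geometry("H2O")


@pytest.fixture(scope="session")
def h2o_integrals(h2o_system):
    return compute_integrals(h2o_system)


@pytest.fixture(scope="session")
def h2o_scf(h2o_integrals):
    return run_rhf(h2o_integrals, 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
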