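"""Minimal STO-3G Cartesian Gaussian basis.

STO-3G expands each Slater orbital in three Gaussians using the universal
least-squares fits of Hehre, Stewart & Pople (J. Chem. Phys. 51, 2657,
1969) for a Slater exponent of 1; element-specific exponents are obtained
by scaling with zeta**2 (Gaussian exponents transform quadratically under
radial scaling). The standard molecular/atomic Slater exponents tabulated
below reproduce the published STO-3G parameter sets exactly.

Shell structure in scope: H/He 1s; C/N/O 1s,2sp; P/S 1s,2sp,3sp. 2s/2p
(and 3s/3p) share exponents, as in the original basis. All functions are
Cartesian; no d shells occur for these elements in STO-3G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import ANGSTROM_TO_BOHR
from .structure_io import MolecularSystem

__all__ = ["BasisFunction", "build_basis", "n_basis_functions", "atom_of_basis"]

# Three-Gaussian fits to Slater orbitals with zeta = 1:
# exponents alpha_i and contraction coefficients d_i (normalized primitives).
_FIT_EXP = {
    "1s": np.array([2.227660584, 0.4057711562, 0.1098180260]),
    "2sp": np.array([0.9942030427, 0.2310313130, 0.0751386016]),
    "3sp": np.array([0.4828540806, 0.1624340565, 0.0640989790]),
}
_FIT_COEF = {
    "1s": np.array([0.1543289673, 0.5353281423, 0.4446345422]),
    "2s": np.array([-0.0999672292, 0.3995128261, 0.7001154689]),
    "2p": np.array([0.1559162750, 0.6076837186, 0.3919573931]),
    "3s": np.array([-0.2196203690, 0.2255954336, 0.9003984260]),
    "3p": np.array([0.0105876043, 0.5951670053, 0.4620010120]),
}

# Slater exponents per shell level, standard STO-3G values.
_ZETA: dict[str, tuple[float, ...]] = {
    "H": (1.24,),
    "He": (1.69,),
    "C": (5.67, 1.72),
    "N": (6.67, 1.95),
    "O": (7.66, 2.25),
    "P": (14.50, 5.31, 1.90),
    "S": (15.47, 5.79, 2.05),
}

_CART = {"s": [(0, 0, 0)], "p": [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}


def _double_factorial(k: int) -> float:
    out = 1.0
    while k > 1:
        out *= k
        k -= 2
    return out


def primitive_norm(alpha: float, lmn: tuple[int, int, int]) -> float:
    """Normalization constant of a Cartesian Gaussian primitive."""
    l, m, n = lmn
    L = l + m + n
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = np.sqrt(
        _double_factorial(2 * l - 1)
        * _double_factorial(2 * m - 1)
        * _double_factorial(2 * n - 1)
    )
    return num / den


@dataclass(frozen=True)
class BasisFunction:
    """A contracted Cartesian Gaussian.

    ``coefs`` are the total contraction coefficients: tabulated coefficient
    x primitive normalization x contracted renormalization, so the
    self-overlap of the function is exactly 1.
    """

    atom_index: int
    lmn: tuple[int, int, int]
    exps: np.ndarray
    coefs: np.ndarray
    center: np.ndarray  # bohr
    shell_label: str = ""

    @property
    def angular_momentum(self) -> int:
        return sum(self.lmn)


def _contracted_self_overlap(exps, coefs, lmn) -> float:
    l, m, n = lmn
    pref = (
        _double_factorial(2 * l - 1)
        * _double_factorial(2 * m - 1)
        * _double_factorial(2 * n - 1)
    )
    a = exps[:, None] + exps[None, :]
    s = (np.pi / a) ** 1.5 / (2.0 * a) ** (l + m + n) * pref
    return float(np.einsum("i,j,ij->", coefs, coefs, s))


def _make_contracted(exps, d, lmn, atom_index, center, label) -> BasisFunction:
    coefs = d * np.array([primitive_norm(a, lmn) for a in exps])
    norm = _contracted_self_overlap(exps, coefs, lmn)
    coefs = coefs / np.sqrt(norm)
    return BasisFunction(
        atom_index=atom_index,
        lmn=lmn,
        exps=np.asarray(exps, dtype=float),
        coefs=coefs,
        center=np.asarray(center, dtype=float),
        shell_label=label,
    )


def shells_for_element(element: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(label, exponents, raw coefficients) for each shell of an element."""
    if element not in _ZETA:
        raise ValueError(
            f"no STO-3G parameters tabulated for element {element!r}; "
            f"supported: {sorted(_ZETA)}"
        )
    zetas = _ZETA[element]
    shells = []
    levels = ["1s", "2sp", "3sp"]
    for level, zeta in zip(levels, zetas):
        exps = _FIT_EXP[level] * zeta**2
        if level == "1s":
            shells.append(("1s", exps, _FIT_COEF["1s"]))
        else:
            nlev = level[0]
            shells.append((f"{nlev}s", exps, _FIT_COEF[f"{nlev}s"]))
            shells.append((f"{nlev}p", exps, _FIT_COEF[f"{nlev}p"]))
    return shells


def build_basis(system: MolecularSystem) -> list[BasisFunction]:
    """STO-3G basis for a system, ordered by atom then shell (s before p;
    p components in x, y, z order). Centers are converted to bohr."""
    basis: list[BasisFunction] = []
    for ia, atom in enumerate(system.atoms):
        center = atom.position * ANGSTROM_TO_BOHR
        for label, exps, d in shells_for_element(atom.element):
            kind = label[-1]
            for lmn in _CART[kind]:
                basis.append(_make_contracted(exps, d, lmn, ia, center, label))
    return basis


def n_basis_functions(system: MolecularSystem) -> int:
    counts = {"H": 1, "He": 1, "C": 5, "N": 5, "O": 5, "P": 9, "S": 9}
    total = 0
    for a in system.atoms:
        if a.element not in counts:
            raise ValueError(f"no STO-3G parameters for {a.element!r}")
        total += counts[a.element]
    return total


def atom_of_basis(basis: list[BasisFunction]) -> np.ndarray:
    """Map basis-function index -> atom index."""
    return np.array([bf.atom_index for bf in basis], dtype=int)
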