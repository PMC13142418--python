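"""Element tables: symbols, atomic numbers, covalent radii.

Covalent radii are the Cordero et al. (2008) consensus values in Angstrom,
used for geometric bond detection. Only elements that plausibly occur in
protein/cofactor structures are tabulated; extending the table is enough to
support further elements in the structure-handling layer (the integral layer
additionally needs basis parameters).
"""

from __future__ import annotations

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Mn": 25, "Fe": 26,
    "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Se": 34, "Br": 35, "I": 53,
}

SYMBOL: dict[int, str] = {z: s for s, z in ATOMIC_NUMBER.items()}

# Cordero et al., Dalton Trans. 2008: single-bond covalent radii, Angstrom.
# (C sp3 value; Mn/Fe/Co high-spin values.)
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.61, "Fe": 1.52, "Co": 1.50, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}

#: Bohr radius in Angstrom (CODATA).
BOHR_IN_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_IN_ANGSTROM

#: One atomic unit of time in femtoseconds.
AU_TIME_IN_FS = 2.4188843265857e-2

#: Hartree in eV (CODATA).
HARTREE_IN_EV = 27.211386245988

#: hc in eV nm; lambda(nm) = HC_EV_NM / E(eV).
HC_EV_NM = 1239.841984

#: lambda(nm) = NM_PER_HARTREE / E(Hartree) = 45.5634 / E.
NM_PER_HARTREE = HC_EV_NM / HARTREE_IN_EV


def normalize_symbol(raw: str) -> str:
    """Canonical capitalization of an element symbol ('FE' -> 'Fe')."""
    s = raw.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def atomic_number(symbol: str) -> int:
    sym = normalize_symbol(symbol)
    try:
        return ATOMIC_NUMBER[sym]
    except KeyError:
        raise ValueError(f"unrecognized element symbol: {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    sym = normalize_symbol(symbol)
    try:
        return COVALENT_RADIUS[sym]
    except KeyError:
        raise ValueError(f"no covalent radius tabulated for {symbol!r}") from None
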