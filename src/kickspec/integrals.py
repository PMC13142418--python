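"""Gaussian integrals over the STO-3G basis (atomic units).

One- and two-electron integrals are evaluated with the McMurchie-Davidson
scheme: Cartesian Gaussian products are expanded in Hermite Gaussians
(E coefficients), Coulomb-type integrals contract those expansions with the
Hermite Coulomb tensor R built on the Boys function.

Two-electron integrals are screened with the Schwarz inequality
|(mu nu|la si)| <= q_{mu nu} q_{la si}, q = sqrt((mu nu|mu nu)). A basis
pair is *significant* when q_pair * max(q) >= screen_threshold; integrals
are generated for significant quartets only and stored twice in dense form:
a pair-compressed symmetric matrix for Coulomb contraction and an
exchange-ordered (N^2, N^2) matrix so that both J and K builds are single
BLAS matrix products. No distance-based cutoff is applied when contracting
the Coulomb term. For large systems the exchange matrix may be held in
single precision (``exchange_dtype='auto'``), a ~1e-7 relative rounding far
below spectroscopic resolution; the Coulomb matrix stays double precision
(the ground-state convergence criteria rely on it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .basis import BasisFunction, build_basis
from .structure_io import MolecularSystem

__all__ = [
    "IntegralSet",
    "ERIStore",
    "one_electron_integrals",
    "two_electron_integrals",
    "compute_integrals",
    "nuclear_repulsion",
    "nuclear_center_of_charge",
]

#: overlap eigenvalues below this are projected out (linear dependence).
LINDEP_TOL = 1e-7


# ----------------------------------------------------------------------
# numba primitives: E coefficients, Boys function, Hermite Coulomb tensor
# ----------------------------------------------------------------------

@njit(cache=True)
def _hermite_e(l1, l2, Q, a, b):
    """Hermite expansion coefficients E_t for a 1-D Gaussian product.

    Returns the vector E_t^{l1 l2}, t = 0..l1+l2, including the Gaussian
    product prefactor exp(-mu Q^2) with Q = A - B.
    """
    p = a + b
    mu = a * b / p
    PA = -b * Q / p
    PB = a * Q / p
    nt = l1 + l2 + 1
    E = np.zeros((l1 + 1, l2 + 1, nt + 1))
    E[0, 0, 0] = np.exp(-mu * Q * Q)
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            val = PA * E[i - 1, 0, t]
            if t > 0:
                val += E[i - 1, 0, t - 1] / (2.0 * p)
            if t + 1 <= nt:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                val = PB * E[i, j - 1, t]
                if t > 0:
                    val += E[i, j - 1, t - 1] / (2.0 * p)
                if t + 1 <= nt:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E[l1, l2, : l1 + l2 + 1]


@njit(cache=True)
def _boys(m_max, T, out):
    """Boys function F_m(T) for m = 0..m_max (stable series + recursion)."""
    if T < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T > 35.0:
        # asymptotic: F_0 = 0.5 sqrt(pi/T); upward recursion is stable here
        out[0] = 0.5 * np.sqrt(np.pi / T)
        expT = np.exp(-T)
        for m in range(1, m_max + 1):
            out[m] = ((2.0 * m - 1.0) * out[m - 1] - expT) / (2.0 * T)
        return
    # convergent series at m_max, then downward recursion
    expT = np.exp(-T)
    term = 1.0 / (2.0 * m_max + 1.0)
    s = term
    k = 1
    while True:
        term *= 2.0 * T / (2.0 * m_max + 2.0 * k + 1.0)
        s += term
        if term < 1e-17 * s or k > 300:
            break
        k += 1
    out[m_max] = expT * s
    for m in range(m_max - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2.0 * m + 1.0)


@njit(cache=True)
def _r_tensor(L, alpha, X, Y, Z):
    """Hermite Coulomb integrals R_{tuv}(alpha, PQ) for t+u+v <= L."""
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.zeros(L + 1)
    _boys(L, T, F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))  # [n, t, u, v]
    for n in range(L + 1):
        R[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=True)
def _nuclear_sum(Ex, Ey, Ez, p, PCx, PCy, PCz):
    """sum_{tuv} E_t E_u E_v R_{tuv}(p, P-C) for one primitive pair."""
    lt = Ex.shape[0] - 1
    lu = Ey.shape[0] - 1
    lv = Ez.shape[0] - 1
    R = _r_tensor(lt + lu + lv, p, PCx, PCy, PCz)
    s = 0.0
    for t in range(lt + 1):
        for u in range(lu + 1):
            for v in range(lv + 1):
                s += Ex[t] * Ey[u] * Ez[v] * R[t, u, v]
    return s


# ----------------------------------------------------------------------
# ERI kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _pair_tables(lmn, exps, coefs, centers, pi, pj):
    """Per-pair primitive data for the ERI kernel.

    For every basis pair and every of the 9 primitive products:
    combined exponent p, product center P, coefficient product, and the
    E-coefficient tables per Cartesian dimension (padded to length 5).
    """
    npair = pi.shape[0]
    p_exp = np.zeros((npair, 9))
    p_cen = np.zeros((npair, 9, 3))
    p_cc = np.zeros((npair, 9))
    p_E = np.zeros((npair, 9, 3, 5))
    p_nt = np.zeros((npair, 3), dtype=np.int64)
    for ip in range(npair):
        i = pi[ip]
        j = pj[ip]
        for d in range(3):
            p_nt[ip, d] = lmn[i, d] + lmn[j, d]
        for ka in range(3):
            for kb in range(3):
                a = exps[i, ka]
                b = exps[j, kb]
                kk = ka * 3 + kb
                p = a + b
                p_exp[ip, kk] = p
                p_cc[ip, kk] = coefs[i, ka] * coefs[j, kb]
                for d in range(3):
                    p_cen[ip, kk, d] = (a * centers[i, d] + b * centers[j, d]) / p
                    Et = _hermite_e(lmn[i, d], lmn[j, d], centers[i, d] - centers[j, d], a, b)
                    for t in range(Et.shape[0]):
                        p_E[ip, kk, d, t] = Et[t]
    return p_exp, p_cen, p_cc, p_E, p_nt


@njit(cache=True)
def _eri_pair_pair(ip, jp, p_exp, p_cen, p_cc, p_E, p_nt):
    """Contracted ERI (bra pair ip | ket pair jp) via McMurchie-Davidson."""
    val = 0.0
    ltb = p_nt[ip, 0]
    lub = p_nt[ip, 1]
    lvb = p_nt[ip, 2]
    ltk = p_nt[jp, 0]
    luk = p_nt[jp, 1]
    lvk = p_nt[jp, 2]
    L = ltb + lub + lvb + ltk + luk + lvk
    for ka in range(9):
        cab = p_cc[ip, ka]
        if cab == 0.0:
            continue
        p = p_exp[ip, ka]
        for kb in range(9):
            ccd = p_cc[jp, kb]
            q = p_exp[jp, kb]
            alpha = p * q / (p + q)
            X = p_cen[ip, ka, 0] - p_cen[jp, kb, 0]
            Y = p_cen[ip, ka, 1] - p_cen[jp, kb, 1]
            Z = p_cen[ip, ka, 2] - p_cen[jp, kb, 2]
            R = _r_tensor(L, alpha, X, Y, Z)
            s = 0.0
            for t in range(ltb + 1):
                et = p_E[ip, ka, 0, t]
                for u in range(lub + 1):
                    eu = et * p_E[ip, ka, 1, u]
                    for v in range(lvb + 1):
                        ev = eu * p_E[ip, ka, 2, v]
                        if ev == 0.0:
                            continue
                        for tt in range(ltk + 1):
                            ft = p_E[jp, kb, 0, tt]
                            for uu in range(luk + 1):
                                fu = ft * p_E[jp, kb, 1, uu]
                                for vv in range(lvk + 1):
                                    fv = fu * p_E[jp, kb, 2, vv]
                                    if fv == 0.0:
                                        continue
                                    sign = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                    s += ev * fv * sign * R[t + tt, u + uu, v + vv]
            pref = 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q))
            val += cab * ccd * pref * s
    return val


@njit(cache=True)
def _schwarz_diagonal(p_exp, p_cen, p_cc, p_E, p_nt):
    npair = p_exp.shape[0]
    q = np.zeros(npair)
    for ip in range(npair):
        v = _eri_pair_pair(ip, ip, p_exp, p_cen, p_cc, p_E, p_nt)
        q[ip] = np.sqrt(abs(v))
    return q


@njit(cache=True)
def _fill_eri(pi, pj, sig, qpair, thresh, p_exp, p_cen, p_cc, p_E, p_nt,
              pidx, Jmat, Kmat, nbf):
    npair = pi.shape[0]
    count = 0
    for ip in range(npair):
        if not sig[ip]:
            continue
        for jp in range(ip + 1):
            if not sig[jp]:
                continue
            if qpair[ip] * qpair[jp] < thresh:
                continue
            val = _eri_pair_pair(ip, jp, p_exp, p_cen, p_cc, p_E, p_nt)
            count += 1
            i = pi[ip]
            j = pj[ip]
            k = pi[jp]
            l = pj[jp]
            # all 8 permutational images (duplicate writes are harmless)
            for br in range(2):
                a, b = (i, j) if br == 0 else (j, i)
                for kt in range(2):
                    c, d = (k, l) if kt == 0 else (l, k)
                    Kmat[a * nbf + c, b * nbf + d] = val
                    Kmat[c * nbf + a, d * nbf + b] = val
                    Jmat[pidx[a, b], pidx[c, d]] = val
                    Jmat[pidx[c, d], pidx[a, b]] = val
    return count


# ----------------------------------------------------------------------
# one-electron integrals
# ----------------------------------------------------------------------

def _s1d(l1, l2, Q, a, b):
    """1-D overlap without the sqrt(pi/p) factor: E_0^{l1 l2}."""
    if l1 < 0 or l2 < 0:
        return 0.0
    return _hermite_e(l1, l2, Q, a, b)[0]


def nuclear_repulsion(system: MolecularSystem) -> float:
    from .elements import ANGSTROM_TO_BOHR

    pos = system.positions() * ANGSTROM_TO_BOHR
    Z = system.atomic_numbers().astype(float)
    e = 0.0
    for i in range(len(Z)):
        for j in range(i + 1, len(Z)):
            e += Z[i] * Z[j] / np.linalg.norm(pos[i] - pos[j])
    return e


def nuclear_center_of_charge(system: MolecularSystem) -> np.ndarray:
    """Charge-weighted nuclear center, bohr (dipole origin convention)."""
    from .elements import ANGSTROM_TO_BOHR

    pos = system.positions() * ANGSTROM_TO_BOHR
    Z = system.atomic_numbers().astype(float)
    return (Z[:, None] * pos).sum(axis=0) / Z.sum()


def one_electron_integrals(
    basis: list[BasisFunction],
    system: MolecularSystem,
    dipole_origin: np.ndarray | None = None,
):
    """Overlap S, kinetic T, nuclear attraction V, dipole D (3, N, N),
    and the nuclear repulsion energy. All in atomic units."""
    from .elements import ANGSTROM_TO_BOHR

    n = len(basis)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    D = np.zeros((3, n, n))
    nuc_pos = system.positions() * ANGSTROM_TO_BOHR
    Zs = system.atomic_numbers().astype(float)
    origin = (
        nuclear_center_of_charge(system)
        if dipole_origin is None
        else np.asarray(dipole_origin, dtype=float)
    )

    for i in range(n):
        bi = basis[i]
        for j in range(i + 1):
            bj = basis[j]
            A, B = bi.center, bj.center
            Q = A - B
            s = t = v = 0.0
            d = np.zeros(3)
            for ka in range(3):
                a = bi.exps[ka]
                ca = bi.coefs[ka]
                for kb in range(3):
                    b = bj.exps[kb]
                    cb = bj.coefs[kb]
                    p = a + b
                    cc = ca * cb
                    vol = (np.pi / p) ** 1.5
                    s1 = np.empty(3)
                    for dim in range(3):
                        s1[dim] = _s1d(bi.lmn[dim], bj.lmn[dim], Q[dim], a, b)
                    s += cc * vol * s1[0] * s1[1] * s1[2]
                    # kinetic: second derivative of the ket Gaussian
                    tk = np.empty(3)
                    for dim in range(3):
                        l2 = bj.lmn[dim]
                        term = -2.0 * b * (2 * l2 + 1) * s1[dim]
                        term += 4.0 * b * b * _s1d(bi.lmn[dim], l2 + 2, Q[dim], a, b)
                        if l2 >= 2:
                            term += l2 * (l2 - 1) * _s1d(bi.lmn[dim], l2 - 2, Q[dim], a, b)
                        tk[dim] = -0.5 * term
                    t += cc * vol * (
                        tk[0] * s1[1] * s1[2]
                        + s1[0] * tk[1] * s1[2]
                        + s1[0] * s1[1] * tk[2]
                    )
                    # dipole: (x - origin) = (x - B) + (B - origin)
                    for dim in range(3):
                        d1 = _s1d(bi.lmn[dim], bj.lmn[dim] + 1, Q[dim], a, b)
                        d1 += (B[dim] - origin[dim]) * s1[dim]
                        others = s1[(dim + 1) % 3] * s1[(dim + 2) % 3]
                        d[dim] += cc * vol * d1 * others
                    # nuclear attraction
                    P = (a * A + b * B) / p
                    Ex = _hermite_e(bi.lmn[0], bj.lmn[0], Q[0], a, b)
                    Ey = _hermite_e(bi.lmn[1], bj.lmn[1], Q[1], a, b)
                    Ez = _hermite_e(bi.lmn[2], bj.lmn[2], Q[2], a, b)
                    acc = 0.0
                    for c in range(len(Zs)):
                        PC = P - nuc_pos[c]
                        acc -= Zs[c] * _nuclear_sum(Ex, Ey, Ez, p, PC[0], PC[1], PC[2])
                    v += cc * (2.0 * np.pi / p) * acc
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
            for dim in range(3):
                D[dim, i, j] = D[dim, j, i] = d[dim]
    return S, T, V, D, nuclear_repulsion(system)


# ----------------------------------------------------------------------
# two-electron store
# ----------------------------------------------------------------------

@dataclass
class ERIStore:
    """Screened two-electron integrals with dense contraction matrices.

    ``jmat``: (npair, npair) symmetric, (ij|kl) over unique pairs i<=j.
    ``kmat``: (N^2, N^2) with kmat[i*N+j, k*N+l] = (ik|jl).
    Retrieval through :meth:`get` / :meth:`dense` honours the 8-fold
    permutational symmetry exactly (a single stored value backs all images).
    """

    nbf: int
    screen_threshold: float
    jmat: np.ndarray
    kmat: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    pidx: np.ndarray
    significant: np.ndarray  # bool per pair
    schwarz: np.ndarray      # q per pair
    n_computed: int = 0

    def get(self, i, j, k, l) -> float:
        return float(self.kmat[i * self.nbf + k, j * self.nbf + l])

    def dense(self) -> np.ndarray:
        """(N, N, N, N) tensor (mu nu | la si); small systems only."""
        n = self.nbf
        return (
            np.asarray(self.kmat, dtype=float)
            .reshape(n, n, n, n)
            .transpose(0, 2, 1, 3)
            .copy()
        )

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [
            (int(a), int(b))
            for a, b, s in zip(self.pair_i, self.pair_j, self.significant)
            if s
        ]

    def coulomb_exchange(self, P):
        """J and K for a stack of Hermitian density matrices.

        ``P`` has shape (..., N, N), real or complex; the Coulomb term uses
        only the (symmetric) real part, which is exact for Hermitian P
        because the imaginary part is antisymmetric and the integrals are
        symmetric in the contracted pair.
        """
        P = np.asarray(P)
        single = P.ndim == 2
        if single:
            P = P[None]
        B, n, _ = P.shape
        iscomplex = np.iscomplexobj(P)
        Pr = np.ascontiguousarray(P.real)
        # Coulomb via pair-compressed symmetric matrix
        w = np.where(self.pair_i == self.pair_j, 1.0, 2.0)
        packed = (Pr[:, self.pair_i, self.pair_j] * w).astype(self.jmat.dtype)
        Jp = (packed @ self.jmat).astype(np.float64)  # jmat symmetric
        J = np.zeros((B, n, n))
        J[:, self.pair_i, self.pair_j] = Jp
        J[:, self.pair_j, self.pair_i] = Jp
        # Exchange via one GEMM over all real/imag columns
        if iscomplex:
            Pi = np.ascontiguousarray(P.imag)
            cols = np.concatenate([Pr, Pi]).reshape(2 * B, n * n).T
        else:
            cols = Pr.reshape(B, n * n).T
        cols = np.ascontiguousarray(cols, dtype=self.kmat.dtype)
        Kcols = (self.kmat @ cols).astype(np.float64)
        if iscomplex:
            K = (
                Kcols[:, :B] + 1j * Kcols[:, B:]
            ).T.reshape(B, n, n)
        else:
            K = Kcols.T.reshape(B, n, n)
        if single:
            return J[0], K[0]
        return J, K


def two_electron_integrals(
    basis: list[BasisFunction],
    screen_threshold: float = 1e-6,
    memory_budget_gb: float = 4.0,
    exchange_dtype: str = "auto",
) -> ERIStore:
    """Compute the screened ERI store.

    ``exchange_dtype``: 'float64', 'float32', or 'auto' (float32 beyond 60
    basis functions, where the exchange matrix dominates memory/bandwidth;
    the ~1e-7 relative rounding is far below spectroscopic resolution).
    """
    n = len(basis)
    if exchange_dtype == "auto":
        kdtype = np.float32 if n > 60 else np.float64
    elif exchange_dtype in ("float32", "float64"):
        kdtype = np.dtype(exchange_dtype).type
    else:
        raise ValueError(f"bad exchange_dtype: {exchange_dtype!r}")
    npair = n * (n + 1) // 2
    need = npair * npair * 8 + n**4 * np.dtype(kdtype).itemsize
    if need > memory_budget_gb * 2**30:
        raise MemoryError(
            f"ERI storage estimate {need / 2**30:.2f} GiB exceeds the "
            f"memory budget of {memory_budget_gb:.2f} GiB "
            f"({n} basis functions)"
        )
    lmn = np.array([bf.lmn for bf in basis], dtype=np.int64)
    exps = np.array([bf.exps for bf in basis])
    coefs = np.array([bf.coefs for bf in basis])
    centers = np.array([bf.center for bf in basis])
    iu, ju = np.triu_indices(n)
    pair_i = iu.astype(np.int64)
    pair_j = ju.astype(np.int64)
    pidx = np.zeros((n, n), dtype=np.int64)
    pidx[pair_i, pair_j] = np.arange(npair)
    pidx[pair_j, pair_i] = np.arange(npair)

    tables = _pair_tables(lmn, exps, coefs, centers, pair_i, pair_j)
    schwarz = _schwarz_diagonal(*tables)
    qmax = float(schwarz.max()) if npair else 0.0
    sig = schwarz * qmax >= screen_threshold if screen_threshold > 0 else np.ones(npair, bool)
    jmat = np.zeros((npair, npair))
    kmat = np.zeros((n * n, n * n), dtype=kdtype)
    count = _fill_eri(
        pair_i, pair_j, sig, schwarz, screen_threshold,
        *tables, pidx, jmat, kmat, n,
    )
    return ERIStore(
        nbf=n,
        screen_threshold=screen_threshold,
        jmat=jmat,
        kmat=kmat,
        pair_i=pair_i,
        pair_j=pair_j,
        pidx=pidx,
        significant=np.asarray(sig, dtype=bool),
        schwarz=schwarz,
        n_computed=int(count),
    )


# ----------------------------------------------------------------------
# bundle
# ----------------------------------------------------------------------

@dataclass
class IntegralSet:
    """All integrals of a system plus the orthonormalization transform."""

    system: MolecularSystem
    basis: list[BasisFunction]
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    D: np.ndarray  # (3, N, N), origin at nuclear center of charge
    nuclear_repulsion: float
    eri: ERIStore
    screen_threshold: float
    _X: np.ndarray | None = field(default=None, repr=False)

    @property
    def nbf(self) -> int:
        return len(self.basis)

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V

    @property
    def X(self) -> np.ndarray:
        """Canonical orthogonalization S^(-1/2); columns with overlap
        eigenvalues below LINDEP_TOL are projected out."""
        if self._X is None:
            s, U = np.linalg.eigh(self.S)
            keep = s > LINDEP_TOL
            self._X = U[:, keep] / np.sqrt(s[keep])
        return self._X

    def fock(self, P):
        """F = Hcore + J - K/2 for density P (Tr(PS) = n_electrons)."""
        J, K = self.eri.coulomb_exchange(P)
        return self.hcore + J - 0.5 * K


def compute_integrals(
    system: MolecularSystem,
    screen_threshold: float = 1e-6,
    memory_budget_gb: float = 4.0,
    exchange_dtype: str = "auto",
) -> IntegralSet:
    basis = build_basis(system)
    S, T, V, D, enuc = one_electron_integrals(basis, system)
    eri = two_electron_integrals(
        basis, screen_threshold, memory_budget_gb, exchange_dtype
    )
    return IntegralSet(
        system=system,
        basis=basis,
        S=S,
        T=T,
        V=V,
        D=D,
        nuclear_repulsion=enuc,
        eri=eri,
        screen_threshold=screen_threshold,
    )
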