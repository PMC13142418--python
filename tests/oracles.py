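"""Independent reference implementations used to check the production code.

Everything here is deliberately written by a different route than the
package: integrals come from numerical quadrature instead of Hermite
recursions, the SCF is a plain damped Roothaan fixed point instead of
DIIS, excitation energies come from explicit linear-response (RPA) matrix
diagonalization instead of real-time propagation, and the carver oracle
(in kickspec.fixtures) is an exhaustive rescan instead of frontier growth.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import linalg
from scipy.special import erf

# ----------------------------------------------------------------------
# quadrature one-electron integrals
# ----------------------------------------------------------------------

_GH_NODES, _GH_W = np.polynomial.hermite.hermgauss(24)


def _poly_factor(x, center, l):
    return (x - center) ** l if l else np.ones_like(x)


def _overlap_prim_1d(l1, l2, A, B, a, b, extra_center=None, extra_power=0):
    """1-D integral of (x-A)^l1 (x-B)^l2 [ (x-extra)^p ] exp Gaussians by
    Gauss-Hermite quadrature (exact: the integrand is polynomial x Gaussian)."""
    p = a + b
    P = (a * A + b * B) / p
    mu = a * b / p
    pref = np.exp(-mu * (A - B) ** 2)
    x = P + _GH_NODES / np.sqrt(p)
    f = _poly_factor(x, A, l1) * _poly_factor(x, B, l2)
    if extra_power:
        f = f * _poly_factor(x, extra_center, extra_power)
    return pref / np.sqrt(p) * np.sum(_GH_W * f)


def quad_overlap_prim(lmn1, lmn2, A, B, a, b):
    return np.prod(
        [_overlap_prim_1d(lmn1[d], lmn2[d], A[d], B[d], a, b) for d in range(3)]
    )


def quad_dipole_prim(lmn1, lmn2, A, B, a, b, origin, comp):
    out = 1.0
    for d in range(3):
        if d == comp:
            out *= _overlap_prim_1d(
                lmn1[d], lmn2[d], A[d], B[d], a, b, extra_center=origin[d], extra_power=1
            )
        else:
            out *= _overlap_prim_1d(lmn1[d], lmn2[d], A[d], B[d], a, b)
    return out


def quad_kinetic_prim(lmn1, lmn2, A, B, a, b):
    """Kinetic energy via the analytic Laplacian expansion of the ket:
    d2/dx2 [(x-B)^l e^(-b x^2)] = l(l-1)(x-B)^(l-2) - 2b(2l+1)(x-B)^l
    + 4 b^2 (x-B)^(l+2), each term integrated by quadrature."""
    out = 0.0
    for d in range(3):
        l2 = lmn2[d]
        term = -2.0 * b * (2 * l2 + 1) * _overlap_prim_1d(lmn1[d], l2, A[d], B[d], a, b)
        term += 4.0 * b * b * _overlap_prim_1d(lmn1[d], l2 + 2, A[d], B[d], a, b)
        if l2 >= 2:
            term += l2 * (l2 - 1) * _overlap_prim_1d(lmn1[d], l2 - 2, A[d], B[d], a, b)
        part = -0.5 * term
        for dd in range(3):
            if dd != d:
                part *= _overlap_prim_1d(lmn1[dd], lmn2[dd], A[dd], B[dd], a, b)
        out += part
    return out


def _spherical_grid(n_r, n_theta, n_phi, rmax):
    """Product quadrature over a ball: returns (points (M,3), weights (M,))
    with the r^2 Jacobian included."""
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    wphi = 2 * np.pi / n_phi
    st = np.sqrt(1 - ct**2)
    R, CT, PH = np.meshgrid(r, ct, phi, indexing="ij")
    WR, WT, _ = np.meshgrid(wr, wt, phi, indexing="ij")
    ST = np.sqrt(1 - CT**2)
    pts = np.stack(
        [R * ST * np.cos(PH), R * ST * np.sin(PH), R * CT], axis=-1
    ).reshape(-1, 3)
    w = (WR * WT * wphi * R**2).reshape(-1)
    return pts, w


def quad_nuclear_prim(lmn1, lmn2, A, B, a, b, C, n_r=160, n_ang=28):
    """-<a| 1/|r-C| |b> for one nucleus by numerical quadrature.

    When the product-Gaussian support overlaps the nucleus, a spherical
    grid centered at the singularity is used (the 1/r cancels against the
    r^2 Jacobian); when it does not, the singularity is outside the
    support and a Gauss-Hermite tensor grid at the product center
    converges much faster."""
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    sep = np.linalg.norm(P - np.asarray(C))
    if sep * np.sqrt(p) > 6.0:
        nodes, wts = np.polynomial.hermite.hermgauss(40)
        x = P[0] + nodes / np.sqrt(p)
        y = P[1] + nodes / np.sqrt(p)
        z = P[2] + nodes / np.sqrt(p)
        Xg, Yg, Zg = np.meshgrid(x, y, z, indexing="ij")
        W = (
            np.multiply.outer(np.multiply.outer(wts, wts), wts)
            / p**1.5
            * np.exp(-a * b / p * np.sum((np.asarray(A) - np.asarray(B)) ** 2))
        )
        f = np.ones_like(Xg)
        for d, G in enumerate((Xg, Yg, Zg)):
            f = f * _poly_factor(G, A[d], lmn1[d]) * _poly_factor(G, B[d], lmn2[d])
        dist = np.sqrt((Xg - C[0]) ** 2 + (Yg - C[1]) ** 2 + (Zg - C[2]) ** 2)
        return -np.sum(W * f / dist)
    rmax = sep + 10.0 / np.sqrt(p)
    pts, w = _spherical_grid(n_r, n_ang, 2 * n_ang, rmax)
    r = pts + np.asarray(C)
    rad = np.linalg.norm(pts, axis=1)
    f = np.ones(len(pts))
    for d in range(3):
        f = f * _poly_factor(r[:, d], A[d], lmn1[d]) * _poly_factor(r[:, d], B[d], lmn2[d])
    f = f * np.exp(
        -a * np.sum((r - np.asarray(A)) ** 2, axis=1)
        - b * np.sum((r - np.asarray(B)) ** 2, axis=1)
    )
    return -np.sum(w * f / np.maximum(rad, 1e-300))


def _contract(basis_i, basis_j, prim_fn):
    out = 0.0
    for a, ca in zip(basis_i.exps, basis_i.coefs):
        for b, cb in zip(basis_j.exps, basis_j.coefs):
            out += ca * cb * prim_fn(a, b)
    return out


def quad_one_electron(basis, system, origin):
    """Quadrature S, T, V, D for a full (small) basis."""
    from kickspec.elements import ANGSTROM_TO_BOHR

    n = len(basis)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    D = np.zeros((3, n, n))
    nuc = system.positions() * ANGSTROM_TO_BOHR
    Z = system.atomic_numbers()
    for i in range(n):
        for j in range(i + 1):
            bi, bj = basis[i], basis[j]
            A, B = bi.center, bj.center
            S[i, j] = S[j, i] = _contract(
                bi, bj, lambda a, b: quad_overlap_prim(bi.lmn, bj.lmn, A, B, a, b)
            )
            T[i, j] = T[j, i] = _contract(
                bi, bj, lambda a, b: quad_kinetic_prim(bi.lmn, bj.lmn, A, B, a, b)
            )
            V[i, j] = V[j, i] = _contract(
                bi,
                bj,
                lambda a, b: sum(
                    Z[c] * quad_nuclear_prim(bi.lmn, bj.lmn, A, B, a, b, nuc[c])
                    for c in range(len(Z))
                ),
            )
            for comp in range(3):
                D[comp, i, j] = D[comp, j, i] = _contract(
                    bi,
                    bj,
                    lambda a, b: quad_dipole_prim(bi.lmn, bj.lmn, A, B, a, b, origin, comp),
                )
    return S, T, V, D


# ----------------------------------------------------------------------
# s-function ERI via the Gaussian electrostatic potential + quadrature
# ----------------------------------------------------------------------

def quad_eri_ssss(bra_i, bra_j, ket_k, ket_l, n_r=160, n_ang=24):
    """(ij|kl) for four s-type contracted functions: the ket charge
    distribution's potential is the analytic erf form, the bra density is
    integrated against it on a spherical grid."""
    out = 0.0
    for a, ca in zip(bra_i.exps, bra_i.coefs):
        for b, cb in zip(bra_j.exps, bra_j.coefs):
            p = a + b
            P = (a * bra_i.center + b * bra_j.center) / p
            kab = np.exp(-a * b / p * np.sum((bra_i.center - bra_j.center) ** 2))
            for c, cc in zip(ket_k.exps, ket_k.coefs):
                for d, cd in zip(ket_l.exps, ket_l.coefs):
                    q = c + d
                    Q = (c * ket_k.center + d * ket_l.center) / q
                    kcd = np.exp(
                        -c * d / q * np.sum((ket_k.center - ket_l.center) ** 2)
                    )
                    rmax = np.linalg.norm(P - Q) + 10.0 / np.sqrt(p)
                    pts, w = _spherical_grid(n_r, n_ang, 2 * n_ang, rmax)
                    r = pts + P
                    rho = kab * np.exp(-p * np.sum((r - P) ** 2, axis=1))
                    d_q = np.linalg.norm(r - Q, axis=1)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        pot = (
                            kcd
                            * (np.pi / q) ** 1.5
                            * np.where(
                                d_q < 1e-10,
                                2.0 * np.sqrt(q / np.pi),
                                erf(np.sqrt(q) * d_q) / np.maximum(d_q, 1e-300),
                            )
                        )
                    out += ca * cb * cc * cd * np.sum(w * rho * pot)
    return out


# ----------------------------------------------------------------------
# naive SCF
# ----------------------------------------------------------------------

def naive_rhf(S, Hcore, eri_dense, enuc, n_electrons, damping=0.35,
              max_iter=500, tol=1e-10):
    """Plain damped Roothaan iteration with an explicit-loop Fock build."""
    n = S.shape[0]
    nocc = n_electrons // 2
    eps, C = linalg.eigh(Hcore, S)
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    E_old = 0.0
    for _ in range(max_iter):
        F = np.array(Hcore)
        for mu in range(n):
            for nu in range(n):
                acc = 0.0
                for la in range(n):
                    for si in range(n):
                        acc += P[la, si] * (
                            eri_dense[mu, nu, la, si]
                            - 0.5 * eri_dense[mu, la, nu, si]
                        )
                F[mu, nu] += acc
        E = 0.5 * np.sum(P * (Hcore + F)) + enuc
        eps, C = linalg.eigh(F, S)
        P_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        P = damping * P + (1 - damping) * P_new
        if abs(E - E_old) < tol:
            break
        E_old = E
    return E, P, C, eps


# ----------------------------------------------------------------------
# linear-response TDHF (RPA) excitation energies
# ----------------------------------------------------------------------

def tdhf_excitations(C, eps, eri_dense, n_electrons):
    """Singlet RPA excitation energies from explicit A/B matrices."""
    n = len(eps)
    nocc = n_electrons // 2
    nvirt = n - nocc
    mo = np.einsum("pi,qj,pqrs,rk,sl->ijkl", C, C, eri_dense, C, C, optimize=True)
    dim = nocc * nvirt
    A = np.zeros((dim, dim))
    B = np.zeros((dim, dim))
    for i in range(nocc):
        for a in range(nvirt):
            ia = i * nvirt + a
            av = nocc + a
            for j in range(nocc):
                for b in range(nvirt):
                    jb = j * nvirt + b
                    bv = nocc + b
                    A[ia, jb] = 2.0 * mo[i, av, j, bv] - mo[i, j, av, bv]
                    if ia == jb:
                        A[ia, jb] += eps[av] - eps[i]
                    B[ia, jb] = 2.0 * mo[i, av, bv, j] - mo[i, bv, av, j]
    # Hermitian reduction: omega^2 eigenvalues of (A-B)^(1/2)(A+B)(A-B)^(1/2)
    amb = A - B
    s, U = np.linalg.eigh(amb)
    half = U @ np.diag(np.sqrt(np.abs(s))) @ U.T
    w2 = np.linalg.eigvalsh(half @ (A + B) @ half)
    return np.sqrt(np.abs(w2))
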