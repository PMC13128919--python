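"""Conventional Cartesian-Gaussian STO-3G restricted Hartree-Fock.

This is a deliberately independent second route through the same physics:
textbook McMurchie-Davidson integrals over Cartesian s/p Gaussians (with
angular prefactors and Boys functions) and a plain dense-tensor RHF.  It
shares nothing with the displaced-lobe path except the published STO-3G
tabulation, and serves as the validation reference for it: for s-only
systems the two routes must agree to near machine precision, and for
p-bearing systems their difference measures the lobe-fitting error.

Function ordering matches the lobe basis (atom-major; 1s, 2s, 2px, 2py,
2pz per atom) so matrices are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .basis import load_reference_basis, _norm_s, _norm_p, shell_self_overlap
from .constants import BOHR_PER_ANGSTROM
from .structures import MolecularSystem

_LMAX = 3          # highest 1D Cartesian power needed (p + kinetic shift)


@njit(cache=True)
def _boys(nmax, t, out):
    """Boys functions F_0..F_nmax(t) (downward recursion from a series)."""
    if t < 1e-13:
        for m in range(nmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if t > 30.0:
        out[0] = 0.5 * math.sqrt(math.pi / t)
        et = math.exp(-t)
        for m in range(nmax):
            out[m + 1] = ((2 * m + 1) * out[m] - et) / (2.0 * t)
        return
    # series for F_nmax, then downward
    acc = 0.0
    term = 1.0 / (2 * nmax + 1)
    k = 0
    while True:
        acc += term
        k += 1
        term *= 2.0 * t / (2 * nmax + 2 * k + 1)
        if term < 1e-17:
            break
    et = math.exp(-t)
    out[nmax] = acc * et
    for m in range(nmax - 1, -1, -1):
        out[m] = (2.0 * t * out[m + 1] + et) / (2 * m + 1)


@njit(cache=True)
def _e1d(la, lb, xpa, xpb, p, k1d, E):
    """Hermite expansion coefficients E[i,j,t] for one dimension."""
    E[:, :, :] = 0.0
    E[0, 0, 0] = k1d
    oo2p = 0.5 / p
    for i in range(la + lb + 1):
        for j in range(la + lb + 1):
            if i + j == 0 or i + j > la + lb or i > la or j > lb:
                continue
            for t in range(i + j + 1):
                if i > 0:
                    v = xpa * E[i - 1, j, t]
                    if t > 0:
                        v += oo2p * E[i - 1, j, t - 1]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i - 1, j, t + 1]
                    E[i, j, t] = v
                else:
                    v = xpb * E[i, j - 1, t]
                    if t > 0:
                        v += oo2p * E[i, j - 1, t - 1]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v


@njit(cache=True)
def _rtensor(nmax, alpha, x, y, z, R):
    """Hermite Coulomb integrals R_tuv for t+u+v <= nmax."""
    t2 = alpha * (x * x + y * y + z * z)
    fb = np.zeros(nmax + 1)
    _boys(nmax, t2, fb)
    Rn = np.zeros((nmax + 1, nmax + 1, nmax + 1, nmax + 1))
    for n in range(nmax + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * fb[n]
    for s in range(1, nmax + 1):
        for n in range(nmax - s + 1):
            for t in range(s + 1):
                for u in range(s - t + 1):
                    v = s - t - u
                    if t > 0:
                        val = x * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    R[:, :, :] = Rn[0, : nmax + 1, : nmax + 1, : nmax + 1]


@njit(cache=True)
def _oneel_pair(la_vec, lb_vec, a, b, A, B, atom_z, atom_xyz):
    """Overlap, kinetic, nuclear attraction for one primitive pair with
    Cartesian powers la_vec/lb_vec (each component <= 1)."""
    p = a + b
    P = (a * A + b * B) / p
    Emats = np.zeros((3, _LMAX + 1, _LMAX + 1, 2 * _LMAX + 1))
    for d in range(3):
        x_ab = A[d] - B[d]
        k1d = math.exp(-a * b / p * x_ab * x_ab)
        _e1d(_LMAX, _LMAX, P[d] - A[d], P[d] - B[d], p, k1d, Emats[d])
    rt_pi_p = math.sqrt(math.pi / p)
    # overlap
    S = 1.0
    for d in range(3):
        S *= Emats[d, la_vec[d], lb_vec[d], 0] * rt_pi_p
    # kinetic: 1D operator per dimension
    Tk = 0.0
    for d in range(3):
        j = lb_vec[d]
        i = la_vec[d]
        tj = -2.0 * b * b * Emats[d, i, j + 2, 0] * rt_pi_p \
            + b * (2 * j + 1) * Emats[d, i, j, 0] * rt_pi_p
        if j >= 2:
            tj -= 0.5 * j * (j - 1) * Emats[d, i, j - 2, 0] * rt_pi_p
        rest = 1.0
        for d2 in range(3):
            if d2 != d:
                rest *= Emats[d2, la_vec[d2], lb_vec[d2], 0] * rt_pi_p
        Tk += tj * rest
    # nuclear attraction
    ltot = la_vec[0] + lb_vec[0] + la_vec[1] + lb_vec[1] + la_vec[2] + lb_vec[2]
    R = np.zeros((ltot + 1, ltot + 1, ltot + 1))
    V = 0.0
    for n in range(atom_z.shape[0]):
        _rtensor(ltot, p, P[0] - atom_xyz[n, 0], P[1] - atom_xyz[n, 1],
                 P[2] - atom_xyz[n, 2], R)
        acc = 0.0
        for t in range(la_vec[0] + lb_vec[0] + 1):
            for u in range(la_vec[1] + lb_vec[1] + 1):
                for v in range(la_vec[2] + lb_vec[2] + 1):
                    acc += (Emats[0, la_vec[0], lb_vec[0], t]
                            * Emats[1, la_vec[1], lb_vec[1], u]
                            * Emats[2, la_vec[2], lb_vec[2], v]
                            * R[t, u, v])
        V -= atom_z[n] * 2.0 * math.pi / p * acc
    return S, Tk, V


@njit(cache=True)
def _eri_quartet(la_vec, lb_vec, lc_vec, ld_vec, a, b, c, d, A, B, C, D):
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    alpha = p * q / (p + q)
    E1 = np.zeros((3, _LMAX + 1, _LMAX + 1, 2 * _LMAX + 1))
    E2 = np.zeros((3, _LMAX + 1, _LMAX + 1, 2 * _LMAX + 1))
    for dd in range(3):
        xab = A[dd] - B[dd]
        xcd = C[dd] - D[dd]
        _e1d(_LMAX, _LMAX, P[dd] - A[dd], P[dd] - B[dd], p,
             math.exp(-a * b / p * xab * xab), E1[dd])
        _e1d(_LMAX, _LMAX, Q[dd] - C[dd], Q[dd] - D[dd], q,
             math.exp(-c * d / q * xcd * xcd), E2[dd])
    l1 = la_vec[0] + lb_vec[0]
    m1 = la_vec[1] + lb_vec[1]
    n1 = la_vec[2] + lb_vec[2]
    l2 = lc_vec[0] + ld_vec[0]
    m2 = lc_vec[1] + ld_vec[1]
    n2 = lc_vec[2] + ld_vec[2]
    ltot = l1 + m1 + n1 + l2 + m2 + n2
    R = np.zeros((ltot + 1, ltot + 1, ltot + 1))
    _rtensor(ltot, alpha, P[0] - Q[0], P[1] - Q[1], P[2] - Q[2], R)
    acc = 0.0
    for t in range(l1 + 1):
        for u in range(m1 + 1):
            for v in range(n1 + 1):
                e1 = (E1[0, la_vec[0], lb_vec[0], t]
                      * E1[1, la_vec[1], lb_vec[1], u]
                      * E1[2, la_vec[2], lb_vec[2], v])
                if e1 == 0.0:
                    continue
                for tt in range(l2 + 1):
                    for uu in range(m2 + 1):
                        for vv in range(n2 + 1):
                            e2 = (E2[0, lc_vec[0], ld_vec[0], tt]
                                  * E2[1, lc_vec[1], ld_vec[1], uu]
                                  * E2[2, lc_vec[2], ld_vec[2], vv])
                            if e2 == 0.0:
                                continue
                            sgn = -1.0 if (tt + uu + vv) % 2 else 1.0
                            acc += e1 * e2 * sgn * R[t + tt, u + uu, v + vv]
    return acc * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))


@njit(cache=True)
def _all_integrals(func_l, func_center, func_nprim, func_exp, func_coef,
                   atom_z, atom_xyz):
    """Dense S, T, V and ERI tensor over contracted Cartesian functions.

    func_l: (n, 3) Cartesian powers; func_exp/coef: (n, maxprim)."""
    n = func_l.shape[0]
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = t = v = 0.0
            for pa in range(func_nprim[i]):
                for pb in range(func_nprim[j]):
                    cc = func_coef[i, pa] * func_coef[j, pb]
                    s1, t1, v1 = _oneel_pair(func_l[i], func_l[j],
                                             func_exp[i, pa], func_exp[j, pb],
                                             func_center[i], func_center[j],
                                             atom_z, atom_xyz)
                    s += cc * s1
                    t += cc * t1
                    v += cc * v1
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
    eri = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(i, n):
            for k in range(n):
                for l in range(k, n):
                    if k * n + l < i * n + j:
                        continue
                    acc = 0.0
                    for pa in range(func_nprim[i]):
                        for pb in range(func_nprim[j]):
                            for pc in range(func_nprim[k]):
                                for pd in range(func_nprim[l]):
                                    acc += (func_coef[i, pa] * func_coef[j, pb]
                                            * func_coef[k, pc] * func_coef[l, pd]
                                            * _eri_quartet(
                                                func_l[i], func_l[j],
                                                func_l[k], func_l[l],
                                                func_exp[i, pa], func_exp[j, pb],
                                                func_exp[k, pc], func_exp[l, pd],
                                                func_center[i], func_center[j],
                                                func_center[k], func_center[l]))
                    for (a2, b2) in ((i, j), (j, i)):
                        for (c2, d2) in ((k, l), (l, k)):
                            eri[a2, b2, c2, d2] = acc
                            eri[c2, d2, a2, b2] = acc
    return S, T, V, eri


@dataclass
class ReferenceIntegrals:
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    eri: np.ndarray

    @property
    def H_core(self):
        return self.T + self.V


def _cartesian_basis_arrays(system: MolecularSystem, family: str = "STO-3G"):
    func_l, centers, nprim, exps, coefs = [], [], [], [], []
    coords = system.positions * BOHR_PER_ANGSTROM
    maxprim = 0
    for ia, atom in enumerate(system.atoms):
        for shell in load_reference_basis(atom.element, family):
            norm = 1.0 / math.sqrt(shell_self_overlap(shell))
            if shell.l == 0:
                prim_norm = _norm_s(shell.exponents)
                func_l.append((0, 0, 0))
                centers.append(coords[ia])
                nprim.append(shell.n_primitives)
                exps.append(shell.exponents)
                coefs.append(norm * shell.coefficients * prim_norm)
            else:
                prim_norm = _norm_p(shell.exponents)
                for axis in range(3):
                    lv = [0, 0, 0]
                    lv[axis] = 1
                    func_l.append(tuple(lv))
                    centers.append(coords[ia])
                    nprim.append(shell.n_primitives)
                    exps.append(shell.exponents)
                    coefs.append(norm * shell.coefficients * prim_norm)
            maxprim = max(maxprim, shell.n_primitives)
    n = len(func_l)
    exp_arr = np.zeros((n, maxprim))
    coef_arr = np.zeros((n, maxprim))
    for i in range(n):
        exp_arr[i, : nprim[i]] = exps[i]
        coef_arr[i, : nprim[i]] = coefs[i]
    return (np.array(func_l, dtype=np.int64), np.array(centers),
            np.array(nprim, dtype=np.int64), exp_arr, coef_arr)


def reference_integrals(system: MolecularSystem,
                        family: str = "STO-3G") -> ReferenceIntegrals:
    """All conventional STO-3G integrals for a system (dense tensors)."""
    func_l, centers, nprim, exp_arr, coef_arr = _cartesian_basis_arrays(system, family)
    S, T, V, eri = _all_integrals(func_l, centers, nprim, exp_arr, coef_arr,
                                  system.atomic_numbers.astype(np.float64),
                                  system.positions * BOHR_PER_ANGSTROM)
    return ReferenceIntegrals(S, T, V, eri)


@dataclass
class ReferenceResult:
    E_total: float
    E_nuc: float
    orbital_energies: np.ndarray
    C: np.ndarray
    P: np.ndarray
    converged: bool
    integrals: ReferenceIntegrals


def reference_rhf(system: MolecularSystem, family: str = "STO-3G",
                  max_iter: int = 200, conv: float = 1e-10) -> ReferenceResult:
    """Plain dense restricted Hartree-Fock over conventional integrals."""
    if system.n_electrons % 2:
        raise ValueError("closed-shell reference requires an even electron count")
    ints = reference_integrals(system, family)
    n_occ = system.n_electrons // 2
    H = ints.H_core
    S = ints.S
    s, U = np.linalg.eigh(S)
    X = U[:, s > 1e-9] / np.sqrt(s[s > 1e-9])
    pos = system.positions * BOHR_PER_ANGSTROM
    z = system.atomic_numbers
    e_nuc = sum(z[a] * z[b] / np.linalg.norm(pos[a] - pos[b])
                for a in range(len(z)) for b in range(a + 1, len(z)))

    def diag(F):
        e, Co = np.linalg.eigh(X.T @ F @ X)
        C = X @ Co
        return e, C, 2.0 * C[:, :n_occ] @ C[:, :n_occ].T

    eps, C, P = diag(H)
    energy_old = 0.0
    converged = False
    diis_F, diis_e = [], []
    F = H
    for _ in range(max_iter):
        J = np.einsum("ijkl,kl->ij", ints.eri, P)
        K = np.einsum("ikjl,kl->ij", ints.eri, P)
        F = H + J - 0.5 * K
        energy = float(np.sum(P * (H + 0.5 * (J - 0.5 * K)))) + e_nuc
        err = F @ P @ S - S @ P @ F
        diis_F.append(F.copy())
        diis_e.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_e.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a2 in range(m):
                for b2 in range(m):
                    B[a2, b2] = np.sum(diis_e[a2] * diis_e[b2])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                cvec = np.linalg.solve(B, rhs)[:m]
                F = sum(cf * Fm for cf, Fm in zip(cvec, diis_F))
            except np.linalg.LinAlgError:
                pass
        eps, C, P = diag(F)
        if abs(energy - energy_old) < conv:
            converged = True
            energy_old = energy
            break
        energy_old = energy
    return ReferenceResult(float(energy_old), float(e_nuc), eps, C, P,
                           converged, ints)
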