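"""Numba-compiled hot loops: primitive-pair tables, screened ERI
evaluation, Fock contraction and their nuclear derivatives.

Everything here works on flat float64/int64 arrays prepared by the
higher-level modules; all lengths are in bohr and energies in hartree.
"""

import math

import numpy as np
from numba import njit

SQRT_PI = np.sqrt(np.pi)
ERF_SHORTCUT = 4.0  # erf(x >= 4) treated as exactly 1 (error <= 1.5e-8)

# Abramowitz-Stegun 7.1.26 rational approximation coefficients
_A_C0 = 0.3275911
_A_C1 = 0.254829592
_A_C2 = -0.284496736
_A_C3 = 1.421413741
_A_C4 = -1.453152027
_A_C5 = 1.061405429


@njit(cache=True)
def erf_approx(x):
    """Rational-polynomial erf for x >= 0 (abs error <= 2e-7 on [0, 4])."""
    if x >= ERF_SHORTCUT:
        return 1.0
    t = 1.0 / (1.0 + _A_C0 * x)
    poly = t * (_A_C1 + t * (_A_C2 + t * (_A_C3 + t * (_A_C4 + t * _A_C5))))
    return 1.0 - poly * np.exp(-x * x)


@njit(cache=True)
def f11_half(x):
    """1F1(1/2, 3/2, -x) = sqrt(pi)*erf(sqrt(x))/(2*sqrt(x)) for x >= 0."""
    if x < 1e-8:
        return 1.0 - x / 3.0 + x * x / 10.0
    sx = np.sqrt(x)
    return SQRT_PI * erf_approx(sx) / (2.0 * sx)


@njit(cache=True)
def f11_half_exact_erf(x):
    """Same as f11_half but with library erf (one-electron/oracle use)."""
    if x < 1e-8:
        return 1.0 - x / 3.0 + x * x / 10.0
    sx = np.sqrt(x)
    return SQRT_PI * math.erf(sx) / (2.0 * sx)


# ------------------------------------------------------------------ #
# primitive pair tables
# ------------------------------------------------------------------ #

@njit(cache=True)
def build_pair_table(pair_i, pair_j, prim_coef, prim_alpha, prim_center,
                     func_start, func_count, floor):
    """Primitive-pair records for each function pair (i, j).

    Returns (pp_start, pp_count, pp_O, pp_center, pp_psum, pp_pa, pp_pb)
    where pp_O is the pair overlap factor
    sqrt(2)*pi^(5/4)*A_a*A_b*(aa+ab)^(-3/2)*exp(-mu*R^2), pp_center the
    composite center, pp_psum the exponent sum, and pp_pa/pp_pb the flat
    primitive indices (needed for derivatives).  Pairs with |O| below
    ``floor`` are dropped.
    """
    n_pairs = pair_i.shape[0]
    pp_start = np.zeros(n_pairs, dtype=np.int64)
    pp_count = np.zeros(n_pairs, dtype=np.int64)
    pref = np.sqrt(2.0) * np.pi ** 1.25

    # first pass: count
    total = 0
    for t in range(n_pairs):
        i = pair_i[t]
        j = pair_j[t]
        cnt = 0
        for a in range(func_start[i], func_start[i] + func_count[i]):
            for b in range(func_start[j], func_start[j] + func_count[j]):
                aa = prim_alpha[a]
                ab = prim_alpha[b]
                p = aa + ab
                mu = aa * ab / p
                r2 = 0.0
                for c in range(3):
                    d = prim_center[a, c] - prim_center[b, c]
                    r2 += d * d
                o = pref * prim_coef[a] * prim_coef[b] * p ** (-1.5) * np.exp(-mu * r2)
                if abs(o) >= floor:
                    cnt += 1
        pp_start[t] = total
        pp_count[t] = cnt
        total += cnt

    pp_O = np.empty(total)
    pp_center = np.empty((total, 3))
    pp_psum = np.empty(total)
    pp_pa = np.empty(total, dtype=np.int64)
    pp_pb = np.empty(total, dtype=np.int64)
    for t in range(n_pairs):
        i = pair_i[t]
        j = pair_j[t]
        idx = pp_start[t]
        for a in range(func_start[i], func_start[i] + func_count[i]):
            for b in range(func_start[j], func_start[j] + func_count[j]):
                aa = prim_alpha[a]
                ab = prim_alpha[b]
                p = aa + ab
                mu = aa * ab / p
                r2 = 0.0
                for c in range(3):
                    d = prim_center[a, c] - prim_center[b, c]
                    r2 += d * d
                o = pref * prim_coef[a] * prim_coef[b] * p ** (-1.5) * np.exp(-mu * r2)
                if abs(o) >= floor:
                    pp_O[idx] = o
                    pp_psum[idx] = p
                    for c in range(3):
                        pp_center[idx, c] = (aa * prim_center[a, c]
                                             + ab * prim_center[b, c]) / p
                    pp_pa[idx] = a
                    pp_pb[idx] = b
                    idx += 1
    return pp_start, pp_count, pp_O, pp_center, pp_psum, pp_pa, pp_pb


# ------------------------------------------------------------------ #
# ERI evaluation over pair records
# ------------------------------------------------------------------ #

@njit(cache=True)
def eri_values(task_p, task_q, pp_start, pp_count, pp_O, pp_center, pp_psum,
               use_exact_erf):
    """Contracted (ij|kl) for each task, via the uniform double sum over
    precomputed primitive pairs."""
    n = task_p.shape[0]
    out = np.zeros(n)
    for t in range(n):
        tp = task_p[t]
        tq = task_q[t]
        acc = 0.0
        for u in range(pp_start[tp], pp_start[tp] + pp_count[tp]):
            o1 = pp_O[u]
            p1 = pp_psum[u]
            x1 = pp_center[u, 0]
            y1 = pp_center[u, 1]
            z1 = pp_center[u, 2]
            for v in range(pp_start[tq], pp_start[tq] + pp_count[tq]):
                p2 = pp_psum[v]
                pp = p1 * p2 / (p1 + p2)
                dx = x1 - pp_center[v, 0]
                dy = y1 - pp_center[v, 1]
                dz = z1 - pp_center[v, 2]
                x = pp * (dx * dx + dy * dy + dz * dz)
                if use_exact_erf:
                    f = f11_half_exact_erf(x)
                else:
                    f = f11_half(x)
                acc += o1 * pp_O[v] * np.sqrt(pp) * f
        out[t] = acc
    return out


@njit(cache=True)
def fock_twoelectron(nbf, task_p, task_q, weights, values,
                     pair_i, pair_j, P):
    """Two-electron matrix G from the canonical weighted task list.

    G_ij = sum_kl P_kl [(ij|kl) - (ik|jl)/2]; each canonical quadruple is
    expanded into its distinct index permutations.
    """
    J = np.zeros((nbf, nbf))
    K = np.zeros((nbf, nbf))
    pi = np.empty(8, dtype=np.int64)
    pj = np.empty(8, dtype=np.int64)
    pk = np.empty(8, dtype=np.int64)
    pl = np.empty(8, dtype=np.int64)
    for t in range(task_p.shape[0]):
        i = pair_i[task_p[t]]
        j = pair_j[task_p[t]]
        k = pair_i[task_q[t]]
        l = pair_j[task_q[t]]
        v = values[t] * weights[t]
        if v == 0.0:
            continue
        pi[0], pj[0], pk[0], pl[0] = i, j, k, l
        pi[1], pj[1], pk[1], pl[1] = j, i, k, l
        pi[2], pj[2], pk[2], pl[2] = i, j, l, k
        pi[3], pj[3], pk[3], pl[3] = j, i, l, k
        pi[4], pj[4], pk[4], pl[4] = k, l, i, j
        pi[5], pj[5], pk[5], pl[5] = l, k, i, j
        pi[6], pj[6], pk[6], pl[6] = k, l, j, i
        pi[7], pj[7], pk[7], pl[7] = l, k, j, i
        for m in range(8):
            dup = False
            for m2 in range(m):
                if (pi[m] == pi[m2] and pj[m] == pj[m2]
                        and pk[m] == pk[m2] and pl[m] == pl[m2]):
                    dup = True
                    break
            if dup:
                continue
            a, b, c, d = pi[m], pj[m], pk[m], pl[m]
            J[a, b] += P[c, d] * v
            K[a, c] += P[b, d] * v
    return J - 0.5 * K


# ------------------------------------------------------------------ #
# one-electron integrals
# ------------------------------------------------------------------ #

@njit(cache=True)
def _switch_weight(d, r_cl, r_cu):
    if d <= r_cl:
        return 1.0
    if d >= r_cu:
        return 0.0
    x = (d - r_cl) / (r_cu - r_cl)
    return 1.0 + 2.0 * x ** 3 - 3.0 * x ** 2


@njit(cache=True)
def one_electron(nbf, prim_coef, prim_alpha, prim_center,
                 func_start, func_count, func_atom, atom_z, atom_xyz,
                 atom_pos_ang, r_cl, r_cu):
    """Overlap, kinetic and nuclear-attraction matrices over the lobe basis.

    Nuclear attraction carries the same smooth Coulomb switching as the
    ERIs, on the distance (angstrom) between the density's atom-midpoint
    and the nucleus; pass r_cl = r_cu = inf to disable the cut.
    """
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    n_at = atom_z.shape[0]
    for i in range(nbf):
        for j in range(i, nbf):
            ai = func_atom[i]
            aj = func_atom[j]
            mx = 0.5 * (atom_pos_ang[ai, 0] + atom_pos_ang[aj, 0])
            my = 0.5 * (atom_pos_ang[ai, 1] + atom_pos_ang[aj, 1])
            mz = 0.5 * (atom_pos_ang[ai, 2] + atom_pos_ang[aj, 2])
            s = 0.0
            tkin = 0.0
            vnuc = 0.0
            for a in range(func_start[i], func_start[i] + func_count[i]):
                aa = prim_alpha[a]
                for b in range(func_start[j], func_start[j] + func_count[j]):
                    ab = prim_alpha[b]
                    p = aa + ab
                    mu = aa * ab / p
                    r2 = 0.0
                    for c in range(3):
                        d = prim_center[a, c] - prim_center[b, c]
                        r2 += d * d
                    e = prim_coef[a] * prim_coef[b] * np.exp(-mu * r2)
                    s00 = e * (np.pi / p) ** 1.5
                    s += s00
                    tkin += mu * (3.0 - 2.0 * mu * r2) * s00
                    # nuclear attraction over all centers
                    for n in range(n_at):
                        dnx = mx - atom_pos_ang[n, 0]
                        dny = my - atom_pos_ang[n, 1]
                        dnz = mz - atom_pos_ang[n, 2]
                        w = _switch_weight(
                            np.sqrt(dnx * dnx + dny * dny + dnz * dnz),
                            r_cl, r_cu)
                        if w == 0.0:
                            continue
                        t2 = 0.0
                        for c in range(3):
                            pc = (aa * prim_center[a, c] + ab * prim_center[b, c]) / p \
                                - atom_xyz[n, c]
                            t2 += pc * pc
                        vnuc -= w * atom_z[n] * e * 2.0 * np.pi / p \
                            * f11_half_exact_erf(p * t2)
            S[i, j] = s
            S[j, i] = s
            T[i, j] = tkin
            T[j, i] = tkin
            V[i, j] = vnuc
            V[j, i] = vnuc
    return S, T, V


# ------------------------------------------------------------------ #
# density relevance (screening)
# ------------------------------------------------------------------ #

@njit(cache=True)
def relevance_matrix(nbf, abs_coef, abs_alpha, abs_center, abs_start, abs_count):
    """r(rho_ij) for all function pairs: analytic integral of the product
    of the two all-positive absolute-value representations."""
    R = np.zeros((nbf, nbf))
    for i in range(nbf):
        for j in range(i, nbf):
            acc = 0.0
            for a in range(abs_start[i], abs_start[i] + abs_count[i]):
                for b in range(abs_start[j], abs_start[j] + abs_count[j]):
                    term = abs_coef[a] * abs_coef[b]
                    for c in range(3):
                        aa = abs_alpha[a, c]
                        ab = abs_alpha[b, c]
                        p = aa + ab
                        d = abs_center[a, c] - abs_center[b, c]
                        term *= np.sqrt(np.pi / p) * np.exp(-aa * ab / p * d * d)
                    acc += term
            R[i, j] = acc
            R[j, i] = acc
    return R


# ------------------------------------------------------------------ #
# task-list construction
# ------------------------------------------------------------------ #

@njit(cache=True)
def f1_boys(x):
    """First-order Boys function F_1(x) = (F_0(x) - exp(-x)) / (2x)."""
    if x < 1e-8:
        return 1.0 / 3.0 - x / 5.0 + x * x / 14.0
    sx = np.sqrt(x)
    f0 = SQRT_PI * math.erf(sx) / (2.0 * sx)
    return (f0 - np.exp(-x)) / (2.0 * x)


@njit(cache=True)
def grad_one_electron(n_atoms, nbf, prim_coef, prim_alpha, prim_center,
                      func_start, func_count, func_atom, atom_z, atom_xyz,
                      atom_pos_ang, r_cl, r_cu, bohr_per_ang, P, W):
    """Nuclear gradient of sum_ij P_ij (T_ij + V_ij) - sum_ij W_ij S_ij.

    Returns (n_atoms, 3) in Ha/bohr.  W is the energy-weighted density
    handling the orbital-orthonormality (Pulay) term.  The nuclear
    attraction carries the smooth switching weight on the atom-midpoint
    to nucleus distance; its derivative is included.
    """
    grad = np.zeros((n_atoms, 3))
    for i in range(nbf):
        for j in range(i, nbf):
            cp = P[i, j] if i == j else 2.0 * P[i, j]
            cw = W[i, j] if i == j else 2.0 * W[i, j]
            if cp == 0.0 and cw == 0.0:
                continue
            ai = func_atom[i]
            aj = func_atom[j]
            for a in range(func_start[i], func_start[i] + func_count[i]):
                aa = prim_alpha[a]
                for b in range(func_start[j], func_start[j] + func_count[j]):
                    ab = prim_alpha[b]
                    p = aa + ab
                    mu = aa * ab / p
                    rx = prim_center[a, 0] - prim_center[b, 0]
                    ry = prim_center[a, 1] - prim_center[b, 1]
                    rz = prim_center[a, 2] - prim_center[b, 2]
                    r2 = rx * rx + ry * ry + rz * rz
                    e = prim_coef[a] * prim_coef[b] * np.exp(-mu * r2)
                    s00 = e * (np.pi / p) ** 1.5
                    tfac = mu * (3.0 - 2.0 * mu * r2)
                    # d s00 / d r_a = -2 mu Rvec s00 ; d/d r_b is the negative
                    for c in range(3):
                        rv = rx if c == 0 else (ry if c == 1 else rz)
                        ds = -2.0 * mu * rv * s00
                        dt = -4.0 * mu * mu * rv * s00 + tfac * ds
                        grad[ai, c] += cp * dt - cw * ds
                        grad[aj, c] -= cp * dt - cw * ds
            # nuclear attraction with switching weight
            mx = 0.5 * (atom_pos_ang[ai, 0] + atom_pos_ang[aj, 0])
            my = 0.5 * (atom_pos_ang[ai, 1] + atom_pos_ang[aj, 1])
            mz = 0.5 * (atom_pos_ang[ai, 2] + atom_pos_ang[aj, 2])
            for n in range(n_atoms):
                dnx = mx - atom_pos_ang[n, 0]
                dny = my - atom_pos_ang[n, 1]
                dnz = mz - atom_pos_ang[n, 2]
                dist = np.sqrt(dnx * dnx + dny * dny + dnz * dnz)
                w = _switch_weight(dist, r_cl, r_cu)
                if w == 0.0:
                    continue
                vsum = 0.0
                for a in range(func_start[i], func_start[i] + func_count[i]):
                    aa = prim_alpha[a]
                    for b in range(func_start[j], func_start[j] + func_count[j]):
                        ab = prim_alpha[b]
                        p = aa + ab
                        mu = aa * ab / p
                        rx = prim_center[a, 0] - prim_center[b, 0]
                        ry = prim_center[a, 1] - prim_center[b, 1]
                        rz = prim_center[a, 2] - prim_center[b, 2]
                        r2 = rx * rx + ry * ry + rz * rz
                        e = prim_coef[a] * prim_coef[b] * np.exp(-mu * r2)
                        px = (aa * prim_center[a, 0] + ab * prim_center[b, 0]) / p \
                            - atom_xyz[n, 0]
                        py = (aa * prim_center[a, 1] + ab * prim_center[b, 1]) / p \
                            - atom_xyz[n, 1]
                        pz = (aa * prim_center[a, 2] + ab * prim_center[b, 2]) / p \
                            - atom_xyz[n, 2]
                        t2 = px * px + py * py + pz * pz
                        x = p * t2
                        f0 = f11_half_exact_erf(x)
                        f1 = f1_boys(x)
                        pref = -atom_z[n] * 2.0 * np.pi / p * e
                        vsum += pref * f0
                        for c in range(3):
                            rv = rx if c == 0 else (ry if c == 1 else rz)
                            pc = px if c == 0 else (py if c == 1 else pz)
                            grad[ai, c] += w * cp * pref * (-2.0 * mu * rv * f0
                                                            - f1 * 2.0 * aa * pc)
                            grad[aj, c] += w * cp * pref * (2.0 * mu * rv * f0
                                                            - f1 * 2.0 * ab * pc)
                            grad[n, c] += w * cp * pref * f1 * 2.0 * p * pc
                # switching-weight derivative term
                if 0.0 < w < 1.0 and dist > 0.0:
                    xsw = (dist - r_cl) / (r_cu - r_cl)
                    dwdd = (6.0 * xsw * xsw - 6.0 * xsw) / (r_cu - r_cl)
                    coef = cp * vsum * dwdd / dist / bohr_per_ang
                    for c in range(3):
                        dd = dnx if c == 0 else (dny if c == 1 else dnz)
                        grad[ai, c] += coef * 0.5 * dd
                        grad[aj, c] += coef * 0.5 * dd
                        grad[n, c] -= coef * dd
    return grad


@njit(cache=True)
def grad_two_electron(n_atoms, task_p, task_q, weights, pair_i, pair_j,
                      pp_start, pp_count, pp_O, pp_center, pp_psum,
                      pp_pa, pp_pb, prim_alpha, prim_center,
                      func_atom, P, atom_pos_ang, r_cl, r_cu, bohr_per_ang):
    """Nuclear gradient of the screened, weighted two-electron energy.

    For every canonical task the generalized density prefactor
    Gamma = sum_perms (P_pq P_rs / 2 - P_pr P_qs / 4) multiplies both the
    integral derivative (chain rule through pair factors, composite
    centers and the erf kernel) and the switching-weight derivative
    (atom-midpoint distance, evaluated in angstrom).
    """
    grad = np.zeros((n_atoms, 3))
    pi_ = np.empty(8, dtype=np.int64)
    pj_ = np.empty(8, dtype=np.int64)
    pk_ = np.empty(8, dtype=np.int64)
    pl_ = np.empty(8, dtype=np.int64)
    for t in range(task_p.shape[0]):
        tp = task_p[t]
        tq = task_q[t]
        i = pair_i[tp]
        j = pair_j[tp]
        k = pair_i[tq]
        l = pair_j[tq]
        w = weights[t]
        # Gamma over distinct permutations
        pi_[0], pj_[0], pk_[0], pl_[0] = i, j, k, l
        pi_[1], pj_[1], pk_[1], pl_[1] = j, i, k, l
        pi_[2], pj_[2], pk_[2], pl_[2] = i, j, l, k
        pi_[3], pj_[3], pk_[3], pl_[3] = j, i, l, k
        pi_[4], pj_[4], pk_[4], pl_[4] = k, l, i, j
        pi_[5], pj_[5], pk_[5], pl_[5] = l, k, i, j
        pi_[6], pj_[6], pk_[6], pl_[6] = k, l, j, i
        pi_[7], pj_[7], pk_[7], pl_[7] = l, k, j, i
        gamma = 0.0
        for m in range(8):
            dup = False
            for m2 in range(m):
                if (pi_[m] == pi_[m2] and pj_[m] == pj_[m2]
                        and pk_[m] == pk_[m2] and pl_[m] == pl_[m2]):
                    dup = True
                    break
            if dup:
                continue
            a, b, c, d = pi_[m], pj_[m], pk_[m], pl_[m]
            gamma += 0.5 * P[a, b] * P[c, d] - 0.25 * P[a, c] * P[b, d]
        if gamma == 0.0:
            continue
        # integral value and its derivative
        v = 0.0
        dv = np.zeros((4, 3))  # wrt atoms of functions i, j, k, l
        for u in range(pp_start[tp], pp_start[tp] + pp_count[tp]):
            o1 = pp_O[u]
            p1 = pp_psum[u]
            a1 = pp_pa[u]
            b1 = pp_pb[u]
            aa = prim_alpha[a1]
            ab = prim_alpha[b1]
            mu1 = aa * ab / p1
            r1x = prim_center[a1, 0] - prim_center[b1, 0]
            r1y = prim_center[a1, 1] - prim_center[b1, 1]
            r1z = prim_center[a1, 2] - prim_center[b1, 2]
            for vv in range(pp_start[tq], pp_start[tq] + pp_count[tq]):
                o2 = pp_O[vv]
                p2 = pp_psum[vv]
                c1 = pp_pa[vv]
                d1 = pp_pb[vv]
                ac = prim_alpha[c1]
                ad = prim_alpha[d1]
                mu2 = ac * ad / p2
                r2x = prim_center[c1, 0] - prim_center[d1, 0]
                r2y = prim_center[c1, 1] - prim_center[d1, 1]
                r2z = prim_center[c1, 2] - prim_center[d1, 2]
                prd = p1 * p2 / (p1 + p2)
                dx = pp_center[u, 0] - pp_center[vv, 0]
                dy = pp_center[u, 1] - pp_center[vv, 1]
                dz = pp_center[u, 2] - pp_center[vv, 2]
                x = prd * (dx * dx + dy * dy + dz * dz)
                f0 = f11_half_exact_erf(x)
                f1 = f1_boys(x)
                base = o1 * o2 * np.sqrt(prd)
                v += base * f0
                dfdx = -base * f1 * prd * 2.0
                for cdim in range(3):
                    r1 = r1x if cdim == 0 else (r1y if cdim == 1 else r1z)
                    r2v = r2x if cdim == 0 else (r2y if cdim == 1 else r2z)
                    dd = dx if cdim == 0 else (dy if cdim == 1 else dz)
                    # bra pair
                    dv[0, cdim] += -2.0 * mu1 * r1 * base * f0 \
                        + dfdx * dd * (aa / p1)
                    dv[1, cdim] += 2.0 * mu1 * r1 * base * f0 \
                        + dfdx * dd * (ab / p1)
                    # ket pair (opposite sign on the composite-center term)
                    dv[2, cdim] += -2.0 * mu2 * r2v * base * f0 \
                        - dfdx * dd * (ac / p2)
                    dv[3, cdim] += 2.0 * mu2 * r2v * base * f0 \
                        - dfdx * dd * (ad / p2)
        at0 = func_atom[i]
        at1 = func_atom[j]
        at2 = func_atom[k]
        at3 = func_atom[l]
        for cdim in range(3):
            grad[at0, cdim] += gamma * w * dv[0, cdim]
            grad[at1, cdim] += gamma * w * dv[1, cdim]
            grad[at2, cdim] += gamma * w * dv[2, cdim]
            grad[at3, cdim] += gamma * w * dv[3, cdim]
        # switching-weight derivative (distance between atom midpoints, ang)
        if w > 0.0 and w < 1.0:
            c1x = 0.5 * (atom_pos_ang[at0, 0] + atom_pos_ang[at1, 0])
            c1y = 0.5 * (atom_pos_ang[at0, 1] + atom_pos_ang[at1, 1])
            c1z = 0.5 * (atom_pos_ang[at0, 2] + atom_pos_ang[at1, 2])
            c2x = 0.5 * (atom_pos_ang[at2, 0] + atom_pos_ang[at3, 0])
            c2y = 0.5 * (atom_pos_ang[at2, 1] + atom_pos_ang[at3, 1])
            c2z = 0.5 * (atom_pos_ang[at2, 2] + atom_pos_ang[at3, 2])
            ddx = c1x - c2x
            ddy = c1y - c2y
            ddz = c1z - c2z
            dist = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if dist > 0.0:
                xsw = (dist - r_cl) / (r_cu - r_cl)
                dwdd = (6.0 * xsw * xsw - 6.0 * xsw) / (r_cu - r_cl)
                coef = gamma * v * dwdd / dist / bohr_per_ang
                for cdim in range(3):
                    dd = ddx if cdim == 0 else (ddy if cdim == 1 else ddz)
                    grad[at0, cdim] += coef * 0.5 * dd
                    grad[at1, cdim] += coef * 0.5 * dd
                    grad[at2, cdim] -= coef * 0.5 * dd
                    grad[at3, cdim] -= coef * 0.5 * dd
    return grad


@njit(cache=True)
def build_tasks(pair_idx_i, pair_idx_j, pair_rel, pair_center_ang,
                r_cl, r_cu, tau_f, d_floor_ang):
    """Canonical (p <= q) tasks over surviving density pairs.

    A task is kept when the pair-center distance is below the upper
    Coulomb cut-off and, if tau_f > 0, when rel_p*rel_q/max(d, d_floor)
    clears the final relevance threshold.  Weight is the smooth cut-off.
    """
    n = pair_idx_i.shape[0]
    # first pass: count
    total = 0
    for p in range(n):
        for q in range(p, n):
            dx = pair_center_ang[p, 0] - pair_center_ang[q, 0]
            dy = pair_center_ang[p, 1] - pair_center_ang[q, 1]
            dz = pair_center_ang[p, 2] - pair_center_ang[q, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= r_cu:
                continue
            if tau_f > 0.0:
                dd = d if d > d_floor_ang else d_floor_ang
                if pair_rel[p] * pair_rel[q] / dd < tau_f:
                    continue
            total += 1
    task_p = np.empty(total, dtype=np.int64)
    task_q = np.empty(total, dtype=np.int64)
    weight = np.empty(total)
    m = 0
    for p in range(n):
        for q in range(p, n):
            dx = pair_center_ang[p, 0] - pair_center_ang[q, 0]
            dy = pair_center_ang[p, 1] - pair_center_ang[q, 1]
            dz = pair_center_ang[p, 2] - pair_center_ang[q, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= r_cu:
                continue
            if tau_f > 0.0:
                dd = d if d > d_floor_ang else d_floor_ang
                if pair_rel[p] * pair_rel[q] / dd < tau_f:
                    continue
            task_p[m] = p
            task_q[m] = q
            if d <= r_cl:
                weight[m] = 1.0
            else:
                x = (d - r_cl) / (r_cu - r_cl)
                weight[m] = 1.0 + 2.0 * x ** 3 - 3.0 * x ** 2
            m += 1
    return task_p, task_q, weight
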