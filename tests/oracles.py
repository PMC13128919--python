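"""Independent numerical oracles used by the tests.

The ERI oracle evaluates the Coulomb interaction of two spherical
Gaussian charge clouds without ever touching an error function or
confluent hypergeometric function: the inner cloud's electrostatic
potential is built from Newton's shell theorem by radial quadrature, and
the outer integral is done with 2-D Gauss-Legendre quadrature (radius x
polar angle).  Only the elementary Gaussian product theorem is shared
with the implementation under test.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad


def _gaussian_potential_numeric(p, s_values):
    """Potential phi(s) of a unit-charge spherical Gaussian rho(r) =
    (p/pi)^(3/2) exp(-p r^2), by shell-theorem radial quadrature."""
    norm = (p / np.pi) ** 1.5
    out = np.empty_like(s_values)
    for i, s in enumerate(s_values):
        inner = quad(lambda r: 4 * np.pi * r * r * norm * np.exp(-p * r * r),
                     0.0, s, limit=200)[0]
        outer = quad(lambda r: 4 * np.pi * r * norm * np.exp(-p * r * r),
                     s, np.inf, limit=200)[0]
        out[i] = (inner / s if s > 0 else 0.0) + outer
    return out


def coulomb_two_gaussians(p, q, d, n_rad=80, n_ang=80):
    """Coulomb integral of two unit-charge spherical Gaussians with
    exponents p and q whose centers are d apart."""
    # radial Gauss-Legendre mapped to (0, rmax)
    rmax = d + 12.0 / np.sqrt(min(p, q))
    xr, wr = leggauss(n_rad)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    xc, wc = leggauss(n_ang)  # cos(theta) in [-1, 1]
    s = np.sqrt(np.maximum(r[:, None] ** 2 + d * d
                           - 2.0 * r[:, None] * d * xc[None, :], 0.0))
    phi = _gaussian_potential_numeric(q, s.ravel()).reshape(s.shape)
    rho = (p / np.pi) ** 1.5 * np.exp(-p * r * r)
    return float(np.sum((2 * np.pi * r * r * rho * wr)[:, None]
                        * phi * wc[None, :]))


def eri_primitive_quadrature(coef_a, alpha_a, ra, coef_b, alpha_b, rb,
                             coef_c, alpha_c, rc, coef_d, alpha_d, rd):
    """(g_a g_b | g_c g_d) for four s primitives via the numeric oracle."""
    ra, rb, rc, rd = (np.asarray(x, float) for x in (ra, rb, rc, rd))
    p = alpha_a + alpha_b
    q = alpha_c + alpha_d
    # Gaussian product theorem (elementary algebra, not under test)
    k1 = coef_a * coef_b * np.exp(-alpha_a * alpha_b / p
                                  * np.sum((ra - rb) ** 2))
    k2 = coef_c * coef_d * np.exp(-alpha_c * alpha_d / q
                                  * np.sum((rc - rd) ** 2))
    c1 = (alpha_a * ra + alpha_b * rb) / p
    c2 = (alpha_c * rc + alpha_d * rd) / q
    d = float(np.linalg.norm(c1 - c2))
    # unit-charge normalization factors of the two product Gaussians
    qch1 = k1 * (np.pi / p) ** 1.5
    qch2 = k2 * (np.pi / q) ** 1.5
    return qch1 * qch2 * coulomb_two_gaussians(p, q, d)


def lr_tdhf_lowest_excitation(state, eri_tensor):
    """Lowest RPA (linear-response TDHF) singlet excitation energy (Ha)
    from a converged SCF state and the dense ERI tensor in its basis."""
    C = state.C
    no = state.n_occ
    nv = C.shape[1] - no
    mo = np.einsum("pi,qj,rk,sl,pqrs->ijkl", C, C, C, C, eri_tensor,
                   optimize=True)
    eps = state.orbital_energies
    A = np.zeros((no * nv, no * nv))
    B = np.zeros_like(A)
    for i in range(no):
        for a in range(nv):
            for j in range(no):
                for b in range(nv):
                    ia, jb = i * nv + a, j * nv + b
                    A[ia, jb] = ((eps[no + a] - eps[i]) * (ia == jb)
                                 + 2 * mo[i, no + a, j, no + b]
                                 - mo[i, j, no + a, no + b])
                    B[ia, jb] = (2 * mo[i, no + a, no + b, j]
                                 - mo[i, no + b, no + a, j])
    w2 = np.linalg.eigvals((A + B) @ (A - B))
    return float(np.sqrt(np.min(np.real(w2))))
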