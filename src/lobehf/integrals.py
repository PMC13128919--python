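"""One- and two-electron integrals over displaced s-type Gaussians.

Because p orbitals are built as displaced s lobes, a single closed-form
expression covers every integral class.  A contracted ERI is a double
sum over precomputed primitive-pair records,

    (ij|kl) = sum_ab sum_cd O_ab O_cd sqrt(P) 1F1(1/2, 3/2, -P d^2),

with the pair overlap factor O, the reduced exponent
P = 1/(1/(a_a+a_b) + 1/(a_c+a_d)) and the composite-center distance d.
1F1 reduces to an error function; by default the library erf is used,
with the rational-polynomial approximation (and its erf(x>=4)=1
shortcut) available as a fast variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .basis import LobeBasis


def erf_approx(x: float) -> float:
    """Five-term rational approximation of erf on x >= 0.

    Absolute error <= 2e-7; returns exactly 1 for x >= 4, where
    1 - erf(4) ~ 1.5e-8 makes the shortcut harmless.
    """
    if x < 0:
        raise ValueError("erf_approx is defined for x >= 0")
    return _kernels.erf_approx(float(x))


def f11_half(x: float) -> float:
    """Confluent hypergeometric 1F1(1/2, 3/2, -x) for x >= 0.

    Equals sqrt(pi)*erf(sqrt(x))/(2 sqrt(x)); the x -> 0 limit is handled
    by its series expansion.
    """
    if x < 0:
        raise ValueError("f11_half is defined for x >= 0")
    return _kernels.f11_half_exact_erf(float(x))


def count_unique_eris(n_bf: int) -> int:
    """Number of permutationally unique ERIs: M(M+1)/2, M = n(n+1)/2."""
    if n_bf < 1:
        raise ValueError("n_bf must be >= 1")
    m = n_bf * (n_bf + 1) // 2
    return m * (m + 1) // 2


@dataclass
class GaussianPairRecord:
    """One primitive pair: overlap factor, composite center, exponent sum."""

    a: int
    b: int
    overlap: float
    center: np.ndarray
    alpha_sum: float


def pair_factor(coef_a, alpha_a, center_a, coef_b, alpha_b, center_b) -> GaussianPairRecord:
    """Exact pair overlap factor and composite center for two s primitives."""
    center_a = np.asarray(center_a, dtype=float)
    center_b = np.asarray(center_b, dtype=float)
    p = alpha_a + alpha_b
    mu = alpha_a * alpha_b / p
    r2 = float(np.sum((center_a - center_b) ** 2))
    o = math.sqrt(2.0) * np.pi ** 1.25 * coef_a * coef_b * p ** (-1.5) * math.exp(-mu * r2)
    center = (alpha_a * center_a + alpha_b * center_b) / p
    return GaussianPairRecord(-1, -1, o, center, p)


def eri_primitive(rec_ab: GaussianPairRecord, rec_cd: GaussianPairRecord,
                  use_fast_erf: bool = False) -> float:
    """ERI of two primitive pairs: O_ab O_cd sqrt(P) 1F1(1/2,3/2,-P d^2)."""
    p = rec_ab.alpha_sum * rec_cd.alpha_sum / (rec_ab.alpha_sum + rec_cd.alpha_sum)
    d2 = float(np.sum((rec_ab.center - rec_cd.center) ** 2))
    x = p * d2
    f = _kernels.f11_half(x) if use_fast_erf else _kernels.f11_half_exact_erf(x)
    return rec_ab.overlap * rec_cd.overlap * math.sqrt(p) * f


@dataclass
class PairTable:
    """Flattened primitive-pair records for a list of function pairs."""

    pair_i: np.ndarray
    pair_j: np.ndarray
    pp_start: np.ndarray
    pp_count: np.ndarray
    pp_O: np.ndarray
    pp_center: np.ndarray
    pp_psum: np.ndarray
    pp_pa: np.ndarray
    pp_pb: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    def index_of(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        hits = np.flatnonzero((self.pair_i == i) & (self.pair_j == j))
        if not hits.size:
            raise KeyError(f"function pair ({i},{j}) not in table")
        return int(hits[0])


PRIMITIVE_OVERLAP_FLOOR = 1e-12


def build_pair_table(basis: LobeBasis, pair_i=None, pair_j=None,
                     floor: float = PRIMITIVE_OVERLAP_FLOOR) -> PairTable:
    """Precompute pair records for the given function pairs (default: all
    i <= j), dropping primitive pairs with |O| below ``floor``."""
    n = basis.n_functions
    if pair_i is None:
        iu, ju = np.triu_indices(n)
        pair_i, pair_j = iu.astype(np.int64), ju.astype(np.int64)
    out = _kernels.build_pair_table(
        pair_i, pair_j, basis.prim_coef, basis.prim_alpha, basis.prim_center,
        basis.func_start, basis.func_count, floor)
    return PairTable(pair_i, pair_j, *out)


def eri_contracted(i: int, j: int, k: int, l: int, basis: LobeBasis,
                   table: PairTable | None = None,
                   use_fast_erf: bool = False) -> float:
    """Single contracted (ij|kl) through the pair-table double sum."""
    if table is None:
        table = build_pair_table(basis)
    p = table.index_of(i, j)
    q = table.index_of(k, l)
    vals = _kernels.eri_values(
        np.array([p], dtype=np.int64), np.array([q], dtype=np.int64),
        table.pp_start, table.pp_count, table.pp_O, table.pp_center,
        table.pp_psum, not use_fast_erf)
    return float(vals[0])


def compute_eri_values(table: PairTable, task_p, task_q,
                       use_fast_erf: bool = False) -> np.ndarray:
    """Contracted ERIs for every task (pairs of pair indices)."""
    return _kernels.eri_values(task_p, task_q, table.pp_start, table.pp_count,
                               table.pp_O, table.pp_center, table.pp_psum,
                               not use_fast_erf)


@dataclass
class OneElectronMatrices:
    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear: np.ndarray

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic + self.nuclear


def one_electron_matrices(basis: LobeBasis,
                          screening=None) -> OneElectronMatrices:
    """Overlap, kinetic and nuclear-attraction matrices (closed forms).

    When a screening configuration with an enabled Coulomb window is
    given, the nuclear attraction is smoothly switched off beyond it
    (consistently with the electron-electron and nucleus-nucleus terms,
    so distant neutral groups cancel).
    """
    z = basis.system.atomic_numbers.astype(np.float64)
    if screening is not None and screening.coulomb_enabled:
        r_cl, r_cu = screening.coulomb_lower, screening.coulomb_upper
    else:
        r_cl = r_cu = np.inf
    s, t, v = _kernels.one_electron(
        basis.n_functions, basis.prim_coef, basis.prim_alpha, basis.prim_center,
        basis.func_start, basis.func_count, basis.func_atom, z,
        basis.atom_coords_bohr, basis.system.positions, r_cl, r_cu)
    return OneElectronMatrices(s, t, v)


def eri_tensor_dense(basis: LobeBasis, use_fast_erf: bool = False) -> np.ndarray:
    """Full (n,n,n,n) ERI tensor with no screening (small systems only)."""
    n = basis.n_functions
    table = build_pair_table(basis)
    iu, ju = np.triu_indices(table.n_pairs)
    # map pair-combination list back to function indices
    vals = compute_eri_values(table, iu.astype(np.int64), ju.astype(np.int64),
                              use_fast_erf)
    out = np.zeros((n, n, n, n))
    fi, fj = table.pair_i, table.pair_j
    for t in range(len(vals)):
        i, j = fi[iu[t]], fj[iu[t]]
        k, l = fi[ju[t]], fj[ju[t]]
        v = vals[t]
        for (a, b, c, d) in {(i, j, k, l), (j, i, k, l), (i, j, l, k),
                             (j, i, l, k), (k, l, i, j), (l, k, i, j),
                             (k, l, j, i), (l, k, j, i)}:
            out[a, b, c, d] = v
    return out
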