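"""Two-tier ERI screening.

Tier 1 (density relevance): a pair of basis functions forms a one-electron
density; its importance is the integral of the absolute value of the
orbital product, evaluated analytically from the all-positive
absolute-lobe representations.  Pairs below the density threshold are
dropped, taking the ERI count from quartic to quadratic in system size.

Tier 2 (Coulomb cut-off): the interaction of two surviving densities is
kept only when the distance between their centers (atom-position
midpoints) is below the upper cut-off, with the cubic switching function
f(x) = 1 + 2x^3 - 3x^2 smoothly interpolating the weight from 1 at the
lower cut-off to 0 at the upper one.

An optional combined test drops tasks whose product of relevances divided
by the center distance falls below a final threshold; it is disabled by
default because no universal value exists for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .basis import LobeBasis
from .constants import ANGSTROM_PER_BOHR
from .integrals import PairTable, build_pair_table


@dataclass
class ScreeningConfig:
    """Cut-off parameters.  Distances are in angstrom.

    Ground-state default thresholds: density 1e-4, Coulomb window 8/10.
    Spectra use a tighter density threshold (1e-6, see
    :func:`spectra_defaults`) because weak absorption features are
    sensitive to discarded mid-range densities.
    """

    density_threshold: float = 1e-4
    coulomb_lower: float = 8.0
    coulomb_upper: float = 10.0
    final_relevance: float = 0.0      # 0 disables the combined test
    density_enabled: bool = True
    coulomb_enabled: bool = True
    d_floor: float = 0.1 * ANGSTROM_PER_BOHR  # guard for coincident centers

    def __post_init__(self):
        if self.coulomb_enabled and not 0 < self.coulomb_lower < self.coulomb_upper:
            raise ValueError("need 0 < coulomb_lower < coulomb_upper")
        if self.density_threshold < 0 or self.final_relevance < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def off(cls) -> "ScreeningConfig":
        """No screening at all (every quadruple kept at weight 1)."""
        return cls(density_threshold=0.0, density_enabled=False,
                   coulomb_enabled=False)

    @classmethod
    def spectra_defaults(cls) -> "ScreeningConfig":
        return cls(density_threshold=1e-6)


def smooth_cutoff(d: float, r_cl: float, r_cu: float) -> float:
    """Cubic switching weight: 1 below r_cl, 0 above r_cu, C1 everywhere."""
    if r_cl >= r_cu:
        raise ValueError("need r_cl < r_cu")
    if d <= r_cl:
        return 1.0
    if d >= r_cu:
        return 0.0
    x = (d - r_cl) / (r_cu - r_cl)
    return 1.0 + 2.0 * x ** 3 - 3.0 * x ** 2


def smooth_cutoff_derivative(d: float, r_cl: float, r_cu: float) -> float:
    """d/dd of the switching weight (zero at and beyond both ends)."""
    if d <= r_cl or d >= r_cu:
        return 0.0
    x = (d - r_cl) / (r_cu - r_cl)
    return (6.0 * x ** 2 - 6.0 * x) / (r_cu - r_cl)


def density_relevance(i: int, j: int, basis: LobeBasis) -> float:
    """Relevance r(rho_ij): analytic integral of the absolute product."""
    acc = 0.0
    for a in range(basis.abs_start[i], basis.abs_start[i] + basis.abs_count[i]):
        for b in range(basis.abs_start[j], basis.abs_start[j] + basis.abs_count[j]):
            term = basis.abs_coef[a] * basis.abs_coef[b]
            for c in range(3):
                aa, ab = basis.abs_alpha[a, c], basis.abs_alpha[b, c]
                p = aa + ab
                d = basis.abs_center[a, c] - basis.abs_center[b, c]
                term *= np.sqrt(np.pi / p) * np.exp(-aa * ab / p * d * d)
            acc += term
    return float(acc)


def relevance_matrix(basis: LobeBasis) -> np.ndarray:
    """All pairwise density relevances (symmetric, non-negative)."""
    return _kernels.relevance_matrix(
        basis.n_functions, basis.abs_coef, basis.abs_alpha, basis.abs_center,
        basis.abs_start, basis.abs_count)


def pair_centers_angstrom(basis: LobeBasis, pair_i, pair_j) -> np.ndarray:
    """Density centers: midpoint of the two host atoms, in angstrom."""
    pos = basis.system.positions
    ai = basis.func_atom[pair_i]
    aj = basis.func_atom[pair_j]
    return 0.5 * (pos[ai] + pos[aj])


def coulomb_distance(center1_ang, center2_ang) -> float:
    """Distance between two density centers (angstrom)."""
    return float(np.linalg.norm(np.asarray(center1_ang) - np.asarray(center2_ang)))


@dataclass
class TaskList:
    """Screened, canonically deduplicated ERI work list.

    ``pairs`` indexes surviving density pairs; each task couples two pair
    indices (p <= q) with a smoothing weight in (0, 1].
    """

    table: PairTable                  # pair records for surviving pairs
    pair_relevance: np.ndarray
    pair_center_ang: np.ndarray
    task_p: np.ndarray
    task_q: np.ndarray
    weight: np.ndarray
    config: ScreeningConfig

    @property
    def n_tasks(self) -> int:
        return len(self.task_p)

    def task_functions(self) -> np.ndarray:
        """(n_tasks, 4) array of (i, j, k, l) function indices."""
        t = self.table
        return np.stack([t.pair_i[self.task_p], t.pair_j[self.task_p],
                         t.pair_i[self.task_q], t.pair_j[self.task_q]], axis=1)


def build_task_list(basis: LobeBasis, config: ScreeningConfig | None = None) -> TaskList:
    """Screen density pairs and assemble the weighted ERI task list."""
    if config is None:
        config = ScreeningConfig()
    n = basis.n_functions
    rel = relevance_matrix(basis)
    iu, ju = np.triu_indices(n)
    keep = np.ones(len(iu), dtype=bool)
    if config.density_enabled and config.density_threshold > 0:
        keep = rel[iu, ju] >= config.density_threshold
    pair_i = iu[keep].astype(np.int64)
    pair_j = ju[keep].astype(np.int64)
    table = build_pair_table(basis, pair_i, pair_j)
    centers = pair_centers_angstrom(basis, pair_i, pair_j)
    pair_rel = rel[pair_i, pair_j]
    if config.coulomb_enabled:
        r_cl, r_cu = config.coulomb_lower, config.coulomb_upper
    else:
        r_cl = r_cu = np.inf
    task_p, task_q, weight = _kernels.build_tasks(
        pair_i, pair_j, pair_rel, centers,
        r_cl, r_cu, config.final_relevance, config.d_floor)
    return TaskList(table, pair_rel, centers, task_p, task_q, weight, config)
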