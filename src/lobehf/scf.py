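"""Restricted Hartree-Fock driven by the screened, weighted ERI task list.

The Fock matrix is assembled once per cycle from precomputed ERI values
(screening and integral evaluation happen once per geometry), the
generalized eigenproblem is solved by canonical orthogonalization with
small-overlap-eigenvalue pruning, and convergence is accelerated with
Pulay error-vector extrapolation (DIIS) plus a damping fallback.
Convergence is measured by the per-element RMSD of successive density
matrices, sqrt(sum dP^2 / n_bf^2), with a 1e-6 hartree-free threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .basis import LobeBasis, build_basis
from .constants import BOHR_PER_ANGSTROM
from .integrals import compute_eri_values, one_electron_matrices
from .screening import ScreeningConfig, TaskList, build_task_list, smooth_cutoff
from .structures import MolecularSystem


class SCFError(RuntimeError):
    pass


@dataclass
class SCFConfig:
    max_iter: int = 100
    rmsd_threshold: float = 1e-6
    diis_size: int = 8
    diis_start: int = 2
    damping: float = 0.3              # fallback mixing when DIIS is unstable
    lindep_tolerance: float = 1e-7    # overlap eigenvalue drop threshold
    use_fast_erf: bool = False

    def __post_init__(self):
        if self.rmsd_threshold <= 0 or self.max_iter < 1:
            raise ValueError("bad SCF configuration")


@dataclass
class SCFState:
    """Converged (or best-effort) restricted Hartree-Fock state."""

    basis: LobeBasis
    S: np.ndarray
    H_core: np.ndarray
    P: np.ndarray
    F: np.ndarray
    G: np.ndarray
    C: np.ndarray
    orbital_energies: np.ndarray
    E_total: float
    E_nuc: float
    n_occ: int
    converged: bool
    iterations: list = field(default_factory=list)  # (cycle, energy, rmsd)
    tasks: TaskList | None = None
    eri_values: np.ndarray | None = None

    @property
    def E_electronic(self) -> float:
        return self.E_total - self.E_nuc

    def electron_count(self) -> float:
        return float(np.trace(self.P @ self.S))


def nuclear_repulsion(system: MolecularSystem,
                      screening: ScreeningConfig | None = None) -> float:
    """Nucleus-nucleus repulsion with the same smooth Coulomb switching
    window applied to internuclear distances (in hartree)."""
    pos_ang = system.positions
    pos = pos_ang * BOHR_PER_ANGSTROM
    z = system.atomic_numbers
    e = 0.0
    n = len(z)
    for a in range(n):
        for b in range(a + 1, n):
            d_bohr = np.linalg.norm(pos[a] - pos[b])
            if d_bohr < 1e-10:
                raise SCFError(f"coincident nuclei {a} and {b}")
            w = 1.0
            if screening is not None and screening.coulomb_enabled:
                d_ang = np.linalg.norm(pos_ang[a] - pos_ang[b])
                w = smooth_cutoff(d_ang, screening.coulomb_lower,
                                  screening.coulomb_upper)
            e += w * z[a] * z[b] / d_bohr
    return float(e)


def build_fock(P: np.ndarray, H_core: np.ndarray, tasks: TaskList,
               eri_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F = H + G with G contracted from the weighted canonical task list."""
    nbf = H_core.shape[0]
    if np.iscomplexobj(P):
        g_re = _kernels.fock_twoelectron(nbf, tasks.task_p, tasks.task_q,
                                         tasks.weight, eri_values,
                                         tasks.table.pair_i, tasks.table.pair_j,
                                         np.ascontiguousarray(P.real))
        g_im = _kernels.fock_twoelectron(nbf, tasks.task_p, tasks.task_q,
                                         tasks.weight, eri_values,
                                         tasks.table.pair_i, tasks.table.pair_j,
                                         np.ascontiguousarray(P.imag))
        G = g_re + 1j * g_im
    else:
        G = _kernels.fock_twoelectron(nbf, tasks.task_p, tasks.task_q,
                                      tasks.weight, eri_values,
                                      tasks.table.pair_i, tasks.table.pair_j,
                                      np.ascontiguousarray(P))
    return H_core + G, G


def orthogonalizer(S: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Canonical orthogonalization X = U s^(-1/2), dropping eigenvalues < tol."""
    s, U = np.linalg.eigh(S)
    keep = s > tol
    return U[:, keep] / np.sqrt(s[keep])


def scf_solve(system: MolecularSystem,
              basis: LobeBasis | None = None,
              screening_cfg: ScreeningConfig | None = None,
              scf_cfg: SCFConfig | None = None) -> SCFState:
    """Converge a restricted Hartree-Fock state for an even-electron system."""
    if scf_cfg is None:
        scf_cfg = SCFConfig()
    if screening_cfg is None:
        screening_cfg = ScreeningConfig()
    n_el = system.n_electrons
    if n_el % 2:
        raise SCFError(f"{system.label or 'system'}: odd electron count {n_el}; "
                       "only closed-shell RHF is supported")
    n_occ = n_el // 2
    if basis is None:
        basis = build_basis(system)
    ints = one_electron_matrices(basis, screening_cfg)
    S, H = ints.overlap, ints.core_hamiltonian
    tasks = build_task_list(basis, screening_cfg)
    eri_vals = compute_eri_values(tasks.table, tasks.task_p, tasks.task_q,
                                  use_fast_erf=scf_cfg.use_fast_erf)
    e_nuc = nuclear_repulsion(system, screening_cfg)
    X = orthogonalizer(S, scf_cfg.lindep_tolerance)

    def diagonalize(F):
        Fo = X.T @ F @ X
        eps, Co = np.linalg.eigh(Fo)
        C = X @ Co
        occ = C[:, :n_occ]
        return eps, C, 2.0 * occ @ occ.T

    nbf = basis.n_functions
    eps, C, P = diagonalize(H)  # core-Hamiltonian guess
    log = []
    diis_F, diis_err = [], []
    converged = False
    energy = 0.0
    P_prev = P
    for cycle in range(1, scf_cfg.max_iter + 1):
        F, G = build_fock(P, H, tasks, eri_vals)
        energy = float(np.sum(P * (H + 0.5 * G))) + e_nuc
        err = F @ P @ S - S @ P @ F
        diis_F.append(F.copy())
        diis_err.append(err.copy())
        if len(diis_F) > scf_cfg.diis_size:
            diis_F.pop(0)
            diis_err.pop(0)
        if cycle >= scf_cfg.diis_start and len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = np.sum(diis_err[a] * diis_err[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                F = sum(c * Fm for c, Fm in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass  # keep plain F this cycle
        eps, C, P_new = diagonalize(F)
        rmsd = float(np.sqrt(np.sum((P_new - P) ** 2)) / nbf)
        log.append((cycle, energy, rmsd))
        if rmsd < scf_cfg.rmsd_threshold:
            P = P_new
            converged = True
            break
        if cycle < scf_cfg.diis_start:
            P = (1 - scf_cfg.damping) * P_new + scf_cfg.damping * P
        else:
            P = P_new

    F, G = build_fock(P, H, tasks, eri_vals)
    energy = float(np.sum(P * (H + 0.5 * G))) + e_nuc
    eps, C, _ = diagonalize(F)
    return SCFState(basis=basis, S=S, H_core=H, P=P, F=F, G=G, C=C,
                    orbital_energies=eps, E_total=energy, E_nuc=e_nuc,
                    n_occ=n_occ, converged=converged, iterations=log,
                    tasks=tasks, eri_values=eri_vals)
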