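"""Analytic nuclear gradients, structure optimization and microcanonical MD.

The gradient is the exact derivative of the implemented (screened,
smoothly truncated) energy: every retained integral class is
differentiated, including the chain rule through the cubic switching
function and the erf kernel, and the orbital-orthonormality (Pulay) term
enters through the energy-weighted density.  Task-list membership is
rebuilt at every new geometry; membership changes are not differentiated
— the switching function keeps the retained energy C^1, which is why the
finite-difference check is the defining contract.

Optimization is BFGS with an inverse-Hessian update and an energy-only
golden-section line search; MD is velocity Verlet (NVE) with
Maxwell-Boltzmann initial velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import (AMU_TO_AU_MASS, ANGSTROM_PER_BOHR, AU_TIME_PER_FS,
                        BOHR_PER_ANGSTROM, ELEMENT_MASS, KB_HARTREE)
from .scf import SCFConfig, SCFState, scf_solve
from .screening import ScreeningConfig, smooth_cutoff, smooth_cutoff_derivative
from .structures import MolecularSystem


@dataclass
class GradientResult:
    gradient: np.ndarray        # (n_atoms, 3), Ha/bohr
    components: dict            # per-class contributions for diagnostics

    @property
    def forces(self) -> np.ndarray:
        return -self.gradient

    @property
    def rms(self) -> float:
        """Per-component RMS over all 3N entries, Ha/bohr."""
        return float(np.sqrt(np.mean(self.gradient ** 2)))


def _energy_weighted_density(state: SCFState) -> np.ndarray:
    occ = state.C[:, : state.n_occ]
    eps = state.orbital_energies[: state.n_occ]
    return 2.0 * (occ * eps) @ occ.T


def _nuclear_repulsion_gradient(system: MolecularSystem,
                                screening: ScreeningConfig | None) -> np.ndarray:
    pos_ang = system.positions
    pos = pos_ang * BOHR_PER_ANGSTROM
    z = system.atomic_numbers
    n = len(z)
    grad = np.zeros((n, 3))
    cut = screening is not None and screening.coulomb_enabled
    for a in range(n):
        for b in range(a + 1, n):
            vec = pos[a] - pos[b]
            d = np.linalg.norm(vec)
            u = vec / d
            w, dw = 1.0, 0.0
            if cut:
                d_ang = d * ANGSTROM_PER_BOHR
                w = smooth_cutoff(d_ang, screening.coulomb_lower,
                                  screening.coulomb_upper)
                dw = smooth_cutoff_derivative(d_ang, screening.coulomb_lower,
                                              screening.coulomb_upper) \
                    * ANGSTROM_PER_BOHR
            g = z[a] * z[b] * (dw / d - w / d ** 2) * u
            grad[a] += g
            grad[b] -= g
    return grad


def gradient(state: SCFState,
             screening_cfg: ScreeningConfig | None = None) -> GradientResult:
    """Analytic nuclear gradient of the converged screened RHF energy."""
    basis = state.basis
    system = basis.system
    if screening_cfg is None and state.tasks is not None:
        screening_cfg = state.tasks.config
    W = _energy_weighted_density(state)
    if screening_cfg is not None and screening_cfg.coulomb_enabled:
        r_cl, r_cu = screening_cfg.coulomb_lower, screening_cfg.coulomb_upper
    else:
        r_cl = r_cu = np.inf
    g1 = _kernels.grad_one_electron(
        system.n_atoms, basis.n_functions, basis.prim_coef, basis.prim_alpha,
        basis.prim_center, basis.func_start, basis.func_count, basis.func_atom,
        system.atomic_numbers.astype(np.float64), basis.atom_coords_bohr,
        system.positions, r_cl, r_cu, BOHR_PER_ANGSTROM,
        np.ascontiguousarray(state.P), np.ascontiguousarray(W))
    tasks = state.tasks
    t = tasks.table
    g2 = _kernels.grad_two_electron(
        system.n_atoms, tasks.task_p, tasks.task_q, tasks.weight,
        t.pair_i, t.pair_j, t.pp_start, t.pp_count, t.pp_O, t.pp_center,
        t.pp_psum, t.pp_pa, t.pp_pb, basis.prim_alpha, basis.prim_center,
        basis.func_atom, np.ascontiguousarray(state.P), system.positions,
        r_cl, r_cu, BOHR_PER_ANGSTROM)
    gnn = _nuclear_repulsion_gradient(system, screening_cfg)
    total = g1 + g2 + gnn
    return GradientResult(total, {"one_electron": g1, "two_electron": g2,
                                  "nuclear": gnn})


def energy_and_gradient(system: MolecularSystem,
                        screening_cfg: ScreeningConfig | None = None,
                        scf_cfg: SCFConfig | None = None):
    state = scf_solve(system, screening_cfg=screening_cfg, scf_cfg=scf_cfg)
    return state, gradient(state, screening_cfg)


def finite_difference_gradient(system: MolecularSystem,
                               screening_cfg: ScreeningConfig | None = None,
                               scf_cfg: SCFConfig | None = None,
                               step_bohr: float = 1e-4) -> np.ndarray:
    """Central finite differences of the total energy (the validation
    method for the analytic gradient)."""
    pos0 = system.positions.copy()
    h_ang = step_bohr * ANGSTROM_PER_BOHR
    grad = np.zeros((system.n_atoms, 3))
    for a in range(system.n_atoms):
        for c in range(3):
            for sgn in (+1, -1):
                pos = pos0.copy()
                pos[a, c] += sgn * h_ang
                e = scf_solve(system.with_positions(pos),
                              screening_cfg=screening_cfg,
                              scf_cfg=scf_cfg).E_total
                grad[a, c] += sgn * e
            grad[a, c] /= 2.0 * step_bohr
    return grad


# ------------------------------------------------------------------ #
# BFGS with golden-section line search
# ------------------------------------------------------------------ #

@dataclass
class OptimizationStep:
    step: int
    energy: float
    rms_force: float
    positions: np.ndarray       # angstrom


@dataclass
class OptimizationLog:
    steps: list[OptimizationStep]
    system: MolecularSystem     # final geometry
    converged: bool

    @property
    def rms_history(self) -> np.ndarray:
        return np.array([s.rms_force for s in self.steps])


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, a, b, rel_tol=1e-2, max_eval=40):
    """Minimize f on [a, b]; returns (x_min, f_min).  Energy-only."""
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    evals = 2
    while (b - a) > rel_tol * max(abs(b), 1e-3) and evals < max_eval:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
        evals += 1
    return (c, fc) if fc < fd else (d, fd)


def bfgs_optimize(system: MolecularSystem,
                  screening_cfg: ScreeningConfig | None = None,
                  scf_cfg: SCFConfig | None = None,
                  max_steps: int = 30,
                  rms_threshold: float = 1e-4,
                  initial_step_bohr: float = 0.5) -> OptimizationLog:
    """BFGS structure optimization.

    The inverse Hessian starts at the identity and is updated with the
    standard BFGS formula; the step length along the search direction is
    chosen by an energy-only golden-section line search.  Terminates on
    the RMS-force threshold, a plateau, or ``max_steps``.
    """
    n = system.n_atoms
    x = system.positions.flatten() * BOHR_PER_ANGSTROM  # bohr
    Hinv = np.eye(3 * n)

    def energy_at(xv):
        sys_ = system.with_positions(xv.reshape(n, 3) * ANGSTROM_PER_BOHR)
        return scf_solve(sys_, screening_cfg=screening_cfg,
                         scf_cfg=scf_cfg).E_total

    def eval_state(xv):
        sys_ = system.with_positions(xv.reshape(n, 3) * ANGSTROM_PER_BOHR)
        state = scf_solve(sys_, screening_cfg=screening_cfg, scf_cfg=scf_cfg)
        g = gradient(state, screening_cfg).gradient.flatten()
        return state.E_total, g

    e, g = eval_state(x)
    steps = [OptimizationStep(0, e, float(np.sqrt(np.mean(g ** 2))),
                              x.reshape(n, 3) * ANGSTROM_PER_BOHR)]
    converged = False
    for it in range(1, max_steps + 1):
        direction = -Hinv @ g
        dnorm = np.linalg.norm(direction)
        if dnorm < 1e-14:
            break
        dhat = direction / dnorm
        span = min(initial_step_bohr, dnorm)

        def f_line(alpha):
            try:
                return energy_at(x + alpha * dhat)
            except Exception:  # SCF failure: reject by making the point awful
                return e + 1.0

        alpha, e_new = _golden_section(f_line, 0.0, span)
        if e_new >= e and span > 1e-4:
            alpha, e_new = _golden_section(f_line, 0.0, span * 0.1)
        if alpha <= 1e-12 or e_new >= e:
            converged = False
            break  # plateau
        x_new = x + alpha * dhat
        e_new, g_new = eval_state(x_new)
        s = x_new - x
        yvec = g_new - g
        sy = float(s @ yvec)
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(3 * n)
            Hinv = (I - rho * np.outer(s, yvec)) @ Hinv @ \
                   (I - rho * np.outer(yvec, s)) + rho * np.outer(s, s)
        x, e, g = x_new, e_new, g_new
        rms = float(np.sqrt(np.mean(g ** 2)))
        steps.append(OptimizationStep(it, e, rms,
                                      x.reshape(n, 3) * ANGSTROM_PER_BOHR))
        if rms < rms_threshold:
            converged = True
            break
    final = system.with_positions(x.reshape(n, 3) * ANGSTROM_PER_BOHR)
    return OptimizationLog(steps, final, converged)


# ------------------------------------------------------------------ #
# molecular dynamics (NVE velocity Verlet)
# ------------------------------------------------------------------ #

@dataclass
class TrajectoryFrame:
    step: int
    time_fs: float
    positions: np.ndarray       # angstrom
    velocities: np.ndarray      # bohr / a.u. time
    potential_energy: float
    kinetic_energy: float

    @property
    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy


def _masses_au(system: MolecularSystem) -> np.ndarray:
    return np.array([ELEMENT_MASS[a.element] * AMU_TO_AU_MASS
                     for a in system.atoms])


def maxwell_boltzmann_velocities(system: MolecularSystem, temperature: float,
                                 seed: int = 0) -> np.ndarray:
    """Initial velocities (bohr/a.u. time) with COM motion removed."""
    rng = np.random.default_rng(seed)
    m = _masses_au(system)
    if temperature <= 0:
        return np.zeros((system.n_atoms, 3))
    v = rng.normal(size=(system.n_atoms, 3)) \
        * np.sqrt(KB_HARTREE * temperature / m)[:, None]
    v -= np.average(v, axis=0, weights=m)
    return v


def md_run(system: MolecularSystem, dt_fs: float = 0.2, n_steps: int = 200,
           init_temperature: float = 300.0, seed: int = 0,
           screening_cfg: ScreeningConfig | None = None,
           scf_cfg: SCFConfig | None = None,
           velocities: np.ndarray | None = None) -> list[TrajectoryFrame]:
    """NVE velocity-Verlet trajectory.  Aborts (returning the partial
    trajectory) if the SCF fails mid-run."""
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    dt = dt_fs * AU_TIME_PER_FS
    m = _masses_au(system)
    x = system.positions * BOHR_PER_ANGSTROM
    if velocities is None:
        v = maxwell_boltzmann_velocities(system, init_temperature, seed)
    else:
        v = np.array(velocities, dtype=float)

    def eval_at(xb):
        sys_ = system.with_positions(xb * ANGSTROM_PER_BOHR)
        state = scf_solve(sys_, screening_cfg=screening_cfg, scf_cfg=scf_cfg)
        f = -gradient(state, screening_cfg).gradient
        return state.E_total, f

    frames = []
    try:
        epot, f = eval_at(x)
    except Exception as exc:
        raise RuntimeError(f"initial SCF failed: {exc}") from exc
    for step in range(n_steps + 1):
        ekin = 0.5 * float(np.sum(m[:, None] * v ** 2))
        frames.append(TrajectoryFrame(step, step * dt_fs,
                                      x * ANGSTROM_PER_BOHR, v.copy(),
                                      epot, ekin))
        if step == n_steps:
            break
        a = f / m[:, None]
        v_half = v + 0.5 * dt * a
        x = x + dt * v_half
        try:
            epot, f = eval_at(x)
        except Exception:
            break  # abort, return partial trajectory
        v = v_half + 0.5 * dt * (f / m[:, None])
    return frames


def energy_drift(frames: list[TrajectoryFrame]) -> float:
    """|dE_total| per atom per femtosecond over the trajectory."""
    if len(frames) < 2:
        return 0.0
    e = np.array([f.total_energy for f in frames])
    t = np.array([f.time_fs for f in frames])
    n_atoms = frames[0].positions.shape[0]
    return float(abs(e[-1] - e[0]) / max(t[-1] - t[0], 1e-12) / n_atoms)
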