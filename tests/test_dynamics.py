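"""Gradients, BFGS optimization and NVE molecular dynamics."""

import numpy as np
import pytest

from lobehf import (ScreeningConfig, SCFConfig, bfgs_optimize, energy_drift,
                    finite_difference_gradient, gradient, md_run, scf_solve)
from lobehf.constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from lobehf.dynamics import _golden_section, energy_and_gradient
from lobehf.fixtures import make_named_small, make_water_cluster
from lobehf.structures import MolecularSystem


TIGHT = SCFConfig(rmsd_threshold=1e-9)


class TestGradient:
    def test_water_matches_finite_differences(self, water):
        """The defining contract: the analytic gradient is the exact
        derivative of the implemented energy."""
        cfg = ScreeningConfig.off()
        _, g = energy_and_gradient(water, cfg, TIGHT)
        fd = finite_difference_gradient(water, cfg, TIGHT, step_bohr=1e-4)
        assert np.abs(g.gradient - fd).max() < 1e-5

    def test_cutoff_window_matches_finite_differences(self):
        """With pairs inside the smooth switching window, the cut-off
        derivative terms are required for FD agreement."""
        dimer = make_water_cluster(2, seed=3)
        cfg = ScreeningConfig(density_threshold=1e-6, coulomb_lower=1.0,
                              coulomb_upper=3.0)
        _, g = energy_and_gradient(dimer, cfg, TIGHT)
        fd = finite_difference_gradient(dimer, cfg, TIGHT, step_bohr=1e-4)
        assert np.abs(g.gradient - fd).max() < 5e-5

    def test_net_force_and_torque_zero(self, water_trimer):
        _, g = energy_and_gradient(water_trimer, ScreeningConfig(), TIGHT)
        # translation invariance is exact -> net force at machine precision
        assert np.abs(g.gradient.sum(axis=0)).max() < 1e-8
        # rotation invariance holds only up to the residual anisotropy of
        # the lab-frame displaced lobes (microhartree scale), so the net
        # torque is bounded by that same scale rather than by round-off
        pos = water_trimer.positions * BOHR_PER_ANGSTROM
        torque = np.sum(np.cross(pos, -g.gradient), axis=0)
        assert np.abs(torque).max() < 5e-5

    def test_h2_equilibrium_force_small(self):
        # optimize first, then the force at the optimum must vanish
        h2 = make_named_small("H2")
        log = bfgs_optimize(h2, ScreeningConfig.off(), TIGHT, max_steps=20,
                            rms_threshold=5e-5)
        _, g = energy_and_gradient(log.system, ScreeningConfig.off(), TIGHT)
        assert np.abs(g.gradient).max() < 1e-4


class TestGoldenSection:
    def test_quadratic_minimum(self):
        x, fx = _golden_section(lambda a: (a - 0.3) ** 2 + 1.0, 0.0, 1.0,
                                rel_tol=1e-4)
        assert x == pytest.approx(0.3, abs=1e-3)
        assert fx == pytest.approx(1.0, abs=1e-6)

    def test_monotone_function_boundary(self):
        x, _ = _golden_section(lambda a: a, 0.0, 1.0, rel_tol=1e-3)
        assert x < 0.01


class TestBFGS:
    def test_h2_bond_length_matches_reference_minimum(self):
        """Starting stretched, BFGS lands on the minimal-basis H2 bond
        length found by independently minimizing the conventional
        reference energy."""
        from scipy.optimize import minimize_scalar
        from lobehf.reference import reference_rhf

        def ref_energy(d_bohr):
            sys_ = MolecularSystem.from_arrays(
                ["H", "H"], [[0, 0, 0], [0, 0, d_bohr * ANGSTROM_PER_BOHR]])
            return reference_rhf(sys_).E_total

        ref_min = minimize_scalar(ref_energy, bounds=(1.1, 1.8),
                                  method="bounded").x
        start = MolecularSystem.from_arrays(
            ["H", "H"], [[0, 0, 0], [0, 0, 1.6 * ANGSTROM_PER_BOHR]])
        log = bfgs_optimize(start, ScreeningConfig.off(), TIGHT,
                            max_steps=25, rms_threshold=1e-5)
        d = np.linalg.norm(log.system.positions[1]
                           - log.system.positions[0]) * BOHR_PER_ANGSTROM
        assert abs(d - ref_min) * ANGSTROM_PER_BOHR < 0.01  # angstrom

    def test_rms_force_drops_an_order_of_magnitude(self):
        # stretched water relaxes; RMS force improves >= 10x before plateau
        w = make_named_small("H2O")
        stretched = w.with_positions(w.positions * 1.15)
        log = bfgs_optimize(stretched, ScreeningConfig.off(), TIGHT,
                            max_steps=20, rms_threshold=1e-7)
        hist = log.rms_history
        assert hist.min() <= hist[0] / 10.0

    def test_energy_monotone_nonincreasing(self):
        w = make_named_small("H2O")
        stretched = w.with_positions(w.positions * 1.1)
        log = bfgs_optimize(stretched, ScreeningConfig.off(), TIGHT,
                            max_steps=10)
        e = [s.energy for s in log.steps]
        assert all(b <= a + 1e-12 for a, b in zip(e, e[1:]))


class TestMD:
    def test_static_at_stationary_point(self):
        h2 = make_named_small("H2")
        log = bfgs_optimize(h2, ScreeningConfig.off(), TIGHT, max_steps=20,
                            rms_threshold=1e-6)
        frames = md_run(log.system, dt_fs=0.2, n_steps=50,
                        init_temperature=0.0,
                        screening_cfg=ScreeningConfig.off(), scf_cfg=TIGHT)
        disp = np.abs(frames[-1].positions - frames[0].positions).max()
        assert disp < 1e-5  # angstrom

    def test_diatomic_period_matches_hessian_frequency(self):
        """Small-amplitude H2 oscillation period agrees with
        omega = sqrt(k/mu) from a finite-difference Hessian."""
        from lobehf.constants import AMU_TO_AU_MASS, ELEMENT_MASS, AU_TIME_PER_FS
        h2 = make_named_small("H2")
        log = bfgs_optimize(h2, ScreeningConfig.off(), TIGHT, max_steps=25,
                            rms_threshold=1e-6)
        d0 = np.linalg.norm(log.system.positions[1] - log.system.positions[0])
        # k from central differences of the bond-stretch gradient
        h = 5e-3  # angstrom
        def axial_force(d):
            sys_ = MolecularSystem.from_arrays(
                ["H", "H"], [[0, 0, 0], [0, 0, d]])
            _, g = energy_and_gradient(sys_, ScreeningConfig.off(), TIGHT)
            return g.gradient[1, 2]
        k = (axial_force(d0 + h) - axial_force(d0 - h)) / (2 * h * BOHR_PER_ANGSTROM)
        mu = 0.5 * ELEMENT_MASS["H"] * AMU_TO_AU_MASS
        period_fs = 2 * np.pi / np.sqrt(k / mu) / AU_TIME_PER_FS
        # kick the bond slightly and time the oscillation
        start = log.system.with_positions(
            log.system.positions * (1 + np.array([[0, 0, 0], [0, 0, 0.02]])))
        frames = md_run(start, dt_fs=0.1, n_steps=120, init_temperature=0.0,
                        screening_cfg=ScreeningConfig.off(), scf_cfg=TIGHT)
        bond = np.array([np.linalg.norm(f.positions[1] - f.positions[0])
                         for f in frames])
        # the run starts at a bond-length maximum with zero velocity, so
        # the first interior maximum marks one full period
        maxima = [i for i in range(1, len(bond) - 1)
                  if bond[i] >= bond[i - 1] and bond[i] >= bond[i + 1]]
        measured = maxima[0] * 0.1
        assert measured == pytest.approx(period_fs, rel=0.05)

    def test_drift_shrinks_with_time_step(self):
        """Second-order integrator: quartering dt cuts the energy drift
        by roughly an order of magnitude."""
        w = make_named_small("H2O")
        drifts = []
        for dt in (0.4, 0.1):
            frames = md_run(w, dt_fs=dt, n_steps=int(8 / dt),
                            init_temperature=250.0, seed=5,
                            screening_cfg=ScreeningConfig.off(),
                            scf_cfg=TIGHT)
            drifts.append(energy_drift(frames))
        assert drifts[1] < drifts[0] / 5.0

    def test_com_motion_removed(self):
        from lobehf.dynamics import maxwell_boltzmann_velocities, _masses_au
        w = make_water_cluster(3, seed=0)
        v = maxwell_boltzmann_velocities(w, 300.0, seed=1)
        m = _masses_au(w)
        p = (m[:, None] * v).sum(axis=0)
        assert np.abs(p).max() < 1e-12 * np.abs(m[:, None] * v).max()
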