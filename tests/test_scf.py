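"""Restricted Hartree-Fock: exactness for s-only systems, the lobe error
budget for p systems, screening convergence, and state invariants."""

import numpy as np
import pytest

from lobehf import (ScreeningConfig, SCFConfig, build_basis, build_fock,
                    build_task_list, nuclear_repulsion, scf_solve)
from lobehf.fixtures import make_named_small, make_water_cluster
from lobehf.integrals import compute_eri_values, eri_tensor_dense
from lobehf.reference import reference_rhf
from lobehf.scf import SCFError
from lobehf.structures import MolecularSystem


class TestNuclearRepulsion:
    def test_h2_value(self, h2):
        assert nuclear_repulsion(h2) == pytest.approx(1.0 / 1.4, rel=1e-10)

    def test_beyond_upper_cutoff_zero(self):
        sys_ = MolecularSystem.from_arrays(["H", "H"],
                                           [[0, 0, 0], [12.0, 0, 0]])
        cfg = ScreeningConfig(coulomb_lower=8.0, coulomb_upper=10.0)
        assert nuclear_repulsion(sys_, cfg) == 0.0

    def test_switching_window_weight(self):
        sys_ = MolecularSystem.from_arrays(["H", "H"],
                                           [[0, 0, 0], [9.0, 0, 0]])
        cfg = ScreeningConfig(coulomb_lower=8.0, coulomb_upper=10.0)
        bare = nuclear_repulsion(sys_)
        assert nuclear_repulsion(sys_, cfg) == pytest.approx(0.5 * bare)


class TestSOnlyExactness:
    """For s-only systems the lobe path must reproduce the conventional
    Cartesian STO-3G reference to near machine precision."""

    @pytest.mark.parametrize("system_name", ["H2", "He"])
    def test_named(self, system_name):
        sys_ = make_named_small(system_name)
        state = scf_solve(sys_, screening_cfg=ScreeningConfig.off())
        ref = reference_rhf(sys_)
        assert state.E_total == pytest.approx(ref.E_total, abs=1e-8)

    def test_h4_chain(self):
        sys_ = MolecularSystem.from_arrays(
            ["H"] * 4, [[0, 0, 0], [0, 0, 0.9], [0, 0, 1.8], [0, 0, 2.7]])
        state = scf_solve(sys_, screening_cfg=ScreeningConfig.off())
        ref = reference_rhf(sys_)
        assert state.E_total == pytest.approx(ref.E_total, abs=1e-8)

    def test_h2_orbital_energies(self, h2_state, h2_reference):
        assert np.allclose(h2_state.orbital_energies,
                           h2_reference.orbital_energies, atol=1e-8)
        assert h2_state.orbital_energies[0] == pytest.approx(-0.578, abs=1e-3)


class TestLobeErrorBudget:
    def test_water_total_energy_band(self, water_state, water_reference):
        # the displaced-lobe p representation reproduces the conventional
        # STO-3G result within its fitting budget (relative deviation on
        # the scale of the few-hundredths-of-a-percent regime)
        rel = abs(water_state.E_total - water_reference.E_total) \
            / abs(water_reference.E_total)
        assert rel < 2e-4

    def test_water_orbital_rmsd_mha_scale(self, water_state, water_reference):
        rmsd = np.sqrt(np.mean((water_state.orbital_energies
                                - water_reference.orbital_energies) ** 2))
        assert rmsd < 5e-3  # a few mHa, the intrinsic lobe-expansion error


class TestFockBuild:
    def test_zero_density_gives_core_hamiltonian(self, water):
        basis = build_basis(water)
        tasks = build_task_list(basis, ScreeningConfig.off())
        vals = compute_eri_values(tasks.table, tasks.task_p, tasks.task_q)
        from lobehf import one_electron_matrices
        H = one_electron_matrices(basis).core_hamiltonian
        F, G = build_fock(np.zeros_like(H), H, tasks, vals)
        assert np.allclose(F, H) and np.allclose(G, 0.0)

    def test_task_contraction_equals_dense_tensor(self, water):
        basis = build_basis(water)
        tasks = build_task_list(basis, ScreeningConfig.off())
        vals = compute_eri_values(tasks.table, tasks.task_p, tasks.task_q)
        eri = eri_tensor_dense(basis)
        rng = np.random.default_rng(1)
        P = rng.normal(size=(7, 7))
        P = P + P.T
        H = np.zeros((7, 7))
        _, G = build_fock(P, H, tasks, vals)
        G_ref = (np.einsum("ijkl,kl->ij", eri, P)
                 - 0.5 * np.einsum("ikjl,kl->ij", eri, P))
        assert np.abs(G - G_ref).max() < 1e-11


class TestSCFState:
    def test_trace_counts_electrons(self, water_state):
        assert water_state.electron_count() == pytest.approx(10.0, abs=1e-6)

    def test_idempotency(self, water_state):
        P, S = water_state.P, water_state.S
        assert np.abs(P @ S @ P - 2 * P).max() < 1e-6

    def test_commutator_converged(self, water_state):
        F, P, S = water_state.F, water_state.P, water_state.S
        assert np.abs(F @ P @ S - S @ P @ F).max() < 1e-4

    def test_matrices_symmetric(self, water_state):
        for M in (water_state.S, water_state.H_core, water_state.P,
                  water_state.F, water_state.G):
            assert np.abs(M - M.T).max() < 1e-10

    def test_odd_electron_count_rejected(self):
        sys_ = MolecularSystem.from_arrays(["H"], [[0, 0, 0]])
        with pytest.raises(SCFError):
            scf_solve(sys_)

    def test_screened_trace_within_half_percent(self, water_trimer):
        state = scf_solve(water_trimer, screening_cfg=ScreeningConfig())
        assert state.electron_count() == pytest.approx(30.0, rel=5e-3)


class TestInvariance:
    @staticmethod
    def _rotation():
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        R2 = np.array([[1, 0, 0],
                       [0, np.cos(0.4), -np.sin(0.4)],
                       [0, np.sin(0.4), np.cos(0.4)]])
        return R @ R2

    def test_energy_invariant_under_consistent_rotation(self, water):
        """Rotating the molecule together with the p-orbital axes leaves
        the energy exactly invariant (covariance of the displaced-lobe
        construction)."""
        e0 = scf_solve(water, screening_cfg=ScreeningConfig.off()).E_total
        R = self._rotation()
        rot = water.with_positions(water.positions @ R.T + 1.7)
        basis = build_basis(rot, p_axes=R)
        e1 = scf_solve(rot, basis=basis,
                       screening_cfg=ScreeningConfig.off()).E_total
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_lab_axis_anisotropy_is_tiny(self, water):
        """With fixed lab p-axes a rotation changes the energy only at
        the scale of the residual lobe anisotropy (microhartrees)."""
        e0 = scf_solve(water, screening_cfg=ScreeningConfig.off()).E_total
        rot = water.with_positions(water.positions @ self._rotation().T)
        e1 = scf_solve(rot, screening_cfg=ScreeningConfig.off()).E_total
        assert abs(e1 - e0) < 5e-5


class TestScreeningConvergence:
    def test_screened_energy_approaches_unscreened(self, water_trimer):
        """|E(tau) - E(0)| decreases monotonically as the density
        threshold is tightened (fixed water trimer)."""
        cfgs = [ScreeningConfig(density_threshold=t, coulomb_enabled=False)
                for t in (1e-3, 1e-4, 1e-6, 1e-8)]
        e0 = scf_solve(water_trimer,
                       screening_cfg=ScreeningConfig.off()).E_total
        devs = [abs(scf_solve(water_trimer, screening_cfg=c).E_total - e0)
                for c in cfgs]
        assert devs[0] >= devs[1] >= devs[2] >= devs[3]
        assert devs[2] < 1e-4  # tight screening is already sub-0.1 mHa
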