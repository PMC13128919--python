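"""Per-atom energies and derived structure-quality scores, plus the
protein-ligand binding-energy workflow.

The atomic energy is a Mulliken-style partition of the electronic energy

    E_a = (1/Z_a) * sum_{i in a} sum_j P_ij (H_ij + G_ij/2),

where the outer sum runs over the (by default valence) basis functions
of atom a and Z_a normalizes across elements.  Summed over all functions
of all atoms without the 1/Z_a factor, the partition recovers the
electronic energy exactly.

For comparison against per-atom confidence scores (e.g. pLDDT on
[0, 100]) the raw profile is smoothed along the chain with a
Savitzky-Golay filter, scaled, shifted by a structure-specific offset and
clipped to the score range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .constants import KCALMOL_PER_HARTREE
from .dnc import cap_cut_bonds, Cluster, detect_bonds
from .scf import SCFConfig, SCFState, scf_solve
from .screening import ScreeningConfig
from .structures import MolecularSystem


@dataclass
class AtomicEnergyProfile:
    raw: np.ndarray                    # hartree (per nuclear charge)
    smoothed: np.ndarray | None = None
    score: np.ndarray | None = None    # rescaled/clipped comparison score
    window_used: int | None = None


@dataclass
class EnergyRescaleConfig:
    window: int = 150                  # rounded up to the nearest odd length
    polyorder: int = 3
    scale: float = 15.0
    offset: float = 0.0                # structure-specific shift
    clip: tuple[float, float] | None = None  # e.g. observed (min, max) pLDDT

    def odd_window(self, n_points: int) -> int:
        w = self.window if self.window % 2 else self.window + 1
        if w > n_points:               # shrink to the largest valid odd length
            w = n_points if n_points % 2 else n_points - 1
        return max(w, self.polyorder + 2 + ((self.polyorder + 2) % 2 == 0))


def atomic_energies(state: SCFState, valence_only: bool = True,
                    normalize: bool = True) -> AtomicEnergyProfile:
    """Atomic-energy partition of a converged SCF state."""
    basis = state.basis
    M = state.P * (state.H_core + 0.5 * state.G)
    per_func = M.sum(axis=1)
    n_atoms = basis.system.n_atoms
    z = basis.system.atomic_numbers.astype(float)
    raw = np.zeros(n_atoms)
    for f in range(basis.n_functions):
        if valence_only and not basis.func_valence[f]:
            continue
        raw[basis.func_atom[f]] += per_func[f]
    if normalize:
        raw /= z
    return AtomicEnergyProfile(raw)


def smooth_and_rescale(profile: AtomicEnergyProfile,
                       cfg: EnergyRescaleConfig) -> AtomicEnergyProfile:
    """Savitzky-Golay smoothing along the atom chain, affine rescale, clip."""
    raw = profile.raw
    w = cfg.odd_window(len(raw))
    if len(raw) >= cfg.polyorder + 2:
        smoothed = savgol_filter(raw, w, cfg.polyorder)
    else:
        smoothed = raw.copy()
        w = 0
    score = cfg.scale * smoothed + cfg.offset
    if cfg.clip is not None:
        score = np.clip(score, cfg.clip[0], cfg.clip[1])
    return AtomicEnergyProfile(raw, smoothed, score, w)


def auto_offset(smoothed: np.ndarray, scale: float,
                target_scores: np.ndarray) -> float:
    """Offset matching the mean of the rescaled profile to the target mean."""
    return float(np.mean(target_scores) - scale * np.mean(smoothed))


def extract_binding_site(complex_system: MolecularSystem,
                         ligand_indices, radius: float = 4.0):
    """Carve the ligand plus its environment within ``radius`` angstrom.

    Returns (complex_part, protein_part, ligand) as consistent capped
    systems; the environment is bond-repaired via the cluster capping
    rules so each part has an even electron count.
    """
    ligand_indices = sorted(set(int(i) for i in ligand_indices))
    if not ligand_indices:
        raise ValueError("empty ligand selection")
    pos = complex_system.positions
    lig_pos = pos[ligand_indices]
    d = np.linalg.norm(pos[:, None, :] - lig_pos[None, :, :], axis=2).min(axis=1)
    env = sorted(set(np.flatnonzero(d <= radius).tolist()) - set(ligand_indices))
    bonds = detect_bonds(complex_system)

    def capped(core_atoms, label):
        cl = Cluster(0, core=list(core_atoms))
        cap_cut_bonds(cl, complex_system, bonds)
        # keep only the selected atoms (plus double-bond pull-ins) and caps
        sub, _ = cl.subsystem(complex_system)
        sub.label = label
        return sub

    ligand = capped(ligand_indices, "ligand")
    if env:
        protein_part = capped(env, "site")
        complex_part = capped(ligand_indices + env, "complex")
    else:
        protein_part = None
        complex_part = ligand
    return complex_part, protein_part, ligand


def binding_energy(complex_part: MolecularSystem,
                   protein_part: MolecularSystem | None,
                   ligand: MolecularSystem,
                   screening_cfg: ScreeningConfig | None = None,
                   scf_cfg: SCFConfig | None = None) -> float:
    """E(complex) - E(site) - E(ligand) in kcal/mol."""
    e_complex = scf_solve(complex_part, screening_cfg=screening_cfg,
                          scf_cfg=scf_cfg).E_total
    e_lig = scf_solve(ligand, screening_cfg=screening_cfg,
                      scf_cfg=scf_cfg).E_total
    e_prot = 0.0
    if protein_part is not None:
        e_prot = scf_solve(protein_part, screening_cfg=screening_cfg,
                           scf_cfg=scf_cfg).E_total
    return (e_complex - e_prot - e_lig) * KCALMOL_PER_HARTREE
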