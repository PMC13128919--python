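"""Structural data model: atoms, molecular systems, density grids, spectra.

Positions on :class:`Atom`/:class:`MolecularSystem` are in angstrom (the
unit of every supported structure format); :class:`DensityGrid` lives in
bohr because it is produced by the electronic layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import ELEMENT_Z


class StructureError(ValueError):
    """Raised for malformed or physically inconsistent structural input."""


@dataclass
class Atom:
    element: str
    position: np.ndarray  # angstrom
    is_cap_hydrogen: bool = False
    source_id: int | None = None

    def __post_init__(self):
        if self.element not in ELEMENT_Z:
            raise StructureError(f"unknown element symbol {self.element!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"bad position for atom {self.element}: {self.position}")

    @property
    def atomic_number(self) -> int:
        return ELEMENT_Z[self.element]


@dataclass
class MolecularSystem:
    atoms: list[Atom]
    net_charge: int = 0
    box: np.ndarray | None = None  # optional extents, angstrom
    label: str = ""

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise StructureError("a molecular system needs at least one atom")
        if self.n_electrons < 0:
            raise StructureError("negative electron count")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.net_charge

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, pos: np.ndarray) -> "MolecularSystem":
        pos = np.asarray(pos, dtype=float).reshape(self.n_atoms, 3)
        atoms = [replace(a, position=pos[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms, self.net_charge, self.box, self.label)

    def subset(self, indices: Sequence[int], label: str = "") -> "MolecularSystem":
        atoms = [replace(self.atoms[i], source_id=i) for i in indices]
        return MolecularSystem(atoms, 0, None, label or self.label)

    @classmethod
    def from_arrays(cls, elements: Iterable[str], positions: np.ndarray,
                    net_charge: int = 0, label: str = "") -> "MolecularSystem":
        positions = np.asarray(positions, dtype=float)
        atoms = [Atom(el, positions[i]) for i, el in enumerate(elements)]
        return cls(atoms, net_charge=net_charge, label=label)


@dataclass
class DensityGrid:
    """Uniform cubic-voxel scalar field in bohr / electrons-per-bohr^3."""

    origin: np.ndarray          # bohr
    spacing: float              # bohr, isotropic
    values: np.ndarray          # shape (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise StructureError("density grid values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise StructureError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def integral(self) -> float:
        """Electron count represented by the grid (midpoint rule)."""
        return float(self.values.sum() * self.spacing ** 3)

    def axis_points(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)


@dataclass
class Spectrum:
    """Absorption spectrum: energies in eV (strictly ascending), intensities a.u."""

    energies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.energies.shape != self.intensities.shape:
            raise StructureError("spectrum energy/intensity length mismatch")
        if self.energies.size and np.any(np.diff(self.energies) <= 0):
            raise StructureError("spectrum energies must be strictly ascending")
        if self.energies.size and not (
            np.all(np.isfinite(self.energies)) and np.all(np.isfinite(self.intensities))
        ):
            raise StructureError("spectrum contains non-finite entries")
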