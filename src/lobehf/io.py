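"""Readers and writers for XYZ, PDB (ATOM/HETATM subset), Gaussian cube
and two-column spectrum text files.

All file formats use angstrom except the cube format, whose header and
atom block are in bohr by convention; the conversion happens here and
nowhere else.
"""

from __future__ import annotations

import os

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, ELEMENT_Z, Z_ELEMENT
from .structures import Atom, DensityGrid, MolecularSystem, Spectrum, StructureError


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- XYZ

def read_xyz(path, net_charge: int = 0) -> MolecularSystem:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` in angstrom)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed count line {lines[0]!r}") from None
    body = lines[2:2 + n]
    if len(body) < n:
        raise ParseError(f"{path}: count line says {n} atoms but only {len(body)} listed")
    atoms = []
    for ln, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln}: expected 'El x y z', got {line!r}")
        el = parts[0].capitalize()
        if el not in ELEMENT_Z:
            raise ParseError(f"{path}:{ln}: unknown element symbol {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}:{ln}: bad coordinate in {line!r}") from None
        atoms.append(Atom(el, np.array(xyz)))
    comment = lines[1] if len(lines) > 1 else ""
    return MolecularSystem(atoms, net_charge=net_charge, label=comment.strip())


def write_xyz(system: MolecularSystem, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment if comment is not None else system.label}\n")
        for a in system.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<2s} {x:20.12f} {y:20.12f} {z:20.12f}\n")


def append_xyz_frame(system: MolecularSystem, path, comment: str = "") -> None:
    """Append one frame to a multi-frame XYZ trajectory."""
    with open(path, "a") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for a in system.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<2s} {x:20.12f} {y:20.12f} {z:20.12f}\n")


# ---------------------------------------------------------------- PDB

def _pdb_element(line: str) -> str | None:
    # wwPDB v3.3: element right-justified in columns 77-78
    el = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if el in ELEMENT_Z:
        return el
    # fall back to the atom-name field (columns 13-16)
    name = line[12:16].strip()
    if not name:
        return None
    stripped = name.lstrip("0123456789")
    for cand in (stripped[:2].capitalize(), stripped[:1].capitalize()):
        if cand in ELEMENT_Z:
            return cand
    return None


WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}


def read_pdb(path, keep_waters: bool = True, net_charge: int = 0) -> MolecularSystem:
    """Read ATOM/HETATM records of the first model of a PDB file.

    Alternate locations are resolved to the highest occupancy (first record
    wins a tie); waters are dropped when ``keep_waters`` is false.
    """
    best: dict[tuple, tuple[float, int, str, np.ndarray]] = {}
    order = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break  # first model only
            if rec not in ("ATOM  ", "HETATM"):
                continue
            resname = line[17:20].strip()
            if not keep_waters and resname in WATER_RESNAMES:
                continue
            el = _pdb_element(line)
            if el is None:
                raise ParseError(f"{path}: cannot infer element for record {line.rstrip()!r}")
            try:
                pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError:
                raise ParseError(f"{path}: bad coordinates in {line.rstrip()!r}") from None
            try:
                occ = float(line[54:60])
            except (ValueError, IndexError):
                occ = 1.0
            # identity of the atom irrespective of altloc
            key = (line[12:16], line[17:20], line[21], line[22:27])
            if key in best and best[key][0] >= occ:
                continue
            if key in best:
                order_id = best[key][1]  # keep original ordering slot
            else:
                order_id = order
                order += 1
            best[key] = (occ, order_id, el, pos)
    if not best:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    records = sorted(best.values(), key=lambda t: t[1])
    atoms = [Atom(el, pos, source_id=i) for i, (_occ, _o, el, pos) in enumerate(records)]
    return MolecularSystem(atoms, net_charge=net_charge, label=os.path.basename(str(path)))


# ---------------------------------------------------------------- cube

def write_cube(grid: DensityGrid, system: MolecularSystem | None, path,
               comment: str = "electron density") -> None:
    """Write a Gaussian cube file (positive atom count, no orbital block).

    Grid data is already in bohr; atom positions are converted from
    angstrom here.
    """
    natom = 0 if system is None else system.n_atoms
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("values in electrons/bohr^3\n")
        ox, oy, oz = grid.origin
        fh.write(f"{natom:5d} {ox:15.8f} {oy:15.8f} {oz:15.8f}\n")
        fh.write(f"{nx:5d} {grid.spacing:15.8f} {0.0:15.8f} {0.0:15.8f}\n")
        fh.write(f"{ny:5d} {0.0:15.8f} {grid.spacing:15.8f} {0.0:15.8f}\n")
        fh.write(f"{nz:5d} {0.0:15.8f} {0.0:15.8f} {grid.spacing:15.8f}\n")
        if system is not None:
            for a in system.atoms:
                x, y, z = a.position * BOHR_PER_ANGSTROM
                fh.write(f"{a.atomic_number:5d} {float(a.atomic_number):11.6f} "
                         f"{x:15.8f} {y:15.8f} {z:15.8f}\n")
        flat = grid.values.reshape(nx * ny, nz)  # x outer, z inner
        for row in flat:
            for start in range(0, nz, 6):
                fh.write(" ".join(f"{v:13.5E}" for v in row[start:start + 6]) + "\n")


def read_cube(path) -> tuple[DensityGrid, MolecularSystem | None]:
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natom = int(parts[0])
        origin = np.array([float(p) for p in parts[1:4]])
        axes = []
        shape = []
        for _ in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            axes.append([float(p) for p in parts[1:4]])
        spacing = axes[0][0]
        atoms = []
        for _ in range(natom):
            parts = fh.readline().split()
            z = int(parts[0])
            pos = np.array([float(p) for p in parts[2:5]]) * ANGSTROM_PER_BOHR
            atoms.append(Atom(Z_ELEMENT[z], pos))
        vals = np.fromstring(fh.read(), sep=" ")
    nx, ny, nz = shape
    if vals.size != nx * ny * nz:
        raise ParseError(f"{path}: cube value count {vals.size} != {nx * ny * nz}")
    grid = DensityGrid(origin, spacing, vals.reshape(nx, ny, nz))
    system = MolecularSystem(atoms) if atoms else None
    return grid, system


# ---------------------------------------------------------------- spectrum

def write_spectrum(spec: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# energy_eV intensity_arb\n")
        for e, i in zip(spec.energies, spec.intensities):
            fh.write(f"{e:.12e} {i:.12e}\n")


def read_spectrum(path) -> Spectrum:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            e, i = line.split()[:2]
            rows.append((float(e), float(i)))
    if not rows:
        return Spectrum(np.empty(0), np.empty(0))
    data = np.array(rows)
    return Spectrum(data[:, 0], data[:, 1])
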