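"""Structure model and file-format round trips."""

import numpy as np
import pytest

from lobehf import (Atom, DensityGrid, MolecularSystem, Spectrum, read_cube,
                    read_pdb, read_spectrum, read_xyz, write_cube,
                    write_spectrum, write_xyz)
from lobehf.io import ParseError
from lobehf.structures import StructureError


class TestXYZ:
    def test_single_atom(self, tmp_path):
        p = tmp_path / "h.xyz"
        p.write_text("1\n\nH 0 0 0\n")
        s = read_xyz(p)
        assert s.n_atoms == 1 and s.atoms[0].element == "H"
        assert np.allclose(s.atoms[0].position, 0.0)

    def test_water_electron_count(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("3\nwater\nO 0 0 0\nH 0.96 0 0\nH -0.24 0.93 0\n")
        s = read_xyz(p)
        assert s.n_atoms == 3 and s.n_electrons == 10

    def test_count_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("4\n\nH 0 0 0\nH 1 0 0\nH 2 0 0\n")
        with pytest.raises(ParseError):
            read_xyz(p)

    def test_unknown_element_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXx 0 0 0\n")
        with pytest.raises(ParseError, match="3"):
            read_xyz(p)

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        s = MolecularSystem.from_arrays(
            ["O", "H", "C", "N"], rng.uniform(-5, 5, (4, 3)))
        p = tmp_path / "rt.xyz"
        write_xyz(s, p)
        s2 = read_xyz(p)
        assert s2.elements == s.elements
        assert np.allclose(s2.positions, s.positions, atol=1e-11)
        # writing the reread system reproduces the file bit-identically
        p2 = tmp_path / "rt2.xyz"
        write_xyz(s2, p2)
        assert p.read_text() == p2.read_text()


PDB_LINES = (
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
    "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  0.60  0.00           C\n"
    "ATOM      3  CA ABLA A   2       1.000   2.000   3.000  0.60  0.00           C\n"
    "ATOM      4  CA BBLA A   2       9.000   9.000   9.000  0.40  0.00           C\n"
    "HETATM    5  O   HOH A   9       0.000   0.000   0.000  1.00  0.00           O\n"
)


class TestPDB:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_LINES)
        s = read_pdb(p)
        assert s.n_atoms == 4
        assert s.atoms[1].element == "C"
        assert np.allclose(s.atoms[0].position, [11.104, 6.134, -6.504])

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_LINES)
        s = read_pdb(p)
        # altloc A (occ 0.60) beats B (occ 0.40)
        assert any(np.allclose(a.position, [1, 2, 3]) for a in s.atoms)
        assert not any(np.allclose(a.position, [9, 9, 9]) for a in s.atoms)

    def test_drop_waters(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(PDB_LINES)
        s = read_pdb(p, keep_waters=False)
        assert s.n_atoms == 3
        assert all(a.element != "O" for a in s.atoms)

    def test_no_records_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(ParseError):
            read_pdb(p)

    def test_element_from_atom_name_fallback(self, tmp_path):
        p = tmp_path / "x.pdb"
        line = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
        p.write_text(line)
        s = read_pdb(p)
        assert s.atoms[0].element == "C"


class TestCube:
    def test_roundtrip(self, tmp_path):
        grid = DensityGrid(np.array([-1.0, -2.0, -3.0]), 0.5,
                           np.ones((2, 2, 2)))
        system = MolecularSystem.from_arrays(["O"], np.zeros((1, 3)))
        p = tmp_path / "d.cube"
        write_cube(grid, system, p)
        g2, s2 = read_cube(p)
        assert np.allclose(g2.values, grid.values)
        assert np.allclose(g2.origin, grid.origin)
        assert g2.spacing == pytest.approx(0.5)
        assert s2.atoms[0].element == "O"

    def test_empty_system_header(self, tmp_path):
        grid = DensityGrid(np.zeros(3), 1.0, np.zeros((2, 3, 4)))
        p = tmp_path / "d.cube"
        write_cube(grid, None, p)
        g2, s2 = read_cube(p)
        assert s2 is None and g2.shape == (2, 3, 4)

    def test_integral_counts_electrons(self):
        # normalized Gaussian on a wide fine grid integrates to ~1
        ax = np.arange(-8, 8.01, 0.25)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        rho = (1.0 / np.pi) ** 1.5 * np.exp(-(X**2 + Y**2 + Z**2))
        grid = DensityGrid(np.array([ax[0]] * 3), 0.25, rho)
        assert grid.integral() == pytest.approx(1.0, rel=0.02)


class TestSpectrum:
    def test_roundtrip_precision(self, tmp_path):
        spec = Spectrum(np.array([1.123456789012, 2.5, 7.75]),
                        np.array([0.1, 0.9, 0.2]))
        p = tmp_path / "s.dat"
        write_spectrum(spec, p)
        s2 = read_spectrum(p)
        assert np.allclose(s2.energies, spec.energies, rtol=1e-11)
        assert np.allclose(s2.intensities, spec.intensities, rtol=1e-11)

    def test_empty_spectrum_header_only(self, tmp_path):
        p = tmp_path / "s.dat"
        write_spectrum(Spectrum(np.empty(0), np.empty(0)), p)
        text = p.read_text()
        assert text.startswith("#") and "eV" in text.split("\n")[0]
        s2 = read_spectrum(p)
        assert s2.energies.size == 0

    def test_nonascending_rejected(self):
        with pytest.raises(StructureError):
            Spectrum(np.array([2.0, 1.0]), np.array([0.0, 0.0]))


class TestModel:
    def test_element_z_consistency(self):
        with pytest.raises(StructureError):
            Atom("Qq", np.zeros(3))

    def test_negative_electron_count_rejected(self):
        with pytest.raises(StructureError):
            MolecularSystem([Atom("H", np.zeros(3))], net_charge=2)
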