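"""Physical constants and per-element tables.

Internal electronic-structure computation is in Hartree atomic units
(bohr, hartree, a.u. time); structure files and cut-off parameters use
angstrom.  The angstrom/bohr conversion is applied exactly once at the
boundary between the structural layer and the electronic layer.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988
KCALMOL_PER_HARTREE = 627.509

# time
AU_TIME_PER_FS = 41.341374575751
FS_PER_AU_TIME = 1.0 / AU_TIME_PER_FS

# Boltzmann constant, Ha/K
KB_HARTREE = 3.166811563e-6
# electron masses per unified atomic mass unit
AMU_TO_AU_MASS = 1822.888486209

ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
Z_ELEMENT = {z: sym for sym, z in ELEMENT_Z.items()}

# atomic masses (amu), isotope-averaged; enough for the MD fixtures
ELEMENT_MASS = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45,
}

# Single-bond covalent radii (angstrom), Cordero-style; used with a 1.3x
# tolerance for distance-based bond detection in cluster capping.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "P": 1.07, "S": 1.05, "Cl": 1.02,
}

# Typical X-H bond lengths (angstrom) for capping hydrogens, keyed by the
# element of the atom that keeps the bond.
CAP_XH_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34, "P": 1.42}

# Distance thresholds (angstrom) below which an X-Y bond is treated as a
# double bond during cluster capping.
DOUBLE_BOND_THRESHOLD = {
    ("C", "C"): 1.40,
    ("C", "O"): 1.28,
    ("C", "N"): 1.32,
}


def double_bond_cutoff(el1: str, el2: str):
    key = (el1, el2) if (el1, el2) in DOUBLE_BOND_THRESHOLD else (el2, el1)
    return DOUBLE_BOND_THRESHOLD.get(key)
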