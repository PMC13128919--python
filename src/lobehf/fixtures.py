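"""Deterministic synthetic structures: small molecules, water clusters and
shells, conjugated polyene chains, and capped polyglycine peptides.

Every generator is reproducible (same arguments and seed give bit-identical
coordinates) and produces an even electron count at net charge zero, so
each fixture is directly usable as a restricted-Hartree-Fock input.
"""

from __future__ import annotations

import numpy as np

from .constants import ANGSTROM_PER_BOHR
from .structures import Atom, MolecularSystem


class PackingError(RuntimeError):
    """Random placement failed to satisfy the clash constraints."""


# Rigid water geometry used by all water fixtures (TIP3P-style).
WATER_ROH = 0.9572          # angstrom
WATER_ANGLE_DEG = 104.52

_OO_MIN = 2.5               # minimum O-O separation, angstrom
_HEAVY_CLASH = 2.2          # minimum water-O to solute-heavy distance, angstrom


def _water_template() -> tuple[list[str], np.ndarray]:
    th = np.deg2rad(WATER_ANGLE_DEG) / 2
    pos = np.array([
        [0.0, 0.0, 0.0],
        [WATER_ROH * np.sin(th), 0.0, WATER_ROH * np.cos(th)],
        [-WATER_ROH * np.sin(th), 0.0, WATER_ROH * np.cos(th)],
    ])
    return ["O", "H", "H"], pos


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_named_small(name: str) -> MolecularSystem:
    """Idealized textbook geometry for a handful of standard molecules."""
    h2_bond = 1.4 * ANGSTROM_PER_BOHR
    if name == "H2":
        els, pos = ["H", "H"], np.array([[0, 0, 0], [0, 0, h2_bond]])
    elif name == "He":
        els, pos = ["He"], np.zeros((1, 3))
    elif name == "H2O":
        els, pos = _water_template()
    elif name == "CH4":
        r = 1.089 / np.sqrt(3)
        els = ["C", "H", "H", "H", "H"]
        pos = np.array([[0, 0, 0], [r, r, r], [r, -r, -r], [-r, r, -r], [-r, -r, r]])
    elif name == "NH3":
        r, ang = 1.012, np.deg2rad(106.7)
        # N apex; H's on a cone reproducing the H-N-H angle
        rho = r * np.sqrt((2 - 2 * np.cos(ang)) / 3)  # ring radius
        zh = -np.sqrt(max(r * r - rho * rho, 0.0))
        els = ["N", "H", "H", "H"]
        angles = np.deg2rad([0, 120, 240])
        pos = np.vstack([[0, 0, 0],
                         *[[rho * np.cos(a), rho * np.sin(a), zh] for a in angles]])
    elif name == "C2H4":
        rcc, rch, a = 1.339, 1.087, np.deg2rad(121.3)
        els = ["C", "C", "H", "H", "H", "H"]
        pos = np.array([
            [0, 0, 0], [rcc, 0, 0],
            [rch * np.cos(a), rch * np.sin(a), 0],
            [rch * np.cos(a), -rch * np.sin(a), 0],
            [rcc - rch * np.cos(a), rch * np.sin(a), 0],
            [rcc - rch * np.cos(a), -rch * np.sin(a), 0],
        ])
    elif name == "C6H6":
        rcc, rch = 1.39, 1.09
        rring = rcc / (2 * np.sin(np.pi / 6))
        els, pos = [], []
        for k in range(6):
            a = k * np.pi / 3
            els.append("C")
            pos.append([rring * np.cos(a), rring * np.sin(a), 0])
            els.append("H")
            pos.append([(rring + rch) * np.cos(a), (rring + rch) * np.sin(a), 0])
        pos = np.array(pos)
    else:
        raise ValueError(f"unknown named fixture {name!r}")
    return MolecularSystem.from_arrays(els, pos, label=name)


def make_water_cluster(n: int, seed: int = 0) -> MolecularSystem:
    """``n`` rigid waters randomly placed and oriented with O-O >= 2.5 angstrom."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    els_t, pos_t = _water_template()
    pos_t = pos_t - pos_t[0]  # O at local origin
    edge = max(3.2, (32.0 * n) ** (1 / 3))
    oxygens: list[np.ndarray] = []
    els: list[str] = []
    coords: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(5000):
            o = rng.uniform(0, edge, size=3)
            if all(np.linalg.norm(o - prev) >= _OO_MIN for prev in oxygens):
                break
        else:
            raise PackingError(f"placed only {i} of {n} waters without O-O clashes")
        rot = _random_rotation(rng)
        w = pos_t @ rot.T + o
        oxygens.append(o)
        els.extend(els_t)
        coords.extend(w)
    return MolecularSystem.from_arrays(els, np.array(coords), label=f"water{n}")


def make_water_shell(solute: MolecularSystem, thickness: float,
                     seed: int = 0) -> MolecularSystem:
    """Surround ``solute`` with waters whose O lies within ``thickness``
    angstrom of some solute atom, avoiding heavy-atom clashes.

    Solute atoms come first in the returned ordering.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    rng = np.random.default_rng(seed)
    els_t, pos_t = _water_template()
    pos_t = pos_t - pos_t[0]
    spos = solute.positions
    heavy = spos[[a.element != "H" for a in solute.atoms]]
    lo = spos.min(axis=0) - thickness - 1.0
    hi = spos.max(axis=0) + thickness + 1.0
    shell_vol = np.prod(hi - lo)
    target = max(1, int(shell_vol / 31.0))
    oxygens: list[np.ndarray] = []
    els = list(solute.elements)
    coords = [p for p in spos]
    for _attempt in range(300 * target):
        o = rng.uniform(lo, hi)
        dmin = np.min(np.linalg.norm(spos - o, axis=1))
        if dmin > thickness:
            continue
        if heavy.size and np.min(np.linalg.norm(heavy - o, axis=1)) < _HEAVY_CLASH:
            continue
        if oxygens and min(np.linalg.norm(o - prev) for prev in oxygens) < _OO_MIN:
            continue
        rot = _random_rotation(rng)
        w = pos_t @ rot.T + o
        oxygens.append(o)
        els.extend(els_t)
        coords.extend(w)
    return MolecularSystem.from_arrays(
        els, np.array(coords), net_charge=solute.net_charge,
        label=f"{solute.label}+shell{thickness:g}")


def make_polyene(n_units: int) -> MolecularSystem:
    """All-trans planar polyene C_{2n}H_{2n+2}, alternating 1.35/1.46 angstrom."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    r_double, r_single, rch = 1.35, 1.46, 1.09
    nc = 2 * n_units
    dirs = np.array([[np.cos(np.pi / 6), np.sin(np.pi / 6), 0],
                     [np.cos(np.pi / 6), -np.sin(np.pi / 6), 0]])
    carbons = [np.zeros(3)]
    for i in range(nc - 1):
        bond = r_double if i % 2 == 0 else r_single
        carbons.append(carbons[-1] + bond * dirs[i % 2])
    carbons = np.array(carbons)
    els, pos = [], []
    for i, c in enumerate(carbons):
        els.append("C")
        pos.append(c)
    for i, c in enumerate(carbons):
        nb = []
        if i > 0:
            nb.append(carbons[i - 1])
        if i < nc - 1:
            nb.append(carbons[i + 1])
        if len(nb) == 2:
            d = -(nb[0] - c) / np.linalg.norm(nb[0] - c) - (nb[1] - c) / np.linalg.norm(nb[1] - c)
            d /= np.linalg.norm(d)
            els.append("H")
            pos.append(c + rch * d)
        else:
            axis = (c - nb[0]) / np.linalg.norm(c - nb[0])
            perp = np.cross([0, 0, 1.0], axis)
            for sgn in (1, -1):
                d = axis * np.cos(np.pi / 3) + sgn * perp * np.sin(np.pi / 3)
                els.append("H")
                pos.append(c + rch * d)
    return MolecularSystem.from_arrays(els, np.array(pos), label=f"polyene{n_units}")


# ------------------------------------------------------------- peptide

def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: new atom bonded to c with given internal coordinates."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(phi),
                  bond * np.sin(theta) * np.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_peptide_chain(n_res: int, seed: int = 0) -> MolecularSystem:
    """Extended (phi=psi=180) polyglycine with ACE/NME caps.

    Geometry is fully deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic fixtures.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    els: list[str] = []
    pos: list[np.ndarray] = []

    def add(el, p):
        els.append(el)
        pos.append(np.asarray(p, dtype=float))
        return pos[-1]

    # ACE: CH3-C(=O)-
    cm = add("C", [0.0, 0.0, 0.0])
    cp = add("C", [1.52, 0.0, 0.0])
    virt = np.array([0.0, 1.0, 0.0])
    o = add("O", _place(virt, cm, cp, 1.231, 120.8, 0.0))
    for dih in (60.0, 180.0, 300.0):
        add("H", _place(o, cp, cm, 1.09, 109.5, dih))

    prev3 = (cm, cp, o)  # (CA-equivalent, C', O) of the previous unit
    for _res in range(n_res):
        ca_prev, c_prev, o_prev = prev3
        n = add("N", _place(o_prev, ca_prev, c_prev, 1.329, 116.2, 180.0))
        add("H", _place(o_prev, c_prev, n, 1.01, 119.5, 180.0))
        ca = add("C", _place(ca_prev, c_prev, n, 1.458, 121.7, 180.0))
        c = add("C", _place(c_prev, n, ca, 1.525, 110.4, 180.0))
        o = add("O", _place(n, ca, c, 1.231, 120.8, 0.0))
        for dih in (62.0, -62.0):
            add("H", _place(c, n, ca, 1.09, 109.5, 180.0 + dih))
        prev3 = (ca, c, o)

    ca_prev, c_prev, o_prev = prev3
    n = add("N", _place(o_prev, ca_prev, c_prev, 1.329, 116.2, 180.0))
    add("H", _place(o_prev, c_prev, n, 1.01, 119.5, 180.0))
    cm2 = add("C", _place(ca_prev, c_prev, n, 1.458, 121.7, 180.0))
    for dih in (60.0, 180.0, 300.0):
        add("H", _place(c_prev, n, cm2, 1.09, 109.5, dih))

    return MolecularSystem.from_arrays(els, np.array(pos), label=f"gly{n_res}")
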