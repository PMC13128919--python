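"""Divide-and-conquer electronic structure.

The system is partitioned into core regions (k-means clusters of atom
positions or axis-aligned grid cells).  Each core is padded with a buffer
of surrounding atoms within a fixed distance; covalent bonds cut by the
cluster boundary are repaired chemically: a cut single bond is capped by
a hydrogen placed along the bond at the typical X-H length, while a cut
double bond pulls both bonded atoms into the cluster (iterated to a
fixpoint).  Bond orders are inferred from interatomic distances.

Clusters are solved independently and sequentially by restricted
Hartree-Fock; the global density matrix is assembled from cluster
densities: an element whose two host atoms share a core is copied from
that cluster, and an element spanning two cores is a weighted mix of the
two clusters' values, the weights coming from where the segment between
the two atoms crosses the inter-cluster border (each cluster weighted by
the opposite side's normalized segment length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .basis import LobeBasis, build_basis, functions_per_element
from .constants import (BOHR_PER_ANGSTROM, CAP_XH_LENGTH, COVALENT_RADIUS,
                        double_bond_cutoff)
from .scf import SCFConfig, SCFState, scf_solve
from .screening import ScreeningConfig, relevance_matrix
from .structures import Atom, DensityGrid, MolecularSystem

BOND_TOLERANCE = 1.3


class PartitionError(RuntimeError):
    pass


@dataclass
class CapHydrogen:
    position: np.ndarray      # angstrom
    inside_atom: int          # global index of the atom keeping the bond
    outside_atom: int         # global index of the replaced atom


@dataclass
class Cluster:
    index: int
    core: list[int]
    buffer: list[int] = field(default_factory=list)
    caps: list[CapHydrogen] = field(default_factory=list)
    centroid: np.ndarray | None = None       # k-means geometry
    cell_bounds: np.ndarray | None = None    # (2,3) grid geometry
    net_charge: int = 0

    @property
    def atoms(self) -> list[int]:
        """All real (non-cap) atoms, in global-index order."""
        return sorted(set(self.core) | set(self.buffer))

    def subsystem(self, system: MolecularSystem) -> tuple[MolecularSystem, list[int]]:
        """Capped cluster system plus the local->global map of real atoms."""
        order = self.atoms
        atoms = [Atom(system.atoms[i].element, system.atoms[i].position.copy(),
                      source_id=i) for i in order]
        for cap in self.caps:
            atoms.append(Atom("H", cap.position.copy(), is_cap_hydrogen=True,
                              source_id=cap.outside_atom))
        sub = MolecularSystem(atoms, net_charge=self.net_charge,
                              label=f"cluster{self.index}")
        return sub, order


@dataclass
class Partition:
    system: MolecularSystem
    method: str               # 'kmeans' or 'grid'
    clusters: list[Cluster]
    parameters: dict = field(default_factory=dict)

    def core_assignment(self) -> np.ndarray:
        assign = np.full(self.system.n_atoms, -1, dtype=int)
        for c in self.clusters:
            for a in c.core:
                if assign[a] != -1:
                    raise PartitionError(f"atom {a} assigned to two cores")
                assign[a] = c.index
        if np.any(assign < 0):
            raise PartitionError("core sets do not cover the system")
        return assign

    def assign_point(self, point_ang: np.ndarray) -> int:
        """Cluster index owning an arbitrary point (border rule of the method)."""
        if self.method == "kmeans":
            cents = np.array([c.centroid for c in self.clusters])
            return int(np.argmin(np.linalg.norm(cents - point_ang, axis=1)))
        lo = self.parameters["grid_origin"]
        edge = self.parameters["cell_edge"]
        key = tuple(np.floor((point_ang - lo) / edge).astype(int))
        return self.parameters["cell_map"].get(key, -1)


def partition_kmeans(system: MolecularSystem, k: int, seed: int = 0) -> Partition:
    """Seeded k-means++ / Lloyd partition of the atom coordinates."""
    if not 1 <= k <= system.n_atoms:
        raise PartitionError("need 1 <= k <= n_atoms")
    pos = system.positions
    km = KMeans(n_clusters=k, n_init=1, random_state=seed, tol=1e-12,
                max_iter=1000).fit(pos)
    labels = km.labels_
    if len(set(labels)) < k:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + 1, tol=1e-12,
                    max_iter=1000).fit(pos)
        labels = km.labels_
        if len(set(labels)) < k:
            raise PartitionError("k-means produced an empty cluster twice")
    clusters = [Cluster(i, core=sorted(np.flatnonzero(labels == i).tolist()),
                        centroid=km.cluster_centers_[i]) for i in range(k)]
    return Partition(system, "kmeans", clusters, {"k": k, "seed": seed})


def partition_grid(system: MolecularSystem, cell_edge: float = 12.5) -> Partition:
    """Axis-aligned cells anchored at the bounding-box minimum.

    Atoms land in half-open cells [lo, hi): a boundary atom belongs to
    the higher cell.  Empty cells are dropped.
    """
    if cell_edge <= 0:
        raise PartitionError("cell_edge must be positive")
    pos = system.positions
    lo = pos.min(axis=0)
    idx = np.floor((pos - lo) / cell_edge).astype(int)
    cell_keys = sorted({tuple(i) for i in idx})
    cell_map = {key: n for n, key in enumerate(cell_keys)}
    clusters = []
    for key, n in cell_map.items():
        members = sorted(np.flatnonzero([tuple(i) == key for i in idx]).tolist())
        bounds = np.array([lo + np.array(key) * cell_edge,
                           lo + (np.array(key) + 1) * cell_edge])
        clusters.append(Cluster(n, core=members, cell_bounds=bounds))
    return Partition(system, "grid", clusters,
                     {"cell_edge": cell_edge, "grid_origin": lo,
                      "cell_map": cell_map})


def detect_bonds(system: MolecularSystem) -> list[tuple[int, int, float]]:
    """Distance-based bond list: pairs within 1.3x the covalent-radius sum."""
    pos = system.positions
    els = system.elements
    bonds = []
    n = system.n_atoms
    for a in range(n):
        ra = COVALENT_RADIUS.get(els[a], 0.8)
        for b in range(a + 1, n):
            d = float(np.linalg.norm(pos[a] - pos[b]))
            if d < BOND_TOLERANCE * (ra + COVALENT_RADIUS.get(els[b], 0.8)):
                bonds.append((a, b, d))
    return bonds


def _is_double_bond(el1: str, el2: str, d: float) -> bool:
    cut = double_bond_cutoff(el1, el2)
    return cut is not None and d < cut


def build_buffer(cluster: Cluster, system: MolecularSystem,
                 thickness: float = 8.0,
                 bonds: list[tuple[int, int, float]] | None = None) -> Cluster:
    """Add every atom within ``thickness`` angstrom of the core, then
    repair cut bonds (see :func:`cap_cut_bonds`)."""
    if thickness <= 0:
        raise PartitionError("buffer thickness must be positive")
    pos = system.positions
    core = np.array(cluster.core)
    d = np.linalg.norm(pos[None, :, :] - pos[core][:, None, :], axis=2)
    near = np.flatnonzero(d.min(axis=0) <= thickness)
    cluster.buffer = sorted(set(near.tolist()) - set(cluster.core))
    return cap_cut_bonds(cluster, system, bonds)


def cap_cut_bonds(cluster: Cluster, system: MolecularSystem,
                  bonds: list[tuple[int, int, float]] | None = None) -> Cluster:
    """Chemically informed boundary repair.

    Cut double bonds pull the outside atom into the cluster (iterated to
    a fixpoint); cut single bonds are capped by a hydrogen on the bond
    vector at the typical X-H distance for the inside atom's element.
    """
    if bonds is None:
        bonds = detect_bonds(system)
    els = system.elements
    pos = system.positions
    inside = set(cluster.core) | set(cluster.buffer)
    # pull in double-bond partners until stable
    changed = True
    while changed:
        changed = False
        for a, b, d in bonds:
            if (a in inside) != (b in inside) and _is_double_bond(els[a], els[b], d):
                inside.add(a if b in inside else b)
                changed = True
    cluster.buffer = sorted(inside - set(cluster.core))
    caps = []
    for a, b, d in bonds:
        if (a in inside) == (b in inside):
            continue
        keep, drop = (a, b) if a in inside else (b, a)
        length = CAP_XH_LENGTH.get(els[keep], 1.09)
        vec = pos[drop] - pos[keep]
        cap_pos = pos[keep] + vec / np.linalg.norm(vec) * length
        caps.append(CapHydrogen(cap_pos, keep, drop))
    cluster.caps = caps
    sub, _ = cluster.subsystem(system)
    if sub.n_electrons % 2:
        raise PartitionError(
            f"cluster {cluster.index} has odd electron count after capping")
    return cluster


def build_buffers(partition: Partition, thickness: float = 8.0) -> Partition:
    bonds = detect_bonds(partition.system)
    for c in partition.clusters:
        build_buffer(c, partition.system, thickness, bonds)
    return partition


@dataclass
class ClusterResult:
    cluster: Cluster
    state: SCFState | None
    atom_map: list[int]       # local real atom -> global atom
    error: str | None = None


def run_clusters(partition: Partition,
                 screening_cfg: ScreeningConfig | None = None,
                 scf_cfg: SCFConfig | None = None) -> list[ClusterResult]:
    """Independent sequential SCF per cluster (bounded peak memory).

    Failures are recorded per cluster and do not abort the run.
    """
    results = []
    for cluster in sorted(partition.clusters, key=lambda c: c.index):
        sub, atom_map = cluster.subsystem(partition.system)
        try:
            state = scf_solve(sub, screening_cfg=screening_cfg, scf_cfg=scf_cfg)
            results.append(ClusterResult(cluster, state, atom_map))
        except Exception as exc:  # noqa: BLE001 - per-cluster fault isolation
            results.append(ClusterResult(cluster, None, atom_map, str(exc)))
    return results


@dataclass
class MergedDensity:
    """Globally merged density matrix with per-atom-pair provenance."""

    P: np.ndarray
    func_offset: np.ndarray   # first global function index per atom
    provenance: dict          # (atomA, atomB) -> list of (cluster id, weight)


def _global_function_offsets(system: MolecularSystem) -> np.ndarray:
    off = np.zeros(system.n_atoms + 1, dtype=int)
    for i, el in enumerate(system.elements):
        off[i + 1] = off[i] + functions_per_element(el)
    return off


def _border_split(partition: Partition, pos_a, pos_b, ca: int, cb: int):
    """Normalized segment lengths (l_a, l_b) on either side of the border
    between clusters ca and cb along the segment a->b."""
    f0 = partition.assign_point(pos_a)
    f1 = partition.assign_point(pos_b)
    if f0 != ca or f1 != cb:
        return None  # no clean crossing; caller falls back to the mean
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if partition.assign_point(pos_a + mid * (pos_b - pos_a)) == ca:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return t, 1.0 - t


def merge_densities(partition: Partition,
                    results: list[ClusterResult]) -> MergedDensity:
    """Assemble the global density matrix from cluster densities."""
    system = partition.system
    off = _global_function_offsets(system)
    nbf = off[-1]
    P = np.zeros((nbf, nbf))
    assign = partition.core_assignment()
    by_id = {r.cluster.index: r for r in results}
    # local function offsets per cluster
    local_off = {}
    atoms_of = {}
    for r in results:
        if r.state is None:
            raise PartitionError(f"cluster {r.cluster.index} failed: {r.error}")
        loff = np.zeros(len(r.atom_map) + 1, dtype=int)
        for i, ga in enumerate(r.atom_map):
            loff[i + 1] = loff[i] + off[ga + 1] - off[ga]
        local_off[r.cluster.index] = loff
        atoms_of[r.cluster.index] = {ga: i for i, ga in enumerate(r.atom_map)}
    pos = system.positions
    provenance = {}

    def block(cid, ga, gb):
        r = by_id[cid]
        la = atoms_of[cid][ga]
        lb = atoms_of[cid][gb]
        loff = local_off[cid]
        return r.state.P[loff[la]:loff[la + 1], loff[lb]:loff[lb + 1]]

    for ga in range(system.n_atoms):
        for gb in range(ga, system.n_atoms):
            ca, cb = assign[ga], assign[gb]
            contributions = []
            if ca == cb:
                contributions = [(ca, 1.0)]
            else:
                have_a = gb in atoms_of[ca]
                have_b = ga in atoms_of[cb]
                if have_a and have_b:
                    split = _border_split(partition, pos[ga], pos[gb], ca, cb)
                    if split is None:
                        contributions = [(ca, 0.5), (cb, 0.5)]
                    else:
                        la, lb = split
                        # each cluster weighted by the *other* side's length
                        contributions = [(ca, lb), (cb, la)]
                elif have_a:
                    contributions = [(ca, 1.0)]
                elif have_b:
                    contributions = [(cb, 1.0)]
                else:
                    continue  # atoms never co-resident: element stays zero
            blk = sum(w * block(cid, ga, gb) for cid, w in contributions)
            P[off[ga]:off[ga + 1], off[gb]:off[gb + 1]] = blk
            if gb != ga:
                P[off[gb]:off[gb + 1], off[ga]:off[ga + 1]] = blk.T
            provenance[(ga, gb)] = contributions
    return MergedDensity(P, off, provenance)


def total_density_on_grid(merged: MergedDensity, basis: LobeBasis,
                          spacing: float = 1.5, margin: float = 4.0,
                          valence_only: bool = False,
                          relevance_threshold: float = 1e-4,
                          continuous_relevance: bool = False) -> DensityGrid:
    """Total electron density rho(r) = sum_ab r(a,b) P_ab phi_a phi_b on a
    uniform grid (bohr).  r(a,b) is the 0/1 relevance indicator at the
    density threshold (or the continuous relevance if requested);
    ``valence_only`` restricts both indices to valence functions.
    """
    rel = relevance_matrix(basis)
    mask = rel.copy() if continuous_relevance else (rel >= relevance_threshold).astype(float)
    if valence_only:
        vmask = basis.func_valence.astype(float)
        mask *= np.outer(vmask, vmask)
    Pm = merged.P * mask
    coords = basis.atom_coords_bohr
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    vals = np.zeros(shape)
    xs = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    # evaluate slab by slab to bound memory
    yy, zz = np.meshgrid(xs[1], xs[2], indexing="ij")
    for ix, x in enumerate(xs[0]):
        pts = np.stack([np.full(yy.size, x), yy.ravel(), zz.ravel()], axis=1)
        phi = basis.evaluate(pts)
        vals[ix] = np.sum((phi @ Pm) * phi, axis=1).reshape(shape[1], shape[2])
    return DensityGrid(lo, spacing, vals)


def dnc_atomic_energies(results: list[ClusterResult],
                        valence_only: bool = True) -> np.ndarray:
    """Per-atom energies of the full system, each taken from the cluster
    whose core owns the atom (cap hydrogens are excluded)."""
    from .properties import atomic_energies  # local import to avoid a cycle
    n_atoms = 1 + max(ga for r in results for ga in r.atom_map)
    out = np.full(n_atoms, np.nan)
    for r in results:
        if r.state is None:
            raise PartitionError(f"cluster {r.cluster.index} failed: {r.error}")
        prof = atomic_energies(r.state, valence_only=valence_only)
        core = set(r.cluster.core)
        for local, ga in enumerate(r.atom_map):
            if ga in core:
                out[ga] = prof.raw[local]
    if np.any(np.isnan(out)):
        raise PartitionError("some atoms missing from all cluster cores")
    return out
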