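"""Polymer shape and aggregation analyses.

Shape is summarised by the mass-weighted gyration tensor (its trace is
R_g^2, its sorted eigenvalue ratios quantify anisotropy); aggregation by
single-linkage clustering of chains, two chains being linked when any
inter-molecular bead pair lies within a distance cutoff under periodic
boundary conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory, minimum_image_vectors

__all__ = [
    "GyrationResult",
    "ClusterResult",
    "gyration",
    "make_whole",
    "cluster_polymers",
    "contacts_per_monomer",
]

POLYMER_SPECIES = ("PE", "PP", "PS", "POL")


@dataclass
class GyrationResult:
    r_g: float  # nm
    eigenvalues: tuple[float, float, float]  # nm^2, descending
    anisotropy_ratio: tuple[float, float, float]  # (l1/l3, l2/l3, 1)


@dataclass
class ClusterResult:
    n_clusters: int
    membership: dict[int, int]  # molecule index -> cluster id
    largest_cluster_fraction: float


def gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> GyrationResult:
    """Mass-weighted gyration tensor of one molecule or aggregate.

    The caller must make the coordinates whole across periodic boundaries
    first (see :func:`make_whole`). R_g is the square root of the tensor
    trace; eigenvalues are returned in descending order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n, 3)")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("no beads")
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    if n == 1:
        warnings.warn("single bead: gyration tensor is degenerate")
        return GyrationResult(0.0, (0.0, 0.0, 0.0), (np.nan, np.nan, 1.0))
    w = masses / masses.sum()
    com = w @ coords
    d = coords - com
    tensor = (d * w[:, None]).T @ d
    eig = np.linalg.eigvalsh(tensor)[::-1]
    eig = np.clip(eig, 0.0, None)
    r_g = float(np.sqrt(eig.sum()))
    l3 = eig[2]
    ratio = ((eig[0] / l3, eig[1] / l3, 1.0) if l3 > 0
             else (np.inf, np.inf, 1.0))
    return GyrationResult(r_g, tuple(float(e) for e in eig), ratio)


def make_whole(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a bonded chain across periodic boundaries.

    Consecutive beads are displaced by the minimum image relative to the
    previous bead, which is exact for molecules whose bonds are shorter
    than half the box. Fails when the resulting extent reaches half the
    box in any direction (the image choice is then ambiguous).
    """
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    out = coords.copy()
    for i in range(1, len(out)):
        delta = minimum_image_vectors(coords[i] - out[i - 1], box)
        out[i] = out[i - 1] + delta
    extent = out.max(axis=0) - out.min(axis=0)
    if (extent >= box / 2.0).any():
        raise ValueError(
            f"molecule extent {extent} reaches half the box {box / 2.0}; "
            "cannot disambiguate periodic images")
    return out


def _polymer_molecules(topology: Topology,
                       species: tuple[str, ...] | None = None) -> np.ndarray:
    species = species or POLYMER_SPECIES
    present = [s for s in species if s in topology.species_set]
    if not present:
        return np.array([], dtype=int)
    return topology.molecule_indices(present)


def cluster_polymers(frame: Frame, topology: Topology, cutoff: float,
                     species: tuple[str, ...] | None = None) -> ClusterResult:
    """Single-linkage clustering of polymer chains by bead proximity.

    Two chains join a cluster when any inter-molecular bead pair is
    within ``cutoff`` (minimum image); connectivity is transitive.
    Cluster ids are assigned in order of the lowest molecule index they
    contain, so labels are deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mols = _polymer_molecules(topology, species)
    if mols.size == 0:
        raise ValueError("no polymer molecules in topology")
    beads = np.concatenate([np.asarray(topology.molecules[i].bead_indices, dtype=int)
                            for i in mols])
    owner = np.concatenate([np.full(len(topology.molecules[i].bead_indices), k)
                            for k, i in enumerate(mols)])
    box = frame.box
    pts = np.mod(frame.coordinates[beads], box)
    pts[pts >= box] = 0.0
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    links = []
    if pairs.size:
        delta = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        delta -= box * np.round(delta / box)
        dist = np.linalg.norm(delta, axis=1)
        keep = (dist < cutoff) & (owner[pairs[:, 0]] != owner[pairs[:, 1]])
        links = pairs[keep]
    nm = mols.size
    if len(links):
        row = owner[np.asarray(links)[:, 0]]
        col = owner[np.asarray(links)[:, 1]]
        graph = coo_matrix((np.ones(len(row)), (row, col)), shape=(nm, nm))
    else:
        graph = coo_matrix((nm, nm))
    n_comp, labels = connected_components(graph, directed=False)
    # relabel so cluster ids follow the lowest molecule index in each cluster
    order = {}
    for k in range(nm):
        order.setdefault(labels[k], len(order))
    membership = {int(mols[k]): order[labels[k]] for k in range(nm)}
    sizes = np.bincount([order[labels[k]] for k in range(nm)], minlength=n_comp)
    return ClusterResult(
        n_clusters=int(n_comp),
        membership=membership,
        largest_cluster_fraction=float(sizes.max() / nm),
    )


def contacts_per_monomer(traj: Trajectory, cutoff: float = 0.8,
                         window: tuple[int, int | None] | None = None,
                         species: tuple[str, ...] | None = None,
                         monomers_per_bead: float = 1.0) -> float:
    """Time-averaged inter-chain contacts per monomer.

    Each bead pair of different chains within ``cutoff`` contributes one
    contact to each of its two beads, so the statistic is
    2 * pairs / (beads * monomers_per_bead). ``monomers_per_bead``
    rescales bead counts to monomer counts for coarse-grained chains
    representing several monomers per bead.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topology = traj.topology
    mols = _polymer_molecules(topology, species)
    if mols.size == 0:
        raise ValueError("no polymer molecules in topology")
    beads = np.concatenate([np.asarray(topology.molecules[i].bead_indices, dtype=int)
                            for i in mols])
    owner = np.concatenate([np.full(len(topology.molecules[i].bead_indices), k)
                            for k, i in enumerate(mols)])
    start, stop = window if window is not None else (0, None)
    frames = traj.frames[start:stop]
    if not frames:
        raise ValueError("empty analysis window")
    per_frame = []
    for frame in frames:
        box = frame.box
        pts = np.mod(frame.coordinates[beads], box)
        pts[pts >= box] = 0.0
        tree = cKDTree(pts, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        n_pairs = 0
        if pairs.size:
            delta = pts[pairs[:, 0]] - pts[pairs[:, 1]]
            delta -= box * np.round(delta / box)
            dist = np.linalg.norm(delta, axis=1)
            n_pairs = int(np.count_nonzero(
                (dist < cutoff) & (owner[pairs[:, 0]] != owner[pairs[:, 1]])))
        per_frame.append(2.0 * n_pairs / (beads.size * monomers_per_bead))
    return float(np.mean(per_frame))
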