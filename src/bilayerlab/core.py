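"""Domain model for coarse-grained bilayer trajectories.

Holds the static topology (molecules, species, head beads, acyl-chain
bonds), per-frame coordinates with orthorhombic periodic boxes, and the
geometric primitives every analysis shares: minimum-image distances,
bead selection, and leaflet assignment.

Conventions
-----------
* Units: nm, ps, kJ/mol (GROMACS convention).
* The membrane normal is the z axis; it is never auto-detected.
* Boxes are orthorhombic; triclinic input is rejected at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import LIPID_SPECIES

__all__ = [
    "MoleculeDef",
    "Topology",
    "Frame",
    "Trajectory",
    "LeafletAssignment",
    "minimum_image_distance",
    "minimum_image_vectors",
    "assign_leaflets",
    "select",
]


@dataclass(frozen=True)
class MoleculeDef:
    """One molecule: a contiguous group of beads with names."""

    name: str
    bead_indices: tuple[int, ...]
    bead_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.bead_indices) != len(self.bead_names):
            raise ValueError("bead_indices and bead_names length mismatch")


@dataclass(frozen=True)
class Topology:
    """Static description of every molecule in the system.

    Parameters
    ----------
    molecules
        Per-molecule bead membership.
    species_of_molecule
        Species label per molecule (DPPC, DLiPC, POPC, CHOL, or a polymer
        label such as PE/PP/PS).
    head_bead_of_molecule
        Global bead index of the head-group bead (phosphate bead for
        phospholipids, hydroxyl bead for cholesterol); ``None`` for
        molecules without one (polymers).
    acyl_bonds_of_molecule
        Ordered pairs of global bead indices along each acyl chain,
        per molecule; empty for species without acyl chains.
    """

    molecules: tuple[MoleculeDef, ...]
    species_of_molecule: tuple[str, ...]
    head_bead_of_molecule: tuple[int | None, ...]
    acyl_bonds_of_molecule: tuple[tuple[tuple[int, int], ...], ...]
    bead_count: int

    def __post_init__(self):
        n = len(self.molecules)
        if not (len(self.species_of_molecule) == len(self.head_bead_of_molecule)
                == len(self.acyl_bonds_of_molecule) == n):
            raise ValueError("per-molecule annotation lengths disagree")
        seen = np.zeros(self.bead_count, dtype=bool)
        for i, mol in enumerate(self.molecules):
            idx = np.asarray(mol.bead_indices, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.bead_count):
                raise ValueError(f"molecule {i}: bead index out of range")
            if seen[idx].any():
                raise ValueError(f"molecule {i}: bead belongs to two molecules")
            seen[idx] = True
            head = self.head_bead_of_molecule[i]
            if head is not None and head not in mol.bead_indices:
                raise ValueError(f"molecule {i}: head bead not in molecule")
            for a, b in self.acyl_bonds_of_molecule[i]:
                if a not in mol.bead_indices or b not in mol.bead_indices:
                    raise ValueError(
                        f"molecule {i}: acyl bond ({a},{b}) crosses molecules")
        if not seen.all():
            raise ValueError("beads not covered by any molecule")
        for i, sp in enumerate(self.species_of_molecule):
            if sp in LIPID_SPECIES and self.head_bead_of_molecule[i] is None:
                raise ValueError(f"lipid molecule {i} ({sp}) lacks a head bead")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(self.species_of_molecule)

    def molecule_indices(self, species: Iterable[str]) -> np.ndarray:
        """Indices of molecules whose species is in ``species``."""
        wanted = _validated_species(self, species)
        return np.array(
            [i for i, sp in enumerate(self.species_of_molecule) if sp in wanted],
            dtype=int,
        )

    def molecule_of_bead(self) -> np.ndarray:
        """Array mapping global bead index -> molecule index."""
        out = np.empty(self.bead_count, dtype=int)
        for i, mol in enumerate(self.molecules):
            out[list(mol.bead_indices)] = i
        return out

    def lipid_molecule_indices(self) -> np.ndarray:
        present = [s for s in LIPID_SPECIES if s in self.species_set]
        if not present:
            return np.array([], dtype=int)
        return self.molecule_indices(present)


@dataclass
class Frame:
    """Coordinates of every bead at one time, with the orthorhombic box.

    Coordinates may lie outside the box: wrapping is an operation, not an
    invariant of the type.
    """

    time: float
    coordinates: np.ndarray  # (bead_count, 3), nm
    box: np.ndarray  # (Lx, Ly, Lz), nm

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        if self.box.shape != (3,) or not (self.box > 0).all():
            raise ValueError("box must be three strictly positive edge lengths")

    @property
    def area(self) -> float:
        """In-plane area Lx*Ly, nm^2."""
        return float(self.box[0] * self.box[1])

    def wrapped(self) -> np.ndarray:
        """Coordinates folded into [0, box)."""
        return np.mod(self.coordinates, self.box)


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != self.topology.bead_count:
                raise ValueError(
                    f"frame {i}: {f.coordinates.shape[0]} beads, topology "
                    f"declares {self.topology.bead_count}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def areas(self) -> np.ndarray:
        """Per-frame in-plane area Lx*Ly, nm^2."""
        return np.array([f.area for f in self.frames])


@dataclass
class LeafletAssignment:
    """Leaflet label per molecule: 'upper', 'lower' or 'midplane'."""

    leaflet_of_molecule: tuple[str, ...]

    def molecules_in(self, leaflet: str) -> np.ndarray:
        return np.array(
            [i for i, l in enumerate(self.leaflet_of_molecule) if l == leaflet],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_vectors(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Works on any (..., 3) array of displacements for an orthorhombic box.
    """
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(p1, p2, box) -> float:
    """Smallest periodic-image Euclidean distance between two points.

    The result lies in [0, half box diagonal].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
        raise ValueError("non-finite coordinates")
    if not (box > 0).all():
        raise ValueError("box entries must be positive")
    d = minimum_image_vectors(p1 - p2, box)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# selection


def _validated_species(topology: Topology, species: Iterable[str]) -> frozenset[str]:
    wanted = frozenset(species)
    unknown = wanted - topology.species_set
    if unknown:
        raise KeyError(
            f"species {sorted(unknown)} not present in topology "
            f"(have {sorted(topology.species_set)})")
    return wanted


def select(topology: Topology, species: Iterable[str], bead_role: str = "all") -> np.ndarray:
    """Bead indices matching a species set and a bead role.

    ``bead_role`` is one of ``all`` (every bead of matching molecules),
    ``head`` (the head-group bead only) or ``acyl`` (beads that take part
    in an acyl-chain bond).
    """
    if bead_role not in ("all", "head", "acyl"):
        raise ValueError(f"unknown bead_role {bead_role!r}")
    wanted = _validated_species(topology, species)
    out: list[int] = []
    for i, sp in enumerate(topology.species_of_molecule):
        if sp not in wanted:
            continue
        if bead_role == "all":
            out.extend(topology.molecules[i].bead_indices)
        elif bead_role == "head":
            head = topology.head_bead_of_molecule[i]
            if head is not None:
                out.append(head)
        else:
            beads = {b for bond in topology.acyl_bonds_of_molecule[i] for b in bond}
            out.extend(sorted(beads))
    return np.array(sorted(set(out)), dtype=int)


# ---------------------------------------------------------------------------
# leaflets


def assign_leaflets(frame: Frame, topology: Topology) -> LeafletAssignment:
    """Assign each lipid to a leaflet by a median split of head-bead z.

    Lipids whose head bead lies at or above the median head-bead z plane
    are 'upper', the rest 'lower'; non-lipid molecules are 'midplane'.
    Cholesterol is assigned by its hydroxyl bead, so flip-flop between
    frames is possible when the assignment is recomputed per frame.

    The median split assumes a quasi-planar membrane: strongly curved or
    single-leaflet geometries still split into two groups, and the caller
    is responsible for validating the geometry.
    """
    lipids = topology.lipid_molecule_indices()
    if lipids.size == 0:
        raise ValueError("no lipid molecules in topology")
    head_z = np.array(
        [frame.coordinates[topology.head_bead_of_molecule[i], 2] for i in lipids]
    )
    median = float(np.median(head_z))
    labels = ["midplane"] * topology.n_molecules
    for mol, z in zip(lipids, head_z):
        labels[mol] = "upper" if z >= median else "lower"
    return LeafletAssignment(tuple(labels))
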