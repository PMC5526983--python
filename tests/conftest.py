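"""Shared fixtures: tiny hand-built systems and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerlab.core import Frame, MoleculeDef, Topology, Trajectory


def brute_min_image(p1, p2, box):
    """Exhaustive minimum-image distance over all 27 periodic shifts.

    Points are first folded into the box (the distance is invariant under
    lattice translations of either point), so 27 images always suffice.
    """
    p1 = np.mod(np.asarray(p1, dtype=float), box)
    p2 = np.mod(np.asarray(p2, dtype=float), box)
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * np.asarray(box)
                best = min(best, float(np.linalg.norm(
                    np.asarray(p1) - np.asarray(p2) + shift)))
    return best


def brute_pair_count(pa, pb, box, cutoff, same_set=False, owners_a=None, owners_b=None):
    """O(n^2) double loop over pairs and periodic images (strict '<')."""
    count = 0
    if same_set:
        for i in range(len(pa)):
            for j in range(i + 1, len(pa)):
                if owners_a is not None and owners_a[i] == owners_a[j]:
                    continue
                if brute_min_image(pa[i], pa[j], box) < cutoff:
                    count += 1
        return count
    for i in range(len(pa)):
        for j in range(len(pb)):
            if owners_a is not None and owners_a[i] == owners_b[j]:
                continue
            if brute_min_image(pa[i], pb[j], box) < cutoff:
                count += 1
    return count


def brute_single_linkage(bead_coords_per_mol, box, cutoff):
    """Union-find clustering over the full molecule pair matrix."""
    n = len(bead_coords_per_mol)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            linked = any(
                brute_min_image(a, b, box) < cutoff
                for a in bead_coords_per_mol[i] for b in bead_coords_per_mol[j])
            if linked:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(n)]
    remap = {}
    for lab in labels:
        remap.setdefault(lab, len(remap))
    return [remap[lab] for lab in labels]


def single_bead_lipid_topology(species, head_name="PO4"):
    """One head bead per molecule: the smallest topology the contact
    analysis accepts."""
    molecules = tuple(
        MoleculeDef(sp, (i,), ("ROH" if sp == "CHOL" else head_name,))
        for i, sp in enumerate(species))
    return Topology(
        molecules=molecules,
        species_of_molecule=tuple(species),
        head_bead_of_molecule=tuple(range(len(species))),
        acyl_bonds_of_molecule=((),) * len(species),
        bead_count=len(species),
    )


def frame_of(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(time=time, coordinates=np.asarray(coords, dtype=float),
                 box=np.asarray(box, dtype=float))


@pytest.fixture
def three_lipid_frame():
    """DLiPC at origin, DPPC 1.0 nm along x, DLiPC 1.0 nm along y."""
    topo = single_bead_lipid_topology(["DLiPC", "DPPC", "DLiPC"])
    frame = frame_of([[2.0, 2.0, 5.0], [3.0, 2.0, 5.0], [2.0, 3.0, 5.0]])
    return Trajectory(topo, [frame])


@pytest.fixture
def flat_bilayer():
    """Minimal flat bilayer: 8 DPPC heads at z=+2/-2 on a 2x2 lattice."""
    species = ["DPPC"] * 8
    topo = single_bead_lipid_topology(species)
    coords = []
    for z in (7.0, 3.0):
        for ix in range(2):
            for iy in range(2):
                coords.append([2.0 + 4.0 * ix, 2.0 + 4.0 * iy, z])
    frame = frame_of(coords, box=(8.0, 8.0, 10.0))
    return Trajectory(topo, [frame])
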