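"""Seeded generators of synthetic trajectories with known ground truth.

These stand in for coarse-grained MD data: every generator is a pure
function of its parameters and a seed, and every artifact carries the
true parameter values so the analysis modules can be validated by
parameter recovery. Lipids are geometric bead stacks on jittered
lattices — no forces or dynamics are simulated anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, KB, KJ_PER_MOL_NM2_TO_MN_PER_M
from .core import Frame, MoleculeDef, Topology, Trajectory
from .mechanics import AreaSeries, BucklingDataset, elastica_force, elastica_shape

__all__ = [
    "BilayerSpec",
    "GroundTruth",
    "gen_bilayer",
    "gen_polymer",
    "gen_area_series",
    "gen_random_walk",
    "gen_ordered_chains",
    "gen_buckled_membrane",
    "gen_buckled_bilayer",
]


@dataclass
class GroundTruth:
    """True parameter values attached to a generated artifact."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def __contains__(self, key):
        return key in self.values


@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for a two-leaflet lattice bilayer.

    The default composition is the ternary mixture studied throughout
    the contact analyses: 598 DPPC, 1598 DLiPC, 642 CHOL.
    ``lateral_arrangement`` is ``random_mixed``, ``demixed_circle`` (a
    liquid-ordered DPPC+CHOL island surrounded by the DLiPC-rich
    disordered phase) or ``demixed_stripe``. ``domain_margin`` leaves an
    empty annulus/gap of that width (nm) between the phases, so a margin
    wider than the contact cutoff guarantees zero cross-phase contacts
    by construction.
    """

    n_dppc: int = 598
    n_dlipc: int = 1598
    n_popc: int = 0
    n_chol: int = 642
    lateral_arrangement: str = "random_mixed"
    lattice_spacing: float = 0.8  # nm
    leaflet_separation: float = 4.0  # nm (head-to-head)
    beads_per_chain: int = 3
    jitter: float = 0.1  # nm, uniform lateral jitter amplitude
    domain_margin: float = 0.0  # nm
    box_edge: float | None = None  # nm; None = auto-sized
    n_frames: int = 1
    dt: float = 1000.0  # ps
    seed: int = 0

    def __post_init__(self):
        if self.n_dppc + self.n_dlipc + self.n_popc + self.n_chol <= 0:
            raise ValueError("total lipid count must be positive")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.lateral_arrangement not in ("random_mixed", "demixed_circle",
                                            "demixed_stripe"):
            raise ValueError(f"unknown arrangement {self.lateral_arrangement!r}")


LO_SPECIES = ("DPPC", "CHOL")
LD_SPECIES = ("DLiPC", "POPC")

_CHAIN_DZ = 0.3  # nm spacing of stacked chain beads
_CHAIN_DX = 0.15  # nm lateral offset of the two acyl chains


def _lipid_beads(species: str, beads_per_chain: int):
    """(bead_names, head_local_index, acyl_bond_local_pairs, z-offsets, x-offsets)."""
    if species == "CHOL":
        names = ["ROH", "R1", "R2"]
        z = [0.0, -_CHAIN_DZ, -2 * _CHAIN_DZ]
        x = [0.0, 0.0, 0.0]
        return names, 0, [], z, x
    names = ["PO4"]
    z = [0.0]
    x = [0.0]
    bonds = []
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        start = len(names)
        for k in range(beads_per_chain):
            names.append(f"C{k + 1}{chain}")
            z.append(-(k + 1) * _CHAIN_DZ)
            x.append(sign * _CHAIN_DX)
        for k in range(start, start + beads_per_chain - 1):
            bonds.append((k, k + 1))
    return names, 0, bonds, z, x


def _species_sequence(spec: BilayerSpec) -> list[str]:
    return (["DPPC"] * spec.n_dppc + ["DLiPC"] * spec.n_dlipc
            + ["POPC"] * spec.n_popc + ["CHOL"] * spec.n_chol)


def _leaflet_split(spec: BilayerSpec) -> tuple[list[str], list[str]]:
    upper, lower = [], []
    for sp, n in (("DPPC", spec.n_dppc), ("DLiPC", spec.n_dlipc),
                  ("POPC", spec.n_popc), ("CHOL", spec.n_chol)):
        upper += [sp] * (n // 2)
        lower += [sp] * (n - n // 2)
    return upper, lower


def _lattice_sites(nx: int, spacing: float) -> np.ndarray:
    ix, iy = np.meshgrid(np.arange(nx), np.arange(nx), indexing="ij")
    return np.column_stack([(ix.ravel() + 0.5) * spacing,
                            (iy.ravel() + 0.5) * spacing])


def _assign_sites(species: list[str], sites: np.ndarray, box_edge: float,
                  spec: BilayerSpec, rng: np.random.Generator):
    """Map each molecule to a lattice site; returns (site per molecule, domain label)."""
    n = len(species)
    lo_idx = [i for i, s in enumerate(species) if s in LO_SPECIES]
    ld_idx = [i for i, s in enumerate(species) if s in LD_SPECIES]
    chosen = np.full(n, -1, dtype=int)
    domain = ["Ld"] * n
    for i in lo_idx:
        domain[i] = "Lo"
    if spec.lateral_arrangement == "random_mixed":
        perm = rng.permutation(len(sites))[:n]
        chosen[:] = perm
        return chosen, domain
    center = np.array([box_edge / 2.0, box_edge / 2.0])
    if spec.lateral_arrangement == "demixed_circle":
        key = np.linalg.norm(sites - center, axis=1)
    else:  # demixed_stripe: order by x
        key = sites[:, 0]
    order = np.argsort(key, kind="stable")
    k = len(lo_idx)
    lo_sites = order[:k]
    if k:
        r_lo = key[order[k - 1]]
        rest = order[k:]
        rest = rest[key[rest] > r_lo + spec.domain_margin]
    else:
        rest = order
    if len(rest) < len(ld_idx):
        need = n + (len(order) - k - len(rest))
        req_edge = math.ceil(math.sqrt(need)) * spec.lattice_spacing
        raise ValueError(
            f"lattice cannot host {n} lipids with margin {spec.domain_margin} nm; "
            f"need a box edge of at least ~{req_edge:.1f} nm")
    lo_perm = rng.permutation(k)
    ld_perm = rng.permutation(len(ld_idx))
    for j, i in enumerate(lo_idx):
        chosen[i] = lo_sites[lo_perm[j]]
    for j, i in enumerate(ld_idx):
        chosen[i] = rest[ld_perm[j]]
    return chosen, domain


def _arrangement_feasible(species: list[str], nx: int, spec: BilayerSpec) -> bool:
    """Whether one leaflet's arrangement fits an nx*nx lattice (rng-free)."""
    n = len(species)
    if nx * nx < n:
        return False
    if spec.lateral_arrangement == "random_mixed":
        return True
    box_edge = nx * spec.lattice_spacing
    sites = _lattice_sites(nx, spec.lattice_spacing)
    center = np.array([box_edge / 2.0, box_edge / 2.0])
    k = sum(1 for s in species if s in LO_SPECIES)
    n_ld = n - k
    key = (np.linalg.norm(sites - center, axis=1)
           if spec.lateral_arrangement == "demixed_circle" else sites[:, 0])
    order = np.argsort(key, kind="stable")
    if k:
        r_lo = key[order[k - 1]]
        rest = order[k:]
        rest = rest[key[rest] > r_lo + spec.domain_margin]
    else:
        rest = order
    return len(rest) >= n_ld


def gen_bilayer(spec: BilayerSpec) -> tuple[Trajectory, GroundTruth]:
    """Two-leaflet lattice bilayer with the requested lateral arrangement.

    Lipids sit on a jittered square lattice per leaflet, head bead at the
    outer z and chain beads stacked inward. Ground truth records each
    molecule's leaflet and phase-domain label.
    """
    rng = np.random.default_rng(spec.seed)
    upper_sp, lower_sp = _leaflet_split(spec)
    n_per_leaflet = max(len(upper_sp), len(lower_sp))
    if spec.box_edge is not None:
        nx = int(spec.box_edge // spec.lattice_spacing)
        box_edge = float(spec.box_edge)
        if nx * nx < n_per_leaflet or not all(
                _arrangement_feasible(sp_list, nx, spec)
                for sp_list in (upper_sp, lower_sp)):
            req = math.ceil(math.sqrt(n_per_leaflet)) * spec.lattice_spacing
            raise ValueError(
                f"box edge {box_edge} nm hosts only {nx * nx} sites per leaflet, "
                f"{n_per_leaflet} lipids requested (plus any domain margin); "
                f"need at least ~{req:.1f} nm")
    else:
        # grow the lattice until the arrangement (incl. margin) fits
        nx = math.ceil(math.sqrt(1.2 * n_per_leaflet)) + 1
        while not all(_arrangement_feasible(sp_list, nx, spec)
                      for sp_list in (upper_sp, lower_sp)):
            nx += 1
        box_edge = nx * spec.lattice_spacing
    box_z = spec.leaflet_separation + 2 * (spec.beads_per_chain + 1) * _CHAIN_DZ + 2.0
    sites = _lattice_sites(nx, spec.lattice_spacing)

    molecules, species_all, heads, acyl, leaflet_truth, domain_truth = [], [], [], [], [], []
    coords_builders = []  # per-molecule (site_xy, z-offsets, x-offsets, outward sign)
    bead_cursor = 0
    for leaflet, sp_list, sign in (("upper", upper_sp, +1.0), ("lower", lower_sp, -1.0)):
        site_of, domain = _assign_sites(sp_list, sites, box_edge, spec, rng)
        z_head = box_z / 2.0 + sign * spec.leaflet_separation / 2.0
        for m, sp in enumerate(sp_list):
            names, head_local, bonds_local, zoff, xoff = _lipid_beads(
                sp, spec.beads_per_chain)
            nb = len(names)
            idx = tuple(range(bead_cursor, bead_cursor + nb))
            molecules.append(MoleculeDef(sp, idx, tuple(names)))
            species_all.append(sp)
            heads.append(bead_cursor + head_local)
            acyl.append(tuple((bead_cursor + a, bead_cursor + b) for a, b in bonds_local))
            leaflet_truth.append(leaflet)
            domain_truth.append(domain[m])
            coords_builders.append(
                (sites[site_of[m]], np.asarray(zoff), np.asarray(xoff), sign, z_head))
            bead_cursor += nb

    topology = Topology(
        molecules=tuple(molecules),
        species_of_molecule=tuple(species_all),
        head_bead_of_molecule=tuple(heads),
        acyl_bonds_of_molecule=tuple(acyl),
        bead_count=bead_cursor,
    )
    frames = []
    for f in range(spec.n_frames):
        coords = np.empty((bead_cursor, 3))
        cursor = 0
        for site_xy, zoff, xoff, sign, z_head in coords_builders:
            nb = len(zoff)
            jxy = rng.uniform(-spec.jitter, spec.jitter, 2) if spec.jitter > 0 else 0.0
            xy = site_xy + jxy
            coords[cursor:cursor + nb, 0] = xy[0] + xoff
            coords[cursor:cursor + nb, 1] = xy[1]
            coords[cursor:cursor + nb, 2] = z_head + sign * zoff
            cursor += nb
        frames.append(Frame(time=f * spec.dt,
                            coordinates=coords,
                            box=np.array([box_edge, box_edge, box_z])))
    truth = GroundTruth({
        "leaflet_of_molecule": tuple(leaflet_truth),
        "domain_of_molecule": tuple(domain_truth),
        "box": (box_edge, box_edge, box_z),
    })
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# polymers


def gen_polymer(n_chains: int, chain_length: int, mode: str,
                membrane: Trajectory, seed: int = 0,
                bond_length: float = 0.47, aggregate_radius: float = 2.0,
                dispersed_spacing: float = 4.0, chain_extent: float = 1.2,
                species: str = "PE",
                max_retries: int = 2000) -> tuple[Trajectory, GroundTruth]:
    """Place random-walk polymer chains in the membrane midplane.

    ``aggregated`` mode confines every chain to a sphere of
    ``aggregate_radius`` around the box center and anchors all chain
    starts within half a contact cutoff of each other, so the chains form
    one single-linkage cluster by construction. ``dispersed`` mode pins
    each chain to its own lattice site (period ``dispersed_spacing``) and
    confines it to a ball of radius ``chain_extent`` around that site, so
    chains stay at least ``dispersed_spacing - 2*chain_extent`` apart.
    """
    if mode not in ("aggregated", "dispersed"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_chains < 1 or chain_length < 1:
        raise ValueError("need at least one chain of at least one bead")
    rng = np.random.default_rng(seed)
    topo = membrane.topology
    frame0 = membrane.frames[0]
    box = frame0.box
    z_mid = box[2] / 2.0
    center = np.array([box[0] / 2.0, box[1] / 2.0, z_mid])

    if mode == "aggregated":
        ring_r = 0.3
        starts = [center + np.array([ring_r * math.cos(2 * math.pi * k / n_chains),
                                     ring_r * math.sin(2 * math.pi * k / n_chains), 0.0])
                  for k in range(n_chains)]
        anchors = [center] * n_chains
        radius = aggregate_radius
    else:
        nxs = max(1, int(box[0] // dispersed_spacing))
        nys = max(1, int(box[1] // dispersed_spacing))
        if nxs * nys < n_chains:
            raise ValueError(
                f"box {box[0]:.1f}x{box[1]:.1f} nm hosts {nxs * nys} dispersed sites "
                f"at spacing {dispersed_spacing} nm; {n_chains} chains requested")
        sx, sy = box[0] / nxs, box[1] / nys
        starts, anchors = [], []
        for k in range(n_chains):
            p = np.array([(k % nxs + 0.5) * sx, (k // nxs + 0.5) * sy, z_mid])
            starts.append(p)
            anchors.append(p)
        radius = chain_extent

    chains = []
    for k in range(n_chains):
        pts = [starts[k]]
        for _ in range(chain_length - 1):
            for attempt in range(max_retries + 1):
                v = rng.normal(size=3)
                v[2] *= 0.3  # stay near the midplane
                v *= bond_length / np.linalg.norm(v)
                cand = pts[-1] + v
                if (np.linalg.norm(cand - anchors[k]) <= radius
                        and abs(cand[2] - z_mid) <= 1.0):
                    pts.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"chain {k}: placement failed after {max_retries} retries")
        chains.append(np.array(pts))

    molecules = list(topo.molecules)
    species_all = list(topo.species_of_molecule)
    heads = list(topo.head_bead_of_molecule)
    acyl = list(topo.acyl_bonds_of_molecule)
    cursor = topo.bead_count
    cluster_truth = dict()
    first_poly_mol = len(molecules)
    for k, pts in enumerate(chains):
        idx = tuple(range(cursor, cursor + len(pts)))
        names = tuple(f"C{j + 1}" for j in range(len(pts)))
        molecules.append(MoleculeDef(species, idx, names))
        species_all.append(species)
        heads.append(None)
        acyl.append(())
        cluster_truth[first_poly_mol + k] = 0 if mode == "aggregated" else k
        cursor += len(pts)
    new_topo = Topology(tuple(molecules), tuple(species_all), tuple(heads),
                        tuple(acyl), cursor)
    poly_coords = np.concatenate(chains)
    frames = [Frame(time=f.time,
                    coordinates=np.concatenate([f.coordinates, poly_coords]),
                    box=f.box.copy())
              for f in membrane.frames]
    truth = GroundTruth({"cluster_of_molecule": cluster_truth, "mode": mode})
    return Trajectory(new_topo, frames), truth


# ---------------------------------------------------------------------------
# scalar-series generators


def gen_area_series(A0: float, K_A: float, T: float = DEFAULT_TEMPERATURE,
                    n_frames: int = 10000, seed: int = 0,
                    dt: float = 100.0) -> tuple[AreaSeries, GroundTruth]:
    """I.i.d. Gaussian area series with the variance implied by K_A.

    ``K_A`` is in mN/m; the variance is k_B T A0 / K_A with K_A converted
    to kJ/mol/nm^2, the inverse of the fluctuation estimator.
    """
    if A0 <= 0 or K_A <= 0 or T <= 0 or n_frames < 2:
        raise ValueError("A0, K_A, T must be positive and n_frames >= 2")
    rng = np.random.default_rng(seed)
    ka_internal = K_A / KJ_PER_MOL_NM2_TO_MN_PER_M  # kJ/mol/nm^2
    var = KB * T * A0 / ka_internal
    areas = rng.normal(A0, math.sqrt(var), n_frames)
    times = np.arange(n_frames) * dt
    truth = GroundTruth({"K_A": K_A, "A0": A0, "T": T, "variance": var})
    return AreaSeries(times=times, areas=areas), truth


def gen_random_walk(n_particles: int, D: float, dt: float, n_frames: int,
                    box, seed: int = 0) -> tuple[Trajectory, GroundTruth]:
    """2D Gaussian random walk at fixed z, wrapped into the box.

    Per-step displacement has variance 2*D*dt in each lateral dimension.
    Ground truth stores the unwrapped tracks, shape (n_frames, n, 2).
    """
    if n_particles < 1 or D < 0 or dt <= 0 or n_frames < 1:
        raise ValueError("invalid walk parameters")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, 1.0, (n_particles, 2)) * box[:2]
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), (n_frames - 1, n_particles, 2)) \
        if n_frames > 1 else np.zeros((0, n_particles, 2))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    z = np.full(n_particles, box[2] / 2.0)
    molecules = tuple(MoleculeDef("TRACER", (i,), ("T1",)) for i in range(n_particles))
    topo = Topology(molecules, ("TRACER",) * n_particles, (None,) * n_particles,
                    ((),) * n_particles, n_particles)
    frames = []
    for f in range(n_frames):
        xy = np.mod(unwrapped[f], box[:2])
        coords = np.column_stack([xy, z])
        frames.append(Frame(time=f * dt, coordinates=coords, box=box.copy()))
    truth = GroundTruth({"D": D, "unwrapped": unwrapped, "dt": dt})
    return Trajectory(topo, frames), truth


def _p2_expectation(a: float) -> float:
    """E[(3u^2-1)/2] for u ~ exp(a u^2) on [-1, 1]."""
    num = quad(lambda u: (1.5 * u * u - 0.5) * math.exp(a * (u * u - 1.0)), 0, 1,
               epsabs=1e-12, epsrel=1e-12)[0]
    den = quad(lambda u: math.exp(a * (u * u - 1.0)), 0, 1,
               epsabs=1e-12, epsrel=1e-12)[0]
    return num / den


def gen_ordered_chains(p_target: float, n_bonds: int, seed: int = 0) -> np.ndarray:
    """Unit bond vectors whose expected P2 against z equals ``p_target``.

    cos(theta) is rejection-sampled from a tilted density proportional to
    exp(a cos^2 theta), with the concentration a solved so the expected
    second-Legendre moment matches the target; the azimuth is uniform.
    ``p_target`` = 1 returns bonds exactly along z, 0 samples
    isotropically.
    """
    if not -0.5 < p_target <= 1.0:
        raise ValueError("p_target must lie in (-0.5, 1]")
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    rng = np.random.default_rng(seed)
    if p_target == 1.0:
        return np.tile([0.0, 0.0, 1.0], (n_bonds, 1))
    if abs(p_target) < 1e-12:
        a = 0.0
    else:
        lo, hi = -400.0, 400.0
        p_lo, p_hi = _p2_expectation(lo), _p2_expectation(hi)
        if not p_lo < p_target < p_hi:
            raise ValueError(
                f"p_target {p_target} outside the attainable range "
                f"({p_lo:.4f}, {p_hi:.4f}) of the tilted-distribution sampler")
        a = brentq(lambda aa: _p2_expectation(aa) - p_target, lo, hi, xtol=1e-12)
    u = np.empty(0)
    while u.size < n_bonds:
        cand = rng.uniform(-1.0, 1.0, max(4 * n_bonds, 1024))
        log_accept = a * (cand ** 2 - (1.0 if a > 0 else 0.0))
        keep = np.log(rng.uniform(size=cand.size)) < log_accept
        u = np.concatenate([u, cand[keep]])
    u = u[:n_bonds]
    phi = rng.uniform(0.0, 2.0 * math.pi, n_bonds)
    s = np.sqrt(1.0 - u ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


# ---------------------------------------------------------------------------
# buckling


def gen_buckled_membrane(K_c: float, strain: float, L: float = 25.0,
                         n_frames: int = 1000, noise: float = 0.0,
                         seed: int = 0, Ly: float = 10.0, Lz: float = 10.0,
                         T: float = DEFAULT_TEMPERATURE,
                         dt: float = 1000.0) -> tuple[BucklingDataset, GroundTruth]:
    """Stress record (and elastica profile) of a membrane buckled at fixed strain.

    ``K_c`` is in k_B T at temperature ``T``. The mean stress is the
    exact elastica force for that modulus; ``noise`` adds multiplicative
    Gaussian noise of that relative amplitude to each stress sample.
    """
    if not 0.0 < strain < 0.5:
        raise ValueError(f"strain {strain} outside (0, 0.5)")
    if K_c <= 0 or L <= 0 or n_frames < 1 or noise < 0:
        raise ValueError("invalid buckling parameters")
    from .constants import BAR_TO_KJ_PER_MOL_NM3
    rng = np.random.default_rng(seed)
    kc_kj = K_c * KB * T
    f_per_length = kc_kj * elastica_force(strain) / L ** 2  # kJ/mol/nm^2
    sigma_bar = -f_per_length / Lz / BAR_TO_KJ_PER_MOL_NM3  # compressive: negative
    stress = sigma_bar * (1.0 + noise * rng.normal(size=n_frames))
    data = BucklingDataset(L=L, Lx=L * (1.0 - strain), Ly=Ly, Lz=Lz,
                           stress_xx=stress, times=np.arange(n_frames) * dt,
                           temperature=T)
    x_prof, z_prof = elastica_shape(strain, L)
    truth = GroundTruth({"K_c": K_c, "strain": strain, "sigma_bar": sigma_bar,
                         "profile": (x_prof, z_prof)})
    return data, truth


def gen_buckled_bilayer(strain: float, L: float = 25.0, Ly: float = 10.0,
                        lattice_spacing: float = 0.8, leaflet_separation: float = 4.0,
                        beads_per_chain: int = 3, jitter: float = 0.0,
                        seed: int = 0) -> tuple[Trajectory, GroundTruth]:
    """Bead bilayer draped on the periodic elastica profile.

    Head beads sit at z(x) +- separation/2 (offset along z, so the local
    head-to-head distance along the normal axis z is exactly the leaflet
    separation everywhere). Ground truth carries leaflet labels and the
    midplane profile. DPPC-only composition.
    """
    if not 0.0 < strain < 0.5:
        raise ValueError(f"strain {strain} outside (0, 0.5)")
    rng = np.random.default_rng(seed)
    Lx = L * (1.0 - strain)
    nx = max(2, int(L // lattice_spacing))
    ny = max(2, int(Ly // lattice_spacing))
    x_prof, z_prof = elastica_shape(strain, L, n_points=2048)
    amp = z_prof.max() - z_prof.min()
    box_z = amp + leaflet_separation + 2 * (beads_per_chain + 1) * _CHAIN_DZ + 2.0
    z0 = box_z / 2.0 - (z_prof.max() + z_prof.min()) / 2.0
    s_grid = np.linspace(0.0, L, nx, endpoint=False)
    x_of_s = np.interp(s_grid, np.linspace(0, L, x_prof.size), x_prof)
    z_of_s = np.interp(s_grid, np.linspace(0, L, x_prof.size), z_prof) + z0

    molecules, species_all, heads, acyl, leaflet_truth = [], [], [], [], []
    coords = []
    cursor = 0
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        for i in range(nx):
            for j in range(ny):
                names, head_local, bonds_local, zoff, xoff = _lipid_beads(
                    "DPPC", beads_per_chain)
                nb = len(names)
                jx, jy = (rng.uniform(-jitter, jitter, 2) if jitter > 0 else (0.0, 0.0))
                cx = x_of_s[i] + jx
                cy = (j + 0.5) * (Ly / ny) + jy
                cz = z_of_s[i] + sign * leaflet_separation / 2.0
                block = np.empty((nb, 3))
                block[:, 0] = cx + np.asarray(xoff)
                block[:, 1] = cy
                block[:, 2] = cz + sign * np.asarray(zoff)
                coords.append(block)
                idx = tuple(range(cursor, cursor + nb))
                molecules.append(MoleculeDef("DPPC", idx, tuple(names)))
                species_all.append("DPPC")
                heads.append(cursor + head_local)
                acyl.append(tuple((cursor + a, cursor + b) for a, b in bonds_local))
                leaflet_truth.append(leaflet)
                cursor += nb
    topo = Topology(tuple(molecules), tuple(species_all), tuple(heads),
                    tuple(acyl), cursor)
    frame = Frame(time=0.0, coordinates=np.concatenate(coords),
                  box=np.array([Lx, Ly, box_z]))
    truth = GroundTruth({
        "leaflet_of_molecule": tuple(leaflet_truth),
        "thickness": leaflet_separation,
        "profile": (x_of_s, z_of_s),
        "amplitude": amp,
    })
    return Trajectory(topo, [frame]), truth
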