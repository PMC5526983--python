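"""Lateral dynamics and structural fields of a bilayer.

* Lateral diffusion: mean square displacement over multiple time
  origins, fitted to MSD(t) = 4 D_L t.
* Acyl-chain order parameter p = (3<cos^2 theta> - 1)/2, theta being the
  angle between an acyl bond vector and the membrane normal (z); p = 1
  for bonds along z, -0.5 in-plane, 0 isotropic.
* 1D profiles along the membrane normal (density, order), centered on
  the membrane midplane per frame.
* 2D lateral maps (density, thickness, order) on an n x n grid in
  fractional box coordinates; thickness is the z distance between the
  per-cell centers of mass of head beads of the two leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (LeafletAssignment, Topology, Trajectory, assign_leaflets,
                   minimum_image_vectors)

__all__ = [
    "MSDResult",
    "Profile1D",
    "Map2D",
    "unwrap_lateral",
    "msd",
    "fit_diffusion",
    "order_parameter",
    "profile_1d",
    "map2d",
]


@dataclass
class MSDResult:
    lag_times: np.ndarray  # ps
    values: np.ndarray  # nm^2
    n_origins: np.ndarray  # averaging count per lag

    def __post_init__(self):
        if self.lag_times[0] != 0 or self.values[0] != 0:
            raise ValueError("msd must start at lag 0 with value 0")


@dataclass
class Profile1D:
    bin_centers: np.ndarray  # nm, membrane-centered z
    values: np.ndarray
    field: str  # 'density' (counts/nm^3) or 'order'


@dataclass
class Map2D:
    grid: np.ndarray  # (n, n)
    x_edges: np.ndarray  # fractional box coordinates, length n+1
    y_edges: np.ndarray
    field: str  # 'density' | 'thickness' | 'order'
    units: str
    occupancy: np.ndarray  # (n, n) sample counts; grid is NaN where 0


def unwrap_lateral(traj: Trajectory, bead_indices: np.ndarray) -> np.ndarray:
    """Continuous (x, y) tracks from wrapped coordinates + box history.

    Frame-to-frame displacements are minimum-imaged and accumulated;
    valid while no bead moves more than half a box edge between frames.
    Returns an array of shape (n_frames, n_beads, 2).
    """
    bead_indices = np.asarray(bead_indices, dtype=int)
    n_frames = len(traj)
    out = np.empty((n_frames, bead_indices.size, 2))
    prev = traj.frames[0].coordinates[bead_indices, :2]
    out[0] = prev
    for k in range(1, n_frames):
        cur = traj.frames[k].coordinates[bead_indices, :2]
        box_xy = traj.frames[k].box[:2]
        step = minimum_image_vectors(cur - prev, box_xy)
        out[k] = out[k - 1] + step
        prev = cur
    return out


def msd(traj: Trajectory, bead_indices: np.ndarray, max_lag: int | None = None,
        origin_stride: int = 1, remove_com_drift: bool = True) -> MSDResult:
    """Lateral mean square displacement averaged over particles and origins.

    ``max_lag`` is in frames (default: half the trajectory); time origins
    are spaced by ``origin_stride`` frames. With ``remove_com_drift`` the
    center-of-mass motion of the selection is subtracted per frame, so a
    collective drift does not masquerade as diffusion.
    """
    n_frames = len(traj)
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if max_lag is None:
        max_lag = n_frames // 2
    if max_lag >= n_frames:
        raise ValueError(f"max_lag {max_lag} >= trajectory length {n_frames}")
    tracks = unwrap_lateral(traj, bead_indices)
    if remove_com_drift:
        tracks = tracks - tracks.mean(axis=1, keepdims=True)
    times = traj.times
    lags = np.arange(max_lag + 1)
    values = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for lag in lags[1:]:
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = tracks[origins + lag] - tracks[origins]
        values[lag] = np.mean(np.sum(disp ** 2, axis=-1))
        counts[lag] = origins.size
    dt = times[1] - times[0]
    return MSDResult(lag_times=lags * dt, values=values, n_origins=counts)


def fit_diffusion(result: MSDResult, window: tuple[float, float] | None = None,
                  zero_intercept: bool = True) -> tuple[float, float]:
    """Lateral diffusion coefficient from MSD(t) = 4 D t, nm^2/ps.

    Least-squares over lags inside ``window`` (ps). The default fit has
    no intercept, matching the pure-diffusion form; a free-intercept
    variant absorbs short-time (ballistic/smoothing) offsets of real
    data. Returns (D, standard error).
    """
    t = result.lag_times
    y = result.values
    if window is not None:
        t_min, t_max = window
        mask = (t >= t_min) & (t <= t_max)
    else:
        mask = t > 0
    t, y = t[mask], y[mask]
    if t.size < 2:
        raise ValueError("fewer than 2 MSD points in the fit window")
    if zero_intercept:
        denom = float(np.sum(t ** 2))
        slope = float(np.sum(t * y) / denom)
        resid = y - slope * t
        dof = max(t.size - 1, 1)
        se_slope = float(np.sqrt(np.sum(resid ** 2) / dof / denom))
    else:
        A = np.vstack([t, np.ones_like(t)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        slope = float(coef[0])
        dof = max(t.size - 2, 1)
        rss = float(res[0]) if res.size else float(np.sum((y - A @ coef) ** 2))
        se_slope = float(np.sqrt(rss / dof / np.sum((t - t.mean()) ** 2)))
    return slope / 4.0, se_slope / 4.0


# ---------------------------------------------------------------------------
# order parameter


def _bond_vectors(frame, topology: Topology, mols: np.ndarray) -> np.ndarray:
    pairs = [bond for i in mols for bond in topology.acyl_bonds_of_molecule[i]]
    if not pairs:
        raise ValueError("no acyl bonds in selection")
    pairs = np.asarray(pairs, dtype=int)
    vec = frame.coordinates[pairs[:, 1]] - frame.coordinates[pairs[:, 0]]
    return minimum_image_vectors(vec, frame.box)


def second_legendre(vectors: np.ndarray) -> np.ndarray:
    """P2(cos theta) per vector, theta measured from the z axis."""
    v = np.asarray(vectors, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if (norm == 0).any():
        raise ValueError("zero-length bond vector")
    cos2 = (v[..., 2] / norm) ** 2
    return 1.5 * cos2 - 0.5


def order_parameter(traj: Trajectory, species=None) -> tuple[float, np.ndarray]:
    """Mean acyl-chain order parameter and per-bond values of the last frame pass.

    The average is flat over all bonds of all selected lipids of all
    frames. Returns ``(p, per_bond)`` where ``per_bond`` concatenates the
    P2 values over frames.
    """
    topology = traj.topology
    if species is None:
        mols = topology.lipid_molecule_indices()
    else:
        mols = topology.molecule_indices(species)
    per_bond = []
    for frame in traj.frames:
        per_bond.append(second_legendre(_bond_vectors(frame, topology, mols)))
    per_bond = np.concatenate(per_bond)
    return float(per_bond.mean()), per_bond


# ---------------------------------------------------------------------------
# profiles


def _membrane_center(frame, topology: Topology) -> float:
    lipids = topology.lipid_molecule_indices()
    if lipids.size == 0:
        raise ValueError("no lipids: cannot locate the membrane center")
    heads = [topology.head_bead_of_molecule[i] for i in lipids]
    return float(frame.coordinates[heads, 2].mean())


def profile_1d(traj: Trajectory, bead_indices: np.ndarray, field: str = "density",
               bin_width: float = 0.1, z_range: tuple[float, float] | None = None) -> Profile1D:
    """Field profile along the membrane normal, centered per frame.

    Density is a number density in counts/nm^3, using the per-frame box
    cross-section; the order profile bins acyl-bond midpoints and
    averages P2 per z bin (beads in ``bead_indices`` are ignored for the
    order field, which always uses the lipid acyl bonds).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if field not in ("density", "order"):
        raise ValueError(f"unknown field {field!r}")
    bead_indices = np.asarray(bead_indices, dtype=int)
    topology = traj.topology
    if z_range is None:
        half = traj.frames[0].box[2] / 2.0
        z_range = (-half, half)
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(centers.size)
    norm = np.zeros(centers.size)
    for frame in traj.frames:
        z0 = _membrane_center(frame, topology)
        if field == "density":
            z = frame.coordinates[bead_indices, 2] - z0
            counts, _ = np.histogram(z, bins=edges)
            acc += counts / (frame.box[0] * frame.box[1] * bin_width)
            norm += 1
        else:
            mols = topology.lipid_molecule_indices()
            pairs = np.asarray(
                [b for i in mols for b in topology.acyl_bonds_of_molecule[i]], dtype=int)
            vec = minimum_image_vectors(
                frame.coordinates[pairs[:, 1]] - frame.coordinates[pairs[:, 0]], frame.box)
            p2 = second_legendre(vec)
            mid = 0.5 * (frame.coordinates[pairs[:, 0], 2] + frame.coordinates[pairs[:, 1], 2]) - z0
            idx = np.digitize(mid, edges) - 1
            ok = (idx >= 0) & (idx < centers.size)
            np.add.at(acc, idx[ok], p2[ok])
            np.add.at(norm, idx[ok], 1)
    with np.errstate(invalid="ignore"):
        values = np.where(norm > 0, acc / np.maximum(norm, 1), np.nan)
    if field == "density":
        values = acc / len(traj)
    return Profile1D(bin_centers=centers, values=values, field=field)


# ---------------------------------------------------------------------------
# 2D maps


def _fractional_xy(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    frac = coords[:, :2] / box[:2]
    return np.mod(frac, 1.0)


def _recenter(frame, topology: Topology, center_on: np.ndarray) -> np.ndarray:
    """Coordinates shifted so center_on molecules' COM sits at the box center."""
    from .polymer import make_whole
    beads = np.concatenate([np.asarray(topology.molecules[i].bead_indices, dtype=int)
                            for i in center_on])
    whole = make_whole(frame.coordinates[beads], frame.box)
    com = whole.mean(axis=0)
    shift = frame.box / 2.0 - com
    return frame.coordinates + shift


def map2d(traj: Trajectory, field: str = "density", n_bins: int = 100,
          bead_indices: np.ndarray | None = None,
          center_on: np.ndarray | None = None,
          leaflets: LeafletAssignment | None = None) -> Map2D:
    """Time-averaged lateral map of density, thickness, or order.

    Binning is in fractional (x/Lx, y/Ly) coordinates so a fluctuating
    NpT box maps onto a fixed grid. ``center_on`` recenters each frame on
    the center of mass of the given molecule indices before binning (used
    to keep a diffusing aggregate stationary on the map). Thickness cells
    are averaged only over frames where both leaflets occupy the cell;
    cells never occupied are NaN (masked), never an error.
    """
    if n_bins < 2:
        raise ValueError("need at least a 2x2 grid")
    if field not in ("density", "thickness", "order"):
        raise ValueError(f"unknown field {field!r}")
    topology = traj.topology
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    acc = np.zeros((n_bins, n_bins))
    occ = np.zeros((n_bins, n_bins))
    mean_area = float(np.mean(traj.areas))
    for frame in traj.frames:
        coords = (_recenter(frame, topology, center_on)
                  if center_on is not None and len(center_on) else frame.coordinates)
        if field == "density":
            sel = (bead_indices if bead_indices is not None
                   else np.arange(topology.bead_count))
            frac = _fractional_xy(coords[np.asarray(sel, dtype=int)], frame.box)
            h, _, _ = np.histogram2d(frac[:, 0], frac[:, 1], bins=[edges, edges])
            acc += h
            occ += h
        elif field == "order":
            mols = topology.lipid_molecule_indices()
            pairs = np.asarray(
                [b for i in mols for b in topology.acyl_bonds_of_molecule[i]], dtype=int)
            vec = minimum_image_vectors(coords[pairs[:, 1]] - coords[pairs[:, 0]], frame.box)
            p2 = second_legendre(vec)
            mid = 0.5 * (coords[pairs[:, 0]] + coords[pairs[:, 1]])
            frac = _fractional_xy(mid, frame.box)
            ix = np.minimum((frac[:, 0] * n_bins).astype(int), n_bins - 1)
            iy = np.minimum((frac[:, 1] * n_bins).astype(int), n_bins - 1)
            np.add.at(acc, (ix, iy), p2)
            np.add.at(occ, (ix, iy), 1)
        else:  # thickness
            la = leaflets if leaflets is not None else assign_leaflets(frame, topology)
            up, lo = _leaflet_head_cells(coords, frame.box, topology, la, n_bins)
            both = ~np.isnan(up) & ~np.isnan(lo)
            acc[both] += (up - lo)[both]
            occ[both] += 1
    if field == "density":
        cell_area = mean_area / n_bins ** 2
        grid = acc / len(traj) / cell_area
        units = "nm^-2"
    else:
        with np.errstate(invalid="ignore"):
            grid = np.where(occ > 0, acc / np.maximum(occ, 1), np.nan)
        units = "nm" if field == "thickness" else "1"
    return Map2D(grid=grid, x_edges=edges, y_edges=edges, field=field,
                 units=units, occupancy=occ)


def _leaflet_head_cells(coords: np.ndarray, box: np.ndarray, topology: Topology,
                        leaflets: LeafletAssignment, n_bins: int):
    """Per-cell mean head-bead z for each leaflet (NaN where unoccupied)."""
    out = []
    for name in ("upper", "lower"):
        mols = leaflets.molecules_in(name)
        mols = [i for i in mols if topology.head_bead_of_molecule[i] is not None]
        grid = np.full((n_bins, n_bins), np.nan)
        if mols:
            heads = np.array([topology.head_bead_of_molecule[i] for i in mols], dtype=int)
            frac = _fractional_xy(coords[heads], box)
            z = coords[heads, 2]
            ix = np.minimum((frac[:, 0] * n_bins).astype(int), n_bins - 1)
            iy = np.minimum((frac[:, 1] * n_bins).astype(int), n_bins - 1)
            s = np.zeros((n_bins, n_bins))
            c = np.zeros((n_bins, n_bins))
            np.add.at(s, (ix, iy), z)
            np.add.at(c, (ix, iy), 1)
            with np.errstate(invalid="ignore"):
                grid = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        out.append(grid)
    return out[0], out[1]
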