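"""Contact counting and phase-separation statistics for ternary bilayers.

Liquid-ordered / liquid-disordered demixing is quantified through three
contact fractions,

    f_mix  = 100 * C(DLiPC-DPPC)  / (C(DLiPC-DPPC)  + C(DLiPC-DLiPC)),
    f_chol = 100 * C(CHOL-DLiPC)  / (C(CHOL-DLiPC)  + C(CHOL-DPPC)),
    f_pol  = 100 * C(pol-DLiPC)   / (C(pol-DLiPC)   + C(pol-DPPC)),

where C(A-B) is a time-averaged contact count. Lipid-lipid contacts are
molecule pairs whose head-group beads (phosphate, or hydroxyl for
cholesterol) lie within 1.1 nm under the minimum-image convention;
polymer-lipid contacts count all bead pairs within 0.8 nm.

The same-species count in the f_mix denominator is taken per DLiPC
molecule, i.e. each DLiPC-DLiPC pair contributes two contacts (one seen
from each end), while a DLiPC-DPPC pair contributes one contact to the
DLiPC side. Under this convention f_mix of an ideally mixed membrane
converges to the DPPC fraction of the DPPC+DLiPC pool (27.2% at
598:1598), and f_chol/f_pol to the DLiPC fraction (72.8%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory, select

__all__ = [
    "ContactSpec",
    "PhaseContactMetrics",
    "count_contacts",
    "phase_metrics",
    "ideal_mixing_expectation",
    "metrics_timeseries",
]


@dataclass(frozen=True)
class ContactSpec:
    """Cutoffs and averaging window for the contact analysis.

    ``analysis_window`` selects frames by index, ``(start, stop)`` with
    ``stop`` exclusive and ``None`` meaning "to the end"; the default
    trailing window keeps the last 40% of the trajectory, mirroring the
    practice of averaging only the equilibrated tail of a production run.
    """

    lipid_head_cutoff: float = 1.1  # nm, strict '<'
    polymer_bead_cutoff: float = 0.8  # nm, strict '<'
    analysis_window: tuple[int | None, int | None] | None = None
    polymer_species: tuple[str, ...] = ("PE", "PP", "PS", "POL")

    def __post_init__(self):
        if self.lipid_head_cutoff <= 0 or self.polymer_bead_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    def window_frames(self, n_frames: int) -> range:
        if self.analysis_window is None:
            start = int(np.floor(0.6 * n_frames))
            return range(start, n_frames)
        start, stop = self.analysis_window
        return range(start or 0, n_frames if stop is None else min(stop, n_frames))


@dataclass
class PhaseContactMetrics:
    """Contact fractions (percent) with block standard errors and raw counts.

    A fraction whose denominator was zero over the whole window (or whose
    species are absent) is ``None``, not 0.
    """

    f_mix: float | None
    f_chol: float | None
    f_pol: float | None
    counts: dict[str, float] = field(default_factory=dict)
    errors: dict[str, float] = field(default_factory=dict)


def _pair_count(pa: np.ndarray, pb: np.ndarray, box: np.ndarray, cutoff: float,
                same_set: bool) -> int:
    """Number of unordered cross-set pairs with distance < cutoff (periodic).

    KD-tree query uses ``<=``; exact-cutoff pairs are removed afterwards to
    honour the strict inequality.
    """
    box = np.asarray(box, dtype=float)
    if pa.size == 0 or pb.size == 0:
        return 0
    wa = np.mod(pa, box)
    wb = np.mod(pb, box)
    # mod can return the upper edge itself through rounding; fold it back
    wa[wa >= box] = 0.0
    wb[wb >= box] = 0.0
    ta = cKDTree(wa, boxsize=box)
    if same_set:
        pairs = ta.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            return 0
        d = _pair_dist(wa[pairs[:, 0]], wa[pairs[:, 1]], box)
        return int(np.count_nonzero(d < cutoff))
    tb = cKDTree(wb, boxsize=box)
    coo = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")
    if coo.nnz == 0:
        return 0
    d = _pair_dist(wa[coo.row], wb[coo.col], box)
    return int(np.count_nonzero(d < cutoff))


def _pair_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    delta = a - b
    delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=1)


def count_contacts(frame: Frame, topology: Topology,
                   species_a, species_b, cutoff: float,
                   mode: str = "molecule_pair") -> int:
    """Count contacts between two species groups in one frame.

    ``molecule_pair`` mode counts unordered molecule pairs whose head
    beads are within ``cutoff`` (each pair once, also when the groups
    coincide); ``bead_pair`` counts bead pairs across the two groups with
    all beads considered. Intra-molecular pairs are always excluded, and
    the count is symmetric in the two groups.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("molecule_pair", "bead_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    species_a = frozenset(species_a)
    species_b = frozenset(species_b)
    box = frame.box
    if mode == "molecule_pair":
        mols_a = topology.molecule_indices(species_a)
        mols_b = topology.molecule_indices(species_b)
        heads_a = np.array([h for i in mols_a
                            if (h := topology.head_bead_of_molecule[i]) is not None],
                           dtype=int)
        heads_b = np.array([h for i in mols_b
                            if (h := topology.head_bead_of_molecule[i]) is not None],
                           dtype=int)
        pa = frame.coordinates[heads_a] if heads_a.size else np.empty((0, 3))
        pb = frame.coordinates[heads_b] if heads_b.size else np.empty((0, 3))
        if species_a == species_b:
            return _pair_count(pa, pa, box, cutoff, same_set=True)
        if set(mols_a) & set(mols_b):
            raise ValueError("overlapping molecule selections for distinct species sets")
        return _pair_count(pa, pb, box, cutoff, same_set=False)
    # bead_pair
    beads_a = select(topology, species_a, "all")
    beads_b = select(topology, species_b, "all")
    pa = frame.coordinates[beads_a] if beads_a.size else np.empty((0, 3))
    pb = frame.coordinates[beads_b] if beads_b.size else np.empty((0, 3))
    mol_of = topology.molecule_of_bead()
    if species_a == species_b:
        if pa.size == 0:
            return 0
        wa = np.mod(pa, box)
        wa[wa >= box] = 0.0
        tree = cKDTree(wa, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            return 0
        d = _pair_dist(wa[pairs[:, 0]], wa[pairs[:, 1]], box)
        keep = (d < cutoff) & (mol_of[beads_a[pairs[:, 0]]] != mol_of[beads_a[pairs[:, 1]]])
        return int(np.count_nonzero(keep))
    if pa.size == 0 or pb.size == 0:
        return 0
    wa = np.mod(pa, box); wa[wa >= box] = 0.0
    wb = np.mod(pb, box); wb[wb >= box] = 0.0
    ta = cKDTree(wa, boxsize=box)
    tb = cKDTree(wb, boxsize=box)
    coo = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")
    if coo.nnz == 0:
        return 0
    d = _pair_dist(wa[coo.row], wb[coo.col], box)
    keep = (d < cutoff) & (mol_of[beads_a[coo.row]] != mol_of[beads_b[coo.col]])
    return int(np.count_nonzero(keep))


_COUNT_KEYS = (
    "C_DLiPC-DPPC", "C_DLiPC-DLiPC", "C_CHOL-DLiPC", "C_CHOL-DPPC",
    "C_pol-DLiPC", "C_pol-DPPC",
)


def _frame_counts(frame: Frame, topology: Topology, spec: ContactSpec,
                  polymer: tuple[str, ...]) -> dict[str, float]:
    sp = topology.species_set
    c = dict.fromkeys(_COUNT_KEYS, 0.0)
    lipid_cut = spec.lipid_head_cutoff
    if "DLiPC" in sp and "DPPC" in sp:
        c["C_DLiPC-DPPC"] = count_contacts(frame, topology, {"DLiPC"}, {"DPPC"}, lipid_cut)
    if "DLiPC" in sp:
        # per-DLiPC convention: each same-species pair is seen from both ends
        c["C_DLiPC-DLiPC"] = 2.0 * count_contacts(
            frame, topology, {"DLiPC"}, {"DLiPC"}, lipid_cut)
    if "CHOL" in sp and "DLiPC" in sp:
        c["C_CHOL-DLiPC"] = count_contacts(frame, topology, {"CHOL"}, {"DLiPC"}, lipid_cut)
    if "CHOL" in sp and "DPPC" in sp:
        c["C_CHOL-DPPC"] = count_contacts(frame, topology, {"CHOL"}, {"DPPC"}, lipid_cut)
    if polymer:
        if "DLiPC" in sp:
            c["C_pol-DLiPC"] = count_contacts(
                frame, topology, polymer, {"DLiPC"}, spec.polymer_bead_cutoff, "bead_pair")
        if "DPPC" in sp:
            c["C_pol-DPPC"] = count_contacts(
                frame, topology, polymer, {"DPPC"}, spec.polymer_bead_cutoff, "bead_pair")
    return c


def _ratio(num: float, den: float) -> float | None:
    return 100.0 * num / den if den > 0 else None


def _metrics_from_counts(c: dict[str, float]) -> tuple[float | None, float | None, float | None]:
    f_mix = _ratio(c["C_DLiPC-DPPC"], c["C_DLiPC-DPPC"] + c["C_DLiPC-DLiPC"])
    f_chol = _ratio(c["C_CHOL-DLiPC"], c["C_CHOL-DLiPC"] + c["C_CHOL-DPPC"])
    f_pol = _ratio(c["C_pol-DLiPC"], c["C_pol-DLiPC"] + c["C_pol-DPPC"])
    return f_mix, f_chol, f_pol


def _block_errors(per_frame: list[dict[str, float]], n_blocks: int = 5) -> dict[str, float]:
    """Block-average standard errors of the three fractions."""
    n = len(per_frame)
    errors: dict[str, float] = {}
    if n < n_blocks:
        return errors
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    block_vals: dict[str, list[float]] = {"f_mix": [], "f_chol": [], "f_pol": []}
    for b in range(n_blocks):
        chunk = per_frame[edges[b]:edges[b + 1]]
        mean_counts = {k: float(np.mean([c[k] for c in chunk])) for k in _COUNT_KEYS}
        for key, val in zip(("f_mix", "f_chol", "f_pol"), _metrics_from_counts(mean_counts)):
            if val is not None:
                block_vals[key].append(val)
    for key, vals in block_vals.items():
        if len(vals) == n_blocks:
            errors[key] = float(np.std(vals, ddof=1) / np.sqrt(n_blocks))
    return errors


def phase_metrics(traj: Trajectory, spec: ContactSpec | None = None) -> PhaseContactMetrics:
    """Contact fractions averaged over the trailing analysis window.

    Counts are time-averaged first and the ratios formed afterwards
    (ratio of means), which stays stable when per-frame denominators are
    small. Metrics whose species are absent, or whose denominator is zero
    over the whole window, come back as ``None``.
    """
    spec = spec or ContactSpec()
    frames_idx = list(spec.window_frames(len(traj)))
    if not frames_idx:
        raise ValueError("empty analysis window")
    polymer = tuple(s for s in spec.polymer_species if s in traj.topology.species_set)
    per_frame = [_frame_counts(traj.frames[i], traj.topology, spec, polymer)
                 for i in frames_idx]
    mean_counts = {k: float(np.mean([c[k] for c in per_frame])) for k in _COUNT_KEYS}
    f_mix, f_chol, f_pol = _metrics_from_counts(mean_counts)
    for name, val, keys in (
        ("f_mix", f_mix, ("C_DLiPC-DPPC", "C_DLiPC-DLiPC")),
        ("f_chol", f_chol, ("C_CHOL-DLiPC", "C_CHOL-DPPC")),
        ("f_pol", f_pol, ("C_pol-DLiPC", "C_pol-DPPC")),
    ):
        if val is None and any(mean_counts[k] > 0 for k in keys):
            warnings.warn(f"{name}: zero denominator over the analysis window")
    return PhaseContactMetrics(
        f_mix=f_mix, f_chol=f_chol, f_pol=f_pol,
        counts=mean_counts, errors=_block_errors(per_frame),
    )


def ideal_mixing_expectation(n_dppc: int, n_dlipc: int) -> tuple[float, float, float]:
    """Contact fractions (percent) expected for an ideally mixed membrane.

    f_mix equals the DPPC share of the DPPC+DLiPC pool; f_chol and f_pol
    equal the DLiPC share (a randomly placed cholesterol or polymer bead
    meets each phospholipid in proportion to its abundance).
    """
    if n_dppc <= 0 or n_dlipc <= 0:
        raise ValueError("both lipid counts must be positive")
    total = n_dppc + n_dlipc
    f_mix = 100.0 * n_dppc / total
    f_other = 100.0 * n_dlipc / total
    return f_mix, f_other, f_other


def metrics_timeseries(traj: Trajectory, spec: ContactSpec | None = None,
                       stride: int = 1):
    """Per-frame contact fractions plus a drift diagnostic.

    Returns ``(times, series, drift)`` where ``series`` maps metric name
    to a per-frame array (NaN where undefined) and ``drift`` maps metric
    name to ``(slope, slope_se, no_drift)`` from an ordinary
    least-squares line; ``no_drift`` is ``|slope| < 2*SE``.
    """
    spec = spec or ContactSpec(analysis_window=(0, None))
    if len(traj) < 2:
        raise ValueError("need at least 2 frames for a time series")
    idx = list(spec.window_frames(len(traj)))[::stride]
    polymer = tuple(s for s in spec.polymer_species if s in traj.topology.species_set)
    series = {"f_mix": [], "f_chol": [], "f_pol": []}
    times = []
    for i in idx:
        c = _frame_counts(traj.frames[i], traj.topology, spec, polymer)
        f_mix, f_chol, f_pol = _metrics_from_counts(c)
        times.append(traj.frames[i].time)
        for k, v in zip(series, (f_mix, f_chol, f_pol)):
            series[k].append(np.nan if v is None else v)
    times = np.array(times)
    series = {k: np.array(v) for k, v in series.items()}
    drift = {}
    for k, y in series.items():
        good = ~np.isnan(y)
        if good.sum() >= 3:
            drift[k] = _drift_stat(times[good], y[good])
    return times, series, drift


def _drift_stat(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    t0 = t - t.mean()
    denom = float(np.sum(t0 ** 2))
    if denom == 0:
        return 0.0, 0.0, True
    slope = float(np.sum(t0 * y) / denom)
    resid = y - y.mean() - slope * t0
    dof = max(len(y) - 2, 1)
    se = float(np.sqrt(np.sum(resid ** 2) / dof / denom))
    if se == 0.0:
        return slope, se, slope == 0.0
    return slope, se, bool(abs(slope) < 2.0 * se)
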