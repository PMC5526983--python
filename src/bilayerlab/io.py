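"""Readers and writers: GRO structures, XTC/TRR trajectories, the
package's plain-text frame format, TSV tables, 2D map grids, and the run
configuration.

GRO/XTC/TRR go through MDAnalysis (positions converted to nm, times in
ps). The plain-text frame format is defined by this package so that test
fixtures stay human-writable:

    # free comment line
    t=<time in ps>
    <bead count>
    x y z            (one line per bead, nm)
    Lx Ly Lz         (orthorhombic box, nm)

repeated once per frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import DEFAULT_SPECIES_ALIASES, DEFAULT_TEMPERATURE, LIPID_SPECIES
from .core import Frame, MoleculeDef, Topology, Trajectory

__all__ = [
    "RunConfig",
    "read_structure",
    "read_trajectory",
    "write_trajectory_text",
    "write_gro",
    "write_table",
    "write_map",
]

DEFAULT_HEAD_BEADS = {"DPPC": "PO4", "DLiPC": "PO4", "POPC": "PO4", "CHOL": "ROH"}
POLYMER_LABELS = ("PE", "PP", "PS", "POL")

_ACYL_RE = re.compile(r"^[CD](\d+)([A-D])$")


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    structure: str | None = None
    trajectory: str | None = None
    species_map: dict = field(default_factory=dict)  # residue name -> species label
    head_beads: dict = field(default_factory=lambda: dict(DEFAULT_HEAD_BEADS))
    acyl_chains: dict = field(default_factory=dict)  # species -> list of bead-name lists
    lipid_head_cutoff: float = 1.1  # nm
    polymer_bead_cutoff: float = 0.8  # nm
    fit_window: tuple[float, float] | None = None  # ps
    grid_size: int = 100
    temperature: float = DEFAULT_TEMPERATURE
    output_dir: str = "."
    seed: int | None = None

    def __post_init__(self):
        if self.lipid_head_cutoff <= 0 or self.polymer_bead_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.grid_size < 2:
            raise ValueError("grid size must be >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def resolve_species(self, resname: str) -> str:
        name = resname.strip()
        if name in self.species_map:
            return self.species_map[name]
        upper = name.upper()
        if upper in self.species_map:
            return self.species_map[upper]
        if upper in DEFAULT_SPECIES_ALIASES:
            return DEFAULT_SPECIES_ALIASES[upper]
        if upper in POLYMER_LABELS:
            return upper
        raise KeyError(
            f"residue name {resname!r} absent from the species map; add it to "
            "RunConfig.species_map")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fit_window" in data and data["fit_window"] is not None:
            data["fit_window"] = tuple(data["fit_window"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _infer_acyl_chains(bead_names) -> list[list[int]]:
    """Group bead names like C1A/D2A/C3B into per-chain ordered local indices."""
    chains: dict[str, list[tuple[int, int]]] = {}
    for local, name in enumerate(bead_names):
        m = _ACYL_RE.match(name)
        if m:
            chains.setdefault(m.group(2), []).append((int(m.group(1)), local))
    out = []
    for letter in sorted(chains):
        out.append([local for _, local in sorted(chains[letter])])
    return out


def _build_topology(resnames: list[str], bead_names_per_mol: list[list[str]],
                    config: RunConfig) -> Topology:
    molecules, species_all, heads, acyl = [], [], [], []
    cursor = 0
    for resname, names in zip(resnames, bead_names_per_mol):
        species = config.resolve_species(resname)
        nb = len(names)
        idx = tuple(range(cursor, cursor + nb))
        molecules.append(MoleculeDef(species, idx, tuple(names)))
        species_all.append(species)
        if species in LIPID_SPECIES:
            head_name = config.head_beads.get(species, "PO4")
            if head_name not in names:
                raise ValueError(
                    f"molecule {len(molecules) - 1} ({species}): head bead "
                    f"{head_name!r} not among beads {names}")
            heads.append(cursor + names.index(head_name))
        else:
            heads.append(None)
        if species in config.acyl_chains:
            chains = [[names.index(n) for n in chain]
                      for chain in config.acyl_chains[species]]
        else:
            chains = _infer_acyl_chains(names)
        bonds = []
        for chain in chains:
            bonds.extend((cursor + a, cursor + b) for a, b in zip(chain, chain[1:]))
        acyl.append(tuple(bonds))
        cursor += nb
    return Topology(tuple(molecules), tuple(species_all), tuple(heads),
                    tuple(acyl), cursor)


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None:
        raise ValueError("missing box")
    dims = np.asarray(dimensions, dtype=float)
    if dims.size >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {dims[3:6]}) not supported; "
            "only orthorhombic boxes are handled")
    if (dims[:3] <= 0).any():
        raise ValueError("box edges must be positive")
    return dims[:3]


def read_structure(path, config: RunConfig | None = None) -> tuple[Topology, Frame]:
    """Parse a GRO file into a topology and a coordinate frame.

    Molecules come from residue grouping; species labels from the
    configuration's species map (MARTINI residue names understood by
    default, including the DIPC alias of DLiPC). Positions are nm as
    written; a velocity block, if present, is ignored.
    """
    import MDAnalysis as mda
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    try:
        with warnings.catch_warnings():
            # beads have no standard element masses; we never use them
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise ValueError(f"{path}: malformed GRO file ({exc})") from exc
    box = _check_orthorhombic(u.dimensions) / 10.0  # A -> nm
    resnames = [str(r.resname) for r in u.residues]
    bead_names = [[str(a.name) for a in r.atoms] for r in u.residues]
    topology = _build_topology(resnames, bead_names, config)
    coords = u.atoms.positions.astype(float) / 10.0  # A -> nm
    frame = Frame(time=0.0, coordinates=coords, box=box)
    return topology, frame


def read_trajectory(path, topology: Topology,
                    structure: str | Path | None = None) -> Trajectory:
    """Read an XTC/TRR (via MDAnalysis, needs ``structure``) or plain-text
    frame file into a Trajectory. Frames must be time-ordered."""
    path = Path(path)
    if path.suffix.lower() in (".xtc", ".trr"):
        import MDAnalysis as mda
        if structure is None:
            raise ValueError("XTC/TRR input needs the matching structure file")
        u = mda.Universe(str(structure), str(path))
        if len(u.atoms) != topology.bead_count:
            raise ValueError(
                f"{path}: {len(u.atoms)} beads, topology declares {topology.bead_count}")
        frames = []
        for ts in u.trajectory:
            box = _check_orthorhombic(ts.dimensions) / 10.0
            frames.append(Frame(time=float(ts.time),
                                coordinates=ts.positions.astype(float) / 10.0,
                                box=box))
    else:
        frames = _read_text_frames(path, topology.bead_count)
    times = [f.time for f in frames]
    bad = [i for i in range(1, len(times)) if times[i] <= times[i - 1]]
    if bad:
        raise ValueError(f"{path}: non-monotonic frame times at indices {bad}")
    return Trajectory(topology, frames)


def _read_text_frames(path: Path, bead_count: int) -> list[Frame]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        block_start = i
        try:
            comment = lines[i]  # noqa: F841 - format requires it
            tline = lines[i + 1]
            if not tline.startswith("t="):
                raise ValueError(f"expected 't=<ps>' line, got {tline!r}")
            time = float(tline[2:])
            n = int(lines[i + 2])
            if n != bead_count:
                raise ValueError(f"frame declares {n} beads, topology {bead_count}")
            coords = np.array(
                [[float(v) for v in lines[i + 3 + k].split()] for k in range(n)])
            box = np.array([float(v) for v in lines[i + 3 + n].split()])
            i = i + 4 + n
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: truncated or malformed frame starting at line "
                f"{block_start + 1} ({exc})") from exc
        frames.append(Frame(time=time, coordinates=coords, box=box))
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_trajectory_text(traj: Trajectory, path, comment: str = "bilayerlab frames") -> None:
    """Write the plain-text frame format (positions to 6 decimals, nm)."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"# {comment}\n")
            fh.write(f"t={frame.time:.6f}\n")
            fh.write(f"{frame.coordinates.shape[0]}\n")
            for x, y, z in frame.coordinates:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write(f"{frame.box[0]:.6f} {frame.box[1]:.6f} {frame.box[2]:.6f}\n")


def write_gro(topology: Topology, frame: Frame, path, title: str = "bilayerlab") -> None:
    """Write a GRO structure file (nm, fixed-column format) via MDAnalysis."""
    import MDAnalysis as mda
    n_atoms = topology.bead_count
    n_res = topology.n_molecules
    resindices = topology.molecule_of_bead()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, n_residues=n_res, atom_resindex=resindices,
                               residue_segindex=np.zeros(n_res, dtype=int),
                               trajectory=True)
    names = [""] * n_atoms
    for mol in topology.molecules:
        for b, nm in zip(mol.bead_indices, mol.bead_names):
            names[b] = nm
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", [m.name for m in topology.molecules])
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.atoms.positions = frame.coordinates * 10.0  # nm -> A
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                    90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def write_table(records: list[dict], path, metadata: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata lines and a stable header order.

    Floats are printed with 6 significant digits. The package version is
    always recorded; pass the seed in ``metadata`` for stochastic runs.
    """
    meta = {"version": __version__}
    meta.update(metadata or {})
    header: list[str] = []
    for rec in records:
        for key in rec:
            if key not in header:
                header.append(key)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(header) + "\n")
        for rec in records:
            cells = []
            for key in header:
                val = rec.get(key, "")
                if isinstance(val, float):
                    cells.append(f"{val:.6g}")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


def write_map(map2d, path, metadata: dict | None = None) -> None:
    """Plain-text matrix dump of a 2D map, with x/y edge headers."""
    with open(path, "w") as fh:
        fh.write(f"# field: {map2d.field} [{map2d.units}]\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# x_edges: " + " ".join(f"{e:.6g}" for e in map2d.x_edges) + "\n")
        fh.write("# y_edges: " + " ".join(f"{e:.6g}" for e in map2d.y_edges) + "\n")
        for row in map2d.grid:
            fh.write(" ".join("nan" if np.isnan(v) else f"{v:.6g}" for v in row) + "\n")
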