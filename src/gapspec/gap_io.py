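"""I/O for per-frame excited-state tables and geometry trajectories.

Gap tables are self-describing delimited text with named columns
(``time_fs``, ``e_s1_eV``, ``e_s2_eV``, optionally ``d_s1_x`` ... for
transition dipoles), comma- or whitespace-delimited, with ``#`` comments.
Geometry trajectories are multi-frame XYZ or multi-MODEL PDB files, parsed
through MDAnalysis.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TEMPERATURE = 300.0  # K; recorded in metadata when the source omits T

_ENERGY_RE = re.compile(r"^e_s(\d+)_eV$")
_DIPOLE_RE = re.compile(r"^d_s(\d+)_([xyz])$")


@dataclass
class GapTrajectory:
    """Time series of vertical excitation energies (and transition dipoles).

    Parameters
    ----------
    times:
        Frame times in fs, strictly increasing with uniform spacing.
    energies:
        Excitation energies in eV, shape ``(n_frames, n_states)``.
    dipoles:
        Optional transition dipoles in Debye, ``(n_frames, n_states, 3)``.
    temperature:
        Bath temperature in K used downstream for the 1/(k_B T) prefactor.
    """

    times: np.ndarray
    energies: np.ndarray
    dipoles: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    replica_id: str = "replica-0"
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim == 1:
            self.energies = self.energies[:, None]
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("a gap trajectory needs at least 2 frames")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            bad = np.nonzero(steps <= 0)[0]
            raise ValueError(f"times must be strictly increasing; bad rows: {bad + 1}")
        dt = steps[0]
        rel = np.abs(steps - dt) / dt
        if np.any(rel > 1e-9):
            bad = np.nonzero(rel > 1e-9)[0]
            raise ValueError(
                "non-uniform time spacing (relative tolerance 1e-9); "
                f"offending rows: {(bad + 1).tolist()}"
            )
        if self.energies.shape[0] != self.times.size:
            raise ValueError("energies and times disagree on frame count")
        if not np.all(np.isfinite(self.energies)) or np.any(self.energies <= 0):
            raise ValueError("excitation energies must be finite and positive")
        if self.dipoles is not None:
            self.dipoles = np.asarray(self.dipoles, dtype=float)
            expected = (*self.energies.shape, 3)
            if self.dipoles.shape != expected:
                raise ValueError(
                    f"dipole array shape {self.dipoles.shape} != {expected}"
                )
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.state_labels is not None:
            self.state_labels = tuple(self.state_labels)
            if len(self.state_labels) != self.n_states:
                raise ValueError("one state label per energy column required")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in fs."""
        return float(self.times[1] - self.times[0])


@dataclass
class GeometryTrajectory:
    """Cartesian coordinates (Angstrom) for a fixed set of atoms over frames."""

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic edge lengths

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        if len(self.atom_names) != n_atoms or len(self.elements) != n_atoms:
            raise ValueError("atom_names/elements length must match coords")
        self.elements = [e.capitalize() for e in self.elements]
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.coords.shape[0], 3):
                raise ValueError("box must be (n_frames, 3) edge lengths")
            if np.any(self.box <= 0):
                raise ValueError("box edge lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# gap tables


def _split_columns(columns: list[str]) -> tuple[list[str], dict[int, dict[str, str]]]:
    energy_cols: dict[int, str] = {}
    dipole_cols: dict[int, dict[str, str]] = {}
    for col in columns:
        m = _ENERGY_RE.match(col)
        if m:
            energy_cols[int(m.group(1))] = col
            continue
        m = _DIPOLE_RE.match(col)
        if m:
            dipole_cols.setdefault(int(m.group(1)), {})[m.group(2)] = col
    ordered = [energy_cols[i] for i in sorted(energy_cols)]
    return ordered, dipole_cols


def read_gap_table(
    path,
    dialect: dict | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    replica_id: str | None = None,
) -> GapTrajectory:
    """Read a per-frame excited-state table into a :class:`GapTrajectory`.

    ``dialect`` may override the default column map with keys ``time``
    (column name), ``energies`` (list of column names, one per state) and
    optionally ``dipoles`` (list of ``[x, y, z]`` column-name triples).
    """
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    if dialect is None:
        time_col = "time_fs"
        energy_names, dipole_map = _split_columns(list(df.columns))
        dipole_names = [
            [dipole_map[i][ax] for ax in "xyz"] for i in sorted(dipole_map)
        ] or None
    else:
        time_col = dialect.get("time", "time_fs")
        energy_names = list(dialect["energies"])
        dipole_names = dialect.get("dipoles")
    if time_col not in df.columns:
        raise ValueError(f"mandatory time column {time_col!r} missing from {path}")
    if not energy_names:
        raise ValueError(f"no per-state energy columns (e_s<i>_eV) found in {path}")
    missing = [c for c in energy_names if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory energy columns missing: {missing}")
    if len(df) < 2:
        raise ValueError("gap table must contain at least 2 frames")

    energies = df[energy_names].to_numpy(dtype=float)
    dipoles = None
    if dipole_names:
        if len(dipole_names) != len(energy_names):
            raise ValueError("dipole columns present for a subset of states only")
        dipoles = np.stack(
            [df[list(cols)].to_numpy(dtype=float) for cols in dipole_names], axis=1
        )
    if replica_id is None:
        replica_id = str(getattr(path, "stem", path))
    return GapTrajectory(
        times=df[time_col].to_numpy(dtype=float),
        energies=energies,
        dipoles=dipoles,
        temperature=temperature,
        replica_id=replica_id,
    )


def write_gap_table(traj: GapTrajectory, path) -> None:
    """Write a gap trajectory in the same dialect :func:`read_gap_table` reads."""
    cols = {"time_fs": traj.times}
    for i in range(traj.n_states):
        cols[f"e_s{i + 1}_eV"] = traj.energies[:, i]
    if traj.dipoles is not None:
        for i in range(traj.n_states):
            for k, ax in enumerate("xyz"):
                cols[f"d_s{i + 1}_{ax}"] = traj.dipoles[:, i, k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# gapspec gap table, replica {traj.replica_id}, "
                 f"T = {traj.temperature} K\n")
        df.to_csv(fh, sep=" ", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# geometry trajectories


def _read_xyz(path) -> GeometryTrajectory:
    """Multi-frame XYZ parser (float64; round-trips printed precision)."""
    frames: list[list[list[float]]] = []
    elements: list[str] = []
    counts: list[int] = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            if not line.strip():
                continue
            n = int(line.split()[0])
            counts.append(n)
            fh.readline()  # comment line
            frame = []
            syms = []
            for _ in range(n):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise ValueError(f"malformed XYZ atom line in {path}")
                syms.append(parts[0])
                frame.append([float(x) for x in parts[1:4]])
            if len(set(counts)) != 1:
                raise ValueError(
                    f"atom count varies between frames in {path}: {counts}")
            frames.append(frame)
            elements = syms
    if not frames:
        raise ValueError(f"no frames found in {path}")
    names = [f"{e.capitalize()}{i + 1}" for i, e in enumerate(elements)]
    return GeometryTrajectory(atom_names=names, elements=elements,
                              coords=np.asarray(frames, dtype=float))


def _scan_pdb_frames(path) -> tuple[list[int], np.ndarray | None]:
    """Atom count per MODEL and the CRYST1 cell lengths (if any)."""
    counts: list[int] = []
    current = 0
    saw_model = False
    cell = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
            elif rec == "CRYST1":
                cell = np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33])])
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not counts and current:
        counts.append(current)
    return counts, cell


def read_geometry_trajectory(path, format: str | None = None) -> GeometryTrajectory:
    """Read a multi-frame XYZ or multi-MODEL PDB file.

    Frames are returned in file order; element symbols are normalized to
    an initial capital. A varying atom count between frames is a hard error.
    XYZ is parsed in-package (full float precision); PDB goes through
    MDAnalysis.
    """
    path = str(path)
    if format is None:
        format = "pdb" if path.lower().endswith(".pdb") else "xyz"
    format = format.lower()
    if format == "xyz":
        return _read_xyz(path)
    if format != "pdb":
        raise ValueError(f"unsupported trajectory format {format!r}")

    import MDAnalysis as mda

    counts, cell = _scan_pdb_frames(path)
    if not counts:
        raise ValueError(f"no frames found in {path}")
    if len(set(counts)) != 1:
        raise ValueError(f"atom count varies between frames in {path}: {counts}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path, format="pdb")
        names = list(u.atoms.names)
        try:
            elements = [str(e) for e in u.atoms.elements]
        except Exception:
            # PDB without element column: fall back to the leading letters
            elements = [re.sub(r"[^A-Za-z].*$", "", n) for n in names]
        coords = np.stack([u.atoms.positions.astype(float).copy()
                           for _ in u.trajectory])
        box = None
        dims = []
        has_box = True
        for _ in u.trajectory:
            d = u.dimensions
            if d is None or not np.all(d[:3] > 0):
                has_box = False
                break
            dims.append(d[:3].astype(float).copy())
        if has_box and dims:
            box = np.stack(dims)
        elif cell is not None and np.all(cell > 0):
            # MDAnalysis drops a global CRYST1 on multi-MODEL files
            box = np.tile(cell, (coords.shape[0], 1))
    return GeometryTrajectory(atom_names=names, elements=elements,
                              coords=coords, box=box)


def write_xyz(traj: GeometryTrajectory, path, comment: str = "") -> None:
    """Write a multi-frame XYZ file (count line, comment, element x y z)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"{comment} frame {f}\n".strip() + "\n"
                     if comment else f"frame {f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{traj.elements[a]:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
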