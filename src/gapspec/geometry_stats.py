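"""Conformational-ensemble statistics for geometry trajectories.

Per-frame internal coordinates (bonds in Angstrom, angles and proper
dihedrals in degrees, IUPAC sign convention), ensemble means with circular
statistics for dihedrals, absolute deviations between two ensembles,
periodic dihedral histograms, and shell-normalized radial distribution
functions with orthorhombic minimum-image handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import distance_array

from .gap_io import GeometryTrajectory

_DEGENERACY_EPS = 1e-10


@dataclass
class InternalCoordinateSet:
    """Bond/angle/dihedral definitions as 0-based atom-index tuples."""

    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    bond_labels: list[str] | None = None
    angle_labels: list[str] | None = None
    dihedral_labels: list[str] | None = None

    def __post_init__(self) -> None:
        for kind, size in (("bonds", 2), ("angles", 3), ("dihedrals", 4)):
            entries = [tuple(int(i) for i in e) for e in getattr(self, kind)]
            if any(len(e) != size for e in entries):
                raise ValueError(f"{kind} entries need {size} atom indices")
            if len(set(entries)) != len(entries):
                raise ValueError(f"duplicate entries in {kind}")
            setattr(self, kind, entries)
        if self.bond_labels is None:
            self.bond_labels = ["-".join(map(str, b)) for b in self.bonds]
        if self.angle_labels is None:
            self.angle_labels = ["-".join(map(str, a)) for a in self.angles]
        if self.dihedral_labels is None:
            self.dihedral_labels = ["-".join(map(str, d)) for d in self.dihedrals]

    def validate_for(self, traj: GeometryTrajectory) -> None:
        top = max(
            (max(e) for e in (*self.bonds, *self.angles, *self.dihedrals)),
            default=-1,
        )
        if top >= traj.n_atoms:
            raise ValueError(
                f"coordinate definition references atom {top}, trajectory "
                f"has {traj.n_atoms} atoms")


def read_internal_coordinates(path) -> InternalCoordinateSet:
    """Read coordinate definitions: lines of ``type i j [k [l]] label``, 1-based."""
    bonds, angles, dihedrals = [], [], []
    blab, alab, dlab = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            kind = parts[0].lower()
            n = {"bond": 2, "angle": 3, "dihedral": 4}.get(kind)
            if n is None:
                raise ValueError(f"unknown coordinate type {kind!r}")
            idx = tuple(int(p) - 1 for p in parts[1:1 + n])
            label = parts[1 + n] if len(parts) > 1 + n else "-".join(parts[1:1 + n])
            if kind == "bond":
                bonds.append(idx); blab.append(label)
            elif kind == "angle":
                angles.append(idx); alab.append(label)
            else:
                dihedrals.append(idx); dlab.append(label)
    return InternalCoordinateSet(bonds=bonds, angles=angles, dihedrals=dihedrals,
                                 bond_labels=blab, angle_labels=alab,
                                 dihedral_labels=dlab)


# ---------------------------------------------------------------------------
# per-frame internal coordinates


def bond_lengths(coords: np.ndarray, pairs) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    d = coords[:, pairs[:, 1], :] - coords[:, pairs[:, 0], :]
    return np.linalg.norm(d, axis=-1)


def bend_angles(coords: np.ndarray, triples) -> np.ndarray:
    """Angles i-j-k in degrees; collinear/coincident geometries give NaN."""
    triples = np.asarray(triples, dtype=int).reshape(-1, 3)
    u = coords[:, triples[:, 0], :] - coords[:, triples[:, 1], :]
    v = coords[:, triples[:, 2], :] - coords[:, triples[:, 1], :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where((nu > _DEGENERACY_EPS) & (nv > _DEGENERACY_EPS), ang, np.nan)


def torsion_angles(coords: np.ndarray, quads) -> np.ndarray:
    """Proper dihedrals i-j-k-l in degrees, in (-180, 180], cis = 0.

    Right-handed (IUPAC) sign convention.  Frames where three consecutive
    atoms are collinear are flagged NaN rather than silently zeroed.
    """
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    b1 = coords[:, quads[:, 1], :] - coords[:, quads[:, 0], :]
    b2 = coords[:, quads[:, 2], :] - coords[:, quads[:, 1], :]
    b3 = coords[:, quads[:, 3], :] - coords[:, quads[:, 2], :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(b2n > 0, b2n, 1.0)
    phi = np.degrees(np.arctan2(y, x))
    phi = np.where(phi <= -180.0, phi + 360.0, phi)
    degenerate = (np.linalg.norm(n1, axis=-1) < _DEGENERACY_EPS) | \
                 (np.linalg.norm(n2, axis=-1) < _DEGENERACY_EPS)
    return np.where(degenerate, np.nan, phi)


@dataclass
class CoordinateTable:
    """Per-frame internal-coordinate values, one column per coordinate."""

    bonds: pd.DataFrame
    angles: pd.DataFrame
    dihedrals: pd.DataFrame

    @property
    def n_frames(self) -> int:
        for df in (self.bonds, self.angles, self.dihedrals):
            if len(df.columns):
                return len(df)
        return 0


def internal_coordinates(
    traj: GeometryTrajectory, defs: InternalCoordinateSet
) -> CoordinateTable:
    """Evaluate every defined bond/angle/dihedral in every frame."""
    defs.validate_for(traj)
    c = traj.coords
    bonds = bond_lengths(c, defs.bonds) if defs.bonds else np.empty((c.shape[0], 0))
    angles = bend_angles(c, defs.angles) if defs.angles else np.empty((c.shape[0], 0))
    dihedrals = torsion_angles(c, defs.dihedrals) if defs.dihedrals else \
        np.empty((c.shape[0], 0))
    return CoordinateTable(
        bonds=pd.DataFrame(bonds, columns=defs.bond_labels),
        angles=pd.DataFrame(angles, columns=defs.angle_labels),
        dihedrals=pd.DataFrame(dihedrals, columns=defs.dihedral_labels),
    )


# ---------------------------------------------------------------------------
# ensemble statistics


def circular_mean_deg(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    """Circular mean in degrees on (-180, 180] (atan2 of mean sin/cos)."""
    rad = np.radians(np.asarray(angles, dtype=float))
    mean = np.degrees(np.arctan2(np.nanmean(np.sin(rad), axis=axis),
                                 np.nanmean(np.cos(rad), axis=axis)))
    return np.where(mean <= -180.0, mean + 360.0, mean)


def circular_std_deg(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    rad = np.radians(np.asarray(angles, dtype=float))
    r = np.hypot(np.nanmean(np.sin(rad), axis=axis),
                 np.nanmean(np.cos(rad), axis=axis))
    r = np.clip(r, 1e-300, 1.0)
    return np.degrees(np.sqrt(-2.0 * np.log(r)))


def wrap_angle_difference(a, b) -> np.ndarray:
    """Smallest absolute angular difference |a - b| on the circle, <= 180."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


@dataclass
class EnsembleStats:
    """Per-coordinate ensemble means and spreads.

    ``table`` columns: kind (bond|angle|dihedral), label, mean, spread.
    Dihedral means/spreads are circular.
    """

    table: pd.DataFrame
    n_frames: int


def ensemble_stats(coords: CoordinateTable) -> EnsembleStats:
    rows = []
    for label in coords.bonds.columns:
        v = coords.bonds[label].to_numpy()
        rows.append(("bond", label, np.nanmean(v), np.nanstd(v)))
    for label in coords.angles.columns:
        v = coords.angles[label].to_numpy()
        rows.append(("angle", label, np.nanmean(v), np.nanstd(v)))
    for label in coords.dihedrals.columns:
        v = coords.dihedrals[label].to_numpy()
        rows.append(("dihedral", label,
                     float(circular_mean_deg(v)), float(circular_std_deg(v))))
    table = pd.DataFrame(rows, columns=["kind", "label", "mean", "spread"])
    return EnsembleStats(table=table, n_frames=coords.n_frames)


def ensemble_deviation(stats_a: EnsembleStats, stats_b: EnsembleStats) -> pd.DataFrame:
    """Absolute per-coordinate mean deviations |mean_A - mean_B|.

    Dihedral differences are taken on the circle (never exceed 180 deg).
    Coordinate sets must match exactly.
    """
    a, b = stats_a.table, stats_b.table
    if len(a) != len(b) or not (a["kind"].values == b["kind"].values).all() \
            or not (a["label"].values == b["label"].values).all():
        raise ValueError("ensembles define different coordinate sets")
    dev = np.abs(a["mean"].to_numpy() - b["mean"].to_numpy())
    circ = a["kind"].to_numpy() == "dihedral"
    dev[circ] = wrap_angle_difference(a["mean"].to_numpy()[circ],
                                      b["mean"].to_numpy()[circ])
    return pd.DataFrame({"kind": a["kind"], "label": a["label"],
                         "abs_deviation": dev})


def dihedral_distribution(
    traj: GeometryTrajectory,
    dihedral: tuple[int, int, int, int],
    bins: int = 36,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one dihedral over (-180, 180], normalized to unit mass.

    Returns ``(edges, mass)`` with ``len(edges) = bins + 1``; angles are
    wrapped periodically before binning.
    """
    phi = torsion_angles(traj.coords, [tuple(dihedral)])[:, 0]
    phi = phi[np.isfinite(phi)]
    wrapped = ((phi + 180.0) % 360.0) - 180.0  # (-180, 180] up to the seam
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, _ = np.histogram(wrapped, bins=edges)
    mass = counts / counts.sum() if counts.sum() else counts.astype(float)
    return edges, mass


# ---------------------------------------------------------------------------
# radial distribution functions


def rdf(
    traj: GeometryTrajectory,
    centers,
    targets,
    r_max: float,
    n_bins: int = 100,
    pbc: bool = True,
    volume: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shell-normalized radial distribution function g(r).

    g(r) = counts / (n_frames * n_centers * rho * 4 pi r^2 dr) with rho the
    target number density.  Under PBC (orthorhombic box required) distances
    use the minimum image and rho = n_targets / V_box; without PBC supply
    ``volume`` or the sphere of radius ``r_max`` is used.  Self pairs
    (same atom index) are excluded.  Returns ``(bin_centers, g)``.
    """
    centers = np.asarray(centers, dtype=int)
    targets = np.asarray(targets, dtype=int)
    if centers.size == 0 or targets.size == 0:
        raise ValueError("empty center or target selection")
    if pbc:
        if traj.box is None:
            raise ValueError("PBC requested but trajectory has no box; "
                             "pass pbc=False for open boundaries")
        if r_max > traj.box.min() / 2.0:
            raise ValueError(
                f"r_max {r_max} exceeds half the shortest box edge "
                f"{traj.box.min() / 2.0:.3f}")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    overlap = centers[:, None] == targets[None, :]
    for f in range(traj.n_frames):
        box = None
        if pbc:
            box = np.array([*traj.box[f], 90.0, 90.0, 90.0], dtype=np.float32)
        d = distance_array(
            traj.coords[f, centers].astype(np.float32),
            traj.coords[f, targets].astype(np.float32),
            box=box,
        )
        d = d[~overlap]
        h, _ = np.histogram(d, bins=edges)
        counts += h
    if pbc:
        vol = float(np.prod(traj.box.mean(axis=0)))
    else:
        vol = volume if volume is not None else 4.0 / 3.0 * np.pi * r_max**3
    rho = targets.size / vol
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    dr = edges[1] - edges[0]
    shell = 4.0 * np.pi * r_mid**2 * dr
    g = counts / (traj.n_frames * centers.size * rho * shell)
    return r_mid, g
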