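"""Diabatic labelling of adiabatic excited states from transition dipoles.

The two lowest pi-pi* states of indole-like chromophores (Platt's L_a and
L_b) swap energetic order along an MD trajectory.  Each frame's
energy-ordered (adiabatic) states are mapped onto fixed diabatic labels by
comparing transition-dipole orientations against reference molecular axes
— for tryptophan/3-methyl-indole the NE1->CE3 vector identifies L_a and
CG->CZ2 identifies L_b (Amber atom names).

Transition-dipole signs from excited-state calculations are arbitrary, so
all angles are folded to [0, 90] degrees.  The per-frame assignment is the
bijection minimizing the summed deviation angle over the full cost matrix
(optimal matching, not greedy).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gap_io import GapTrajectory, GeometryTrajectory

DEFAULT_MIXING_THRESHOLD_DEG = 60.0


@dataclass
class ReferenceAxes:
    """Reference orientation axes, one per diabatic label.

    Axes are either fixed 3-vectors or atom-name/index pairs resolved
    against each frame of a geometry trajectory (the molecular frame
    rotates during MD, so per-frame resolution is the default when a
    geometry is available).
    """

    labels: tuple[str, ...]
    vectors: np.ndarray | None = None  # (n_labels, 3)
    atom_pairs: list[tuple] | None = None  # [(a, b), ...] names or 0-based ints

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if (self.vectors is None) == (self.atom_pairs is None):
            raise ValueError("give exactly one of vectors or atom_pairs")
        if self.vectors is not None:
            self.vectors = np.asarray(self.vectors, dtype=float)
            if self.vectors.shape != (len(self.labels), 3):
                raise ValueError("need one 3-vector per label")
            if np.any(np.linalg.norm(self.vectors, axis=1) == 0):
                raise ValueError("reference axes must be non-zero")
        else:
            if len(self.atom_pairs) != len(self.labels):
                raise ValueError("need one atom pair per label")

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def resolve(self, geometry: GeometryTrajectory | None = None) -> np.ndarray:
        """Return axes as an ``(n_frames_or_1, n_labels, 3)`` array."""
        if self.vectors is not None:
            return self.vectors[None, :, :]
        if geometry is None:
            raise ValueError("atom-pair axes require a geometry trajectory")
        idx = []
        for a, b in self.atom_pairs:
            pair = []
            for atom in (a, b):
                if isinstance(atom, str):
                    matches = [i for i, n in enumerate(geometry.atom_names)
                               if n == atom]
                    if len(matches) != 1:
                        raise ValueError(
                            f"atom name {atom!r} matches {len(matches)} atoms")
                    pair.append(matches[0])
                else:
                    if not 0 <= atom < geometry.n_atoms:
                        raise ValueError(f"atom index {atom} out of range")
                    pair.append(int(atom))
            idx.append(pair)
        idx = np.asarray(idx)  # (n_labels, 2)
        axes = geometry.coords[:, idx[:, 1], :] - geometry.coords[:, idx[:, 0], :]
        if np.any(np.linalg.norm(axes, axis=-1) == 0):
            raise ValueError("coincident atoms give a zero reference axis")
        return axes


@dataclass
class StateAssignment:
    """Per-frame bijection from diabatic labels to adiabatic state indices.

    ``mapping[f, l]`` is the adiabatic (energy-ordered) state index carrying
    label ``labels[l]`` at frame ``f``.  ``deviation_angles`` holds the
    folded angle (degrees) between that state's dipole and the label's
    reference axis; ``mixing_flags`` marks frames whose best total deviation
    exceeds the mixing threshold.
    """

    labels: tuple[str, ...]
    mapping: np.ndarray  # (n_frames, n_labels) int
    deviation_angles: np.ndarray  # (n_frames, n_labels) degrees
    mixing_flags: np.ndarray  # (n_frames,) bool
    mixing_threshold_deg: float = DEFAULT_MIXING_THRESHOLD_DEG

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=int)
        n_labels = self.mapping.shape[1]
        sorted_rows = np.sort(self.mapping, axis=1)
        if not np.all(sorted_rows == np.arange(n_labels)):
            raise ValueError("mapping rows must each be a permutation")
        if np.any(self.deviation_angles < 0) or np.any(self.deviation_angles > 90):
            raise ValueError("deviation angles must lie in [0, 90] degrees")

    @property
    def n_frames(self) -> int:
        return self.mapping.shape[0]


def deviation_angle(dipole: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Angle (degrees) between a dipole and an axis, folded to [0, 90].

    Computed as arccos(|d.a| / (|d| |a|)); the fold removes the arbitrary
    sign of computed transition dipoles.  Broadcasts over leading axes.
    """
    d = np.asarray(dipole, dtype=float)
    a = np.asarray(axis, dtype=float)
    dn = np.linalg.norm(d, axis=-1)
    an = np.linalg.norm(a, axis=-1)
    if np.any(dn == 0) or np.any(an == 0):
        raise ValueError("zero-norm vector passed to deviation_angle")
    cosang = np.abs(np.sum(d * a, axis=-1)) / (dn * an)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def assign_states(
    traj: GapTrajectory,
    refs: ReferenceAxes,
    geometry: GeometryTrajectory | None = None,
    mixing_threshold_deg: float = DEFAULT_MIXING_THRESHOLD_DEG,
    continuity_penalty_deg: float = 0.0,
) -> StateAssignment:
    """Assign diabatic labels to the adiabatic states of every frame.

    Per frame the label<->state bijection minimizing the total deviation
    angle over the full cost matrix is chosen.  With a positive
    ``continuity_penalty_deg`` a bijection differing from the previous
    frame's is additionally penalized by that amount per swapped label
    (off by default: frames are independent snapshots).
    """
    if traj.dipoles is None:
        raise ValueError(
            "trajectory has no transition dipoles; orientation-based "
            "assignment is impossible — fall back to energy ordering "
            "(identity mapping) explicitly if that is acceptable"
        )
    if traj.n_states < refs.n_labels:
        raise ValueError("fewer adiabatic states than diabatic labels")
    axes = refs.resolve(geometry)
    if axes.shape[0] not in (1, traj.n_frames):
        raise ValueError("geometry frame count does not match gap trajectory")

    n_frames, n_labels = traj.n_frames, refs.n_labels
    # cost[f, s, l]: angle between state s dipole and label l axis
    cost = deviation_angle(traj.dipoles[:, :, None, :], axes[:, None, :, :])

    mapping = np.empty((n_frames, n_labels), dtype=int)
    totals = np.empty(n_frames)
    prev = None
    for f in range(n_frames):
        c = cost[f].copy()
        if continuity_penalty_deg > 0 and prev is not None:
            for lab in range(n_labels):
                mask = np.ones(c.shape[0], dtype=bool)
                mask[prev[lab]] = False
                c[mask, lab] += continuity_penalty_deg
        rows, cols = linear_sum_assignment(c)
        perm = np.empty(n_labels, dtype=int)
        perm[cols] = rows
        mapping[f] = perm
        totals[f] = cost[f][perm, np.arange(n_labels)].sum()
        prev = perm
    deviations = cost[np.arange(n_frames)[:, None], mapping, np.arange(n_labels)]
    return StateAssignment(
        labels=refs.labels,
        mapping=mapping,
        deviation_angles=deviations,
        mixing_flags=totals > mixing_threshold_deg,
        mixing_threshold_deg=mixing_threshold_deg,
    )


def relabel_energies(traj: GapTrajectory, assignment: StateAssignment) -> GapTrajectory:
    """Reorder state columns so column ``l`` is diabatic label ``l`` everywhere."""
    if assignment.n_frames != traj.n_frames:
        raise ValueError("assignment and trajectory frame counts differ")
    rows = np.arange(traj.n_frames)[:, None]
    energies = traj.energies[rows, assignment.mapping]
    dipoles = None
    if traj.dipoles is not None:
        dipoles = traj.dipoles[rows, assignment.mapping, :]
    return replace(
        traj,
        energies=energies,
        dipoles=dipoles,
        state_labels=assignment.labels,
    )
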