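"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: stationary
Gaussian-process energy-gap trajectories whose spectral density is
prescribed (a sum of Lorentzian peaks, the same family the broadened
vertical-gradient model produces), transition-dipole series with
controlled orientation noise, geometry ensembles built from internal
coordinates with set distributions, and normal-mode sets.

The gap generator inverts the spectral-density convention: from a target
J(w) the classical autocorrelation is

    C(t) = (2 / beta) * Integral_0^inf [J(w) / w] cos(w t) dw ,

so C(0) = 2 lambda_total / beta, and a Gaussian process with that
covariance is realized by spectral synthesis — independent normal
amplitudes on a dense frequency comb, guaranteeing stationarity and exact
seeded reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .gap_io import GapTrajectory, GeometryTrajectory
from .spectral_density import Acf, SpectralDensity
from .state_tracking import ReferenceAxes
from .vertical_gradient import lorentzian_profile

#: frequency-comb resolution: at least this many points per HWHM
_POINTS_PER_HWHM = 8.0


@dataclass
class BathSpec:
    """Generative specification of a fluctuating energy gap.

    ``peaks`` is a list of ``(center_cm1, hwhm_cm1, lambda_cm1)`` Lorentzian
    contributions to the target spectral density.  Defaults mirror a
    20-ps replica sampled every 5 fs at 300 K, five replicas.
    """

    peaks: list[tuple[float, float, float]]
    temperature: float = 300.0
    dt: float = 5.0  # fs
    n_frames: int = 4000  # 20 ps at 5-fs stride
    n_replicas: int = 5
    seed: int = 0
    baseline_ev: float = 4.5  # mean vertical gap; keeps energies positive

    def __post_init__(self) -> None:
        self.peaks = [tuple(float(x) for x in p) for p in self.peaks]
        if not self.peaks:
            raise ValueError("at least one spectral peak required")
        for c, h, lam in self.peaks:
            if c <= 0 or h <= 0 or lam <= 0:
                raise ValueError("peak centers, HWHMs and lambdas must be positive")
        if self.dt <= 0 or self.n_frames < 2 or self.temperature <= 0:
            raise ValueError("invalid sampling parameters")
        nyq = units.nyquist_wavenumber(self.dt)
        for c, h, lam in self.peaks:
            if c >= nyq:
                raise ValueError(
                    f"peak at {c} cm^-1 violates the Nyquist limit "
                    f"{nyq:.1f} cm^-1 for dt = {self.dt} fs")

    @property
    def total_lambda(self) -> float:
        return float(sum(p[2] for p in self.peaks))

    def c0_ev2(self) -> float:
        """Target variance C(0) = 2 lambda_total / beta, in eV^2."""
        lam_ev = self.total_lambda / units.CM_PER_EV
        return 2.0 * lam_ev / units.beta_ev(self.temperature)


def la_like_spec(seed: int = 0) -> BathSpec:
    """Canonical two-peak bath (the L_a-like case: ~1400 and ~1700 cm^-1)."""
    return BathSpec(peaks=[(1400.0, 15.0, 300.0), (1700.0, 15.0, 150.0)],
                    seed=seed)


def lb_like_spec(seed: int = 0) -> BathSpec:
    """Canonical one-peak bath (the L_b-like case: ~1400 cm^-1 only)."""
    return BathSpec(peaks=[(1400.0, 15.0, 300.0)], seed=seed)


def _j_over_omega(spec: BathSpec, grid: np.ndarray) -> np.ndarray:
    """Target J(w)/w (dimensionless ratio of cm^-1 quantities) on a grid."""
    out = np.zeros_like(grid)
    for c, h, lam in spec.peaks:
        out += lam * lorentzian_profile(grid, c, h)
    return out


def target_sd(spec: BathSpec, freq_grid: np.ndarray | None = None) -> SpectralDensity:
    """The spectral density the generator aims at, on a wavenumber grid."""
    if freq_grid is None:
        hi = max(c + 50.0 * h for c, h, _ in spec.peaks)
        freq_grid = np.arange(0.0, hi, min(h for _, h, _ in spec.peaks) / 4.0)
    grid = np.asarray(freq_grid, dtype=float)
    return SpectralDensity(
        frequencies=grid,
        values=grid * _j_over_omega(spec, grid),
        temperature=spec.temperature,
        provenance="target",
        metadata={"peaks": spec.peaks},
    )


def _quadrature_grid(spec: BathSpec) -> np.ndarray:
    dmin = min(h for _, h, _ in spec.peaks) / _POINTS_PER_HWHM
    hi = max(c + 400.0 * h for c, h, _ in spec.peaks)
    n = int(math.ceil(hi / dmin))
    return (np.arange(n) + 0.5) * dmin


def target_acf(spec: BathSpec, lag_grid: np.ndarray) -> Acf:
    """Exact classical ACF implied by the target spectral density.

    Evaluated by trapezoid-free midpoint quadrature of
    (2/beta) Integral [J/w] cos(wt) dw on a dense comb; C(0) honours the
    sum rule C(0) = 2 lambda_total / beta.
    """
    lags = np.asarray(lag_grid, dtype=float)
    grid = _quadrature_grid(spec)
    weight = _j_over_omega(spec, grid) * (grid[1] - grid[0])  # cm^-1 mass
    omega = units.ANGFREQ_PER_CM * grid  # rad/fs
    kT_ev = 1.0 / units.beta_ev(spec.temperature)
    c = 2.0 * kT_ev / units.CM_PER_EV * (
        np.cos(lags[:, None] * omega[None, :]) @ weight
    )
    return Acf(
        lags=lags,
        values=c,
        n_windows=0,
        window_length=float(lags[-1]),
        temperature=spec.temperature,
        metadata={"provenance": "target", "peaks": spec.peaks},
    )


def _synthesize_series(s: BathSpec, gen: np.random.Generator) -> np.ndarray:
    """FFT spectral synthesis of one zero-mean stationary Gaussian series.

    The frequency comb is commensurate with an oversampled FFT length
    (at least twice the series, and fine enough to resolve every HWHM), so
    each Lorentzian is carried by many independent modes and a single long
    realization's variance converges to the target.
    """
    # comb spacing 1/(M dt) in cm^-1; resolve the narrowest peak too
    min_hwhm = min(h for _, h, _ in s.peaks)
    m_needed = max(
        2 * s.n_frames,
        int(_POINTS_PER_HWHM / (min_hwhm * s.dt * units.C_CM_PER_FS)),
    )
    m = 1 << (m_needed - 1).bit_length()
    dnu = 1.0 / (m * s.dt * units.C_CM_PER_FS)  # cm^-1 per FFT bin
    nu = np.arange(1, m // 2) * dnu  # skip DC and Nyquist bins
    var = (2.0 / units.beta_ev(s.temperature) / units.CM_PER_EV) * \
        _j_over_omega(s, nu) * dnu  # eV^2 per mode
    sigma = np.sqrt(var)
    a = gen.standard_normal(nu.size) * sigma
    b = gen.standard_normal(nu.size) * sigma
    coef = np.zeros(m // 2 + 1, dtype=complex)
    coef[1:m // 2] = (m / 2.0) * (a - 1j * b)
    return np.fft.irfft(coef, m)[: s.n_frames]


def generate_gap_trajectory(
    spec: BathSpec | list[BathSpec],
    replica_index: int = 0,
    rng: np.random.Generator | None = None,
) -> GapTrajectory:
    """One replica of a stationary Gaussian gap process per bath spec.

    Spectral synthesis: on a frequency comb resolving every peak's HWHM,
    each mode gets independent N(0, sigma_m^2) cosine/sine amplitudes with
    sigma_m^2 equal to the spectral mass (2/beta) [J/w] dw of the bin; the
    sum is an exactly Gaussian, exactly stationary series whose covariance
    converges to :func:`target_acf` as the comb refines.  A second spec in
    a list becomes a second state column.  Reproducible per (seed, replica).
    """
    specs = [spec] if isinstance(spec, BathSpec) else list(spec)
    base = specs[0]
    for s in specs[1:]:
        if (s.dt, s.n_frames, s.temperature) != (base.dt, base.n_frames,
                                                 base.temperature):
            raise ValueError("all state specs must share dt, n_frames, T")
    times = np.arange(base.n_frames) * base.dt
    energies = np.empty((base.n_frames, len(specs)))
    for col, s in enumerate(specs):
        gen = rng if rng is not None else np.random.default_rng(
            [s.seed, replica_index, col])
        energies[:, col] = s.baseline_ev + _synthesize_series(s, gen)
    return GapTrajectory(
        times=times,
        energies=energies,
        temperature=base.temperature,
        replica_id=f"synthetic-{replica_index}",
    )


def generate_replicas(spec: BathSpec | list[BathSpec]) -> list[GapTrajectory]:
    """All replicas the spec asks for (independent seeds per replica)."""
    base = spec if isinstance(spec, BathSpec) else spec[0]
    return [generate_gap_trajectory(spec, replica_index=r)
            for r in range(base.n_replicas)]


# ---------------------------------------------------------------------------
# dipole series with controlled orientation noise


def cone_mean_angle(halfangle_deg: float, distribution: str = "shell") -> float:
    """Analytic mean deviation angle of the cone sampler, in degrees.

    ``shell``: directions on the cone surface — the mean deviation equals
    the half-angle.  ``cap``: uniform over the solid angle of the cap —
    mean = (sin a - a cos a) / (1 - cos a).
    """
    a = math.radians(halfangle_deg)
    if distribution == "shell":
        return halfangle_deg
    if distribution == "cap":
        return math.degrees((math.sin(a) - a * math.cos(a)) / (1.0 - math.cos(a)))
    raise ValueError("distribution must be 'shell' or 'cap'")


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2, u


def generate_dipole_series(
    axes: ReferenceAxes,
    cone_halfangle: float | list[float],
    n_frames: int,
    swap_schedule=None,
    seed: int = 0,
    distribution: str = "shell",
    random_sign: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit transition dipoles scattered in cones around reference axes.

    Per label, dipole directions deviate from the axis by the cone sampler
    (default ``shell``: fixed polar angle equal to ``cone_halfangle``, so
    that parameter IS the mean deviation; ``cap`` draws uniformly inside
    the cone).  Azimuths are uniform; ``random_sign`` flips each dipole's
    overall sign at random, mimicking the arbitrary phase of computed
    transition dipoles.  At frames in ``swap_schedule`` the adiabatic order
    of the two states is swapped.

    Returns ``(dipoles, truth)``: dipoles with shape
    ``(n_frames, n_labels, 3)`` in adiabatic order, and the ground-truth
    mapping ``truth[f, l]`` = adiabatic index carrying label ``l``.
    """
    if axes.vectors is None:
        raise ValueError("dipole generation needs fixed reference vectors")
    n_labels = axes.n_labels
    halfangles = np.broadcast_to(np.asarray(cone_halfangle, dtype=float),
                                 (n_labels,))
    if np.any(halfangles <= 0) or np.any(halfangles >= 90):
        raise ValueError("cone half-angles must lie in (0, 90) degrees")
    rng = np.random.default_rng(seed)
    swap = np.zeros(n_frames, dtype=bool)
    if swap_schedule is not None:
        swap[np.asarray(list(swap_schedule), dtype=int)] = True

    dipoles = np.empty((n_frames, n_labels, 3))
    truth = np.tile(np.arange(n_labels), (n_frames, 1))
    for l in range(n_labels):
        e1, e2, u = _orthonormal_frame(axes.vectors[l])
        alpha = math.radians(halfangles[l])
        if distribution == "shell":
            theta = np.full(n_frames, alpha)
        elif distribution == "cap":
            theta = np.arccos(rng.uniform(math.cos(alpha), 1.0, n_frames))
        else:
            raise ValueError("distribution must be 'shell' or 'cap'")
        phi = rng.uniform(0.0, 2.0 * np.pi, n_frames)
        d = (np.sin(theta)[:, None] *
             (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
             + np.cos(theta)[:, None] * u)
        if random_sign:
            d *= rng.choice([-1.0, 1.0], size=(n_frames, 1))
        dipoles[:, l, :] = d
    if n_labels >= 2 and swap.any():
        dipoles[swap] = dipoles[swap][:, ::-1, :]
        truth[swap] = truth[swap][:, ::-1]
    return dipoles, truth


# ---------------------------------------------------------------------------
# geometry ensembles from internal-coordinate distributions


@dataclass
class ChainAtom:
    """Z-matrix-style atom: distributions of its defining internal coordinates.

    ``bond`` = (mean_A, sigma_A) to the previous atom; ``angle`` =
    (mean_deg, sigma_deg) over the previous two; ``dihedral`` = list of von
    Mises modes ``(mean_deg, kappa, weight)`` over the previous three
    (``kappa = inf`` pins the value).  Leading atoms omit what they cannot
    define.
    """

    element: str = "C"
    bond: tuple[float, float] | None = None
    angle: tuple[float, float] | None = None
    dihedral: list[tuple[float, float, float]] | None = None


def _place_atom(a, b, c, r, theta_deg, phi_deg):
    """Natural-extension placement: position D with |CD| = r,
    angle(B,C,D) = theta and dihedral(A,B,C,D) = phi (IUPAC sign)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("collinear reference atoms in chain build")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(phi),
        r * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _draw_dihedral(modes, rng) -> float:
    weights = np.array([w for _, _, w in modes], dtype=float)
    weights /= weights.sum()
    mu, kappa, _ = modes[rng.choice(len(modes), p=weights)]
    if not np.isfinite(kappa):
        return float(mu)
    phi = math.degrees(rng.vonmises(math.radians(mu), kappa))
    return float(((phi + 180.0) % 360.0) - 180.0)


def generate_geometry_ensemble(
    chain: list[ChainAtom],
    n_frames: int,
    seed: int = 0,
    box: float | None = None,
) -> GeometryTrajectory:
    """Build a chain-molecule ensemble frame by frame from internal coordinates.

    Bonds and angles are independent Gaussian draws, dihedrals von Mises
    mixtures; each frame is assembled by natural extension, so realized
    ensemble statistics converge to the specified distributions.
    """
    if len(chain) < 2:
        raise ValueError("chain needs at least 2 atoms")
    for i, atom in enumerate(chain):
        if i >= 1:
            if atom.bond is None or atom.bond[0] <= 0 or atom.bond[1] < 0:
                raise ValueError(f"atom {i}: bond mean must be > 0, sigma >= 0")
        if i >= 2:
            if atom.angle is None or not 0 < atom.angle[0] < 180 or atom.angle[1] < 0:
                raise ValueError(f"atom {i}: angle mean must lie in (0, 180)")
        if i >= 3 and not atom.dihedral:
            raise ValueError(f"atom {i}: dihedral modes required")
    rng = np.random.default_rng(seed)
    n_atoms = len(chain)
    coords = np.zeros((n_frames, n_atoms, 3))
    for f in range(n_frames):
        pos = np.zeros((n_atoms, 3))
        r1 = rng.normal(*chain[1].bond)
        pos[1] = [r1, 0.0, 0.0]
        if n_atoms > 2:
            r2 = rng.normal(*chain[2].bond)
            a2 = math.radians(rng.normal(*chain[2].angle))
            pos[2] = pos[1] + [-r2 * math.cos(a2), r2 * math.sin(a2), 0.0]
        for i in range(3, n_atoms):
            r = rng.normal(*chain[i].bond)
            theta = rng.normal(*chain[i].angle)
            phi = _draw_dihedral(chain[i].dihedral, rng)
            pos[i] = _place_atom(pos[i - 3], pos[i - 2], pos[i - 1],
                                 r, theta, phi)
        coords[f] = pos
    box_arr = None
    if box is not None:
        box_arr = np.full((n_frames, 3), float(box))
    elements = [a.element for a in chain]
    names = [f"{a.element}{i + 1}" for i, a in enumerate(chain)]
    return GeometryTrajectory(atom_names=names, elements=elements,
                              coords=coords, box=box_arr)


def generate_ideal_gas(
    n_atoms: int, box: float, n_frames: int, seed: int = 0, element: str = "O"
) -> GeometryTrajectory:
    """Uniform random points in a cubic box — the g(r) = 1 reference."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_frames, n_atoms, 3))
    return GeometryTrajectory(
        atom_names=[f"{element}{i + 1}" for i in range(n_atoms)],
        elements=[element] * n_atoms,
        coords=coords,
        box=np.full((n_frames, 3), float(box)),
    )
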