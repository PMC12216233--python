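"""Energy-gap autocorrelation functions and spectral densities.

The central quantities:

* the classical autocorrelation function of gap fluctuations, estimated
  per window with the unbiased lag estimator

      C(t_j) = 1/(N-j) * sum_{k} dE(t_{k+j}) dE(t_k),

  averaged over windows (4 ps windows by default downstream);

* the spectral density of vibronic coupling

      J(w) = (beta * w / pi) * Integral_0^inf C(t) cos(w t) dt,

  with beta = 1/(k_B T), evaluated by trapezoidal quadrature on the
  stored lag grid.  With C in eV^2 and beta in eV^-1 the bookkeeping
  yields J in cm^-1 on a wavenumber grid.

The convention implies the sum rule  Integral J(w)/w dw = beta * C(0) / 2,
i.e. the reorganization energy is fixed by the gap variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from . import units

DEFAULT_FREQ_GRID = np.arange(0.0, 2501.0, 1.0)  # cm^-1


@dataclass
class Acf:
    """Window-averaged classical autocorrelation of gap fluctuations."""

    lags: np.ndarray  # fs, starting at 0 with the trajectory spacing
    values: np.ndarray  # eV^2
    n_windows: int
    window_length: float  # fs
    temperature: float = 300.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValueError("lags and values must be equal-length 1-D arrays")
        if self.lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if self.values[0] < 0:
            raise ValueError("C(0) is a variance and cannot be negative")

    @property
    def c0(self) -> float:
        """Zero-lag value C(0) = variance of the fluctuations, eV^2."""
        return float(self.values[0])

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class SpectralDensity:
    """Spectral density J on a wavenumber grid, in energy units (cm^-1)."""

    frequencies: np.ndarray  # cm^-1, strictly increasing, starting at 0
    values: np.ndarray  # cm^-1
    temperature: float
    provenance: str = "md"  # md | vg | target
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequency grid and values must match")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral density values must be finite")
        if self.frequencies[0] == 0.0 and self.values[0] != 0.0:
            raise ValueError("J(0) must vanish (beta*omega prefactor)")


def _acf_fft(x: np.ndarray) -> np.ndarray:
    """Raw lag sums sum_k x[k+j] x[k] for j = 0..N-1, via FFT."""
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    return np.fft.irfft(fx * np.conj(fx), nfft)[:n]


def window_acf(
    series: np.ndarray,
    dt: float,
    window_length: float,
    overlap: float = 0.0,
    mean_subtraction: str = "window",
    estimator: str = "unbiased",
    temperature: float = 300.0,
    max_lag: float | None = None,
) -> Acf:
    """Window-averaged autocorrelation of an energy series.

    The series (eV) is cut into windows of ``window_length`` fs; within each
    window the mean is removed (``mean_subtraction='global'`` removes a
    single overall mean instead) and the lag covariance is estimated with
    the unbiased 1/(N-j) normalization (``estimator='biased'`` selects the
    1/N form, which trades bias for variance at large lags).  Windows are
    non-overlapping unless ``overlap`` (fraction in [0, 1)) says otherwise.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if mean_subtraction not in ("window", "global"):
        raise ValueError("mean_subtraction must be 'window' or 'global'")
    if estimator not in ("unbiased", "biased"):
        raise ValueError("estimator must be 'unbiased' or 'biased'")
    n_win = int(round(window_length / dt))
    if n_win < 2:
        raise ValueError("window must span at least 2 frames")
    n = series.size
    if n_win > n:
        raise ValueError(
            f"window of {n_win} frames longer than series of {n} frames")

    if mean_subtraction == "global":
        series = series - series.mean()
    stride = max(1, int(round(n_win * (1.0 - overlap))))
    starts = range(0, n - n_win + 1, stride)

    acc = np.zeros(n_win)
    n_windows = 0
    for s in starts:
        w = series[s:s + n_win]
        if mean_subtraction == "window":
            w = w - w.mean()
        acc += _acf_fft(w)
        n_windows += 1
    if n_windows < 1:
        raise ValueError("series too short for a single complete window")
    norm = (n_win - np.arange(n_win)) if estimator == "unbiased" else n_win
    values = acc / (n_windows * norm)
    lags = np.arange(n_win) * dt
    if max_lag is not None:
        keep = lags <= max_lag
        lags, values = lags[keep], values[keep]
    return Acf(
        lags=lags,
        values=values,
        n_windows=n_windows,
        window_length=window_length,
        temperature=temperature,
        metadata={
            "mean_subtraction": mean_subtraction,
            "estimator": estimator,
            "overlap": overlap,
        },
    )


def average_acfs(acfs: list[Acf]) -> Acf:
    """Pool window-ACFs across replicas (window-count-weighted average)."""
    if not acfs:
        raise ValueError("no ACFs to average")
    ref = acfs[0]
    for a in acfs[1:]:
        if a.lags.shape != ref.lags.shape or not np.allclose(a.lags, ref.lags):
            raise ValueError("replica ACFs must share one lag grid")
    weights = np.array([a.n_windows for a in acfs], dtype=float)
    values = sum(w * a.values for w, a in zip(weights, acfs)) / weights.sum()
    return Acf(
        lags=ref.lags.copy(),
        values=values,
        n_windows=int(weights.sum()),
        window_length=ref.window_length,
        temperature=ref.temperature,
        metadata=dict(ref.metadata, n_replicas=len(acfs)),
    )


def acf_to_sd(
    acf: Acf,
    temperature: float | None = None,
    freq_grid: np.ndarray | None = None,
    taper_tau: float | None = None,
) -> SpectralDensity:
    """Cosine-transform an ACF into the spectral density J (cm^-1).

    J(w) = (beta w / pi) * trapezoid of C(t) cos(w t) over the stored lags,
    optionally damping C by exp(-t/taper_tau) to tame noisy tails (no taper
    by default).  ``temperature`` defaults to the ACF's own.
    """
    T = acf.temperature if temperature is None else temperature
    if T <= 0:
        raise ValueError("temperature must be positive")
    grid = DEFAULT_FREQ_GRID.copy() if freq_grid is None else \
        np.asarray(freq_grid, dtype=float)
    c = acf.values
    if taper_tau is not None:
        if taper_tau <= 0:
            raise ValueError("taper time constant must be positive")
        c = c * np.exp(-acf.lags / taper_tau)
    omega = units.ANGFREQ_PER_CM * grid  # rad/fs
    # (n_freq, n_lag) cosine kernel; trapezoid over the uniform lag grid
    kernel = np.cos(omega[:, None] * acf.lags[None, :])
    integral = np.trapezoid(kernel * c[None, :], acf.lags, axis=1)  # eV^2 fs
    J = units.beta_ev(T) * omega / np.pi * integral * units.CM_PER_EV
    return SpectralDensity(
        frequencies=grid,
        values=J,
        temperature=T,
        provenance="md",
        metadata=dict(acf.metadata, taper_tau=taper_tau,
                      n_windows=acf.n_windows,
                      window_length=acf.window_length),
    )


def _j_over_omega(sd: SpectralDensity) -> np.ndarray:
    """J(w)/w on the grid, with the w->0 limit taken as the first finite ratio."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd.frequencies > 0,
                         sd.values / np.where(sd.frequencies > 0,
                                              sd.frequencies, 1.0), np.nan)
    if sd.frequencies[0] == 0.0:
        finite = np.nonzero(np.isfinite(ratio))[0]
        ratio[0] = ratio[finite[0]] if finite.size else 0.0
    return ratio


def reorganization_energy(sd: SpectralDensity, omega_min: float = 0.0) -> float:
    """Reorganization energy Integral J(w)/w dw above ``omega_min``, cm^-1."""
    if omega_min < 0:
        raise ValueError("omega_min must be non-negative")
    ratio = _j_over_omega(sd)
    mask = sd.frequencies >= omega_min
    return float(np.trapezoid(ratio[mask], sd.frequencies[mask]))


def find_peaks(
    sd: SpectralDensity,
    min_prominence: float = 0.05,
    smooth_sigma_cm1: float | None = None,
) -> pd.DataFrame:
    """Locate J's local maxima and integrate each peak's reorganization energy.

    ``min_prominence`` is a fraction of max(J).  Per-peak lambda is
    Integral J/w dw between the flanking minima (grid edges for the outer
    peaks), evaluated on the raw J.  For statistically noisy spectra a
    Gaussian pre-smoothing of width ``smooth_sigma_cm1`` keeps sampling
    wiggles from splitting a physical band into spurious sub-peaks; peak
    locations and flanking minima are then taken on the smoothed curve.
    Returns a table with columns ``center_cm1``, ``height_cm1``,
    ``lambda_cm1``.
    """
    y = sd.values
    if smooth_sigma_cm1 is not None:
        step = np.median(np.diff(sd.frequencies))
        y = scipy.ndimage.gaussian_filter1d(sd.values,
                                            smooth_sigma_cm1 / step)
    jmax = y.max(initial=0.0)
    empty = pd.DataFrame(columns=["center_cm1", "height_cm1", "lambda_cm1"])
    if jmax <= 0:
        return empty
    idx, _ = scipy.signal.find_peaks(y, prominence=min_prominence * jmax)
    if idx.size == 0:
        return empty
    # flanking minima between consecutive peaks; grid ends outside
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(a + int(np.argmin(y[a:b + 1])))
    bounds.append(sd.frequencies.size - 1)
    ratio = _j_over_omega(sd)
    rows = []
    for k, p in enumerate(idx):
        lo, hi = bounds[k], bounds[k + 1]
        lam = float(np.trapezoid(ratio[lo:hi + 1], sd.frequencies[lo:hi + 1]))
        rows.append((float(sd.frequencies[p]), float(sd.values[p]), lam))
    return pd.DataFrame(rows, columns=["center_cm1", "height_cm1", "lambda_cm1"])


# ---------------------------------------------------------------------------
# text output (two-column data + JSON sidecar with full settings)


def write_spectral_density(sd: SpectralDensity, path) -> None:
    path = str(path)
    arr = np.column_stack([sd.frequencies, sd.values])
    np.savetxt(path, arr, header="frequency_cm-1 J_cm-1", fmt="%.10g")
    sidecar = {
        "temperature_K": sd.temperature,
        "provenance": sd.provenance,
        "metadata": sd.metadata,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_spectral_density(path) -> SpectralDensity:
    path = str(path)
    arr = np.loadtxt(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return SpectralDensity(
        frequencies=arr[:, 0],
        values=arr[:, 1],
        temperature=sidecar["temperature_K"],
        provenance=sidecar.get("provenance", "md"),
        metadata=sidecar.get("metadata", {}),
    )


def write_acf(acf: Acf, path) -> None:
    path = str(path)
    arr = np.column_stack([acf.lags, acf.values])
    np.savetxt(path, arr, header="lag_fs C_eV2", fmt="%.12g")
    sidecar = {
        "n_windows": acf.n_windows,
        "window_length_fs": acf.window_length,
        "temperature_K": acf.temperature,
        "metadata": acf.metadata,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_acf(path) -> Acf:
    path = str(path)
    arr = np.loadtxt(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return Acf(
        lags=arr[:, 0],
        values=arr[:, 1],
        n_windows=sidecar["n_windows"],
        window_length=sidecar["window_length_fs"],
        temperature=sidecar["temperature_K"],
        metadata=sidecar.get("metadata", {}),
    )
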