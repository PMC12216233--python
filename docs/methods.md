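# Methods

## Model

The package treats the vertical excitation energy of a chromophore along
an MD trajectory as a stationary stochastic process. Its fluctuation
autocorrelation C(t) and the spectral density of vibronic coupling are
related by the classical (high-temperature) harmonic mapping

    J(ω) = (βω/π) ∫₀^∞ C(t) cos(ωt) dt,        β = 1/(k_B T),

which assumes the bath is harmonic and classical statistics sample it
(the βω/π prefactor is the only quantum correction applied; no
alternative correction factors are offered). Under this convention the
reorganization energy obeys the sum rule

    λ = ∫₀^∞ J(ω)/ω dω = β C(0) / 2,

which the test suite enforces on every ACF → SD pass: the spectral
density must carry exactly the energy the gap variance implies. Units
are fs / eV / cm⁻¹ / D / Å throughout; conversion constants are CODATA
values checked against `scipy.constants`.

### ACF estimation

C(t) is estimated per window with the unbiased lag normalization
C(t_j) = 1/(N−j) Σ_k δE(t_{k+j}) δE(t_k). Defaults, all overridable:

- `window_length` = 4000 fs. A window of length L holds round(L/dt)
  frames with lags 0 … L−dt, so a 20-ps replica yields exactly five
  non-overlapping 4-ps windows.
- `overlap` = 0 (non-overlapping windows).
- mean subtraction is per window, removing slow inter-window drift; a
  global-mean mode is available and recorded in the output metadata.
- estimator `unbiased` (1/(N−j)); the biased 1/N form is available for
  variance control at large lags.
- no taper by default; an optional exponential damping exp(−t/τ) and an
  optional truncation lag are exposed for noisy tails.

Replicas are never concatenated: each replica is windowed separately and
the window-ACFs are pooled (window-count-weighted average) before the
single cosine transform per state. By linearity of the transform this is
equivalent in expectation to averaging spectral densities, at a fifth of
the transform count.

### Transform and summaries

The cosine transform uses trapezoidal quadrature on the uniform lag
grid against a default frequency grid of 0–2500 cm⁻¹ at 1 cm⁻¹ (covering
all features of interest for aromatic chromophores, ≤ ~1850 cm⁻¹).
J(0) = 0 exactly by the ω prefactor. For the reorganization integral
∫ J/ω dω the ω → 0 bin takes the first finite J/ω ratio as its limit.

Quadrature accuracy: the transform of an exponential ACF matches the
Debye closed form (βω/π)·C₀τ/(1+ω²τ²) to < 0.5 % when the lag grid
resolves τ by ≥ 20 points, t_max ≥ 10 τ, and ω·dt stays below ~0.25 rad
per step; the acceptance checks run at 100 points per τ. Note the Debye
J decays only as 1/ω, so its reorganization integral converges slowly
with grid extent — the sum-rule regression therefore uses band-limited
(Lorentzian-peak) fixtures, for which the default grid captures
essentially all spectral mass.

Peak tables come from `scipy.signal.find_peaks` with a prominence
threshold expressed as a fraction of max(J); per-peak λ integrates J/ω
between flanking minima (grid edges outside the outermost peaks). For
MD-derived spectra the finite window count leaves point-to-point
statistical noise that would split one physical band into several
sub-peaks, so `find_peaks` accepts a Gaussian pre-smoothing width
(`smooth_sigma_cm1`); peak locations and band boundaries are then taken
on the smoothed curve while λ is always integrated on the raw J. The
recovery experiments use σ = 15 cm⁻¹ (one peak HWHM) and prominence 0.1.
Smoothing is off by default so constructed, noise-free spectra are
reported exactly.

### Diabatic state tracking

Adiabatic (energy-ordered) states are mapped to diabatic labels per
frame by minimizing the summed deviation angle over the full
label-state cost matrix (optimal assignment via the Hungarian method,
never greedy, so two states cannot claim one label). Deviation angles
are folded to [0°, 90°] because computed transition-dipole signs are
arbitrary. Reference axes are fixed vectors or atom pairs resolved
against each frame's own geometry (the molecular frame rotates during
MD). Frames whose best total deviation exceeds a threshold (default 60°
summed) are flagged as strongly mixed but never excluded — exclusion
policy is the user's. Frames are assigned independently by default; an
optional continuity penalty discourages label swaps between consecutive
frames for users who want temporal smoothing.

### Vertical-gradient spectral densities

In the displaced-harmonic-oscillator picture each ground-state normal
mode k (frequency ω_k in cm⁻¹, dimensionless coordinate q_k) with gap
gradient g_k relaxes by λ_k = g_k²/(2ω_k), with Huang–Rhys factor
S_k = λ_k/ω_k. The stick spectrum is broadened with Lorentzians (the
package treats the HWHM purely as a parameter; 15 and 35 cm⁻¹ are the
standard condensed-phase and gas-phase settings). Normalization pins the
physically meaningful contract: each mode's Lorentzian is normalized
over the frequency window the grid spans, so ∫ J/ω dω over an isolated
peak equals λ_k exactly and totals equal Σλ_k regardless of broadening.
(Normalizing over the infinite line instead loses ~1.4 % of a 1700 cm⁻¹
mode's mass beyond a 2500 cm⁻¹ grid edge at HWHM 35 — enough to break λ
conservation, which is why the window normalization was chosen.) Modes
within 5× HWHM of zero frequency trigger a warning because the
ω-weighting visibly distorts their peak; they are kept.

### Geometry statistics

Bonds (Å), angles and proper dihedrals (degrees, IUPAC right-handed
sign, cis = 0) are computed in float64; geometrically degenerate frames
(collinear atoms) yield NaN rather than a silent zero. Dihedral means
and spreads use circular statistics (atan2 of mean sin/cos;
√(−2 ln R) spread), and ensemble mean differences are taken on the
circle so a 170° vs −170° comparison reports 20°, never 340°. RDFs use
minimum-image distances (orthorhombic boxes only) and the shell
normalization counts/(n_frames · n_centers · ρ · 4πr²Δr); without a box
the user supplies the normalization volume (default: the r_max sphere).
r_max beyond half the shortest box edge is rejected under PBC.

## Synthetic data: what it does and does not emulate

The bath generator inverts the spectral-density convention: from a
target J(ω) — a sum of Lorentzian peaks (center, HWHM, λ), the same
family the broadened VG model produces; any tabulated J can be
substituted — the implied classical ACF is

    C(t) = (2/β) ∫₀^∞ [J(ω)/ω] cos(ωt) dω,     C(0) = 2 λ_total / β,

and a stationary Gaussian process with that covariance is realized by
FFT spectral synthesis: independent N(0, σ_m²) cosine/sine amplitudes on
a frequency comb commensurate with an FFT length of at least twice the
series (and at least 8 points per HWHM), so every peak is carried by
many modes and a single long realization's variance converges to the
target. Default conditions: five replicas of
20 ps at 5-fs stride, 300 K, with independent seeds per (seed, replica,
state). The canonical two-peak bath (1400 cm⁻¹/λ=300 and
1700 cm⁻¹/λ=150, HWHM 15 cm⁻¹) gives an ACF decaying within ~350 fs and
gap fluctuations of σ ≈ 0.05 eV around a 4.5 eV baseline — realistic
magnitudes for an aromatic chromophore in solution.

What passing tests show: the estimator chain (windowing, unbiased lags,
transform, peak integration) is unbiased and internally consistent at
realistic sampling, and its statistical scatter is as expected (a
few percent on integrated intensities at 100 ps total sampling). What
they do not show: anything about real anharmonicity, non-Gaussian gap
statistics, slow conformational gating, or non-classical bath effects —
the generator is Gaussian and stationary by construction.

The dipole generator scatters unit dipoles on a cone about each label's
reference axis. By default the polar angle is fixed at the cone
half-angle (uniform azimuth), so the half-angle parameter *is* the mean
deviation angle — convenient when emulating reported mean-deviation
diagnostics; a uniform solid-angle cap (mean (sin α − α cos α)/(1 − cos α))
is available as `distribution="cap"`. Random overall sign flips mimic
the arbitrary phase of computed transition dipoles. Geometry ensembles
are built atom-by-atom by natural extension from independent Gaussian
bonds/angles and von Mises-mixture dihedrals; they emulate
internal-coordinate distributions, not correlated vibrational dynamics.

## Problem sizes

The test suite and the acceptance script run the full recovery at the
default sampling design — 5 × 4000 frames — which takes about two seconds; the
long-realization variance check uses a single 0.5-ns series. Brute-force
oracle comparisons use series up to 4096 points.

## Known limitations

- Orthorhombic PBC only; no triclinic minimum image.
- No binary trajectory formats (DCD/XTC); no QM-engine log parsing —
  users export plain-text tables.
- Diabatization is orientation-only; no wavefunction-overlap or charge
  criteria.
- The λ-ratio of two recovered peaks carries ~9 % statistical scatter at
  the default 100-ps sampling; longer sampling or more replicas are the
  remedy, not estimator tweaks.
- The ω → 0 treatment of J/ω assumes J grows linearly below the first
  grid point; baths with genuine zero-frequency structure need a finer
  low-frequency grid.
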