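# gapspec

Spectral densities of vibronic coupling from MD trajectories of
excitation-energy fluctuations.

When a chromophore — say the 3-methyl-indole side chain of tryptophan —
is simulated with excited-state calculations along an MD trajectory, the
fluctuations of its vertical excitation energies ΔE(t) encode how the
electronic excitation couples to nuclear motion. `gapspec` turns those
per-frame energies and transition dipoles into the spectral density of
system–bath coupling, the central input for Franck–Condon lineshape and
open-quantum-system models. It is written for molecular-simulation
practitioners who export per-frame excited-state tables from their QM/MM
or ML/MM pipelines.

## What it computes

The classical autocorrelation function of the gap fluctuations is
estimated per trajectory window with the unbiased lag estimator

```
C(t_j) = 1/(N−j) Σ_k  δE(t_{k+j}) δE(t_k),        δE = ΔE − ⟨ΔE⟩
```

averaged over 4-ps windows (and over replicas), and transformed to the
spectral density with the harmonic prefactor

```
J(ω) = (βω/π) ∫₀^∞ C(t) cos(ωt) dt,               β = 1/(k_B T)
```

With C in eV² this yields J in cm⁻¹ on a wavenumber grid, and the
convention fixes the sum rule λ = ∫ J(ω)/ω dω = β C(0)/2 relating the
reorganization energy to the gap variance.

The package covers the full workflow around that transform:

- **gap_io** — self-describing gap tables (`time_fs`, `e_s1_eV`, …,
  optional dipole columns) and multi-frame XYZ / multi-MODEL PDB
  geometries; times in fs, energies in eV, frequencies in cm⁻¹,
  dipoles in D, lengths in Å.
- **state_tracking** — assigns the two lowest adiabatic states of each
  frame to diabatic labels (Platt's L_a / L_b for indoles) from
  transition-dipole orientation against reference axes (NE1→CE3 and
  CG→CZ2 for tryptophan in Amber naming), with sign-folded deviation
  angles and optimal 2×2 matching.
- **spectral_density** — windowed ACF, cosine transform, reorganization
  energies and peak tables.
- **vertical_gradient** — displaced-harmonic-oscillator spectral
  densities from ground-state normal modes (λ_k = g_k²/2ω_k,
  S_k = λ_k/ω_k) broadened with Lorentzians (HWHM 15 or 35 cm⁻¹ are the
  standard settings), normalized so each peak integrates to its mode's λ.
- **geometry_stats** — bond/angle/dihedral ensemble statistics with
  circular means, dihedral distributions, and minimum-image radial
  distribution functions.
- **synthetic** — stationary Gaussian-process gap trajectories with a
  prescribed Lorentzian-peaked spectral density, dipole series with
  controlled orientation noise, and internal-coordinate geometry
  ensembles — every pipeline input with known ground truth.

## Worked example

Generate five 20-ps replicas (5-fs stride, 300 K) of a bath with two
Lorentzian peaks — 1400 cm⁻¹ carrying λ = 300 cm⁻¹ and 1700 cm⁻¹
carrying λ = 150 cm⁻¹ — and recover the spectral density:

```python
import numpy as np
from gapspec import (BathSpec, generate_replicas, window_acf, average_acfs,
                     acf_to_sd, find_peaks, reorganization_energy)

spec = BathSpec(peaks=[(1400.0, 15.0, 300.0), (1700.0, 15.0, 150.0)], seed=0)
replicas = generate_replicas(spec)          # five 20-ps replicas, 5-fs stride
acfs = [window_acf(r.energies[:, 0], r.dt, window_length=4000.0)
        for r in replicas]                  # 4-ps windows, unbiased estimator
pooled = average_acfs(acfs)                 # 25 windows in total
sd = acf_to_sd(pooled)                      # J(w) on 0-2500 cm^-1 at 300 K

print(f"C(0) = {pooled.c0:.3e} eV^2 over {pooled.n_windows} windows")
print(f"reorganization energy = {reorganization_energy(sd):.1f} cm^-1")
peaks = find_peaks(sd, min_prominence=0.1, smooth_sigma_cm1=15.0)
print(peaks.round(1).to_string(index=False))
```

prints

```
C(0) = 2.750e-03 eV^2 over 25 windows
reorganization energy = 428.0 cm^-1
 center_cm1  height_cm1  lambda_cm1
     1396.0     10729.4       284.7
     1698.0      1276.4       143.3
```

The peak centers land within a few cm⁻¹ of the prescribed 1400 and
1700 cm⁻¹; the per-peak reorganization energies recover the prescribed
2:1 ratio to a few percent, and the total (428 cm⁻¹) sits within the
statistical scatter of the prescribed 450 cm⁻¹ — 100 ps of sampling of
15-cm⁻¹-wide bands leaves a several-percent uncertainty on integrated
intensities, which is exactly why such analyses average over windows and
replicas.

## Command line

The same stages run from a shell via a YAML config:

```
gapspec synth    --config synth.yaml    --outdir data/
gapspec md-sd    --config md.yaml       --outdir out/
gapspec vg-sd    --config vg.yaml       --outdir out-vg/
gapspec geometry --config geom.yaml     --outdir out-geom/
```

Every output directory gets a `manifest.json` with the fully resolved
configuration (all defaults included) so any run can be reproduced
bit-for-bit.

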