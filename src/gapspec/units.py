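"""Unit conventions used throughout the package.

The global unit policy is: times in femtoseconds, energies in eV,
frequencies in wavenumbers (cm^-1), transition dipoles in Debye and
lengths in Angstrom.  Spectral densities are reported in cm^-1 (energy
units) on a wavenumber grid.

Conversion constants follow CODATA.
"""

import math

#: 1 eV expressed in wavenumbers (cm^-1), CODATA.
CM_PER_EV = 8065.543937

#: Boltzmann constant in eV/K, CODATA.
KB_EV = 8.617333262e-5

#: Speed of light in cm/fs (2.99792458e10 cm/s * 1e-15 s/fs).
C_CM_PER_FS = 2.99792458e-5

#: Angular frequency (rad/fs) corresponding to 1 cm^-1.
ANGFREQ_PER_CM = 2.0 * math.pi * C_CM_PER_FS


def beta_ev(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in eV^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_EV * temperature)


def wavenumber_to_angfreq(nu_cm: float) -> float:
    """Convert a wavenumber (cm^-1) to angular frequency in rad/fs."""
    return ANGFREQ_PER_CM * nu_cm


def nyquist_wavenumber(dt_fs: float) -> float:
    """Highest wavenumber representable at sampling interval ``dt_fs``.

    The sampling (ordinary) Nyquist frequency 1/(2 dt) expressed in cm^-1.
    """
    if dt_fs <= 0:
        raise ValueError(f"dt must be positive, got {dt_fs}")
    return 1.0 / (2.0 * dt_fs * C_CM_PER_FS)
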