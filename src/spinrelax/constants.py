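"""Physical constants and unit conversions.

Internal convention: positions in nm, times in ps, angular frequencies in
rad/ps. Conversion to SI happens exactly once, when spectral densities enter
the rate prefactors (see :mod:`spinrelax.rates`).
"""

# CODATA 2018
GAMMA_H = 2.6752218744e8
"""Proton gyromagnetic ratio, rad s^-1 T^-1."""

HBAR = 1.054571817e-34
"""Reduced Planck constant, J s."""

MU0_OVER_4PI = 1.0e-7
"""mu_0 / (4 pi), T m A^-1 (== 1e-7 exactly in SI since the 2019 redefinition
to within relative 1.6e-10; the difference is far below every tolerance
used here)."""

K_DIPOLAR = MU0_OVER_4PI * GAMMA_H**2 * HBAR
"""Dipolar coupling prefactor (mu_0/4pi) * gamma_H^2 * hbar, m^3 s^-1."""

# unit conversions
NM6PS_TO_SI = 1e42
"""Spectral density nm^-6 ps -> m^-6 s  (nm^-6 -> m^-6 is 1e54, ps -> s is 1e-12)."""

RAD_PER_S_TO_RAD_PER_PS = 1e-12

NM2_PER_PS_TO_CM2_PER_S = 1e-2
"""Diffusion coefficient nm^2/ps -> cm^2/s."""

CM2_PER_S_TO_NM2_PER_PS = 1e2

SI_SPECTRAL_UNITS = "m^-6 s"
INTERNAL_SPECTRAL_UNITS = "nm^-6 ps"


def larmor_frequency(B0: float) -> float:
    """Proton Larmor angular frequency gamma_H * B0 in rad/s for B0 in tesla."""
    return GAMMA_H * B0
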