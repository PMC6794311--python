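"""Dipolar correlation machinery: spherical harmonics, autocorrelations,
numerically integrated spectral densities.

For a spin pair the relevant lattice functions are the rank-2 spherical
harmonics of the internuclear vector (theta, phi measured against the B0 = z
axis, r in nm)::

    F_{2,0} = (1 - 3 cos^2 theta) / r^3
    F_{2,1} = sin theta cos theta e^{-i phi} / r^3
    F_{2,2} = sin^2 theta e^{-2 i phi} / r^3

Their lag autocorrelations G_q(tau) = Re<F_q(t) F_q*(t+tau)>_t (nm^-6) carry
the motional information; the spectral density is the one-sided cosine
transform J_q(omega) = 2 * int_0^inf G_q(tau) cos(omega tau) dtau, evaluated
here by trapezoidal integration on the truncated lag grid. Units stay in
nm^-6 ps until the rate stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import INTERNAL_SPECTRAL_UNITS, NM6PS_TO_SI, SI_SPECTRAL_UNITS
from .trajectory import SpinTrajectory, minimum_image

__all__ = [
    "PolarSeries",
    "HarmonicSeries",
    "CorrelationFunction",
    "SpectralDensity",
    "pair_polar_series",
    "pair_displacements",
    "harmonics_from_polar",
    "harmonics_from_displacements",
    "autocorrelate",
    "autocorrelate_direct",
    "spectral_density_numeric",
]


@dataclass
class PolarSeries:
    """Per-frame polar coordinates of one internuclear vector (r nm, angles rad)."""

    r: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    dt: float


@dataclass
class HarmonicSeries:
    """F_{2,q}(t) series for q = 0, 1, 2, in nm^-3.

    F_{2,-q} = F_{2,q}^*, so only q >= 0 is stored; F0 is real-valued.
    """

    F: np.ndarray  # (3, n_frames) complex
    dt: float

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class CorrelationFunction:
    """G_q(tau) on a uniform lag grid (nm^-6; dimensionless if normalized)."""

    lags: np.ndarray          # ps, starting at 0, spacing dt
    G: np.ndarray             # (3, n_lags) real
    dt: float
    A: np.ndarray = None      # magnitudes G_q(0) in nm^-6
    normalized: bool = False
    truncation_fraction: float = 1.0

    def __post_init__(self):
        if self.A is None:
            self.A = self.G[:, 0].copy()


@dataclass
class SpectralDensity:
    """J_q(omega) values with explicit units ("nm^-6 ps" or "m^-6 s")."""

    omega: np.ndarray         # rad/ps (internal) or rad/s (SI)
    J: np.ndarray             # (3, n_omega) or (n_omega,) matching omega
    units: str = INTERNAL_SPECTRAL_UNITS
    method: str = "numeric"

    def to_si(self) -> "SpectralDensity":
        if self.units == SI_SPECTRAL_UNITS:
            return self
        if self.units != INTERNAL_SPECTRAL_UNITS:
            raise ValueError(f"unknown spectral density units {self.units!r}")
        return SpectralDensity(self.omega * 1e12, self.J * NM6PS_TO_SI,
                               units=SI_SPECTRAL_UNITS, method=self.method)


def pair_displacements(traj: SpinTrajectory, i: int, j: int) -> np.ndarray:
    """Minimum-image displacement j - i per frame, (n_frames, 3) in nm."""
    d = traj.positions[:, j, :] - traj.positions[:, i, :]
    return minimum_image(d, traj.box)


def pair_polar_series(traj: SpinTrajectory, i: int, j: int) -> PolarSeries:
    """Polar coordinates (r, theta, phi) of nucleus j relative to i.

    theta is measured from the B0 (z) axis; minimum-image convention applies
    when the trajectory is periodic.
    """
    if i == j:
        raise ValueError("i and j must differ")
    d = pair_displacements(traj, i, j)
    r = np.linalg.norm(d, axis=1)
    zero = np.flatnonzero(r == 0)
    if zero.size:
        raise ValueError(f"coincident nuclei {i},{j} at frame {zero[0]}")
    theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return PolarSeries(r=r, theta=theta, phi=phi, dt=traj.dt)


def harmonics_from_polar(p: PolarSeries) -> HarmonicSeries:
    """Evaluate F_{2,q} for q = 0, 1, 2 from a polar series."""
    r3 = p.r**3
    ct = np.cos(p.theta)
    st = np.sin(p.theta)
    F = np.empty((3, p.r.size), dtype=np.complex128)
    F[0] = (1.0 - 3.0 * ct**2) / r3
    F[1] = st * ct * np.exp(-1j * p.phi) / r3
    F[2] = st**2 * np.exp(-2j * p.phi) / r3
    return HarmonicSeries(F=F, dt=p.dt)


def harmonics_from_displacements(d: np.ndarray, dt: float) -> HarmonicSeries:
    """F_{2,q} directly from displacement vectors (avoids angle round-trips).

    Uses cos(theta) = z/r and e^{-i phi} = (x - i y)/(r sin theta); equivalent
    to going through :func:`pair_polar_series` + :func:`harmonics_from_polar`.
    """
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise ValueError("coincident nuclei in displacement series")
    r3 = r**3
    z = d[:, 2] / r
    xy = (d[:, 0] - 1j * d[:, 1]) / r  # sin(theta) e^{-i phi}
    F = np.empty((3, r.size), dtype=np.complex128)
    F[0] = (1.0 - 3.0 * z**2) / r3
    F[1] = xy * z / r3
    F[2] = xy**2 / r3
    return HarmonicSeries(F=F, dt=dt)


def _next_pow2(n: int) -> int:
    k = 1
    while k < n:
        k <<= 1
    return k


def autocorrelate(h: HarmonicSeries, truncation_fraction: float = 0.3) -> CorrelationFunction:
    """Lag autocorrelation of each harmonic via FFT.

    G_q(k dt) = Re( sum_t F_q(t) F_q*(t+k) ) / (N - k): the unbiased per-lag
    divisor, computed with zero padding to >= 2N so no circular wrap-around
    occurs. The lag grid is truncated at ``truncation_fraction`` of the series
    duration (the tail of a finite-trajectory estimate is noise-dominated).
    """
    if not 0 < truncation_fraction <= 1:
        raise ValueError("truncation_fraction must be in (0, 1]")
    n = h.n_frames
    if n < 10:
        raise ValueError("series too short to autocorrelate (need >= 10 frames)")
    n_lags = int(np.floor(truncation_fraction * (n - 1))) + 1
    nfft = _next_pow2(2 * n)
    fhat = np.fft.fft(h.F, n=nfft, axis=1)
    corr = np.fft.ifft(fhat * np.conj(fhat), axis=1)[:, :n_lags].real
    divisor = n - np.arange(n_lags)
    G = corr / divisor
    lags = np.arange(n_lags) * h.dt
    return CorrelationFunction(lags=lags, G=G, dt=h.dt,
                               truncation_fraction=truncation_fraction)


def autocorrelate_direct(h: HarmonicSeries, truncation_fraction: float = 0.3) -> CorrelationFunction:
    """O(N^2) double-loop autocorrelation; independent cross-check of the FFT path."""
    if not 0 < truncation_fraction <= 1:
        raise ValueError("truncation_fraction must be in (0, 1]")
    n = h.n_frames
    n_lags = int(np.floor(truncation_fraction * (n - 1))) + 1
    G = np.empty((3, n_lags))
    for q in range(3):
        f = h.F[q]
        for k in range(n_lags):
            G[q, k] = np.mean(f[: n - k] * np.conj(f[k:])).real
    lags = np.arange(n_lags) * h.dt
    return CorrelationFunction(lags=lags, G=G, dt=h.dt,
                               truncation_fraction=truncation_fraction)


def spectral_density_numeric(G: CorrelationFunction, omega) -> SpectralDensity:
    """J_q(omega) = 2 * trapezoidal integral of G_q(tau) cos(omega tau).

    ``omega`` in rad/ps (scalar or array); result in nm^-6 ps. The lag grid
    must resolve the oscillation: |omega| * dt <= pi/4 is enforced (at the
    0.5 ps sampling typical of the source data this admits all proton Larmor
    frequencies up to well above 7 T).
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    wmax = np.abs(omega).max()
    if wmax * G.dt > np.pi / 4:
        raise ValueError(
            f"omega*dt = {wmax * G.dt:.3g} rad exceeds pi/4; the lag grid "
            "cannot resolve this frequency")
    # (n_omega, n_lags) cosine kernel; J shape (3, n_omega)
    kernel = np.cos(np.outer(omega, G.lags))
    J = 2.0 * np.trapezoid(G.G[:, None, :] * kernel[None, :, :], dx=G.dt, axis=2)
    return SpectralDensity(omega=omega, J=J, units=INTERNAL_SPECTRAL_UNITS,
                           method="numeric")
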