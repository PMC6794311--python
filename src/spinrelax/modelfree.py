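"""Model-free analysis of macromolecular correlation functions.

Hydrogens bonded in a flexible macromolecular lattice move on two separated
timescales: fast internal fluctuation (tau_i) superimposed on the global
tumbling of the molecule (tau_M). The normalized orientational correlation
then factorizes into the two-exponential model-free form

    Ghat(tau) = S^2 exp(-tau/tau_M) + (1 - S^2) exp(-tau/tau_i),

with order parameter S^2 in [0, 1] measuring how much correlation the fast
motion leaves behind (1 = rigid, 0 = fully averaged). Its spectral density
is the matching two-Lorentzian closed form

    J(omega) = 2 A [ S^2 tau_M / (1 + omega^2 tau_M^2)
                   + (1 - S^2) tau_i / (1 + omega^2 tau_i^2) ],

where A is the magnitude G(0) of the unnormalized correlation. The closed
form extrapolates the slow decay beyond the simulated window, which is why
it is used for pools whose correlations do not decay within the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import INTERNAL_SPECTRAL_UNITS
from .dipolar import CorrelationFunction, SpectralDensity

__all__ = [
    "ModelFreeFit",
    "normalize",
    "fit_modelfree",
    "fit_modelfree_all_q",
    "modelfree_curve",
    "spectral_density_modelfree",
]

#: amplitude of the fast component below which tau_i is unidentifiable
_TAU_I_AMPLITUDE_FLOOR = 0.01


@dataclass
class ModelFreeFit:
    S2: float
    tau_M: float      # ps
    tau_i: float      # ps
    A: float = 1.0    # nm^-6, magnitude carried from the unnormalized G
    residual: float = np.nan   # sum of squared residuals
    converged: bool = False
    tau_i_identifiable: bool = True
    q: int | None = None


def normalize(G: CorrelationFunction) -> CorrelationFunction:
    """Ghat_q(tau) = G_q(tau) / G_q(0); the magnitudes A_q are retained."""
    if G.normalized:
        return G
    A = G.G[:, 0].copy()
    if np.any(A <= 0):
        bad = int(np.flatnonzero(A <= 0)[0])
        raise ValueError(f"G_{bad}(0) <= 0: no dipolar coupling to normalize")
    return CorrelationFunction(lags=G.lags, G=G.G / A[:, None], dt=G.dt,
                               A=A, normalized=True,
                               truncation_fraction=G.truncation_fraction)


def modelfree_curve(tau, S2, tau_M, tau_i):
    """The two-exponential model-free correlation form."""
    return S2 * np.exp(-tau / tau_M) + (1.0 - S2) * np.exp(-tau / tau_i)


def _single_fit(lags, g, x0, bounds):
    def resid(x):
        return modelfree_curve(lags, *x) - g

    return least_squares(resid, x0, bounds=bounds, xtol=1e-10, ftol=1e-12,
                         gtol=1e-12, max_nfev=10_000)


def fit_modelfree(lags: np.ndarray, ghat: np.ndarray, dt: float,
                  A: float = 1.0, q: int | None = None) -> ModelFreeFit:
    """Bounded least-squares fit of one normalized correlation curve.

    Multi-start over a coarse (S^2, tau_M) grid with tau_i seeded from the
    initial decay; the best-residual solution is kept. The two exponentials
    are symmetric under swapping (S^2, tau_M) <-> (1 - S^2, tau_i), so after
    fitting the slower timescale is reported as tau_M. When the fast
    amplitude 1 - S^2 falls below 1%, tau_i is flagged unidentifiable.
    """
    lags = np.asarray(lags, float)
    ghat = np.asarray(ghat, float)
    if lags.size < 20:
        raise ValueError("need at least 20 lag points for a model-free fit")
    if not np.all(np.isfinite(ghat)):
        raise ValueError("non-finite correlation values")
    tau_max = lags[-1]
    lo = np.array([0.0, dt * 1e-3, dt * 1e-3])
    hi = np.array([1.0, 100.0 * tau_max, 100.0 * tau_max])

    # tau_i seed: first lag where the curve has lost 1/e of its fast part
    drop = ghat[0] - ghat
    idx = np.flatnonzero(drop > 0.1)
    tau_i0 = max(lags[idx[0]], dt) if idx.size else max(0.01 * tau_max, dt)

    best = None
    for s2 in (0.2, 0.5, 0.8):
        for scale in (0.1, 1.0, 10.0):
            x0 = np.array([s2,
                           np.clip(scale * 0.1 * tau_max, lo[1], hi[1]),
                           np.clip(tau_i0, lo[2], hi[2])])
            try:
                res = _single_fit(lags, ghat, x0, (lo, hi))
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return ModelFreeFit(np.nan, np.nan, np.nan, A=A, converged=False, q=q)

    S2, tau_M, tau_i = best.x
    if tau_i > tau_M:  # relabel: slower timescale is the global one
        tau_M, tau_i = tau_i, tau_M
        S2 = 1.0 - S2
    if tau_M > 0 and (tau_M - tau_i) / tau_M < 0.01:
        # single-exponential degeneracy: the amplitude split between two
        # equal timescales is arbitrary, so report the rigid limit
        S2 = 1.0
    identifiable = (1.0 - S2) >= _TAU_I_AMPLITUDE_FLOOR
    return ModelFreeFit(S2=float(S2), tau_M=float(tau_M), tau_i=float(tau_i),
                        A=float(A), residual=float(2.0 * best.cost),
                        converged=bool(best.success),
                        tau_i_identifiable=bool(identifiable), q=q)


def fit_modelfree_all_q(Ghat: CorrelationFunction) -> list:
    """Independent per-q fits of a normalized correlation function."""
    if not Ghat.normalized:
        Ghat = normalize(Ghat)
    return [fit_modelfree(Ghat.lags, Ghat.G[q], Ghat.dt, A=float(Ghat.A[q]), q=q)
            for q in range(3)]


def spectral_density_modelfree(fit: ModelFreeFit, omega,
                               allow_unconverged: bool = False) -> SpectralDensity:
    """Closed-form two-Lorentzian spectral density of a model-free fit.

    omega in rad/ps; J in nm^-6 ps (A in nm^-6, timescales in ps).
    """
    if not fit.converged and not allow_unconverged:
        raise ValueError("fit did not converge; pass allow_unconverged=True to override")
    omega = np.atleast_1d(np.asarray(omega, float))
    J = 2.0 * fit.A * (fit.S2 * fit.tau_M / (1.0 + omega**2 * fit.tau_M**2)
                       + (1.0 - fit.S2) * fit.tau_i / (1.0 + omega**2 * fit.tau_i**2))
    return SpectralDensity(omega=omega, J=J, units=INTERNAL_SPECTRAL_UNITS,
                           method="modelfree")
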