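"""Vogel–Fulcher–Tammann analysis of α-relaxation times.

The super-Arrhenius temperature dependence of the structural relaxation time
in a supercooled liquid is parameterized as

    τ_α(T) = τ∞ · exp(B / (T − T0)),     T > T0,

with pre-exponential τ∞ (s), activation parameter B (K), and Vogel
temperature T0 (K). The dielectric glass-transition temperature is defined
operationally as the temperature at which τ_α reaches a reference value
(100 s by convention); isochronal storage temperatures use the same
inversion at other reference times (1.5 ms in this work).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, UnderdeterminedError, ValidationError
from .hn import RelaxationPoint

#: glass-transition reference relaxation time, seconds
TAU_GLASS = 100.0
#: isochronal-comparison reference relaxation time, seconds
TAU_ISOCHRONAL = 1.5e-3

#: hard lower bound on the Vogel temperature during fitting, kelvin
_T0_FLOOR = 1.0


@dataclass(frozen=True)
class VFTFit:
    """VFT parameters with fit diagnostics.

    ``covariance`` is the 3×3 covariance of (log10 τ∞, B, T0) from the final
    Jacobian of the log10 τ fit (None for ground-truth parameter sets).
    """

    tau_inf: float
    B: float
    T0: float
    covariance: Optional[np.ndarray] = None
    residual: float = float("nan")
    status: str = "ok"

    def __post_init__(self):
        if self.tau_inf <= 0:
            raise ValidationError(f"tau_inf must be positive, got {self.tau_inf}")
        if self.B <= 0:
            raise ValidationError(f"B must be positive, got {self.B}")
        if self.T0 < 0:
            raise ValidationError(f"T0 must be non-negative, got {self.T0}")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise ValidationError("covariance must be 3x3")
            object.__setattr__(self, "covariance", cov)


def eval_vft(fit: VFTFit, temperature) -> np.ndarray | float:
    """τ_α(T) in seconds; defined only above the Vogel temperature."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= fit.T0):
        raise DomainError(
            f"temperature must exceed the Vogel temperature T0={fit.T0} K"
        )
    tau = fit.tau_inf * np.exp(fit.B / (T - fit.T0))
    return float(tau) if np.isscalar(temperature) else tau


def fit_vft(points: Sequence[RelaxationPoint]) -> VFTFit:
    """Least squares on log10 τ_α with unit weights.

    Requires ≥ 4 points spanning ≥ 2 decades in τ (three parameters plus one
    degree of freedom; a narrower span cannot separate B from T0). A fit
    whose T0 lands on a bound (e.g. Arrhenius-like data pushing T0 to its
    floor) is flagged ``status='at-bound'`` rather than rejected.
    """
    points = sorted(points, key=lambda p: p.temperature)
    if len(points) < 4:
        raise UnderdeterminedError(
            f"fit_vft requires at least 4 points, got {len(points)}"
        )
    T = np.array([p.temperature for p in points])
    log_tau = np.log10([p.tau_alpha for p in points])
    if log_tau.max() - log_tau.min() < 2.0:
        raise UnderdeterminedError(
            "fit_vft requires points spanning at least 2 decades in tau"
        )

    def model(temp, log10_tau_inf, B, T0):
        return log10_tau_inf + B / (np.log(10.0) * (temp - T0))

    t0_hi = T.min() - 1e-3
    p0 = (-14.0, 2000.0, max(_T0_FLOOR, T.min() - 50.0))
    popt, pcov = curve_fit(
        model, T, log_tau, p0=p0,
        bounds=([-40.0, 1.0, _T0_FLOOR], [10.0, 1e6, t0_hi]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
    )
    resid = model(T, *popt) - log_tau
    status = "ok"
    if popt[2] <= _T0_FLOOR * (1 + 1e-6) or popt[2] >= t0_hi * (1 - 1e-9):
        status = "at-bound"
    return VFTFit(
        tau_inf=10.0 ** popt[0], B=float(popt[1]), T0=float(popt[2]),
        covariance=pcov, residual=float(np.sum(resid**2)), status=status,
    )


def isochronal_temperature(fit: VFTFit, tau: float) -> float:
    """Temperature at which τ_α equals ``tau`` (closed-form VFT inversion).

        T(τ) = T0 + B / ln(τ/τ∞)

    Monotone decreasing in τ on (τ∞, ∞); no solution at or below τ∞.
    """
    if tau <= fit.tau_inf:
        raise DomainError(
            f"tau={tau} s must exceed the pre-exponential tau_inf={fit.tau_inf} s"
        )
    return float(fit.T0 + fit.B / np.log(tau / fit.tau_inf))


def tg_from_vft(fit: VFTFit, tau_ref: float = TAU_GLASS) -> float:
    """Dielectric glass-transition temperature Tg = T(τ_α = tau_ref)."""
    return isochronal_temperature(fit, tau_ref)


def tg_uncertainty(fit: VFTFit, tau_ref: float = TAU_GLASS) -> float:
    """First-order standard deviation of Tg from the parameter covariance.

    Propagates the covariance of (log10 τ∞, B, T0) through
    Tg = T0 + B/L with L = ln(τ_ref) − ln(10)·log10 τ∞.
    Returns NaN when no covariance is available.
    """
    if fit.covariance is None:
        return float("nan")
    L = np.log(tau_ref / fit.tau_inf)
    grad = np.array([fit.B * np.log(10.0) / L**2, 1.0 / L, 1.0])
    return float(np.sqrt(grad @ fit.covariance @ grad))


def extrapolation_distance(fit: VFTFit, points: Sequence[RelaxationPoint],
                           tau_ref: float = TAU_GLASS) -> float:
    """Kelvin between the coldest fitted point and the extrapolated T(τ_ref)."""
    t_min = min(p.temperature for p in points)
    return t_min - isochronal_temperature(fit, tau_ref)
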