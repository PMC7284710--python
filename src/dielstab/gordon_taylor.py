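"""Gordon–Taylor mixing rule: Tg of a miscible drug–polymer blend.

    Tg(w2) = (W1·Tg1 + K·W2·Tg2) / (W1 + K·W2),    W1 = 1 − W2,

where component 1 is the drug, component 2 the polymer, ``w2`` the polymer
weight fraction and K a dimensionless mixing parameter, approximable from
the heat-capacity steps at Tg as K ≈ ΔCp2/ΔCp1. The rule is strictly
monotone in composition for K > 0, so it inverts in closed form — the basis
of the residual-composition (solubility-limit) determination: the Tg of the
saturated amorphous phase left after crystallization is mapped back to the
drug fraction dissolved in the polymer at the storage temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import CompositionPoint, HeatCapacityStep
from .errors import DomainError, OutOfRangeError, UnderdeterminedError, ValidationError


@dataclass(frozen=True)
class GTModel:
    """Pure-component glass transitions (K) and the Gordon–Taylor parameter."""

    tg1: float  # drug
    tg2: float  # polymer
    K: float

    def __post_init__(self):
        if self.tg1 <= 0 or self.tg2 <= 0:
            raise ValidationError("pure-component Tgs must be positive")
        if self.K <= 0:
            raise ValidationError(f"K must be positive, got {self.K}")


@dataclass(frozen=True)
class GTFitResult:
    model: GTModel
    residuals: np.ndarray  # per-point Tg_pred − Tg_obs, kelvin


@dataclass(frozen=True)
class InversionResult:
    """Composition recovered from a mixture Tg, with first-order uncertainty."""

    w2: float
    w1: float
    dw2_dtg: float          # sensitivity of the inversion, 1/K
    w2_sd: Optional[float]  # None when no tg_sd was supplied


def gt_predict(model: GTModel, w2) -> np.ndarray | float:
    """Mixture Tg at polymer weight fraction ``w2`` (endpoints exact)."""
    w = np.asarray(w2, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise DomainError(f"w2 must lie in [0, 1], got {w2}")
    w1 = 1.0 - w
    tg = (w1 * model.tg1 + model.K * w * model.tg2) / (w1 + model.K * w)
    # endpoints exact by definition (the ratio above can round off at w2=1)
    tg = np.where(w == 0.0, model.tg1, np.where(w == 1.0, model.tg2, tg))
    return float(tg) if np.isscalar(w2) else tg


def gt_k_from_dcp(dcp1: HeatCapacityStep, dcp2: HeatCapacityStep) -> float:
    """K ≈ ΔCp2/ΔCp1 from the pure-component heat-capacity steps at Tg."""
    return dcp2.delta_cp / dcp1.delta_cp


def _k_single_point(tg1: float, tg2: float, p: CompositionPoint) -> float:
    # exact solve of the mixing rule for K at one interior composition
    return (1.0 - p.w2) * (p.tg - tg1) / (p.w2 * (tg2 - p.tg))


def fit_gt_k(points: Sequence[CompositionPoint], tg1: float, tg2: float) -> GTFitResult:
    """Least-squares K (kelvin residuals, unweighted), endpoints held fixed.

    Pure-component Tgs are data, not fitted. Requires at least one interior
    point (0 < w2 < 1); a single interior point is solved exactly.
    """
    if tg1 == tg2:
        raise ValidationError("tg1 and tg2 must differ to constrain K")
    interior = [p for p in points if 0.0 < p.w2 < 1.0]
    if not interior:
        raise UnderdeterminedError("fit_gt_k requires at least one interior composition")

    k_guesses = [_k_single_point(tg1, tg2, p) for p in interior]
    k_guesses = [k for k in k_guesses if np.isfinite(k) and k > 0]
    k0 = float(np.median(k_guesses)) if k_guesses else 1.0

    w = np.array([p.w2 for p in interior])
    tg_obs = np.array([p.tg for p in interior])

    def resid(log_k):
        model = GTModel(tg1=tg1, tg2=tg2, K=float(np.exp(log_k[0])))
        return gt_predict(model, w) - tg_obs

    sol = least_squares(resid, x0=[np.log(k0)], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    model = GTModel(tg1=tg1, tg2=tg2, K=float(np.exp(sol.x[0])))
    return GTFitResult(model=model, residuals=gt_predict(model, w) - tg_obs)


def gt_invert(model: GTModel, tg: float, tg_sd: Optional[float] = None) -> InversionResult:
    """Closed-form inverse of the mixing rule: composition from a mixture Tg.

        w2 = (Tg − Tg1) / [(Tg − Tg1) + K·(Tg2 − Tg)]

    Valid for Tg between the pure-component values (endpoints included).
    The reported sensitivity dw2/dTg = K·(Tg2 − Tg1)/denom² quantifies how
    strongly Tg noise propagates to composition — large when the endpoint
    Tgs are close together; with ``tg_sd`` a first-order standard deviation
    of w2 is attached.
    """
    lo, hi = min(model.tg1, model.tg2), max(model.tg1, model.tg2)
    if not lo <= tg <= hi:
        dist = lo - tg if tg < lo else tg - hi
        raise OutOfRangeError(
            f"tg={tg} K lies {dist:.3g} K outside the model range [{lo}, {hi}] K",
            distance=float(dist),
        )
    u = tg - model.tg1
    v = model.tg2 - tg
    denom = u + model.K * v
    w2 = u / denom
    dw2_dtg = model.K * (model.tg2 - model.tg1) / denom**2
    w2_sd = abs(dw2_dtg) * tg_sd if tg_sd is not None else None
    return InversionResult(w2=float(w2), w1=float(1.0 - w2),
                           dw2_dtg=float(dw2_dtg), w2_sd=w2_sd)
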