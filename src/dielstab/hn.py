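"""Havriliak–Negami fitting of dielectric loss spectra.

The model for the complex permittivity of a single structural (α) relaxation
plus dc conduction is

    ε*(ω) = ε∞ + Δε / [1 + (iωτ_HN)^a]^b + σ_dc / (ε0·iω),        ω = 2πf,

with the physics sign convention ε* = ε′ − iε″ (ε″ ≥ 0). ``a`` and ``b`` are
the symmetric and asymmetric broadening exponents (Debye at a = b = 1,
Cole–Davidson at a = 1). The α-relaxation time reported downstream is the
inverse angular frequency of the loss maximum, obtained from the fitted
parameters in closed form by :func:`hn_peak_time`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import lmfit
import numpy as np

from .datatypes import DielectricSpectrum, SpectrumSeries
from .errors import DomainError, EmptyResultError, InitializationError, ValidationError

logger = logging.getLogger(__name__)

#: vacuum permittivity, F/m
EPS_VAC = 8.8541878128e-12

#: default box bounds for the fit parameters (physical admissibility)
DEFAULT_BOUNDS = {
    "delta_eps": (1e-6, 1e4),
    "tau_hn": (1e-12, 1e6),
    "a": (0.05, 1.0),
    "b": (0.05, 1.0),
    "eps_inf": (1.0, 1e3),
    "sigma_dc": (0.0, 1.0),
}


@dataclass(frozen=True)
class HNFit:
    """Fitted (or ground-truth) parameters of one HN + conductivity spectrum."""

    delta_eps: float
    tau_hn: float
    a: float
    b: float
    eps_inf: float
    sigma_dc: float = 0.0
    residual: float = float("nan")
    converged: bool = True
    status: str = "ok"

    def __post_init__(self):
        if not 0.0 < self.a <= 1.0:
            raise ValidationError(f"a must lie in (0, 1], got {self.a}")
        if not 0.0 < self.b <= 1.0:
            raise ValidationError(f"b must lie in (0, 1], got {self.b}")
        if self.tau_hn <= 0:
            raise ValidationError(f"tau_hn must be positive, got {self.tau_hn}")
        if self.delta_eps <= 0:
            raise ValidationError(f"delta_eps must be positive, got {self.delta_eps}")
        if self.sigma_dc < 0:
            raise ValidationError(f"sigma_dc must be non-negative, got {self.sigma_dc}")
        if self.eps_inf < 0:
            raise ValidationError(f"eps_inf must be non-negative, got {self.eps_inf}")


@dataclass(frozen=True)
class RelaxationPoint:
    """One (temperature, τ_α) point of the relaxation map."""

    temperature: float
    tau_alpha: float
    source: str = ""

    def __post_init__(self):
        if self.tau_alpha <= 0:
            raise ValidationError(f"tau_alpha must be positive, got {self.tau_alpha}")


def hn_complex(
    frequencies: np.ndarray,
    delta_eps: float,
    tau_hn: float,
    a: float,
    b: float,
    eps_inf: float,
    sigma_dc: float = 0.0,
) -> np.ndarray:
    """Evaluate ε*(ω) = ε′ − iε″ on a frequency grid (Hz)."""
    omega = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
    hn = delta_eps / (1.0 + (1j * omega * tau_hn) ** a) ** b
    cond = -1j * sigma_dc / (EPS_VAC * omega)
    return eps_inf + hn + cond


def eval_hn(fit: HNFit, frequencies) -> tuple[np.ndarray, np.ndarray]:
    """Return (ε′, ε″) of the model on a frequency grid in Hz."""
    freq = np.asarray(frequencies, dtype=float)
    if np.any(freq <= 0):
        raise DomainError("frequencies must be strictly positive")
    eps = hn_complex(freq, fit.delta_eps, fit.tau_hn, fit.a, fit.b,
                     fit.eps_inf, fit.sigma_dc)
    return eps.real, -eps.imag


def hn_peak_time(fit: HNFit) -> float:
    """Time 1/ω_max of the HN loss maximum (the α-relaxation time).

    Closed form:

        τ_α = τ_HN · [sin(πa/(2+2b))]^(−1/a) · [sin(πab/(2+2b))]^(1/a)

    In the Debye limit (a = b = 1) τ_α = τ_HN; in the Cole–Davidson limit
    (a = 1) it reduces to ω_max·τ = tan(π/(2b+2)). The exponent signs are
    fixed by requiring agreement with direct numeric maximization of ε″(ω);
    the same expression occasionally circulates with the exponents swapped,
    which is its reciprocal and places the peak on the wrong side of τ_HN.
    """
    a, b = fit.a, fit.b
    if not (0.0 < a <= 1.0 and 0.0 < b <= 1.0):
        raise DomainError(f"a and b must lie in (0, 1], got a={a}, b={b}")
    half = np.pi / (2.0 + 2.0 * b)
    return float(
        fit.tau_hn * np.sin(a * half) ** (-1.0 / a) * np.sin(a * b * half) ** (1.0 / a)
    )


def _find_loss_peak(frequencies: np.ndarray, eps_imag: np.ndarray) -> Optional[int]:
    """Index of the interior loss maximum, or None if the loss is monotone.

    The loss is smoothed on a log scale (5-point moving average) before the
    search so that 1%-level noise does not create spurious local maxima; the
    low-frequency conductivity upturn is rejected because it places the
    global maximum at the edge.
    """
    y = np.log10(np.clip(eps_imag, 1e-300, None))
    if y.size >= 7:
        kernel = np.ones(5) / 5.0
        ys = np.convolve(y, kernel, mode="same")
        # convolution edge bias: keep raw values near the boundaries
        ys[:2], ys[-2:] = y[:2], y[-2:]
    else:
        ys = y
    interior = np.arange(1, y.size - 1)
    is_max = (ys[interior] >= ys[interior - 1]) & (ys[interior] >= ys[interior + 1])
    candidates = interior[is_max]
    if candidates.size == 0:
        return None
    return int(candidates[np.argmax(ys[candidates])])


def _default_init(spectrum: DielectricSpectrum) -> dict:
    """Starting point from the observed loss-peak position (Debye heuristic)."""
    idx = _find_loss_peak(spectrum.frequencies, spectrum.eps_imag)
    if idx is None:
        raise InitializationError(
            "no interior loss maximum found; supply an explicit init "
            "(spectrum may be conductivity-dominated or featureless)"
        )
    f_peak = spectrum.frequencies[idx]
    peak_height = spectrum.eps_imag[idx]
    eps_inf = (
        float(spectrum.eps_real[-1])
        if spectrum.eps_real is not None
        else DEFAULT_BOUNDS["eps_inf"][0]
    )
    f0 = spectrum.frequencies[0]
    sigma0 = max(0.0, 0.5 * spectrum.eps_imag[0] * EPS_VAC * 2.0 * np.pi * f0)
    return {
        "delta_eps": 2.0 * peak_height,
        "tau_hn": 1.0 / (2.0 * np.pi * f_peak),
        "a": 0.8,
        "b": 0.8,
        "eps_inf": max(eps_inf, 1.0),
        "sigma_dc": sigma0,
    }


def fit_hn(
    spectrum: DielectricSpectrum,
    mode: str = "loss_only",
    bounds: Optional[dict] = None,
    init: Optional[dict] = None,
) -> HNFit:
    """Least-squares HN + conductivity fit to one spectrum.

    ``mode='loss_only'`` (default) minimizes residuals on log ε″ — the loss
    spans decades, so log residuals weight every decade equally. ε∞ does not
    enter ε″ and is then taken from the high-frequency limit of ε′ (or held
    at its initial value if ε′ is absent). ``mode='complex'`` minimizes joint
    relative residuals on ε′ and ε″.

    Non-convergence yields a flagged result (``converged=False``), not an
    exception. A spectrum whose fitted relaxation contributes negligibly
    next to the conductivity term is flagged ``status='non-identifiable'``.
    """
    if mode not in ("loss_only", "complex"):
        raise ValidationError(f"mode must be 'loss_only' or 'complex', got {mode!r}")
    if spectrum.n_points < 6:
        raise ValidationError("fit_hn requires at least 6 frequency points")
    if spectrum.eps_imag is None:
        raise ValidationError("fit_hn requires eps_imag")
    if mode == "complex" and spectrum.eps_real is None:
        raise ValidationError("mode='complex' requires eps_real")

    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    start = _default_init(spectrum) if init is None else dict(init)

    params = lmfit.Parameters()
    params.add("log10_tau", value=np.log10(start["tau_hn"]),
               min=np.log10(box["tau_hn"][0]), max=np.log10(box["tau_hn"][1]))
    params.add("delta_eps", value=np.clip(start["delta_eps"], *box["delta_eps"]),
               min=box["delta_eps"][0], max=box["delta_eps"][1])
    params.add("a", value=np.clip(start["a"], *box["a"]), min=box["a"][0], max=box["a"][1])
    params.add("b", value=np.clip(start["b"], *box["b"]), min=box["b"][0], max=box["b"][1])
    # conductivity is fitted on a log scale: its magnitude is unknown a
    # priori over ~15 decades and a linear parameterization stalls the solver
    sigma_floor = 1e-20  # numerically indistinguishable from zero conduction
    sigma_start = max(start.get("sigma_dc", 0.0), sigma_floor)
    sigma_hi = max(box["sigma_dc"][1], 10 * sigma_floor)
    params.add("log10_sigma", value=np.log10(np.clip(sigma_start, sigma_floor, sigma_hi)),
               min=np.log10(sigma_floor), max=np.log10(sigma_hi))
    params.add("eps_inf", value=np.clip(start.get("eps_inf", 1.0), *box["eps_inf"]),
               min=box["eps_inf"][0], max=box["eps_inf"][1], vary=(mode == "complex"))

    freq = spectrum.frequencies
    loss = spectrum.eps_imag
    pos = loss > 0  # log residuals are defined only on positive loss values

    def residual(p):
        eps = hn_complex(freq, p["delta_eps"].value, 10.0 ** p["log10_tau"].value,
                         p["a"].value, p["b"].value, p["eps_inf"].value,
                         10.0 ** p["log10_sigma"].value)
        model_loss = np.clip(-eps.imag, 1e-300, None)
        if mode == "loss_only":
            return np.log10(model_loss[pos]) - np.log10(loss[pos])
        scale_r = np.maximum(np.abs(spectrum.eps_real), 1e-12)
        scale_i = np.maximum(np.abs(loss), 1e-12)
        return np.concatenate(
            [(eps.real - spectrum.eps_real) / scale_r,
             (model_loss - loss) / scale_i]
        )

    result = lmfit.minimize(residual, params, method="least_squares",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p = result.params
    tau = 10.0 ** p["log10_tau"].value
    sigma = 10.0 ** p["log10_sigma"].value
    if sigma <= 1e-18:
        sigma = 0.0
    eps_inf = p["eps_inf"].value
    if mode == "loss_only" and spectrum.eps_real is not None:
        # ε∞ from the high-frequency tail of ε′, corrected for residual relaxation
        eps_model = hn_complex(freq[-3:], p["delta_eps"].value, tau, p["a"].value,
                               p["b"].value, 0.0, 0.0)
        eps_inf = float(np.mean(spectrum.eps_real[-3:] - eps_model.real))

    fit = HNFit(
        delta_eps=p["delta_eps"].value,
        tau_hn=tau,
        a=p["a"].value,
        b=p["b"].value,
        eps_inf=max(eps_inf, 0.0),
        sigma_dc=sigma,
        residual=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=bool(result.success),
        status="ok" if result.success else "not-converged",
    )
    return _flag_identifiability(fit, freq, loss)


def _flag_identifiability(fit: HNFit, freq: np.ndarray, loss: np.ndarray) -> HNFit:
    """Flag fits whose relaxation peak is buried under the conductivity term."""
    eps_relax = hn_complex(freq, fit.delta_eps, fit.tau_hn, fit.a, fit.b, 0.0, 0.0)
    peak = float(np.max(-eps_relax.imag))
    total = float(np.max(loss))
    if total > 0 and peak < 0.05 * total:
        return replace(fit, converged=False, status="non-identifiable")
    return fit


def fit_series(
    series: SpectrumSeries,
    mode: str = "loss_only",
    bounds: Optional[dict] = None,
) -> list[tuple[DielectricSpectrum, Optional[HNFit]]]:
    """Fit every spectrum of a wide-band series; failures yield ``None``."""
    out: list[tuple[DielectricSpectrum, Optional[HNFit]]] = []
    for spectrum in series:
        try:
            out.append((spectrum, fit_hn(spectrum, mode=mode, bounds=bounds)))
        except (InitializationError, ValidationError) as exc:
            logger.warning("skipping spectrum at T=%.2f K: %s", spectrum.temperature, exc)
            out.append((spectrum, None))
    return out


def extract_relaxation_map(
    series: SpectrumSeries,
    mode: str = "loss_only",
    bounds: Optional[dict] = None,
    truncate_collapsed: bool = True,
    collapse_threshold: float = 0.10,
) -> list[RelaxationPoint]:
    """Fit a temperature series and return τ_α(T) points.

    Spectra that fail to fit are logged and skipped, never interpolated.
    With ``truncate_collapsed`` the fitted Δε(T) sequence is screened for a
    crystallization collapse against its 1/T baseline; fits at and beyond
    the detected onset are flagged and the map is truncated there, since
    their τ_α no longer describes the supercooled liquid.
    """
    fits = fit_series(series, mode=mode, bounds=bounds)
    good = [(s, f) for s, f in fits if f is not None and f.status == "ok"]
    if truncate_collapsed and len(good) >= 5:
        from .crystallization import detect_onset  # late import: avoids a cycle

        temps = np.array([s.temperature for s, _ in good])
        deps = np.array([f.delta_eps for _, f in good])
        onset = detect_onset(temps, deps, baseline="inverse_T",
                             threshold=collapse_threshold)
        if onset.detected:
            n_before = len(good)
            good = [(s, f) for s, f in good if s.temperature < onset.onset]
            logger.info(
                "dielectric-strength collapse at %.1f K: truncated %d crystallized spectra",
                onset.onset, n_before - len(good),
            )
    if not good:
        raise EmptyResultError("no spectrum in the series could be fitted")
    return [
        RelaxationPoint(
            temperature=s.temperature,
            tau_alpha=hn_peak_time(f),
            source=f"T={s.temperature:.2f}K",
        )
        for s, f in good
    ]
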