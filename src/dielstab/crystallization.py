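"""Crystallization detection, kinetics, and residual-composition analysis.

Crystallization immobilizes reorienting dipoles, so the dielectric strength
Δε (∝ Nμ²) of the α relaxation collapses as the crystalline fraction grows.
Two detectors exploit this: a wide-band detector that screens fitted Δε(T)
against its Langevin 1/T baseline, and a single-frequency detector that
screens ε′(T) (e.g. a 1 kHz heating scan) against a local linear trend.
Isothermal kinetics are quantified on the normalized real permittivity

    ε′_N(t) = (ε′(0) − ε′(t)) / (ε′(0) − ε′(∞)),

which runs from 0 (fully amorphous) to 1 (fully crystallized) and is
invariant under affine rescaling of ε′. The residual-composition pipeline
re-fits the relaxation process that survives crystallization (α′), extracts
its Tg by VFT extrapolation, and inverts the Gordon–Taylor model to the
drug fraction still dissolved in the polymer — the solubility limit at the
storage temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import SpectrumSeries
from .errors import DomainError, ValidationError
from .gordon_taylor import GTModel, InversionResult, gt_invert
from .hn import RelaxationPoint, extract_relaxation_map
from .vft import VFTFit, fit_vft, tg_from_vft, tg_uncertainty

logger = logging.getLogger(__name__)

#: default relative shortfall from the baseline that counts as "a noticeable drop"
ONSET_THRESHOLD = 0.10
#: default ε′_N level marking the induction time
INDUCTION_THRESHOLD = 0.05
#: default |dε′_N/dt| below which the trace counts as flat, per second
PLATEAU_SLOPE_TOL = 1e-3 / 3600.0
#: final_norm below this flags crystallization as incomplete
COMPLETENESS_THRESHOLD = 0.9


@dataclass(frozen=True)
class CrystallizationTrace:
    """ε′ versus time (isothermal) or temperature (scan) at one frequency."""

    axis: str  # 'time' (s) or 'temperature' (K)
    axis_values: np.ndarray
    eps_real: np.ndarray
    frequency: Optional[float] = None
    eps0: Optional[float] = None
    eps_inf_limit: Optional[float] = None
    eps_norm: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.axis not in ("time", "temperature"):
            raise ValidationError(f"axis must be 'time' or 'temperature', got {self.axis!r}")
        x = np.asarray(self.axis_values, dtype=float)
        y = np.asarray(self.eps_real, dtype=float)
        if x.size != y.size or x.size < 2:
            raise ValidationError("axis_values and eps_real must be equal-length (≥ 2)")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("axis_values must be strictly increasing")
        object.__setattr__(self, "axis_values", x)
        object.__setattr__(self, "eps_real", y)
        if (self.eps0 is not None and self.eps_inf_limit is not None
                and self.eps0 <= self.eps_inf_limit):
            raise ValidationError("eps0 must exceed eps_inf_limit")


@dataclass(frozen=True)
class OnsetResult:
    """Crystallization onset along the scanned axis; ``onset is None`` when
    the sample showed no tendency towards crystallization (a first-class
    outcome, not an error)."""

    onset: Optional[float]
    method: str
    threshold_used: float
    baseline_model: str
    detected: bool

    @property
    def no_onset(self) -> bool:
        return not self.detected


@dataclass(frozen=True)
class KineticsSummary:
    """Induction/cessation times and final crystallinity of one trace."""

    induction_time: Optional[float]
    cessation_time: Optional[float]
    final_norm: float
    complete: bool

    def __post_init__(self):
        if (self.induction_time is not None and self.cessation_time is not None
                and self.induction_time > self.cessation_time):
            raise ValidationError("induction_time must not exceed cessation_time")


def trace_from_series(series: SpectrumSeries) -> CrystallizationTrace:
    """Collapse a single-frequency series into a ε′-vs-axis trace."""
    if series.fixed_frequency is None:
        raise ValidationError("trace_from_series requires a single-frequency series")
    eps = np.array([s.eps_real[0] for s in series])
    return CrystallizationTrace(
        axis=series.axis, axis_values=series.axis_values, eps_real=eps,
        frequency=series.fixed_frequency,
    )


def normalize_permittivity(
    trace: CrystallizationTrace,
    eps0: Optional[float] = None,
    eps_inf: Optional[float] = None,
    initial_points: int = 3,
    final_points: int = 3,
) -> CrystallizationTrace:
    """Attach ε′_N(t) = (ε′(0) − ε′(t)) / (ε′(0) − ε′(∞)) to the trace.

    ε′(0) defaults to the mean of the initial plateau (first ``initial_points``
    samples); ε′(∞) must reflect the fully crystallized (high-frequency-limit)
    permittivity — supply it when crystallization is incomplete, otherwise it
    defaults to the final-plateau mean.
    """
    e0 = eps0 if eps0 is not None else trace.eps0
    einf = eps_inf if eps_inf is not None else trace.eps_inf_limit
    if e0 is None:
        e0 = float(np.mean(trace.eps_real[:initial_points]))
    if einf is None:
        einf = float(np.mean(trace.eps_real[-final_points:]))
    if e0 <= einf:
        raise ValidationError(
            f"eps0={e0} must exceed eps_inf_limit={einf} for normalization"
        )
    norm = (e0 - trace.eps_real) / (e0 - einf)
    return replace(trace, eps0=e0, eps_inf_limit=einf, eps_norm=norm)


def _fit_inverse_t(T: np.ndarray, y: np.ndarray) -> float:
    """Least-squares amplitude A of the Langevin baseline y = A/T."""
    x = 1.0 / T
    return float(np.dot(y, x) / np.dot(x, x))


def _fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def detect_onset(
    axis_values: np.ndarray,
    values: np.ndarray,
    baseline: str = "inverse_T",
    threshold: float = ONSET_THRESHOLD,
    min_baseline: int = 5,
    window: int = 8,
) -> OnsetResult:
    """First axis point whose value falls ≥ ``threshold`` below the baseline.

    ``baseline='inverse_T'`` extrapolates an A/T trend — the Langevin decay
    of dielectric strength — fitted over the growing pre-onset window (for
    Δε(T) sequences from wide-band fits). ``baseline='linear'`` extrapolates
    a local linear trend over the last ``window`` pre-onset points (for
    single-frequency ε′(T) scans, whose shape is only locally smooth).

    The baseline window grows point by point while observations stay within
    the threshold, so the baseline is never contaminated by post-onset data.
    """
    x = np.asarray(axis_values, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValidationError("axis_values and values must have equal length")
    if baseline not in ("inverse_T", "linear"):
        raise ValidationError(f"unknown baseline model {baseline!r}")
    if x.size < min_baseline + 1:
        raise ValidationError(
            f"need more than min_baseline={min_baseline} points, got {x.size}"
        )

    method = "delta_eps_drop" if baseline == "inverse_T" else "single_freq_drop"
    for i in range(min_baseline, x.size):
        if baseline == "inverse_T":
            A = _fit_inverse_t(x[:i], y[:i])
            predicted = A / x[i]
        else:
            j0 = max(0, i - window)
            slope, intercept = _fit_linear(x[j0:i], y[j0:i])
            predicted = slope * x[i] + intercept
        if predicted > 0 and y[i] < (1.0 - threshold) * predicted:
            return OnsetResult(onset=float(x[i]), method=method,
                               threshold_used=threshold,
                               baseline_model=baseline, detected=True)
    return OnsetResult(onset=None, method=method, threshold_used=threshold,
                       baseline_model=baseline, detected=False)


def detect_onset_from_scan(
    trace: CrystallizationTrace,
    threshold: float = ONSET_THRESHOLD,
    min_baseline: int = 3,
    window: int = 8,
    eps_inf: Optional[float] = None,
) -> OnsetResult:
    """Onset from a single-frequency ε′(T) heating scan.

    Such a scan starts in the glass at the high-frequency limit ε∞, steps up
    to the static permittivity where the α relaxation crosses the probe
    frequency, then decays slowly — until crystallization collapses ε′ back
    towards ε∞. The detector estimates ε∞ from the initial glass plateau
    (first three points unless supplied), restricts the search to beyond the
    ε′ maximum (the step-up itself must not trigger), extrapolates a local
    linear baseline over the last ``window`` accepted points, and reports
    the first temperature where the shortfall from the baseline exceeds
    ``threshold`` of the remaining relaxation step (baseline − ε∞) — i.e.
    where the given fraction of the dielectric strength has been lost.
    """
    x = trace.axis_values
    y = trace.eps_real
    if eps_inf is None:
        eps_inf = float(np.mean(y[:3]))
    # light smoothing so 1%-level noise does not displace the maximum
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same") if y.size >= 5 else y
    start = int(np.argmax(ys))
    method = "single_freq_drop"
    n_tail = y.size - start
    if n_tail < min_baseline + 1:
        return OnsetResult(onset=None, method=method, threshold_used=threshold,
                           baseline_model="linear", detected=False)
    for i in range(start + min_baseline, y.size):
        j0 = max(start, i - window)
        slope, intercept = _fit_linear(x[j0:i], y[j0:i])
        predicted = slope * x[i] + intercept
        step = predicted - eps_inf
        if step > 0 and (predicted - y[i]) > threshold * step:
            return OnsetResult(onset=float(x[i]), method=method,
                               threshold_used=threshold,
                               baseline_model="linear", detected=True)
    return OnsetResult(onset=None, method=method, threshold_used=threshold,
                       baseline_model="linear", detected=False)


def kinetics_summary(
    trace: CrystallizationTrace,
    induction_threshold: float = INDUCTION_THRESHOLD,
    plateau_window: int = 5,
    slope_tol: float = PLATEAU_SLOPE_TOL,
    completeness_threshold: float = COMPLETENESS_THRESHOLD,
) -> KineticsSummary:
    """Induction time, cessation time and final crystallinity of a trace.

    Induction: first time ε′_N exceeds ``induction_threshold``. Cessation:
    start of the final stretch over which |dε′_N/dt| stays below
    ``slope_tol`` (at least ``plateau_window`` samples long). A trace that
    never crystallizes yields no induction time and final_norm ≈ 0; a
    plateau short of 1 (``final_norm < completeness_threshold``) flags
    incomplete crystallization — a saturated amorphous phase survives.
    """
    if trace.axis != "time":
        raise ValidationError("kinetics_summary requires a time-axis trace")
    if trace.eps_norm is None:
        raise ValidationError("normalize the trace before summarizing kinetics")
    t = trace.axis_values
    y = trace.eps_norm

    above = np.nonzero(y > induction_threshold)[0]
    induction = float(t[above[0]]) if above.size else None

    # slope on a lightly smoothed trace: a pointwise gradient would let
    # sample-to-sample noise mask a genuine plateau
    if y.size >= plateau_window >= 3:
        kernel = np.ones(plateau_window) / plateau_window
        ys = np.convolve(y, kernel, mode="same")
        edge = plateau_window // 2
        ys[:edge], ys[-edge:] = y[:edge], y[-edge:]
    else:
        ys = y
    slopes = np.gradient(ys, t)
    flat = np.abs(slopes) < slope_tol
    # walk back from the end of the trace over the terminal flat stretch
    i = y.size - 1
    while i > 0 and flat[i - 1]:
        i -= 1
    has_plateau = (y.size - i) >= plateau_window
    final_norm = float(np.mean(y[i:])) if has_plateau else float(np.mean(y[-plateau_window:]))

    cessation = None
    if induction is not None and has_plateau and i > 0:
        cessation = float(t[i])
        cessation = max(cessation, induction)

    return KineticsSummary(
        induction_time=induction,
        cessation_time=cessation,
        final_norm=final_norm,
        complete=final_norm >= completeness_threshold,
    )


def stability_factor(tg: float, tc: float) -> float:
    """Thermal stability factor Tc − Tg: width of the stable supercooled-
    liquid window between the glass transition and crystallization onset."""
    if not (np.isfinite(tg) and np.isfinite(tc)):
        raise ValidationError("tg and tc must be finite")
    return tc - tg


@dataclass(frozen=True)
class ResidualCompositionResult:
    """Solubility-limit estimate from the post-crystallization α′ process."""

    drug_fraction: float
    polymer_fraction: float
    tg: float
    tg_sd: float
    fraction_sd: Optional[float]
    vft: VFTFit
    points: tuple[RelaxationPoint, ...]
    warnings: tuple[str, ...] = ()


def residual_composition(
    post_cryst_series: SpectrumSeries,
    gt_model: GTModel,
    mode: str = "loss_only",
    tau_ref: float = 100.0,
    neat_polymer_tolerance: float = 0.02,
) -> ResidualCompositionResult:
    """Drug fraction of the saturated amorphous phase after crystallization.

    Pipeline: fit the α′ relaxation across the post-crystallization cooling
    series → VFT fit of τ_α′(T) → Tg = T(τ_α′ = ``tau_ref``) → Gordon–Taylor
    inversion to composition. An out-of-range Tg propagates as
    :class:`~dielstab.errors.OutOfRangeError` (reported, never clamped). A
    recovered drug fraction within ``neat_polymer_tolerance`` of zero is
    warned about: the α′ process is then indistinguishable from the neat
    polymer's segmental relaxation (fully crystallized or immiscible drug).
    """
    points = extract_relaxation_map(post_cryst_series, mode=mode,
                                    truncate_collapsed=False)
    vft = fit_vft(points)
    tg = tg_from_vft(vft, tau_ref=tau_ref)
    tg_sd = tg_uncertainty(vft, tau_ref=tau_ref)
    inv = gt_invert(gt_model, tg, tg_sd=tg_sd if np.isfinite(tg_sd) else None)
    warnings = ()
    if inv.w1 <= neat_polymer_tolerance:
        warnings = (
            "recovered drug fraction ~ 0: the α' process matches the neat-polymer "
            "segmental relaxation (drug fully crystallized or immiscible)",
        )
        logger.warning(warnings[0])
    return ResidualCompositionResult(
        drug_fraction=inv.w1,
        polymer_fraction=inv.w2,
        tg=tg,
        tg_sd=tg_sd,
        fraction_sd=inv.w2_sd,
        vft=vft,
        points=tuple(points),
        warnings=warnings,
    )
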