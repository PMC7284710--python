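"""Seeded synthetic dielectric datasets with recorded ground truth.

Forward models mirror what the analysis assumes: HN + conductivity spectra,
VFT-governed temperature evolution of τ_HN, a Langevin A/T decay of the
dielectric strength, and crystallization as a stretched-exponential (Avrami)
decay of the amorphous fraction — a generator choice recorded in the
manifest; the detectors make no use of it. Noise is multiplicative Gaussian
(relative), applied last and independently to ε′ and ε″: dielectric loss
spans decades, so additive noise would swamp the low-loss wings. All
randomness flows from a single integer seed through per-spectrum substreams,
so regeneration with the same seed is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import CompositionPoint, DielectricSpectrum, SpectrumSeries
from .errors import DomainError, ValidationError
from .gordon_taylor import GTModel, gt_predict
from .hn import HNFit, hn_complex
from .crystallization import CrystallizationTrace
from .vft import VFTFit, eval_vft, isochronal_temperature

#: default relative noise level on ε′ and ε″
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class CrystallizationKernel:
    """Avrami-type crystallized-fraction kernel.

        X(x) = x_max · (1 − exp(−k · max(0, x − onset)^n))

    ``x`` is time (s) or temperature (K) past ``onset``; ``x_max < 1``
    models incomplete crystallization (a saturated amorphous phase remains).
    """

    onset: float
    rate: float
    exponent: float
    x_max: float = 1.0

    def __post_init__(self):
        if self.onset < 0:
            raise ValidationError(f"onset must be non-negative, got {self.onset}")
        if self.rate <= 0 or self.exponent <= 0:
            raise ValidationError("rate and exponent must be positive")
        if not 0.0 < self.x_max <= 1.0:
            raise ValidationError(f"x_max must lie in (0, 1], got {self.x_max}")

    def fraction(self, x) -> np.ndarray:
        dx = np.maximum(0.0, np.asarray(x, dtype=float) - self.onset)
        return self.x_max * (1.0 - np.exp(-self.rate * dx**self.exponent))


@dataclass
class GroundTruth:
    """Manifest sufficient to regenerate a dataset bit-exactly."""

    seed: int
    noise_sd: float
    hn_by_condition: dict = field(default_factory=dict)
    vft: Optional[VFTFit] = None
    gt: Optional[GTModel] = None
    crystallization: Optional[CrystallizationKernel] = None
    grids: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        out = {"seed": self.seed, "noise_sd": self.noise_sd,
               "hn_by_condition": clean(self.hn_by_condition),
               "grids": clean(self.grids)}
        if self.vft is not None:
            out["vft"] = {"tau_inf": self.vft.tau_inf, "B": self.vft.B, "T0": self.vft.T0}
        if self.gt is not None:
            out["gt"] = asdict(self.gt)
        if self.crystallization is not None:
            out["crystallization"] = asdict(self.crystallization)
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _apply_noise(values: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0.0:
        return values
    return values * (1.0 + noise_sd * rng.standard_normal(values.shape))


def generate_spectrum(
    hn_params: HNFit,
    freq_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    temperature: float = 300.0,
    time: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> DielectricSpectrum:
    """One HN + conductivity spectrum with multiplicative Gaussian noise.

    ``noise_sd=0`` returns the exact forward model. Either a ``seed`` or an
    externally managed ``rng`` substream may drive the noise.
    """
    freq = np.asarray(freq_grid, dtype=float)
    eps = hn_complex(freq, hn_params.delta_eps, hn_params.tau_hn, hn_params.a,
                     hn_params.b, hn_params.eps_inf, hn_params.sigma_dc)
    if rng is None:
        rng = np.random.default_rng(seed)
    return DielectricSpectrum(
        temperature=temperature,
        time=time,
        frequencies=freq,
        eps_real=_apply_noise(eps.real, noise_sd, rng),
        eps_imag=_apply_noise(-eps.imag, noise_sd, rng),
    )


def _delta_eps_profile(
    temp_grid: np.ndarray,
    amplitude: float,
    kernel: Optional[CrystallizationKernel],
) -> np.ndarray:
    """Langevin A/T dielectric strength, scaled by the amorphous fraction."""
    deps = amplitude / temp_grid
    if kernel is not None:
        deps = deps * (1.0 - kernel.fraction(temp_grid))
    return deps


def generate_temperature_series(
    vft: VFTFit,
    delta_eps_amplitude: float,
    temp_grid: np.ndarray,
    freq_grid: np.ndarray,
    tc_true: Optional[float] = None,
    kernel: Optional[CrystallizationKernel] = None,
    shape: tuple[float, float] = (0.8, 0.6),
    eps_inf: float = 3.0,
    sigma_dc: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumSeries, GroundTruth]:
    """Wide-band spectra on a heating ramp, with optional crystallization.

    τ_HN(T) follows the VFT law exactly (recorded in the manifest); Δε(T)
    decays as A/T below ``tc_true`` and is multiplied by the remaining
    amorphous fraction above it. ``tc_true`` is the kernel onset; pass a
    full ``kernel`` to control rate/exponent/x_max (default: rate 0.05 K⁻²,
    exponent 2 — a collapse essentially complete within ~10 K, as sharp as
    cold crystallization on a slow heating ramp).
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    if np.any(temp_grid <= vft.T0):
        raise DomainError(
            f"temperature grid must lie above the Vogel temperature T0={vft.T0} K"
        )
    if tc_true is not None and kernel is None:
        kernel = CrystallizationKernel(onset=tc_true, rate=0.05, exponent=2.0)
    elif tc_true is not None and kernel is not None and kernel.onset != tc_true:
        raise ValidationError("tc_true and kernel.onset disagree")

    a, b = shape
    deps = _delta_eps_profile(temp_grid, delta_eps_amplitude, kernel)
    streams = _substreams(seed, temp_grid.size)
    spectra = []
    hn_by_condition = {}
    for T, de, rng in zip(temp_grid, deps, streams):
        tau = eval_vft(vft, float(T))
        params = HNFit(delta_eps=float(de), tau_hn=tau, a=a, b=b,
                       eps_inf=eps_inf, sigma_dc=sigma_dc)
        spectra.append(generate_spectrum(params, freq_grid, noise_sd=noise_sd,
                                         temperature=float(T), rng=rng))
        hn_by_condition[float(T)] = {
            "delta_eps": float(de), "tau_hn": tau, "a": a, "b": b,
            "eps_inf": eps_inf, "sigma_dc": sigma_dc,
        }
    series = SpectrumSeries(spectra=tuple(spectra), axis="temperature")
    truth = GroundTruth(
        seed=seed, noise_sd=noise_sd, hn_by_condition=hn_by_condition,
        vft=vft, crystallization=kernel,
        grids={"temperature_K": temp_grid, "frequency_Hz": np.asarray(freq_grid)},
    )
    return series, truth


def generate_single_frequency_scan(
    vft: VFTFit,
    delta_eps_amplitude: float,
    temp_grid: np.ndarray,
    frequency: float = 1.0e3,
    tc_true: Optional[float] = None,
    kernel: Optional[CrystallizationKernel] = None,
    shape: tuple[float, float] = (0.8, 0.6),
    eps_inf: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SpectrumSeries, GroundTruth]:
    """ε′(T) at a fixed frequency across the glass transition.

    Reproduces the canonical shape of such scans: ε′ ≈ ε∞ deep in the glass,
    a step up to the static permittivity where the relaxation crosses the
    probe frequency, the slow A/T decay of the supercooled liquid, and a
    rapid collapse back towards ε∞ once crystallization sets in.
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    if np.any(temp_grid <= vft.T0):
        raise DomainError(
            f"temperature grid must lie above the Vogel temperature T0={vft.T0} K"
        )
    if tc_true is not None and kernel is None:
        kernel = CrystallizationKernel(onset=tc_true, rate=0.05, exponent=2.0)

    a, b = shape
    deps = _delta_eps_profile(temp_grid, delta_eps_amplitude, kernel)
    streams = _substreams(seed, temp_grid.size)
    spectra = []
    for T, de, rng in zip(temp_grid, deps, streams):
        tau = eval_vft(vft, float(T))
        eps = hn_complex(np.array([frequency]), float(de), tau, a, b, eps_inf, 0.0)
        spectra.append(
            DielectricSpectrum(
                temperature=float(T),
                frequencies=np.array([frequency]),
                eps_real=_apply_noise(eps.real, noise_sd, rng),
            )
        )
    series = SpectrumSeries(spectra=tuple(spectra), axis="temperature",
                            fixed_frequency=frequency)
    truth = GroundTruth(
        seed=seed, noise_sd=noise_sd, vft=vft, crystallization=kernel,
        grids={"temperature_K": temp_grid, "frequency_Hz": np.array([frequency])},
    )
    return series, truth


def generate_isothermal_trace(
    eps0: float,
    eps_inf: float,
    kernel: CrystallizationKernel,
    time_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    frequency: float = 1.0e3,
) -> CrystallizationTrace:
    """ε′(t) during isothermal crystallization at a fixed frequency.

        ε′(t) = ε′(∞) + (ε′(0) − ε′(∞)) · (1 − X(t))

    flat at ε′(0) before the kernel onset; with ``x_max < 1`` the observed
    plateau stays above ε′(∞) — incomplete crystallization.
    """
    if eps0 <= eps_inf:
        raise ValidationError(f"eps0={eps0} must exceed eps_inf={eps_inf}")
    t = np.asarray(time_grid, dtype=float)
    eps = eps_inf + (eps0 - eps_inf) * (1.0 - kernel.fraction(t))
    rng = np.random.default_rng(seed)
    return CrystallizationTrace(
        axis="time", axis_values=t,
        eps_real=_apply_noise(eps, noise_sd, rng),
        frequency=frequency, eps0=eps0, eps_inf_limit=eps_inf,
    )


def generate_tg_composition(
    gt_model: GTModel,
    w2_grid: Sequence[float],
    noise_sd_K: float = 0.0,
    seed: int = 0,
) -> list[CompositionPoint]:
    """Tg(w2) per the mixing rule plus Gaussian noise in kelvin."""
    rng = np.random.default_rng(seed)
    w2 = np.asarray(w2_grid, dtype=float)
    tg = np.asarray(gt_predict(gt_model, w2), dtype=float).reshape(w2.shape)
    if noise_sd_K > 0:
        tg = tg + noise_sd_K * rng.standard_normal(tg.shape)
    return [CompositionPoint(w2=float(w), tg=float(t)) for w, t in zip(w2, tg)]


def vft_for_tg(
    tg: float,
    tau_inf: float = 1e-14,
    T0: Optional[float] = None,
    tau_ref: float = 100.0,
    shape: Optional[tuple[float, float]] = None,
) -> VFTFit:
    """A VFT parameter set whose T(τ_ref) equals ``tg`` exactly.

    Solves B = ln(τ_ref/τ∞)·(Tg − T0); the default Vogel temperature sits
    45 K below Tg, a typical offset for moderately fragile glass formers.

    The generators drive τ_HN with this law, whereas Tg downstream is
    defined on the loss-peak time τ_α, which differs from τ_HN by a fixed
    shape factor. Pass the HN ``shape`` (a, b) to anchor the law so that
    the *peak time* reaches ``tau_ref`` exactly at ``tg``.
    """
    if shape is not None:
        from .hn import hn_peak_time

        ratio = hn_peak_time(HNFit(delta_eps=1.0, tau_hn=1.0, a=shape[0],
                                   b=shape[1], eps_inf=1.0))
        tau_ref = tau_ref / ratio
    if T0 is None:
        T0 = tg - 45.0
    if T0 <= 0 or T0 >= tg:
        raise ValidationError(f"T0={T0} must lie in (0, tg={tg})")
    B = np.log(tau_ref / tau_inf) * (tg - T0)
    return VFTFit(tau_inf=tau_inf, B=float(B), T0=float(T0))


def generate_saturated_series(
    gt_model: GTModel,
    drug_fraction: float,
    freq_grid: np.ndarray,
    n_temps: int = 15,
    tau_range: tuple[float, float] = (1e-4, 1.0),
    delta_eps_amplitude: float = 1500.0,
    shape: tuple[float, float] = (0.8, 0.6),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[SpectrumSeries, GroundTruth]:
    """Post-crystallization cooling series of a saturated drug–polymer phase.

    Builds the α′ scenario end-to-end: the residual amorphous phase holds
    ``drug_fraction`` of drug, its Tg follows the supplied mixing model, and
    its τ_α′(T) follows a VFT law anchored to that Tg. The temperature grid
    spans the window where τ_α′ runs over ``tau_range`` — the practically
    measurable decades just above Tg.
    """
    if not 0.0 <= drug_fraction <= 1.0:
        raise ValidationError(f"drug_fraction must lie in [0, 1], got {drug_fraction}")
    tg_true = gt_predict(gt_model, 1.0 - drug_fraction)
    vft = vft_for_tg(tg_true, shape=shape)
    t_slow = isochronal_temperature(vft, tau_range[1])
    t_fast = isochronal_temperature(vft, tau_range[0])
    temp_grid = np.linspace(t_slow, t_fast, n_temps)
    series, truth = generate_temperature_series(
        vft, delta_eps_amplitude, temp_grid, freq_grid,
        shape=shape, noise_sd=noise_sd, seed=seed,
    )
    truth.gt = gt_model
    truth.grids["drug_fraction_true"] = drug_fraction
    truth.grids["tg_true_K"] = float(tg_true)
    return series, truth
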