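"""Core domain types shared across the analysis stages.

Conventions used throughout the package: temperatures in kelvin, frequency
``f`` in Hz, angular frequency ``ω = 2πf`` in rad/s, relaxation times in
seconds, complex permittivity written ``ε*(ω) = ε′ − iε″`` with ``ε″ ≥ 0``
for a passive dielectric. Unit conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .errors import ValidationError

Axis = Literal["temperature", "time"]


def _as_float_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DielectricSpectrum:
    """One frequency sweep of complex permittivity at a fixed temperature.

    ``eps_imag`` may be omitted for real-only scans (single-frequency
    temperature sweeps record only ε′); at least one of ε′/ε″ is required.
    ``time`` tags spectra belonging to an isothermal time series.
    """

    temperature: float
    frequencies: np.ndarray
    eps_real: Optional[np.ndarray] = None
    eps_imag: Optional[np.ndarray] = None
    time: Optional[float] = None

    def __post_init__(self):
        freq = _as_float_array("frequencies", self.frequencies)
        if freq.size == 0:
            raise ValidationError("frequencies must not be empty")
        if np.any(freq <= 0):
            raise ValidationError("frequencies must be strictly positive")
        if np.any(np.diff(freq) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freq)
        if self.eps_real is None and self.eps_imag is None:
            raise ValidationError("at least one of eps_real/eps_imag is required")
        for name in ("eps_real", "eps_imag"):
            val = getattr(self, name)
            if val is not None:
                arr = _as_float_array(name, val)
                if arr.size != freq.size:
                    raise ValidationError(
                        f"{name} has {arr.size} points but the frequency grid has {freq.size}"
                    )
                object.__setattr__(self, name, arr)
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValidationError(f"temperature must be positive, got {self.temperature}")

    @property
    def n_points(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class SpectrumSeries:
    """An ordered collection of spectra along a temperature or time axis.

    Wide-band mode: all spectra share one frequency grid. Single-frequency
    mode: every spectrum holds one point at ``fixed_frequency``.
    """

    spectra: tuple[DielectricSpectrum, ...]
    axis: Axis = "temperature"
    fixed_frequency: Optional[float] = None

    def __post_init__(self):
        spectra = tuple(self.spectra)
        object.__setattr__(self, "spectra", spectra)
        if self.axis not in ("temperature", "time"):
            raise ValidationError(f"axis must be 'temperature' or 'time', got {self.axis!r}")
        if not spectra:
            return
        keys = self.axis_values
        if np.any(np.diff(keys) <= 0):
            raise ValidationError(f"series {self.axis} values must be strictly increasing")
        if self.fixed_frequency is not None:
            for s in spectra:
                if s.n_points != 1 or not np.isclose(
                    s.frequencies[0], self.fixed_frequency, rtol=1e-9
                ):
                    raise ValidationError(
                        "single-frequency series must hold one point per spectrum "
                        "at the declared fixed_frequency"
                    )
        else:
            ref = spectra[0].frequencies
            for s in spectra[1:]:
                if s.n_points != ref.size or not np.allclose(s.frequencies, ref, rtol=1e-9):
                    raise ValidationError("all spectra in a wide-band series must share one frequency grid")

    @property
    def axis_values(self) -> np.ndarray:
        if self.axis == "temperature":
            return np.array([s.temperature for s in self.spectra])
        vals = [s.time for s in self.spectra]
        if any(v is None for v in vals):
            raise ValidationError("time-axis series requires every spectrum to carry a time stamp")
        return np.array(vals, dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[DielectricSpectrum]:
        return iter(self.spectra)


@dataclass(frozen=True)
class CompositionPoint:
    """A (polymer weight fraction, glass-transition temperature) observation.

    ``w2`` is the polymer fraction; the drug fraction is ``1 − w2``.
    """

    w2: float
    tg: float
    method: Optional[str] = None

    def __post_init__(self):
        if not 0.0 <= self.w2 <= 1.0:
            raise ValidationError(f"w2 must lie in [0, 1], got {self.w2}")
        if not np.isfinite(self.tg) or self.tg <= 0:
            raise ValidationError(f"tg must be positive, got {self.tg}")

    @property
    def w1(self) -> float:
        """Drug weight fraction."""
        return 1.0 - self.w2


@dataclass(frozen=True)
class HeatCapacityStep:
    """Heat-capacity increment ΔCp at the glass transition, in J/(g·K)."""

    delta_cp: float

    def __post_init__(self):
        if not np.isfinite(self.delta_cp) or self.delta_cp <= 0:
            raise ValidationError(f"delta_cp must be positive, got {self.delta_cp}")


@dataclass(frozen=True)
class StabilityReport:
    """Per-sample glass-stability summary.

    ``stability_factor = tc − tg`` measures the width of the supercooled-
    liquid window in which the sample survives before cold crystallization;
    ``tc`` is absent when no crystallization onset was detected.
    """

    tg: float
    tc: Optional[float] = None
    stability_factor: Optional[float] = None
    isochronal_temperature: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.tg) or self.tg <= 0:
            raise ValidationError(f"tg must be positive, got {self.tg}")
        if (self.tc is None) != (self.stability_factor is None):
            raise ValidationError("tc and stability_factor must be set together")
        if self.tc is not None and self.stability_factor != self.tc - self.tg:
            raise ValidationError("stability_factor must equal tc - tg exactly")

    @classmethod
    def build(
        cls,
        tg: float,
        tc: Optional[float] = None,
        isochronal_temperature: Optional[float] = None,
    ) -> "StabilityReport":
        factor = None if tc is None else tc - tg
        return cls(tg=tg, tc=tc, stability_factor=factor,
                   isochronal_temperature=isochronal_temperature)

    def to_dict(self) -> dict:
        return {
            "tg_K": self.tg,
            "tc_K": self.tc,
            "stability_factor_K": self.stability_factor,
            "isochronal_temperature_K": self.isochronal_temperature,
        }
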