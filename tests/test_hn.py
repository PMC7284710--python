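"""HN model evaluation, peak-time convention and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dielstab.errors import DomainError, InitializationError, ValidationError
from dielstab.hn import (
    EPS_VAC,
    HNFit,
    eval_hn,
    extract_relaxation_map,
    fit_hn,
    hn_peak_time,
)
from dielstab.synth import generate_spectrum, generate_temperature_series, vft_for_tg
from dielstab.vft import isochronal_temperature


def _loss_inline(freq, delta_eps, tau, a, b):
    """Independent term-by-term complex evaluation of the HN loss."""
    omega = 2 * np.pi * freq
    z = (1j * omega * tau) ** a
    return -np.imag(delta_eps / (1 + z) ** b)


class TestEvalHN:
    def test_debye_at_omega_tau_one(self):
        fit = HNFit(delta_eps=4.0, tau_hn=1.0, a=1.0, b=1.0, eps_inf=3.0)
        f = 1.0 / (2 * np.pi)  # ωτ = 1
        er, ei = eval_hn(fit, [f])
        assert er[0] == pytest.approx(3.0 + 2.0, rel=1e-12)
        assert ei[0] == pytest.approx(2.0, rel=1e-12)

    def test_static_limit(self):
        fit = HNFit(delta_eps=4.0, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0)
        er, _ = eval_hn(fit, [1e-9])
        assert er[0] == pytest.approx(7.0, rel=1e-6)

    def test_matches_independent_complex_arithmetic(self, freq_grid):
        fit = HNFit(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0)
        _, ei = eval_hn(fit, freq_grid)
        np.testing.assert_allclose(
            ei, _loss_inline(freq_grid, 5.0, 1e-3, 0.8, 0.6), rtol=1e-12)

    @given(
        delta_eps=st.floats(0.1, 100.0),
        log_tau=st.floats(-9.0, 0.0),
        a=st.floats(0.3, 1.0),
        b=st.floats(0.2, 1.0),
    )
    def test_dielectric_strength_conserved(self, delta_eps, log_tau, a, b):
        """ε′(ω→0) − ε′(ω→∞) = Δε at zero conductivity.

        The wings converge algebraically — as (ωτ)^a at low and (ωτ)^(−ab)
        at high frequency — so the probe frequencies scale with the
        exponents to keep the truncation below the tolerance.
        """
        tau = 10.0**log_tau
        fit = HNFit(delta_eps=delta_eps, tau_hn=tau, a=a, b=b, eps_inf=3.0)
        f_lo = 10.0 ** (-9.0 / a) / (2 * np.pi * tau)
        f_hi = 10.0 ** (9.0 / (a * b)) / (2 * np.pi * tau)
        lo, _ = eval_hn(fit, [f_lo])
        hi, _ = eval_hn(fit, [f_hi])
        assert lo[0] - hi[0] == pytest.approx(delta_eps, rel=1e-6)

    def test_conductivity_slope_minus_one(self):
        fit = HNFit(delta_eps=1e-3, tau_hn=1e-6, a=1.0, b=1.0, eps_inf=3.0,
                    sigma_dc=1e-10)
        f = np.logspace(-2, 0, 21)
        _, ei = eval_hn(fit, f)
        slope = np.polyfit(np.log10(f), np.log10(ei), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-3)

    def test_rescaling_invariance(self, freq_grid):
        """ω → cω with τ → τ/c leaves the relaxation term unchanged."""
        c = 137.0
        f1 = HNFit(delta_eps=5.0, tau_hn=1e-3, a=0.7, b=0.4, eps_inf=3.0)
        f2 = HNFit(delta_eps=5.0, tau_hn=1e-3 / c, a=0.7, b=0.4, eps_inf=3.0)
        np.testing.assert_allclose(eval_hn(f1, freq_grid)[1],
                                   eval_hn(f2, freq_grid * c)[1], rtol=1e-12)


class TestPeakTime:
    def test_debye_identity(self):
        fit = HNFit(delta_eps=1.0, tau_hn=2.5, a=1.0, b=1.0, eps_inf=1.0)
        assert hn_peak_time(fit) == pytest.approx(2.5, rel=1e-14)

    def test_cole_davidson_closed_form(self):
        # a=1, b=0.5: ω_max·τ = tan(π/(2b+2)) = tan(π/3)
        fit = HNFit(delta_eps=1.0, tau_hn=1.0, a=1.0, b=0.5, eps_inf=1.0)
        assert hn_peak_time(fit) == pytest.approx(1.0 / np.tan(np.pi / 3), rel=1e-12)

    def test_matches_numeric_peak(self):
        from scipy.optimize import minimize_scalar

        fit = HNFit(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0)
        res = minimize_scalar(
            lambda lw: -_loss_inline(10.0**lw / (2 * np.pi), 5.0, 1e-3, 0.8, 0.6),
            bounds=(0.0, 7.0), method="bounded", options={"xatol": 1e-12})
        tau_numeric = 1.0 / 10.0 ** res.x
        assert hn_peak_time(fit) == pytest.approx(tau_numeric, rel=1e-3)

    def test_domain_error_outside_unit_interval(self):
        fit = HNFit(delta_eps=1.0, tau_hn=1.0, a=1.0, b=1.0, eps_inf=1.0)
        bad = object.__new__(HNFit)  # bypass construction-time validation
        object.__setattr__(bad, "a", 1.5)
        object.__setattr__(bad, "b", 0.5)
        object.__setattr__(bad, "tau_hn", 1.0)
        with pytest.raises(DomainError):
            hn_peak_time(bad)
        assert hn_peak_time(fit) == 1.0


class TestFitHN:
    def test_noiseless_recovery(self, freq_grid):
        truth = HNFit(delta_eps=5.0, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0)
        spec = generate_spectrum(truth, np.logspace(-1, 6, 211))
        fit = fit_hn(spec)
        assert fit.status == "ok"
        for name in ("delta_eps", "tau_hn", "a", "b"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-6)
        assert fit.eps_inf == pytest.approx(3.0, rel=1e-4)

    def test_recovery_with_conductivity_and_noise(self, hn_truth, freq_grid):
        spec = generate_spectrum(hn_truth, freq_grid, noise_sd=0.01, seed=7)
        fit = fit_hn(spec)
        assert fit.tau_hn == pytest.approx(hn_truth.tau_hn, rel=0.05)
        assert fit.a == pytest.approx(hn_truth.a, abs=0.05)
        assert fit.b == pytest.approx(hn_truth.b, abs=0.05)
        assert fit.sigma_dc == pytest.approx(hn_truth.sigma_dc, rel=0.2)

    def test_complex_mode_recovers_eps_inf(self, hn_truth, freq_grid):
        spec = generate_spectrum(hn_truth, freq_grid, noise_sd=0.005, seed=3)
        fit = fit_hn(spec, mode="complex")
        assert fit.eps_inf == pytest.approx(3.0, abs=0.05)
        assert fit.tau_hn == pytest.approx(hn_truth.tau_hn, rel=0.05)

    def test_conductivity_only_without_init_raises(self, freq_grid):
        truth = HNFit(delta_eps=1e-4, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0,
                      sigma_dc=1e-10)
        spec = generate_spectrum(truth, freq_grid)
        with pytest.raises(InitializationError):
            fit_hn(spec)

    def test_conductivity_only_with_init_flagged(self, freq_grid):
        truth = HNFit(delta_eps=1e-4, tau_hn=1e-3, a=0.8, b=0.6, eps_inf=3.0,
                      sigma_dc=1e-10)
        spec = generate_spectrum(truth, freq_grid)
        fit = fit_hn(spec, init={"delta_eps": 1.0, "tau_hn": 1e-3, "a": 0.8,
                                 "b": 0.8, "eps_inf": 3.0, "sigma_dc": 1e-10})
        assert fit.status == "non-identifiable"
        assert not fit.converged

    def test_too_few_points_rejected(self):
        spec = generate_spectrum(
            HNFit(delta_eps=5.0, tau_hn=1e-3, a=1.0, b=1.0, eps_inf=3.0),
            np.logspace(1, 3, 5))
        with pytest.raises(ValidationError):
            fit_hn(spec)


class TestRelaxationMap:
    def test_tau_decreases_with_temperature(self, freq_grid):
        vft = vft_for_tg(328.0, shape=(0.8, 0.6))
        t_lo = isochronal_temperature(vft, 1.0)
        temps = np.linspace(t_lo, t_lo + 30, 10)
        series, _ = generate_temperature_series(vft, 1500.0, temps, freq_grid,
                                                noise_sd=0.01, seed=1)
        points = extract_relaxation_map(series)
        taus = [p.tau_alpha for p in points]
        assert all(t1 > t2 for t1, t2 in zip(taus, taus[1:]))

    def test_recovers_generator_truth(self, freq_grid):
        vft = vft_for_tg(328.0, shape=(0.8, 0.6))
        t_lo = isochronal_temperature(vft, 1.0)
        temps = np.linspace(t_lo, t_lo + 30, 10)
        series, truth = generate_temperature_series(vft, 1500.0, temps, freq_grid,
                                                    noise_sd=0.01, seed=2)
        points = extract_relaxation_map(series)
        ref = HNFit(delta_eps=1.0, tau_hn=1.0, a=0.8, b=0.6, eps_inf=1.0)
        shape_ratio = hn_peak_time(ref)
        for p in points:
            tau_true = truth.hn_by_condition[p.temperature]["tau_hn"] * shape_ratio
            assert p.tau_alpha == pytest.approx(tau_true, rel=0.05)

    def test_crystallized_spectra_truncated(self, freq_grid):
        vft = vft_for_tg(328.0, shape=(0.8, 0.6))
        t_lo = isochronal_temperature(vft, 1.0)
        tc = t_lo + 20
        temps = np.arange(t_lo, tc + 12, 2.0)
        series, _ = generate_temperature_series(vft, 1500.0, temps, freq_grid,
                                                tc_true=float(tc), seed=3)
        truncated = extract_relaxation_map(series, truncate_collapsed=True)
        full = extract_relaxation_map(series, truncate_collapsed=False)
        assert len(truncated) < len(full)
        assert max(p.temperature for p in truncated) <= tc + 2.0
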