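"""Synthetic-data generators: forward-model exactness, determinism, manifests."""

import numpy as np
import pytest

from dielstab import io
from dielstab.errors import DomainError, ValidationError
from dielstab.gordon_taylor import GTModel, fit_gt_k, gt_predict
from dielstab.hn import HNFit, hn_complex
from dielstab.synth import (
    CrystallizationKernel,
    generate_isothermal_trace,
    generate_spectrum,
    generate_temperature_series,
    generate_tg_composition,
    generate_single_frequency_scan,
    vft_for_tg,
)
from dielstab.vft import VFTFit, eval_vft, isochronal_temperature, tg_from_vft


class TestGenerateSpectrum:
    def test_noiseless_equals_forward_model(self, hn_truth, freq_grid):
        spec = generate_spectrum(hn_truth, freq_grid)
        eps = hn_complex(freq_grid, hn_truth.delta_eps, hn_truth.tau_hn,
                         hn_truth.a, hn_truth.b, hn_truth.eps_inf,
                         hn_truth.sigma_dc)
        np.testing.assert_allclose(spec.eps_real, eps.real, rtol=1e-12)
        np.testing.assert_allclose(spec.eps_imag, -eps.imag, rtol=1e-12)

    def test_debye_peak_at_inverse_tau(self, freq_grid):
        tau = 1e-3
        spec = generate_spectrum(
            HNFit(delta_eps=5.0, tau_hn=tau, a=1.0, b=1.0, eps_inf=3.0),
            freq_grid)
        f_peak = freq_grid[np.argmax(spec.eps_imag)]
        f_expected = 1.0 / (2 * np.pi * tau)
        # agreement to the grid resolution (20 points/decade)
        assert abs(np.log10(f_peak / f_expected)) <= 0.05

    def test_same_seed_is_deterministic(self, hn_truth, freq_grid):
        s1 = generate_spectrum(hn_truth, freq_grid, noise_sd=0.01, seed=9)
        s2 = generate_spectrum(hn_truth, freq_grid, noise_sd=0.01, seed=9)
        np.testing.assert_array_equal(s1.eps_imag, s2.eps_imag)
        np.testing.assert_array_equal(s1.eps_real, s2.eps_real)

    def test_conductivity_limb_slope(self):
        spec = generate_spectrum(
            HNFit(delta_eps=5.0, tau_hn=1e-6, a=1.0, b=1.0, eps_inf=3.0,
                  sigma_dc=1e-10),
            np.logspace(-2, 0, 21))
        slope = np.polyfit(np.log10(spec.frequencies),
                           np.log10(spec.eps_imag), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)


class TestTemperatureSeries:
    VFT = VFTFit(tau_inf=1e-14, B=2000.0, T0=250.0)

    def test_no_crystallization_delta_eps_decreasing(self, freq_grid):
        temps = np.linspace(300.0, 340.0, 9)
        series, truth = generate_temperature_series(self.VFT, 1500.0, temps,
                                                    freq_grid)
        deps = [truth.hn_by_condition[float(T)]["delta_eps"] for T in temps]
        assert np.all(np.diff(deps) < 0)
        np.testing.assert_allclose(deps, 1500.0 / temps, rtol=1e-12)

    def test_manifest_tau_follows_vft_exactly(self, freq_grid):
        temps = np.linspace(300.0, 340.0, 5)
        _, truth = generate_temperature_series(self.VFT, 1500.0, temps, freq_grid)
        for T in temps:
            assert truth.hn_by_condition[float(T)]["tau_hn"] == pytest.approx(
                eval_vft(self.VFT, float(T)), rel=1e-14)

    def test_temperature_below_vogel_rejected(self, freq_grid):
        with pytest.raises(DomainError):
            generate_temperature_series(self.VFT, 1500.0,
                                        np.array([240.0, 300.0]), freq_grid)

    def test_crystallization_scales_delta_eps(self, freq_grid):
        temps = np.linspace(300.0, 340.0, 21)
        tc = 320.0
        _, truth = generate_temperature_series(self.VFT, 1500.0, temps,
                                               freq_grid, tc_true=tc)
        for T in temps:
            de = truth.hn_by_condition[float(T)]["delta_eps"]
            if T <= tc:
                assert de == pytest.approx(1500.0 / T, rel=1e-12)
            else:
                assert de < 1500.0 / T

    def test_manifest_round_trip_bit_exact(self, tmp_path, freq_grid):
        temps = np.linspace(300.0, 330.0, 4)
        series, truth = generate_temperature_series(
            self.VFT, 1500.0, temps, freq_grid, noise_sd=0.01, seed=21)
        io.write_spectrum_series(series, tmp_path / "a.csv")
        series2, _ = generate_temperature_series(
            self.VFT, 1500.0, temps, freq_grid, noise_sd=truth.noise_sd,
            seed=truth.seed)
        io.write_spectrum_series(series2, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestSingleFrequencyScan:
    def test_scan_shape(self):
        vft = vft_for_tg(328.0, shape=(0.8, 0.6))
        temps = np.arange(vft.T0 + 20.0, 400.0, 2.0)
        series, _ = generate_single_frequency_scan(vft, 1500.0, temps)
        eps = np.array([s.eps_real[0] for s in series])
        # glass plateau near ε∞, then a step up towards εs
        assert eps[0] == pytest.approx(3.0, abs=0.1)
        assert eps.max() > 6.0


class TestIsothermalTrace:
    KERNEL = CrystallizationKernel(onset=7200.0, rate=2e-9, exponent=2.0)

    def test_rate_to_zero_limit_is_flat(self):
        kern = CrystallizationKernel(onset=0.0, rate=1e-30, exponent=2.0)
        tr = generate_isothermal_trace(10.0, 4.0, kern, np.linspace(0, 1e5, 50))
        np.testing.assert_allclose(tr.eps_real, 10.0, rtol=1e-9)

    def test_characteristic_time_crossing(self):
        """ε′_N reaches 1 − 1/e exactly where k·(t − t_onset)^n = 1."""
        t_char = self.KERNEL.onset + (1.0 / self.KERNEL.rate) ** (1.0 / self.KERNEL.exponent)
        t = np.array([0.0, self.KERNEL.onset, t_char, 1e7])
        tr = generate_isothermal_trace(10.0, 4.0, self.KERNEL, t)
        norm = (10.0 - tr.eps_real) / (10.0 - 4.0)
        assert norm[2] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)

    def test_plateau_before_onset(self):
        t = np.linspace(0.0, self.KERNEL.onset, 20)
        tr = generate_isothermal_trace(10.0, 4.0, self.KERNEL, t)
        np.testing.assert_allclose(tr.eps_real, 10.0, rtol=1e-12)

    def test_incomplete_crystallization_floor(self):
        kern = CrystallizationKernel(onset=0.0, rate=1e-6, exponent=2.0, x_max=0.8)
        tr = generate_isothermal_trace(10.0, 4.0, kern, np.linspace(0, 1e6, 50))
        # observed plateau stays above the true high-frequency limit
        assert tr.eps_real[-1] == pytest.approx(10.0 - 0.8 * 6.0, rel=1e-6)
        assert tr.eps_real[-1] > 4.0

    def test_validation(self):
        with pytest.raises(ValidationError):
            generate_isothermal_trace(4.0, 10.0, self.KERNEL, np.linspace(0, 10, 5))


class TestTgComposition:
    def test_k_one_linear(self):
        model = GTModel(tg1=331.0, tg2=376.0, K=1.0)
        pts = generate_tg_composition(model, np.linspace(0, 1, 5))
        tgs = np.array([p.tg for p in pts])
        np.testing.assert_allclose(np.diff(tgs), np.diff(tgs)[0], rtol=1e-10)

    def test_noiseless_endpoint(self):
        model = GTModel(tg1=331.0, tg2=376.0, K=0.7)
        pts = generate_tg_composition(model, [0.0, 0.5])
        assert pts[0].tg == pytest.approx(331.0, rel=1e-14)

    def test_fit_round_trip(self):
        model = GTModel(tg1=331.0, tg2=376.0, K=1.5)
        pts = generate_tg_composition(model, np.linspace(0.1, 0.9, 7))
        fit = fit_gt_k(pts, tg1=331.0, tg2=376.0)
        assert fit.model.K == pytest.approx(1.5, rel=1e-10)


class TestVFTAnchoring:
    def test_plain_anchor_hits_tau_ref(self):
        vft = vft_for_tg(328.0)
        assert eval_vft(vft, 328.0) == pytest.approx(100.0, rel=1e-12)
        assert tg_from_vft(vft) == pytest.approx(328.0, rel=1e-12)

    def test_shape_anchor_hits_peak_time(self):
        from dielstab.hn import hn_peak_time

        vft = vft_for_tg(328.0, shape=(0.8, 0.6))
        ratio = hn_peak_time(HNFit(delta_eps=1.0, tau_hn=1.0, a=0.8, b=0.6,
                                   eps_inf=1.0))
        # τ_HN at Tg is 100/ratio, so the loss-peak time is exactly 100 s
        assert eval_vft(vft, 328.0) * ratio == pytest.approx(100.0, rel=1e-12)
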