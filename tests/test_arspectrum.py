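"""Burg AR estimation, AIC order selection, PSD and peak frequency.

The independent oracles here are: per-order from-scratch Burg refits (for
the single-sweep error sequence), the closed-form AR(2) peak location, a
Parseval power balance, and zero-padded periodograms.
"""

import numpy as np
import pytest
from scipy import signal as ss

from gillwave.arspectrum import (
    ARModel,
    ar_psd,
    aic_curve,
    burg_fit,
    peak_frequency,
    segment_peak_frequency,
    select_order_aic,
)
from gillwave.conditioning import VENTILATORY_FILTER, bandpass, segment_signal, standardize
from gillwave.errors import NoPeakError, OrderError
from gillwave.synth import VentilatorySimSpec, gen_ventilatory

RATE = 500.0


def simulate_ar(coeffs, n, seed, sigma=1.0):
    """x_t = -sum a_k x_{t-k} + e_t with burn-in."""
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    x = np.zeros(n + 500)
    e = sigma * rng.standard_normal(n + 500)
    for t in range(p, n + 500):
        x[t] = -np.dot(coeffs, x[t - p : t][::-1]) + e[t]
    return x[500:]


class TestBurgFit:
    def test_ar1_consistency(self):
        x = simulate_ar([-0.9], 5000, seed=1)
        m = burg_fit(x - x.mean(), 1, RATE)
        assert m.coefficients[0] == pytest.approx(-0.9, abs=0.02)

    def test_white_noise(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        m = burg_fit(x - x.mean(), 1, RATE)
        assert abs(m.coefficients[0]) < 0.05
        assert m.residual_variance == pytest.approx(np.var(x), rel=0.05)

    def test_order_too_high(self):
        with pytest.raises(OrderError):
            burg_fit(np.random.default_rng(0).standard_normal(40), 20, RATE)

    @pytest.mark.parametrize("seed", range(5))
    def test_stability_and_monotone_error(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(400)
        errors = []
        for p in range(1, 30):
            m = burg_fit(x, p, RATE)
            assert np.all(np.abs(m.reflection) < 1.0)
            assert np.all(np.abs(m.poles()) < 1.0)
            errors.append(m.residual_variance)
        assert np.all(np.diff(errors) <= 1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1000)
        m1 = burg_fit(x, 8, RATE)
        m2 = burg_fit(5.0 * x, 8, RATE)
        np.testing.assert_allclose(m2.coefficients, m1.coefficients, atol=1e-12)
        assert m2.residual_variance == pytest.approx(25.0 * m1.residual_variance)


class TestOrderSelection:
    def test_sweep_matches_independent_refits(self):
        # the single-sweep error sequence must equal from-scratch fits
        rng = np.random.default_rng(4)
        x = rng.standard_normal(600)
        orders, aic = aic_curve(x, p_min=1, p_max=30)
        for p in orders:
            ref = burg_fit(x, int(p), RATE).residual_variance
            expected = len(x) * np.log(ref) + 2 * p
            assert aic[p - 1] == pytest.approx(expected, abs=1e-9)

    def test_low_order_process_clamps_to_p_min(self):
        # AR(4) with well-damped poles: AIC is flat beyond the true order,
        # so the selected order clamps to the lower bound of the scan range
        a = np.real(np.poly([0.5, -0.4, 0.3j, -0.3j]))[1:]
        x = simulate_ar(a, 2500, seed=5)
        best, model = select_order_aic(x - x.mean(), RATE, p_min=10, p_max=50)
        orders, aic = aic_curve(x - x.mean(), p_min=10, p_max=50)
        assert best == orders[np.argmin(aic)]  # brute-force grid agreement
        assert best == 10

    def test_singleton_range(self):
        rng = np.random.default_rng(6)
        best, model = select_order_aic(rng.standard_normal(200), RATE, p_min=12, p_max=12)
        assert best == 12 and model.order == 12


class TestArPsd:
    def test_flat_spectrum_for_trivial_model(self):
        m = ARModel(order=1, coefficients=np.array([0.0]), residual_variance=2.0,
                    rate_hz=RATE, n_samples=1000)
        psd = ar_psd(m, n_freq=64)
        np.testing.assert_allclose(psd.power, 2.0 / RATE, rtol=1e-12)

    @pytest.mark.parametrize("radius", [0.98, 0.995, 0.999])
    def test_ar2_peak_matches_closed_form(self, radius):
        # closed-form AR(2) peak: cos(w) = -a1 (1 + a2) / (4 a2).  Note the
        # peak sits below the pole angle when the pole is near DC relative
        # to the bandwidth (e.g. 2.533 Hz for radius 0.98 at 3 Hz / 500 Hz);
        # only as radius -> 1 does it converge to the pole angle.
        theta = 2 * np.pi * 3.0 / RATE
        a = np.array([-2 * radius * np.cos(theta), radius**2])
        expected = np.arccos(-a[0] * (1 + a[1]) / (4 * a[1])) * RATE / (2 * np.pi)
        m = ARModel(order=2, coefficients=a, residual_variance=1.0,
                    rate_hz=RATE, n_samples=2500)
        psd = ar_psd(m, n_freq=9001, band=(0.5, 10.0))
        assert peak_frequency(psd, band=(0.5, 10.0)) == pytest.approx(expected, abs=0.01)

    def test_ar2_sharp_pole_peaks_at_pole_angle(self):
        theta = 2 * np.pi * 3.0 / RATE
        a = np.array([-2 * 0.999 * np.cos(theta), 0.999**2])
        m = ARModel(order=2, coefficients=a, residual_variance=1.0,
                    rate_hz=RATE, n_samples=2500)
        psd = ar_psd(m, n_freq=9001, band=(1.0, 10.0))
        assert peak_frequency(psd) == pytest.approx(3.0, abs=0.05)

    def test_parseval_total_power(self):
        x = simulate_ar([-0.8], 20000, seed=7)
        m = burg_fit(x - x.mean(), 1, RATE)
        psd = ar_psd(m, n_freq=8192)
        total = 2.0 * np.trapezoid(psd.power, psd.frequencies_hz)  # one-sided
        assert total == pytest.approx(np.var(x), rel=0.05)


class TestPeakFrequency:
    def test_argmax_definition(self):
        freqs = np.arange(1.0, 10.0001, 0.02)
        power = np.ones_like(freqs)
        power[np.argmin(np.abs(freqs - 2.44))] = 5.0
        m = ARModel(1, np.array([0.0]), 1.0, RATE, 100)
        psd = ar_psd(m, n_freq=2)
        psd.frequencies_hz, psd.power = freqs, power
        assert peak_frequency(psd) == pytest.approx(2.44, abs=1e-9)

    def test_flat_spectrum_raises(self):
        m = ARModel(1, np.array([0.0]), 1.0, RATE, 100)
        psd = ar_psd(m, n_freq=2001, band=(1.0, 10.0))
        with pytest.raises(NoPeakError):
            peak_frequency(psd)

    def test_white_noise_low_order_fit_is_flat(self):
        # a first-order fit to white noise leaves the 1-10 Hz band flat
        # (max/min ratio under the 1.001 guard), so no peak is reported
        x = np.random.default_rng(0).standard_normal(2500)
        m = burg_fit(x - x.mean(), 1, RATE)
        psd = ar_psd(m, n_freq=901, band=(1.0, 10.0))
        with pytest.raises(NoPeakError):
            peak_frequency(psd)

    def test_coarse_grid_rejected(self):
        m = ARModel(1, np.array([-0.5]), 1.0, RATE, 100)
        psd = ar_psd(m, n_freq=32)  # ~8 Hz spacing
        with pytest.raises(NoPeakError):
            peak_frequency(psd)


class TestFullSpectralChain:
    def test_periodic_3hz_signal(self):
        rec, _ = gen_ventilatory(
            VentilatorySimSpec(mean_freq_hz=3.0, interval_cv=0.0, noise_sd=0.01,
                               duration_s=10.0, seed=9)
        )
        x = bandpass(rec.samples[0], rec.rate_hz, VENTILATORY_FILTER)
        z = standardize(segment_signal(x, rec.rate_hz)[1])
        pf = segment_peak_frequency(z.values, rec.rate_hz)
        assert pf == pytest.approx(3.0, abs=0.05)
        # periodogram oracle on the same segment agrees to within a grid step
        f, p = ss.periodogram(z.values, fs=rec.rate_hz, nfft=2**16)
        band = (f >= 1.0) & (f <= 10.0)
        assert pf == pytest.approx(f[band][np.argmax(p[band])], abs=0.05)

    def test_peak_invariant_to_amplitude(self):
        rec, _ = gen_ventilatory(
            VentilatorySimSpec(mean_freq_hz=2.5, interval_cv=0.05, duration_s=6.0, seed=10)
        )
        x = rec.samples[0][:2500]
        x = x - x.mean()
        assert segment_peak_frequency(x, RATE) == segment_peak_frequency(40.0 * x, RATE)
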