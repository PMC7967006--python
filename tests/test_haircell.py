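import numpy as np
import pytest

from vestsim.haircell import (AdaptationParams, adaptation_response,
                              combined_rate, fit_adaptation_gains,
                              transfer_function)
from vestsim.stimulus import make_sinusoid, make_step, make_zero

DT = 0.1
P_SYM = AdaptationParams(G_f=2.0, G_s=0.5, tau_f=0.15, tau_s=2.0,
                         anodic_fast_attenuation=1.0, f_c=1e6)


class TestAdaptationResponse:
    def test_zero_stimulus_zero_response(self):
        w = make_zero(1000.0, DT)
        assert np.all(adaptation_response(w, P_SYM) == 0.0)

    def test_step_matches_closed_form(self):
        # cathodic step of -A uA -> drive +A: fr = A (G_f e^-t/tf + G_s e^-t/ts)
        A = 10.0
        w = make_step(-A, 0.0, 20000.0, 20000.0, DT)
        fr = adaptation_response(w, P_SYM, include_lpf=False)
        t_s = w.t / 1000.0
        expected = A * (P_SYM.G_f * np.exp(-t_s / P_SYM.tau_f)
                        + P_SYM.G_s * np.exp(-t_s / P_SYM.tau_s))
        np.testing.assert_allclose(fr, expected, rtol=1e-6, atol=1e-6 * A)

    def test_full_adaptation_returns_to_zero(self):
        w = make_step(-10.0, 0.0, 25000.0, 25000.0, DT)
        fr = adaptation_response(w, P_SYM)
        t10 = w.t >= 10 * P_SYM.tau_s * 1000.0
        assert np.all(np.abs(fr[t10]) < 0.5)

    def test_anodic_fast_component_attenuated(self):
        p = AdaptationParams(anodic_fast_attenuation=0.5)
        cath = adaptation_response(make_step(-10, 0, 5000, 5000, DT), p)
        anod = adaptation_response(make_step(+10, 0, 5000, 5000, DT), p)
        # anodic transient is weaker than mirror-image of cathodic
        assert np.abs(anod).max() < cath.max()

    def test_onset_amplitude_is_sum_of_gains(self):
        A = 10.0
        w = make_step(-A, 0.0, 5000.0, 5000.0, DT)
        fr = adaptation_response(w, P_SYM, include_lpf=False)
        assert fr.max() == pytest.approx(A * (P_SYM.G_f + P_SYM.G_s), rel=1e-3)


class TestCombinedRate:
    def test_zero_adaptation_is_clipped_axonal(self):
        fr_ax = np.array([-5.0, 10.0, 70.0])
        out = combined_rate(np.zeros(3), fr_ax, 0.0, 55.0)
        np.testing.assert_allclose(out.fr_total, [0.0, 10.0, 55.0])

    def test_sum_clips_at_fr_max(self):
        out = combined_rate(np.array([50.0]), np.array([20.0]), 0.0, 55.0)
        assert out.fr_total[0] == 55.0

    def test_invalid_fr_max_rejected(self):
        with pytest.raises(ValueError):
            combined_rate(np.zeros(3), np.zeros(3), 0.0, -1.0)

    def test_effect_v_asymmetry_in_vitro(self):
        """Anodic baseline + further anodic step plateaus at 0 while the
        cathodic mirror plateaus at the ceiling (low-rate clipped afferent)."""
        p = P_SYM
        fr_o = 17.5
        from vestsim.stimulus import make_baseline_step

        w_an = make_baseline_step(+10.0, +20.0, 15000.0, 10000.0, DT)
        fr = adaptation_response(w_an, p)
        out = combined_rate(fr, fr_o, 0.0, 55.0)
        seg = out.fr_total[(w_an.t > 15000.0) & (w_an.t < 16000.0)]
        assert np.any(seg == 0.0)  # floored
        w_ca = make_baseline_step(-10.0, -20.0, 15000.0, 10000.0, DT)
        out2 = combined_rate(adaptation_response(w_ca, p), fr_o, 0.0, 55.0)
        seg2 = out2.fr_total[(w_ca.t > 15000.0) & (w_ca.t < 16000.0)]
        assert np.any(seg2 == 55.0)  # ceiling


class TestTransferFunction:
    def test_low_frequency_highpass_limit(self):
        H = transfer_function(1e-5, P_SYM)
        assert np.abs(H) < 1e-3
        assert np.angle(H, deg=True) == pytest.approx(90.0, abs=0.5)

    def test_single_pole_closed_form(self):
        p = AdaptationParams(G_f=2.0, G_s=0.0, tau_f=0.15, tau_s=2.0, f_c=1e9)
        f_corner = 1.0 / (2 * np.pi * p.tau_f)
        H = transfer_function(f_corner, p)
        assert np.abs(H) == pytest.approx(p.G_f / np.sqrt(2), rel=1e-6)
        assert np.angle(H, deg=True) == pytest.approx(45.0, abs=1e-6)

    def test_phase_lead_decays_with_frequency(self):
        f = np.array([0.1, 1.0, 4.0, 8.0])
        ph = np.angle(transfer_function(f, AdaptationParams()), deg=True)
        assert ph[0] > 20.0
        assert np.all(np.diff(ph) < 0)
        assert ph[-1] < 10.0

    def test_fft_oracle_matches_transfer_function(self):
        """Impulse response of the discrete filters vs the analytic H(f), to
        1% over 0.01-100 Hz."""
        p = AdaptationParams()
        dt = 0.1  # ms
        n = 2 ** 20  # ~105 s record -> resolves 0.01 Hz
        dt_s = dt / 1000.0
        x = np.zeros(n)
        x[0] = 1.0 / dt_s  # unit-area impulse
        from vestsim.stimulus import StimulusWaveform

        w = StimulusWaveform(np.arange(n) * dt, -x, "step", {})
        h = adaptation_response(w, p)
        freqs = np.fft.rfftfreq(n, d=dt_s)
        sel = (freqs >= 0.01) & (freqs <= 100.0)
        # the filters treat input as piecewise-constant over each sample;
        # compensate the known half-sample (zero-order-hold) delay before
        # comparing against the continuous-time response
        H_num = (np.fft.rfft(h)[sel] * dt_s
                 * np.exp(1j * np.pi * freqs[sel] * dt_s))
        H_ana = transfer_function(freqs[sel], p)
        rel = np.abs(H_num - H_ana) / np.abs(H_ana)
        assert rel.max() < 0.01


class TestFitGains:
    def _trace(self, p, A, total_ms=15000.0, dt=10.0, noise=0.0, rng=None):
        t = np.arange(0.0, total_ms, dt)
        att = 1.0 if A >= 0 else p.anodic_fast_attenuation
        y = A * (att * p.G_f * np.exp(-t / (p.tau_f * 1000.0))
                 + p.G_s * np.exp(-t / (p.tau_s * 1000.0)))
        if noise:
            y = y + rng.normal(0, noise, size=y.size)
        return t, y, A

    def test_noiseless_exact_recovery(self):
        p = AdaptationParams(G_f=1.8, G_s=0.6)
        traces = [self._trace(p, 10.0), self._trace(p, -10.0)]
        fit, resid = fit_adaptation_gains(traces, fixed_taus=(0.15, 2.0))
        assert fit.G_f == pytest.approx(1.8, rel=1e-6)
        assert fit.G_s == pytest.approx(0.6, rel=1e-6)
        assert resid < 1e-8

    def test_noisy_recovery_within_15_percent(self, rng):
        p = AdaptationParams(G_f=2.0, G_s=0.5)
        peak = 10.0 * (p.G_f + p.G_s)
        errs_f, errs_s = [], []
        for _ in range(20):
            traces = [self._trace(p, 10.0, noise=0.1 * peak, rng=rng),
                      self._trace(p, -10.0, noise=0.1 * peak, rng=rng)]
            fit, _ = fit_adaptation_gains(traces, fixed_taus=(0.15, 2.0))
            errs_f.append(abs(fit.G_f - p.G_f) / p.G_f)
            errs_s.append(abs(fit.G_s - p.G_s) / p.G_s)
        assert np.median(errs_f) < 0.15
        assert np.median(errs_s) < 0.15

    def test_in_vitro_like_traces_give_fast_dominant(self):
        p = AdaptationParams(G_f=2.2, G_s=0.4)
        traces = [self._trace(p, 10.0), self._trace(p, -10.0)]
        fit, _ = fit_adaptation_gains(traces)
        assert fit.G_f > fit.G_s

    def test_degenerate_trace_rejected(self):
        t = np.arange(0.0, 1000.0, 10.0)
        with pytest.raises(RuntimeError):
            fit_adaptation_gains([(t, np.ones_like(t) * 3.0, 10.0)])


def test_params_validation():
    with pytest.raises(ValueError):
        AdaptationParams(tau_f=2.0, tau_s=0.15)
    with pytest.raises(ValueError):
        AdaptationParams(anodic_fast_attenuation=1.5)
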