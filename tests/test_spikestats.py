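import numpy as np
import pytest

from vestsim.axon import SpikeTrain
from vestsim.experiments import generate_fixtures
from vestsim.spikestats import (CVStarEnvelope, cluster_permutation_test,
                                cv_star_conformance, cycle_metrics,
                                fit_step_response, rate_trace, response_slope,
                                spike_statistics)
from vestsim.stimulus import make_sinusoid


class TestSpikeStatistics:
    def test_periodic_train(self):
        tr = generate_fixtures("periodic_train", {"isi_ms": 10.0}, seed=0)
        st = spike_statistics(tr)
        assert st.mean_rate == pytest.approx(100.0, rel=1e-9)
        assert st.cv == pytest.approx(0.0, abs=1e-12)

    def test_alternating_isis_closed_form(self):
        # ISIs a=5, b=15 alternating -> CV = |a-b|/(a+b) = 0.5
        isis = np.tile([5.0, 15.0], 500)
        tr = SpikeTrain(np.concatenate([[0.0], np.cumsum(isis)]))
        st = spike_statistics(tr)
        assert st.cv == pytest.approx(0.5, abs=1e-3)

    def test_poisson_cv_near_one(self):
        # 1e4 spikes; SE of CV for exponential ISIs ~ 1/sqrt(n)
        tr = generate_fixtures("poisson_train",
                               {"rate_sps": 100.0, "total_ms": 1.0e5}, seed=2)
        st = spike_statistics(tr)
        assert abs(st.cv - 1.0) < 3.0 / np.sqrt(st.n_spikes)

    def test_rate_isi_consistency(self):
        tr = generate_fixtures("poisson_train",
                               {"rate_sps": 80.0, "total_ms": 20000.0}, seed=3)
        st = spike_statistics(tr)
        assert st.mean_rate * st.mean_isi == pytest.approx(1000.0, rel=1e-6)

    def test_too_few_spikes_flags_cv(self):
        st = spike_statistics(SpikeTrain(np.array([1.0, 5.0])),
                              window_ms=(0.0, 10.0))
        assert st.mean_rate == pytest.approx(200.0)
        assert not st.cv_defined

    def test_subsampling_raises_cv(self, rng):
        """Sampling-variance law: keeping fewer events from one underlying
        train (fewer EPSCs become APs) increases CV.  For a periodic source
        thinned with probability p the ISI is a geometric multiple of the
        period, so CV = sqrt(1 - p): monotone in the retained fraction."""
        tr = generate_fixtures("periodic_train",
                               {"isi_ms": 5.0, "total_ms": 4.0e5}, seed=0)
        fracs = (1.0, 0.5, 0.25, 0.125)
        cvs = []
        for frac in fracs:
            keep = rng.uniform(size=tr.spike_times.size) < frac
            cvs.append(spike_statistics(SpikeTrain(tr.spike_times[keep])).cv)
        assert all(b > a for a, b in zip(cvs, cvs[1:]))
        for frac, cv in zip(fracs[1:], cvs[1:]):
            assert cv == pytest.approx(np.sqrt(1 - frac), abs=0.05)


class TestCVStar:
    def test_midline_points_inside(self):
        env = CVStarEnvelope()
        isi = np.geomspace(2, 500, 50)
        mid = 0.5 * (env.lower(isi) + env.upper(isi))
        assert cv_star_conformance(np.column_stack([isi, mid]), env) == 1.0

    def test_points_above_envelope_outside(self):
        env = CVStarEnvelope()
        isi = np.geomspace(2, 500, 50)
        pts = np.column_stack([isi, env.upper(isi) * 2.0])
        assert cv_star_conformance(pts, env) == 0.0

    def test_half_in_half_out(self):
        env = CVStarEnvelope()
        isi = np.geomspace(2, 500, 40)
        mid = 0.5 * (env.lower(isi) + env.upper(isi))
        pts = np.column_stack([np.tile(isi, 2),
                               np.concatenate([mid, env.upper(isi) * 3])])
        assert cv_star_conformance(pts, env) == pytest.approx(0.5)

    def test_out_of_domain_counted_with_warning(self):
        env = CVStarEnvelope(isi_min=1.0, isi_max=100.0)
        inside_cv = 0.5 * (env.lower(10.0) + env.upper(10.0))
        pts = np.array([[10.0, inside_cv], [1e4, inside_cv]])
        with pytest.warns(UserWarning):
            frac = cv_star_conformance(pts, env)
        assert frac == pytest.approx(0.5)


class TestResponseSlope:
    def test_exact_line(self):
        amps = np.arange(-40.0, 41.0, 10.0)
        rates = np.tile(100.0 - 2.0 * amps, (5, 1))
        curve = response_slope(amps, rates, (-45, 45), n_boot=200, seed=0)
        assert curve.slope == pytest.approx(-2.0, rel=1e-9)
        assert curve.slope_ci[1] - curve.slope_ci[0] == pytest.approx(0.0, abs=1e-9)

    def test_bootstrap_ci_covers_truth(self, rng):
        # 100 synthetic replicates with Gaussian rate noise; ~95% coverage
        amps = np.arange(-40.0, 41.0, 10.0)
        true_slope = -1.5
        covered = 0
        for rep in range(100):
            rates = (100.0 + true_slope * amps
                     + rng.normal(0, 4.0, size=(8, amps.size)))
            c = response_slope(amps, rates, (-45, 45), n_boot=300, seed=rep)
            if c.slope_ci[0] <= true_slope <= c.slope_ci[1]:
                covered += 1
        assert covered >= 88  # >= ~93 expected minus binomial slack

    def test_too_few_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            response_slope(np.array([0.0, 10.0]), np.zeros((2, 2)), (-45, 45))


class TestFitStepResponse:
    def test_noiseless_recovery(self):
        t, y = generate_fixtures("double_exp_rate_trace",
                                 {"G_f": 18.0, "G_s": 6.0, "tau_f": 0.15,
                                  "tau_s": 2.0, "offset": -12.0,
                                  "baseline": 100.0, "onset_ms": 1000.0,
                                  "total_ms": 15000.0}, seed=0)
        fit = fit_step_response(t, y, 1000.0)
        assert fit["G_f"] == pytest.approx(18.0, rel=1e-3)
        assert fit["G_s"] == pytest.approx(6.0, rel=1e-3)
        assert fit["tau_f"] == pytest.approx(0.15, rel=1e-3)
        assert fit["tau_s"] == pytest.approx(2.0, rel=1e-3)
        assert fit["baseline_shift"] == pytest.approx(-12.0, rel=1e-3)

    def test_noisy_recovery_reasonable(self):
        # median over seeds: single noisy traces identify tau_s only weakly
        errs_f, errs_s = [], []
        for seed in range(7):
            t, y = generate_fixtures("double_exp_rate_trace",
                                     {"G_f": 20.0, "G_s": 6.0,
                                      "noise_sps": 1.5, "baseline": 50.0,
                                      "onset_ms": 1000.0,
                                      "total_ms": 21000.0}, seed=seed)
            fit = fit_step_response(t, y, 1000.0)
            errs_f.append(abs(fit["tau_f"] - 0.15) / 0.15)
            errs_s.append(abs(fit["tau_s"] - 2.0) / 2.0)
        assert np.median(errs_f) < 0.5
        assert np.median(errs_s) < 0.5


class TestCycleMetrics:
    def test_uniform_spikes_symmetric(self):
        stim = make_sinusoid(10.0, 1.0, 10, 0.1)
        tr = SpikeTrain(np.arange(5.0, 10000.0, 7.0))
        m = cycle_metrics(tr, stim)
        assert m["cathodic_rate"] == pytest.approx(m["anodic_rate"], rel=0.02)

    def test_sinusoidal_poisson_phase_recovery(self):
        # rate = R0 + R1 sin(2 pi f t + phi): the rate peak precedes the
        # cathodic stimulus peak (quarter cycle into the period) by exactly
        # phi, so the estimated lead should recover phi within 5 deg given
        # ~1e4 spikes
        f = 1.0
        phi = 30.0
        tr = generate_fixtures("sinusoidal_poisson_train",
                               {"R0_sps": 100.0, "R1_sps": 40.0,
                                "freq_hz": f, "phase_deg": phi,
                                "total_ms": 1.0e5}, seed=6)
        assert tr.spike_times.size > 9000
        stim = make_sinusoid(10.0, f, 100, 0.1)
        m = cycle_metrics(tr, stim)
        assert m["phase_defined"]
        assert m["phase_lead_deg"] == pytest.approx(phi, abs=5.0)

    def test_phase_reference_roundtrip(self):
        # spikes exactly at the cathodic peak of every cycle -> zero lead
        f = 2.0
        period = 500.0
        stim = make_sinusoid(10.0, f, 20, 0.1)
        tr = SpikeTrain(period * np.arange(20) + period / 4.0)
        m = cycle_metrics(tr, stim)
        assert m["phase_lead_deg"] == pytest.approx(0.0, abs=6.0)
        # spikes an eighth-cycle earlier -> +45 deg lead
        tr2 = SpikeTrain(period * np.arange(20) + period / 8.0)
        m2 = cycle_metrics(tr2, stim)
        assert m2["phase_lead_deg"] == pytest.approx(45.0, abs=6.0)

    def test_no_spikes_flagged(self):
        stim = make_sinusoid(10.0, 1.0, 10, 0.1)
        m = cycle_metrics(SpikeTrain(np.empty(0)), stim)
        assert m["cathodic_rate"] == 0.0
        assert not m["phase_defined"]


class TestClusterPermutation:
    def _null_traces(self, rng, n=6, t=80):
        return rng.normal(50.0, 5.0, size=(n, t))

    def test_identical_data_no_clusters(self, rng):
        A = self._null_traces(rng)
        assert cluster_permutation_test(A, A.copy(), n_perm=200, seed=1) == []

    def test_strong_offset_segment_detected(self, rng):
        A = self._null_traces(rng, n=8, t=100)
        B = self._null_traces(rng, n=8, t=100)
        B[:, 40:60] += 40.0  # offset >> noise on a contiguous window
        found = cluster_permutation_test(A, B, n_perm=300, seed=2)
        assert len(found) >= 1
        best = max(found, key=lambda c: c["score"])
        assert best["start"] >= 35 and best["stop"] <= 65

    def test_small_n_perm_refused(self, rng):
        A = self._null_traces(rng)
        with pytest.raises(ValueError):
            cluster_permutation_test(A, A, n_perm=50)


def test_rate_trace_boxcar():
    trains = [SpikeTrain(np.arange(0.0, 1000.0, 10.0))]  # 100 sps
    t, R = rate_trace(trains, 1000.0, bin_ms=100.0)
    assert R.shape == (1, 10)
    np.testing.assert_allclose(R[0], 100.0)
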