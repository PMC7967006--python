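"""Spike-train response statistics.

Firing rate / ISI / CV summaries, conformance to a CV-vs-ISI (CV*) envelope,
rate-versus-current slopes with bootstrap confidence intervals, fast/slow
double-exponential fits of adapting rate traces, sinusoidal half-cycle gain
and phase, and a cluster-based permutation test for comparing rate traces
between conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.optimize import curve_fit

from .axon import SpikeTrain
from .stimulus import StimulusWaveform

__all__ = [
    "SpikeStatistics",
    "CVStarEnvelope",
    "ResponseCurve",
    "spike_statistics",
    "cv_star_conformance",
    "response_slope",
    "rate_trace",
    "fit_step_response",
    "cycle_metrics",
    "cluster_permutation_test",
]


@dataclass(frozen=True)
class SpikeStatistics:
    mean_rate: float  # sps
    mean_isi: float  # ms (nan if < 2 spikes)
    cv: float  # std(ISI)/mean(ISI); nan if undefined
    n_spikes: int

    @property
    def cv_defined(self) -> bool:
        return np.isfinite(self.cv)


def spike_statistics(train: SpikeTrain, window_ms: tuple | None = None) -> SpikeStatistics:
    """Rate, mean ISI and CV of a spike train (optionally within a window).

    ``mean_rate`` counts spikes over the window span (sps).  CV requires at
    least three spikes (two ISIs); otherwise it is returned as nan.
    """
    t = train.spike_times
    if window_ms is not None:
        lo, hi = window_ms
        t = t[(t >= lo) & (t < hi)]
        span = hi - lo
        n_for_rate = t.size
    else:
        span = t[-1] - t[0] if t.size >= 2 else np.nan
        n_for_rate = t.size - 1  # events per spanned interval, = 1000/mean_isi
    n = t.size
    rate = (1000.0 * n_for_rate / span
            if span and np.isfinite(span) and span > 0 else 0.0)
    if n >= 2:
        isi = np.diff(t)
        mean_isi = float(isi.mean())
        cv = float(isi.std(ddof=0) / mean_isi) if n >= 3 else np.nan
    else:
        mean_isi, cv = np.nan, np.nan
    return SpikeStatistics(float(rate), mean_isi, cv, int(n))


# --------------------------------------------------------------------------
# CV* envelope


@dataclass(frozen=True)
class CVStarEnvelope:
    """Lower/upper CV-vs-mean-ISI boundary curves.

    Curves are parameterized as power laws ``cv = c * (isi_ms)**e`` between
    ``isi_min`` and ``isi_max``; any callable pair can be substituted.  The
    default is a synthetic irregular-afferent-like band (CV falling with
    rate), intended for testing conformance logic — it is not a digitization
    of any published boundary.
    """

    lower_coef: float = 0.04
    lower_exp: float = 0.9
    upper_coef: float = 0.12
    upper_exp: float = 0.9
    isi_min: float = 1.0
    isi_max: float = 1000.0
    source: str = "synthetic-default"

    def lower(self, isi_ms):
        return self.lower_coef * np.asarray(isi_ms, dtype=float) ** self.lower_exp

    def upper(self, isi_ms):
        return self.upper_coef * np.asarray(isi_ms, dtype=float) ** self.upper_exp

    def __post_init__(self) -> None:
        isi = np.geomspace(max(self.isi_min, 1e-6), self.isi_max, 64)
        if np.any(self.upper(isi) < self.lower(isi)):
            raise ValueError("upper boundary must lie above the lower boundary")


def cv_star_conformance(points, env: CVStarEnvelope) -> float:
    """Fraction of (mean_isi_ms, cv) points lying inside the envelope.

    Points with ISI outside the envelope's domain are excluded from the
    numerator but kept in the denominator, with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("no points supplied")
    isi, cv = pts[:, 0], pts[:, 1]
    in_domain = (isi >= env.isi_min) & (isi <= env.isi_max)
    if not np.all(in_domain):
        warnings.warn(f"{np.count_nonzero(~in_domain)} points outside the "
                      "envelope ISI domain; counted as non-conforming")
    inside = in_domain & (cv >= env.lower(isi)) & (cv <= env.upper(isi))
    return float(np.count_nonzero(inside) / pts.shape[0])


# --------------------------------------------------------------------------
# rate-vs-current slope


@dataclass(frozen=True)
class ResponseCurve:
    amplitudes: np.ndarray  # uA
    mean_rates: np.ndarray  # (n_neurons, n_amplitudes) sps
    slope: float  # sps/uA over the fit range
    slope_ci: tuple  # 95% bootstrap CI
    fit_range_uA: tuple
    degenerate: bool = False
    per_amplitude_mean: np.ndarray = field(default=None, repr=False)
    per_amplitude_std: np.ndarray = field(default=None, repr=False)


def response_slope(
    amplitudes: np.ndarray,
    rates: np.ndarray,
    fit_range_uA: tuple = (-45.0, 45.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> ResponseCurve:
    """Least-squares rate-vs-current slope with a bootstrap-over-neurons CI.

    ``rates`` has shape (n_neurons, n_amplitudes).  The slope is fitted on
    the per-neuron-averaged rates within ``fit_range_uA`` (the linear region
    below cathodic block); the 95% CI resamples neurons with replacement.
    """
    amps = np.asarray(amplitudes, dtype=float)
    R = np.atleast_2d(np.asarray(rates, dtype=float))
    if R.shape[1] != amps.size:
        raise ValueError("rates must be (n_neurons, n_amplitudes)")
    lo, hi = fit_range_uA
    sel = (amps >= lo) & (amps <= hi)
    if np.count_nonzero(sel) < 3:
        raise ValueError("need >= 3 amplitudes inside the fit range")
    x = amps[sel]

    def fit(mean_rates):
        return np.polyfit(x, mean_rates, 1)[0]

    mean_over_neurons = R[:, sel].mean(axis=0)
    slope = float(fit(mean_over_neurons))
    degenerate = bool(np.ptp(R[:, sel]) == 0)
    rng = np.random.default_rng(seed)
    n_neu = R.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_neu, size=n_neu)
        boots[b] = fit(R[pick][:, sel].mean(axis=0))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    if degenerate and np.ptp(mean_over_neurons) == 0:
        slope, ci = 0.0, (0.0, 0.0)
    return ResponseCurve(amps, R, slope, ci, (float(lo), float(hi)), degenerate,
                         R.mean(axis=0), R.std(axis=0))


# --------------------------------------------------------------------------
# rate traces and adaptation fits


def rate_trace(
    trains: list,
    total_ms: float,
    bin_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar firing-rate traces: (t_centers_ms, rates (n_neurons, n_bins) sps)."""
    edges = np.arange(0.0, total_ms + bin_ms / 2, bin_ms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.empty((len(trains), centers.size))
    for i, tr in enumerate(trains):
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        out[i] = counts * (1000.0 / bin_ms)
    return centers, out


def fit_step_response(
    t_ms: np.ndarray,
    rate_sps: np.ndarray,
    stim_onset_ms: float,
    baseline_rate: float | None = None,
    p0: dict | None = None,
) -> dict:
    """Fit a double exponential plus offset to the post-onset rate.

    Model (t measured from onset):
        rate(t) = baseline + shift + A_f exp(-t/tau_f) + A_s exp(-t/tau_s)

    ``shift`` (the axonal baseline offset that the transient decays to) and
    the fast/slow transient amplitudes and time constants are returned with
    keys G_f, G_s (amplitudes, sps), tau_f, tau_s (seconds) and
    baseline_shift (sps).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    rate = np.asarray(rate_sps, dtype=float)
    post = t_ms >= stim_onset_ms
    tt = (t_ms[post] - stim_onset_ms) / 1000.0  # seconds
    yy = rate[post]
    if baseline_rate is None:
        pre = t_ms < stim_onset_ms
        baseline_rate = float(rate[pre].mean()) if np.any(pre) else 0.0

    def model(t_s, A_f, A_s, tau_f, tau_s, shift):
        return (baseline_rate + shift + A_f * np.exp(-t_s / tau_f)
                + A_s * np.exp(-t_s / tau_s))

    peak = yy[0] - baseline_rate
    guess = p0 or {}
    p_init = [guess.get("G_f", 0.7 * peak), guess.get("G_s", 0.3 * peak),
              guess.get("tau_f", 0.15), guess.get("tau_s", 2.0),
              guess.get("baseline_shift", yy[-yy.size // 4:].mean() - baseline_rate)]
    sign = 1.0 if peak >= 0 else -1.0
    lo = [0, 0, 1e-3, 0.3, -np.inf] if sign > 0 else [-np.inf, -np.inf, 1e-3, 0.3, -np.inf]
    hi = [np.inf, np.inf, 0.3, 20.0, np.inf] if sign > 0 else [0, 0, 0.3, 20.0, np.inf]
    try:
        popt, pcov = curve_fit(model, tt, yy, p0=p_init, bounds=(lo, hi),
                               maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"step-response fit failed (baseline={baseline_rate:.2f}, "
            f"peak={peak:.2f}): {err}") from err
    A_f, A_s, tau_f, tau_s, shift = popt
    resid = yy - model(tt, *popt)
    return {
        "G_f": float(A_f), "G_s": float(A_s),
        "tau_f": float(tau_f), "tau_s": float(tau_s),
        "baseline_shift": float(shift),
        "baseline_rate": float(baseline_rate),
        "residual_norm": float(np.linalg.norm(resid)),
    }


# --------------------------------------------------------------------------
# sinusoidal metrics


def cycle_metrics(train: SpikeTrain, stim: StimulusWaveform, n_bins: int = 36) -> dict:
    """Half-cycle rates and first-harmonic phase lead for sinusoidal GVS.

    The stimulus convention puts the cathodic (excitatory) half first in each
    cycle with its peak at phase 90 deg.  ``phase_lead_deg`` is the phase of
    the fundamental of the cycle-averaged rate relative to that cathodic
    peak (positive = response peaks earlier in the cycle).
    """
    if stim.kind != "sinusoid":
        raise ValueError("cycle_metrics needs a sinusoid stimulus")
    f = stim.meta["freq_hz"]
    n_cycles = stim.meta["n_cycles"]
    if n_cycles < 5:
        raise ValueError("need >= 5 full cycles")
    period_ms = 1000.0 / f
    total_ms = n_cycles * period_ms
    t = train.spike_times
    t = t[(t >= 0) & (t < total_ms)]
    if t.size == 0:
        return {"cathodic_rate": 0.0, "anodic_rate": 0.0,
                "phase_lead_deg": np.nan, "phase_defined": False}
    phase = (t % period_ms) / period_ms  # in [0,1); cathodic half = [0, 0.5)
    cath = np.count_nonzero(phase < 0.5)
    anod = t.size - cath
    half_s = (n_cycles * period_ms / 2) / 1000.0
    cath_rate = cath / half_s
    anod_rate = anod / half_s
    # cycle-averaged rate histogram and its fundamental
    counts, edges = np.histogram(phase, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    c1 = np.sum(counts * np.exp(-2j * np.pi * centers))
    if np.abs(c1) == 0:
        return {"cathodic_rate": cath_rate, "anodic_rate": anod_rate,
                "phase_lead_deg": np.nan, "phase_defined": False}
    # response peak phase (fraction of cycle); cathodic stimulus peak at 0.25
    peak_frac = (-np.angle(c1) / (2 * np.pi)) % 1.0
    lead = (0.25 - peak_frac + 0.5) % 1.0 - 0.5  # wrap to (-0.5, 0.5]
    return {
        "cathodic_rate": float(cath_rate),
        "anodic_rate": float(anod_rate),
        "phase_lead_deg": float(lead * 360.0),
        "phase_defined": True,
    }


# --------------------------------------------------------------------------
# cluster-based permutation test


def _pointwise_t(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    nA, nB = A.shape[0], B.shape[0]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    vA, vB = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    pooled = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    denom = np.sqrt(pooled * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mA - mB) / denom, 0.0)
    return t


def _clusters(t_vals: np.ndarray, thresh: float) -> list:
    """Contiguous runs where |t| exceeds thresh, scored by summed |t|."""
    above = np.abs(t_vals) > thresh
    out = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            out.append((start, i, float(np.abs(t_vals[start:i]).sum())))
            start = None
    if start is not None:
        out.append((start, above.size, float(np.abs(t_vals[start:]).sum())))
    return out


def cluster_permutation_test(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> list:
    """Non-parametric cluster statistic comparing two sets of rate traces.

    Pointwise two-sample t-statistics are thresholded at the two-sided
    ``cluster_alpha`` critical value; contiguous supra-threshold clusters are
    scored by summed |t| and referred to a null distribution of maximum
    cluster scores obtained by permuting condition labels.

    Returns a list of dicts {start, stop, score, p} for clusters with
    p < alpha (start/stop are sample indices, stop exclusive).
    """
    A = np.atleast_2d(np.asarray(rates_a, dtype=float))
    B = np.atleast_2d(np.asarray(rates_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("conditions must share the time grid")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 traces per condition")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    nA = A.shape[0]
    df = nA + B.shape[0] - 2
    t_crit = sp_stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    observed = _clusters(_pointwise_t(A, B), t_crit)
    if not observed:
        return []
    pooled = np.vstack([A, B])
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    n_tot = pooled.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n_tot)
        pa, pb = pooled[perm[:nA]], pooled[perm[nA:]]
        cl = _clusters(_pointwise_t(pa, pb), t_crit)
        null_max[b] = max((c[2] for c in cl), default=0.0)
    results = []
    for start, stop, score in observed:
        p = (1.0 + np.count_nonzero(null_max >= score)) / (n_perm + 1.0)
        if p < alpha:
            results.append({"start": int(start), "stop": int(stop),
                            "score": score, "p": float(p)})
    return results
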