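"""Hair-cell adaptation: fast/slow high-pass response to galvanic current.

A step of current delivered at the hair cell produces a transient change in
afferent firing rate that decays fully back to baseline — the classic
adaptation seen with mechanical (cupula) steps.  Phenomenologically this is
the sum of a fast and a slow first-order high-pass filter acting on the
transduced drive:

    fr_adapt(t) = G_f * HP_{tau_f}[x](t) + G_s * HP_{tau_s}[x](t)

with x(t) = -i_ext(t) so that cathodic (negative uA) current is an
excitatory drive.  A step of drive amplitude A gives

    fr_adapt(t) = A * (G_f exp(-t/tau_f) + G_s exp(-t/tau_s)).

The fast component is weaker for inhibitory (anodic) input; this asymmetry
is applied on the input side of the fast filter.  A first-order low-pass
H_lpf (cutoff f_c, default 1 kHz) caps how fast the pathway can follow the
stimulus.  The total rate combines adaptation with the axonal rate and is
clipped to the afferent's firing range:

    fr(t) = clip(fr_adapt(t) + fr_axon(t), fr_min, fr_max).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import lfilter

from .stimulus import StimulusWaveform

__all__ = [
    "AdaptationParams",
    "FiringRateSeries",
    "adaptation_response",
    "combined_rate",
    "transfer_function",
    "fit_adaptation_gains",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Fast/slow adaptation gains and time constants.

    G_f, G_s : gains in sps per uA of (cathodic-positive) drive
    tau_f, tau_s : time constants in seconds (tau_f < tau_s)
    anodic_fast_attenuation : multiplier (<= 1) on the fast-component drive
        during anodic (inhibitory) input
    f_c : low-pass cutoff in Hz bounding how fast firing can follow the input
    """

    G_f: float = 2.0
    G_s: float = 0.5
    tau_f: float = 0.15
    tau_s: float = 2.0
    anodic_fast_attenuation: float = 0.5
    f_c: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_f < self.tau_s):
            raise ValueError("need 0 < tau_f < tau_s")
        if self.G_f < 0 or self.G_s < 0:
            raise ValueError("gains must be >= 0")
        if not (0 <= self.anodic_fast_attenuation <= 1):
            raise ValueError("anodic_fast_attenuation must be in [0, 1]")
        if self.f_c <= 0:
            raise ValueError("f_c must be positive")


@dataclass(frozen=True)
class FiringRateSeries:
    """Deterministic rate-level decomposition fr = clip(fr_adapt + fr_axon)."""

    t: np.ndarray  # ms
    fr_adapt: np.ndarray  # sps
    fr_axon: np.ndarray  # sps
    fr_total: np.ndarray  # sps, clipped
    clip_bounds: tuple  # (fr_min, fr_max)


def _lowpass_tau(x: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """First-order low-pass, exact for input held constant over each sample
    interval [t_k, t_{k+1}) (zero-order hold): the state at t_k has only
    integrated inputs up to x_{k-1}."""
    a = np.exp(-dt_ms / tau_ms)
    return lfilter([0.0, 1.0 - a], [1.0, -a], x)


def _highpass(x: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """Exact first-order high-pass (x minus its low-pass); a unit step yields
    exp(-t/tau) exactly on the grid, including 1 at the onset sample."""
    return x - _lowpass_tau(x, tau_ms, dt_ms)


def _lowpass(x: np.ndarray, f_c_hz: float, dt_ms: float) -> np.ndarray:
    return _lowpass_tau(x, 1000.0 / (2.0 * np.pi * f_c_hz), dt_ms)


def adaptation_response(
    w: StimulusWaveform,
    p: AdaptationParams,
    include_lpf: bool = True,
) -> np.ndarray:
    """fr_adapt(t) in sps for an electrode waveform.

    The drive is x(t) = -i_ext(t) (cathodic current excites).  During anodic
    segments (x < 0) the fast-component drive is scaled by
    ``anodic_fast_attenuation``.
    """
    dt = w.dt
    x = -w.i_ext
    x_fast = np.where(x >= 0, x, p.anodic_fast_attenuation * x)
    out = (p.G_f * _highpass(x_fast, p.tau_f * 1000.0, dt)
           + p.G_s * _highpass(x, p.tau_s * 1000.0, dt))
    if include_lpf:
        out = _lowpass(out, p.f_c, dt)
    return out


def combined_rate(
    fr_adapt: np.ndarray,
    fr_axon: np.ndarray | float,
    fr_min: float = 0.0,
    fr_max: float = 55.0,
    t: np.ndarray | None = None,
) -> FiringRateSeries:
    """fr(t) = clip(fr_adapt + fr_axon, fr_min, fr_max), element-wise."""
    if fr_max <= 0:
        raise ValueError("fr_max must be positive")
    fr_adapt = np.asarray(fr_adapt, dtype=float)
    fr_axon_arr = np.broadcast_to(np.asarray(fr_axon, dtype=float),
                                  fr_adapt.shape).astype(float)
    total = np.clip(fr_adapt + fr_axon_arr, fr_min, fr_max)
    if t is None:
        t = np.arange(fr_adapt.size, dtype=float)
    return FiringRateSeries(t, fr_adapt, fr_axon_arr, total, (fr_min, fr_max))


def transfer_function(freq_hz, p: AdaptationParams) -> np.ndarray:
    """Complex frequency response H(f) of the adaptation pathway.

    H(f) = [G_f s tau_f / (1 + s tau_f) + G_s s tau_s / (1 + s tau_s)]
           / (1 + i f / f_c),   s = i 2 pi f.

    Two high-pass filters with corner frequencies 1/(2 pi tau) in series with
    a first-order low-pass at f_c; together a band-pass centered near
    1/tau_f.  Magnitude is ``np.abs`` of the result, phase lead in degrees is
    ``np.angle(..., deg=True)``.
    """
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    s = 1j * 2 * np.pi * f
    h_fast = p.G_f * s * p.tau_f / (1 + s * p.tau_f)
    h_slow = p.G_s * s * p.tau_s / (1 + s * p.tau_s)
    h_lpf = 1.0 / (1.0 + 1j * f / p.f_c)
    return (h_fast + h_slow) * h_lpf


def fit_adaptation_gains(
    target_rate_traces: list,
    fixed_taus: tuple | None = (0.15, 2.0),
    p0: AdaptationParams | None = None,
) -> tuple[AdaptationParams, float]:
    """Least-squares fit of (G_f, G_s) — and optionally the taus — to
    step-response rate traces.

    Parameters
    ----------
    target_rate_traces : list of (t_ms, rate_sps, drive_amplitude) tuples
        Post-step rate relative to baseline; ``drive_amplitude`` is the
        cathodic-positive step height in uA (negative for anodic steps).
    fixed_taus : (tau_f, tau_s) in seconds, or None to fit them too.

    Returns
    -------
    (AdaptationParams, residual_norm)
    """
    if not target_rate_traces:
        raise ValueError("need at least one trace")
    base = p0 or AdaptationParams()
    ts, ys, amps = [], [], []
    for t_ms, rate, amp in target_rate_traces:
        t_ms = np.asarray(t_ms, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if np.ptp(rate) == 0:
            raise RuntimeError("degenerate (constant) trace: nothing to fit")
        ts.append(t_ms)
        ys.append(rate)
        amps.append(float(amp))
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys)
    a_all = np.concatenate([np.full(t.size, a) for t, a in zip(ts, amps)])

    def model_fixed(tA, G_f, G_s):
        t_ms, amp = tA
        att = np.where(amp >= 0, 1.0, base.anodic_fast_attenuation)
        tau_f, tau_s = fixed_taus
        return amp * (att * G_f * np.exp(-t_ms / (tau_f * 1000.0))
                      + G_s * np.exp(-t_ms / (tau_s * 1000.0)))

    def model_free(tA, G_f, G_s, tau_f, tau_s):
        t_ms, amp = tA
        att = np.where(amp >= 0, 1.0, base.anodic_fast_attenuation)
        return amp * (att * G_f * np.exp(-t_ms / (tau_f * 1000.0))
                      + G_s * np.exp(-t_ms / (tau_s * 1000.0)))

    try:
        if fixed_taus is not None:
            popt, _ = curve_fit(model_fixed, (t_all, a_all), y_all,
                                p0=[base.G_f, base.G_s])
            G_f, G_s = popt
            tau_f, tau_s = fixed_taus
            resid = y_all - model_fixed((t_all, a_all), *popt)
        else:
            popt, _ = curve_fit(
                model_free, (t_all, a_all), y_all,
                p0=[base.G_f, base.G_s, base.tau_f, base.tau_s],
                bounds=([0, 0, 1e-3, 0.2], [np.inf, np.inf, 1.0, 20.0]),
                maxfev=20000)
            G_f, G_s, tau_f, tau_s = popt
            resid = y_all - model_free((t_all, a_all), *popt)
    except RuntimeError as err:
        raise RuntimeError(f"adaptation fit failed to converge: {err}") from err
    fitted = replace(base, G_f=float(G_f), G_s=float(G_s),
                     tau_f=float(tau_f), tau_s=float(tau_s))
    return fitted, float(np.linalg.norm(resid))
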