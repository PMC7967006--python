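"""Stochastic EPSC drive of the afferent axon.

Vesicle release from the type I hair cell is modeled as a renewal process
with exponential (memoryless) inter-arrival times of mean ``mu`` (ms); each
event deposits a unitary biexponential EPSC of peak amplitude ``K`` (pA) on
the membrane.  Hair-cell adaptation reaches the axon by modulating the
arrival-rate parameter: ``mu(t)`` is re-evaluated only every ``t_dmu`` ms
(piecewise constant), which is itself a low-pass bottleneck on how fast the
synapse can track a changing drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EPSCParams",
    "EPSCTrain",
    "draw_epsc_times",
    "render_epsc_current",
    "update_mu",
    "make_epsc_train",
]


@dataclass(frozen=True)
class EPSCParams:
    """EPSC generator parameters.

    mu0 : mean inter-EPSC interval at rest (ms)
    K : unitary EPSC peak amplitude (pA)
    t_dmu : interval at which mu(t) is re-evaluated (ms); defaults to mu0
    tau_rise, tau_decay : biexponential template time constants (ms)
    mu_min, mu_max : clip bounds on mu(t) (ms)
    fr_floor : firing-rate floor used when inverting rate -> mu (sps)
    """

    mu0: float = 3.0
    K: float = 40.0
    t_dmu: float | None = None
    tau_rise: float = 0.3
    tau_decay: float = 0.5
    mu_min: float = 0.05
    mu_max: float = 1.0e4
    fr_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.K <= 0:
            raise ValueError("mu0 and K must be positive")
        if self.tau_rise <= 0 or self.tau_decay <= 0 or self.tau_rise >= self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.t_dmu is not None and self.t_dmu <= 0:
            raise ValueError("t_dmu must be positive")

    @property
    def update_interval(self) -> float:
        return self.mu0 if self.t_dmu is None else self.t_dmu

    def with_t_dmu(self, t_dmu: float) -> "EPSCParams":
        return replace(self, t_dmu=t_dmu)


@dataclass(frozen=True)
class EPSCTrain:
    """Realized EPSC event train and its rendered current."""

    event_times: np.ndarray  # ms, sorted
    i_syn: np.ndarray  # pA on the simulation grid, >= 0
    seed: int
    params: EPSCParams = field(repr=False, default=EPSCParams())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.event_times[:, None], delimiter=",",
                   header="event_time_ms", comments="")


def draw_epsc_times(
    mu_series: np.ndarray | float,
    total_ms: float,
    seed: int,
    t_dmu: float | None = None,
) -> np.ndarray:
    """Draw EPSC arrival times on [0, total_ms) from an exponential renewal process.

    Parameters
    ----------
    mu_series : float or 1-D array
        Mean inter-arrival interval (ms).  A scalar gives a homogeneous
        process.  An array is interpreted as the piecewise-constant value of
        mu on consecutive windows of length ``t_dmu`` starting at t = 0.
    total_ms : float
        Record length (ms).
    seed : int
        RNG seed; identical (mu_series, total_ms, seed) gives an identical
        train.
    t_dmu : float, required when mu_series is an array
        Window length (ms) of the piecewise-constant segments.

    Notes
    -----
    With time-varying mu the process is generated sequentially: each waiting
    time is drawn exponential with the mean in force at the arrival time of
    the previous event.  The expected count is approximately
    ``integral dt / mu(t)``.
    """
    mu_arr = np.atleast_1d(np.asarray(mu_series, dtype=float))
    if np.any(mu_arr <= 0) or not np.all(np.isfinite(mu_arr)):
        raise ValueError("mu must be positive and finite everywhere")
    if total_ms <= 0:
        raise ValueError("total_ms must be positive")
    rng = np.random.default_rng(seed)

    if mu_arr.size == 1:
        mu = float(mu_arr[0])
        # draw in blocks for speed; expected count total/mu
        n_guess = max(16, int(total_ms / mu * 1.2) + 8 * int(np.sqrt(total_ms / mu) + 1))
        times = []
        t = 0.0
        while True:
            gaps = rng.exponential(mu, size=n_guess)
            cum = t + np.cumsum(gaps)
            inside = cum[cum < total_ms]
            times.append(inside)
            if inside.size < n_guess:
                break
            t = cum[-1]
        return np.concatenate(times)

    if t_dmu is None or t_dmu <= 0:
        raise ValueError("t_dmu must be given (and positive) for time-varying mu")
    # sequential draws; mu looked up at the current time
    out = []
    t = 0.0
    n_seg = mu_arr.size
    while True:
        k = min(int(t / t_dmu), n_seg - 1)
        t = t + rng.exponential(mu_arr[k])
        if t >= total_ms:
            break
        out.append(t)
    return np.asarray(out, dtype=float)


def epsc_template(t_grid_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak biexponential EPSC kernel evaluated at t >= 0."""
    t = np.asarray(t_grid_ms, dtype=float)
    raw = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    t_peak = (np.log(tau_decay / tau_rise) * tau_rise * tau_decay
              / (tau_decay - tau_rise))
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = raw / peak
    out[t < 0] = 0.0
    return out


def render_epsc_current(
    event_times: np.ndarray,
    params: EPSCParams,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Superpose ``K * template(t - t_k)`` for every event onto the grid.

    The kernel is truncated where it has decayed below 1e-6 of peak, so
    superposition is additive and the trace is everywhere >= 0 (the drive is
    purely excitatory).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    events = np.asarray(event_times, dtype=float)
    if events.size and events.min() < t_grid[0]:
        raise ValueError("event times fall outside the simulation grid")
    dt = t_grid[1] - t_grid[0]
    if events.size and events.max() >= t_grid[-1] + dt:
        raise ValueError("event times fall outside the simulation grid")
    # kernel support: decay to 1e-6 of peak
    support_ms = params.tau_decay * np.log(1e6)
    n_kernel = int(np.ceil(support_ms / dt)) + 1
    kernel = params.K * epsc_template(np.arange(n_kernel) * dt,
                                      params.tau_rise, params.tau_decay)
    i_syn = np.zeros(t_grid.size + n_kernel)
    idx = np.floor((events - t_grid[0]) / dt).astype(np.int64)
    for k in idx:
        i_syn[k:k + n_kernel] += kernel
    return i_syn[: t_grid.size]


def update_mu(
    fr_target_series: np.ndarray,
    mu0: float,
    fr_o: float,
    t_dmu: float,
    dt_ms: float,
    params: EPSCParams | None = None,
) -> np.ndarray:
    """Convert a target firing-rate series into a piecewise-constant mu(t).

    EPSC arrival rate is taken inversely proportional to the target rate,
    anchored at the fixed point (fr_o <-> mu0):

        mu_k = mu0 * fr_o / max(fr_target(t_k), fr_floor)

    re-evaluated only at multiples of ``t_dmu`` and clipped to
    [mu_min, mu_max].

    Parameters
    ----------
    fr_target_series : 1-D array
        Target rate (sps) sampled on the simulation grid (spacing dt_ms).
    mu0, fr_o : floats
        Resting mean interval (ms) and the spontaneous rate (sps) it produces.
    t_dmu : float
        Update interval (ms); must be >= dt_ms.
    dt_ms : float
        Simulation grid spacing (ms).

    Returns
    -------
    mu : 1-D array of per-window mean intervals (ms), one entry per t_dmu
        window covering the record; feed to :func:`draw_epsc_times` with the
        same ``t_dmu``.
    """
    p = params if params is not None else EPSCParams(mu0=mu0)
    if fr_o <= 0:
        raise ValueError("fr_o must be positive")
    if t_dmu < dt_ms:
        raise ValueError("t_dmu must be >= the simulation step")
    fr = np.asarray(fr_target_series, dtype=float)
    stride = max(1, int(round(t_dmu / dt_ms)))
    samples = fr[::stride]
    mu = mu0 * fr_o / np.maximum(samples, p.fr_floor)
    return np.clip(mu, p.mu_min, p.mu_max)


def make_epsc_train(
    params: EPSCParams,
    t_grid: np.ndarray,
    seed: int,
    mu_series: np.ndarray | None = None,
) -> EPSCTrain:
    """Draw events (homogeneous at mu0, or from a mu(t) series) and render them."""
    dt = float(t_grid[1] - t_grid[0])
    total = float(t_grid[-1] - t_grid[0] + dt)
    if mu_series is None:
        events = draw_epsc_times(params.mu0, total, seed)
    else:
        events = draw_epsc_times(mu_series, total, seed, t_dmu=params.update_interval)
    i_syn = render_epsc_current(events, params, t_grid)
    return EPSCTrain(events, i_syn, seed, params)
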