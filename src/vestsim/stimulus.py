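"""Galvanic stimulus waveforms in electrode units and their axonal coupling.

Convention: electrode current is expressed in microamperes with *cathodic*
current negative.  Cathodic current depolarizes the afferent (it is
excitatory), so conversion to axon-injected current flips the sign:
a -10 uA cathodic step becomes a positive (depolarizing) picoampere current
at the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusWaveform",
    "InvalidProtocolError",
    "make_step",
    "make_baseline_step",
    "make_sinusoid",
    "make_zero",
    "to_axonal_current",
]

DEFAULT_DT_MS = 0.01  # resolves Na gating kinetics


class InvalidProtocolError(ValueError):
    """Raised when a stimulus protocol is ill-formed (negative duration, etc.)."""


@dataclass(frozen=True)
class StimulusWaveform:
    """Electrode-referenced GVS current over time.

    Attributes
    ----------
    t : ndarray
        Time grid in ms, uniform spacing ``dt``.
    i_ext : ndarray
        Electrode current in uA per sample (cathodic negative).
    kind : str
        One of ``step``, ``baseline_step``, ``sinusoid``, ``zero``.
    meta : dict
        Protocol parameters (amplitudes in uA, onset in ms, frequency in Hz).
    """

    t: np.ndarray
    i_ext: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        i = np.asarray(self.i_ext, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InvalidProtocolError("time grid must be 1-D with >= 2 samples")
        if i.shape != t.shape:
            raise InvalidProtocolError("i_ext must match the time grid")
        dts = np.diff(t)
        if not np.all(dts > 0):
            raise InvalidProtocolError("time grid must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise InvalidProtocolError("time grid must be uniform")
        if not np.all(np.isfinite(i)):
            raise InvalidProtocolError("i_ext must be finite everywhere")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "i_ext", i)

    @property
    def dt(self) -> float:
        """Grid spacing in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def total_ms(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)

    def to_csv(self, path) -> None:
        """Write a two-column CSV (t_ms, i_uA)."""
        np.savetxt(
            path,
            np.column_stack([self.t, self.i_ext]),
            delimiter=",",
            header="t_ms,i_uA",
            comments="",
        )


def _grid(total_ms: float, dt_ms: float) -> np.ndarray:
    if dt_ms <= 0:
        raise InvalidProtocolError(f"dt must be positive, got {dt_ms}")
    if total_ms <= dt_ms:
        raise InvalidProtocolError("total duration must exceed dt")
    n = int(round(total_ms / dt_ms))
    return np.arange(n) * dt_ms


def make_zero(total_ms: float, dt_ms: float = DEFAULT_DT_MS) -> StimulusWaveform:
    """All-zero (no stimulation) waveform."""
    t = _grid(total_ms, dt_ms)
    return StimulusWaveform(t, np.zeros_like(t), "zero", {"amplitude_uA": 0.0})


def make_step(
    amplitude_uA: float,
    onset_ms: float,
    duration_ms: float,
    total_ms: float,
    dt_ms: float = DEFAULT_DT_MS,
) -> StimulusWaveform:
    """Rectangular GVS step: ``amplitude`` on [onset, onset+duration), 0 elsewhere."""
    if duration_ms <= 0 or onset_ms < 0:
        raise InvalidProtocolError("onset must be >= 0 and duration > 0")
    if total_ms < onset_ms + duration_ms:
        raise InvalidProtocolError("total_ms must cover onset + duration")
    t = _grid(total_ms, dt_ms)
    i = np.zeros_like(t)
    mask = (t >= onset_ms) & (t < onset_ms + duration_ms)
    i[mask] = amplitude_uA
    meta = {
        "amplitude_uA": float(amplitude_uA),
        "onset_ms": float(onset_ms),
        "duration_ms": float(duration_ms),
    }
    return StimulusWaveform(t, i, "step", meta)


def make_baseline_step(
    baseline_uA: float,
    step_uA: float,
    t_baseline_ms: float,
    t_step_ms: float,
    dt_ms: float = DEFAULT_DT_MS,
) -> StimulusWaveform:
    """Baseline current followed by an additional step on top of it.

    The second segment carries ``baseline + step`` uA, mirroring protocols in
    which a test step is delivered after the afferent has equilibrated to a
    standing GVS baseline.
    """
    if t_baseline_ms <= 0 or t_step_ms <= 0:
        raise InvalidProtocolError("both segment durations must be > 0")
    total = t_baseline_ms + t_step_ms
    t = _grid(total, dt_ms)
    i = np.where(t < t_baseline_ms, baseline_uA, baseline_uA + step_uA)
    meta = {
        "baseline_uA": float(baseline_uA),
        "step_uA": float(step_uA),
        "t_baseline_ms": float(t_baseline_ms),
        "t_step_ms": float(t_step_ms),
    }
    return StimulusWaveform(t, i.astype(float), "baseline_step", meta)


def make_sinusoid(
    amplitude_uA: float,
    freq_hz: float,
    n_cycles: int,
    dt_ms: float = DEFAULT_DT_MS,
) -> StimulusWaveform:
    """Sinusoidal GVS of ``n_cycles`` full cycles.

    Phase convention: t = 0 is the zero crossing heading into the *cathodic*
    (negative, excitatory) half-cycle: ``i_ext(t) = -amplitude sin(2 pi f t)``.
    The cathodic peak therefore sits a quarter cycle into each period, which
    is the reference downstream phase-lead estimates use.
    """
    if freq_hz <= 0:
        raise InvalidProtocolError(f"frequency must be positive, got {freq_hz}")
    if n_cycles < 1:
        raise InvalidProtocolError("need at least one full cycle")
    total_ms = n_cycles * 1000.0 / freq_hz
    t = _grid(total_ms, dt_ms)
    # negative-going first half-cycle == cathodic (excitatory) half first
    i = -amplitude_uA * np.sin(2 * np.pi * freq_hz * t / 1000.0)
    meta = {
        "amplitude_uA": float(amplitude_uA),
        "freq_hz": float(freq_hz),
        "n_cycles": int(n_cycles),
    }
    return StimulusWaveform(t, i, "sinusoid", meta)


def to_axonal_current(
    w: StimulusWaveform,
    coupling_pA_per_uA: float,
    nq_gain: float = 1.0,
) -> np.ndarray:
    """Convert an electrode waveform to membrane-injected current (pA).

    ``i_axon(t) = -coupling * nq_gain * i_ext(t)``: cathodic (negative uA)
    electrode current depolarizes the axon (positive pA).  ``nq_gain`` models
    the non-quantal amplification of external current at the calyx synapse
    (up to ~4.5x for irregular afferents); it scales the GVS-injected current
    only, never the EPSC current.
    """
    if coupling_pA_per_uA <= 0:
        raise InvalidProtocolError("coupling must be positive")
    if nq_gain < 1.0:
        raise InvalidProtocolError("nq_gain must be >= 1")
    return -coupling_pA_per_uA * nq_gain * w.i_ext
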