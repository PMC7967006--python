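"""End-to-end in silico experiments.

Each experiment simulates a population of afferents under a stimulation
protocol and runs the statistics battery.  The full pipeline for one neuron:

    electrode waveform --(coupling, NQ gain)--> axon-injected GVS current
    electrode waveform --(hair-cell adaptation)--> fr_adapt(t)
    fr_o + fr_adapt(t) --(inverse rate rule, every t_dmu)--> mu(t)
    mu(t) --(exponential renewal draw)--> EPSC events --> i_syn(t)
    i_syn + i_gvs --(conductance model)--> V(t) --> spike times

With adaptation disabled the EPSC train is homogeneous at mu0 and the hair
cell contributes nothing; that is the axon-only configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import axon as ax
from . import haircell, spikestats, stimulus, synapse
from .params import ModelVariant, load_variant, variant_from_dict

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "simulate_afferent",
    "run_amplitude_sweep",
    "run_adaptation_step",
    "run_sine_sweep",
    "run_full_invivo",
    "generate_fixtures",
    "neuron_seeds",
]


def neuron_seeds(base_seed: int, n: int) -> np.ndarray:
    """Distinct per-neuron seeds derived deterministically from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return np.array([int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(n)])


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    experiment: str
    variant: str = "invivo"
    n_neurons: int = 19
    seed: int = 0
    protocol: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)  # e.g. {"mu0": 0.75}

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")

    def resolve_variant(self) -> ModelVariant:
        v = load_variant(self.variant)
        ov = dict(self.overrides)
        if "mu0" in ov:
            v = v.with_mu0(ov.pop("mu0"), ov.pop("fr_o", None))
        if "nq_gain" in ov:
            v = replace(v, nq_gain=ov.pop("nq_gain"))
        if "t_dmu" in ov:
            v = replace(v, epsc=v.epsc.with_t_dmu(ov.pop("t_dmu")))
        if ov:
            raise KeyError(f"unknown overrides: {sorted(ov)}")
        return v

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    tables: dict  # name -> DataFrame
    summary: dict  # machine-readable scalar outcomes

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        payload = {"config": json.loads(self.config.to_json()),
                   "config_hash": self.config.config_hash,
                   "summary": self.summary}
        (out / "summary.json").write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# single-neuron pipeline


def simulate_afferent(
    variant: ModelVariant,
    waveform: stimulus.StimulusWaveform,
    seed: int,
    adaptation: bool = False,
    return_trace: bool = False,
    epsc_enabled: bool = True,
):
    """Simulate one afferent under an electrode waveform; return its spikes."""
    dt = variant.dt_ms
    i_gvs = stimulus.to_axonal_current(waveform, variant.coupling_pA_per_uA,
                                       variant.nq_gain)
    if epsc_enabled:
        if adaptation:
            fr_adapt = haircell.adaptation_response(waveform, variant.adaptation)
            fr_target = variant.fr_o + fr_adapt
            mu = synapse.update_mu(fr_target, variant.epsc.mu0, variant.fr_o,
                                   variant.epsc.update_interval, dt,
                                   params=variant.epsc)
            train = synapse.make_epsc_train(variant.epsc, waveform.t, seed,
                                            mu_series=mu)
        else:
            train = synapse.make_epsc_train(variant.epsc, waveform.t, seed)
        i_syn = train.i_syn
    else:
        i_syn = np.zeros_like(waveform.t)
    trace = ax.simulate(variant.axon, i_syn, i_gvs, dt=dt)
    spikes = ax.detect_spikes(trace, neuron_id=seed,
                              meta={"variant": variant.name, "seed": seed})
    return (spikes, trace) if return_trace else spikes


def _population(variant, waveform, seeds, adaptation=False, epsc_enabled=True):
    return [simulate_afferent(variant, waveform, int(s), adaptation=adaptation,
                              epsc_enabled=epsc_enabled) for s in seeds]


# --------------------------------------------------------------------------
# experiments


def run_amplitude_sweep(cfg: ExperimentConfig) -> ExperimentResult:
    """GVS amplitude sweep: per-amplitude rates, (ISI, CV) points, slope + CI.

    Protocol keys: amplitudes_uA (list), duration_ms (step length, default
    5000), onset_ms (default 500), adaptation (default False),
    fit_range_uA (default (-45, 45)).
    """
    v = cfg.resolve_variant()
    prot = {"amplitudes_uA": [0.0], "duration_ms": 5000.0, "onset_ms": 500.0,
            "adaptation": False, **cfg.protocol}
    amps = np.asarray(prot["amplitudes_uA"], dtype=float)
    dur, onset = float(prot["duration_ms"]), float(prot["onset_ms"])
    seeds = neuron_seeds(cfg.seed, cfg.n_neurons)
    rows = []
    rates = np.empty((cfg.n_neurons, amps.size))
    for j, amp in enumerate(amps):
        w = stimulus.make_step(amp, onset, dur, onset + dur, v.dt_ms)
        trains = _population(v, w, seeds, adaptation=prot["adaptation"])
        for i, tr in enumerate(trains):
            st = spikestats.spike_statistics(tr, window_ms=(onset, onset + dur))
            rates[i, j] = st.mean_rate
            rows.append({"neuron": i, "seed": int(seeds[i]),
                         "amplitude_uA": amp, "mean_rate": st.mean_rate,
                         "mean_isi_ms": st.mean_isi, "cv": st.cv,
                         "n_spikes": st.n_spikes})
    stats_df = pd.DataFrame(rows)
    fit_range = tuple(cfg.analysis.get("fit_range_uA", (-45.0, 45.0)))
    n_boot = int(cfg.analysis.get("n_boot", 500))
    summary: dict = {}
    if np.count_nonzero((amps >= fit_range[0]) & (amps <= fit_range[1])) >= 3:
        curve = spikestats.response_slope(amps, rates, fit_range, n_boot,
                                          seed=cfg.seed)
        summary["slope_sps_per_uA"] = curve.slope
        summary["slope_ci95"] = list(curve.slope_ci)
    per_amp = rates.mean(axis=0)
    summary.update({
        "fr_spontaneous": float(per_amp[amps == 0.0][0]) if np.any(amps == 0.0) else None,
        "fr_max": float(per_amp.max()),
        "fr_max_amplitude_uA": float(amps[int(np.argmax(per_amp))]),
        "per_amplitude_mean": per_amp.tolist(),
        "per_amplitude_std": rates.std(axis=0).tolist(),
    })
    return ExperimentResult(cfg, {"spike_stats": stats_df}, summary)


def run_adaptation_step(cfg: ExperimentConfig) -> ExperimentResult:
    """Long GVS steps (>= 10 s) from optional baselines, with rate traces,
    double-exponential fits and an anodic-vs-cathodic cluster test.

    Protocol keys: step_uA (list of step amplitudes), baseline_uA (default 0),
    t_baseline_ms (default 2000), t_step_ms (default 10000),
    adaptation (default True), bin_ms (default 100).
    """
    v = cfg.resolve_variant()
    prot = {"step_uA": [-10.0, 10.0], "baseline_uA": 0.0,
            "t_baseline_ms": 2000.0, "t_step_ms": 10000.0,
            "adaptation": True, "bin_ms": 100.0, **cfg.protocol}
    seeds = neuron_seeds(cfg.seed, cfg.n_neurons)
    bin_ms = float(prot["bin_ms"])
    t_base, t_step = float(prot["t_baseline_ms"]), float(prot["t_step_ms"])
    total = t_base + t_step
    traces = {}
    fits = []
    for amp in prot["step_uA"]:
        w = stimulus.make_baseline_step(prot["baseline_uA"], amp, t_base,
                                        t_step, v.dt_ms)
        trains = _population(v, w, seeds, adaptation=prot["adaptation"])
        centers, R = spikestats.rate_trace(trains, total, bin_ms)
        traces[amp] = (centers, R)
        if amp != 0:
            try:
                fit = spikestats.fit_step_response(centers, R.mean(axis=0), t_base)
                fit["step_uA"] = amp
                fits.append(fit)
            except RuntimeError:
                pass
    rows = []
    for amp, (centers, R) in traces.items():
        for i in range(R.shape[0]):
            for tt, rr in zip(centers, R[i]):
                rows.append({"step_uA": amp, "neuron": i, "t_ms": tt,
                             "rate_sps": rr})
    summary: dict = {"fits": fits}
    steps = sorted(traces)
    if len(steps) >= 2 and steps[0] < 0 < steps[-1] and cfg.n_neurons >= 2:
        _, RA = traces[steps[0]]
        _, RB = traces[steps[-1]]
        clusters = spikestats.cluster_permutation_test(
            RA, RB, n_perm=int(cfg.analysis.get("n_perm", 500)),
            seed=cfg.seed)
        summary["cathodic_anodic_clusters"] = clusters
    return ExperimentResult(cfg, {"rate_traces": pd.DataFrame(rows)}, summary)


def run_sine_sweep(cfg: ExperimentConfig) -> ExperimentResult:
    """Sinusoidal GVS across frequencies: half-cycle rates and phase leads.

    Protocol keys: freqs_hz (list), amplitude_uA (default 10),
    adaptation (default True), min_cycles (default 5),
    min_duration_ms (default 20000 -- the record is the longer of the two).
    """
    v = cfg.resolve_variant()
    prot = {"freqs_hz": [0.1, 0.5, 1.0, 2.0, 4.0, 8.0], "amplitude_uA": 10.0,
            "adaptation": True, "min_cycles": 5, "min_duration_ms": 20000.0,
            **cfg.protocol}
    seeds = neuron_seeds(cfg.seed, cfg.n_neurons)
    rows = []
    for f in prot["freqs_hz"]:
        n_cyc = max(int(prot["min_cycles"]),
                    int(np.ceil(prot["min_duration_ms"] * f / 1000.0)))
        w = stimulus.make_sinusoid(prot["amplitude_uA"], f, n_cyc, v.dt_ms)
        trains = _population(v, w, seeds, adaptation=prot["adaptation"])
        for i, tr in enumerate(trains):
            m = spikestats.cycle_metrics(tr, w)
            rows.append({"freq_hz": f, "neuron": i, **m})
    df = pd.DataFrame(rows)
    by_f = df.groupby("freq_hz").agg(
        cathodic_rate=("cathodic_rate", "mean"),
        anodic_rate=("anodic_rate", "mean"),
        phase_lead_deg=("phase_lead_deg", "mean")).reset_index()
    return ExperimentResult(cfg, {"cycle_metrics": df},
                            {"per_frequency": by_f.to_dict("records")})


def run_full_invivo(cfg: ExperimentConfig) -> ExperimentResult:
    """Complete closed-loop in vivo model (adaptation -> mu(t) -> EPSC ->
    axon + NQ-amplified GVS): amplitude sweep with the full battery."""
    base = replace(cfg, experiment="amplitude_sweep",
                   protocol={"adaptation": True, **cfg.protocol})
    return run_amplitude_sweep(base)


# --------------------------------------------------------------------------
# synthetic fixtures with known ground truth


def generate_fixtures(kind: str, params: dict, seed: int):
    """Deterministic synthetic data for testing the analysis modules.

    Kinds: ``periodic_train``, ``poisson_train``,
    ``sinusoidal_poisson_train``, ``double_exp_rate_trace``, ``epsc_train``.
    """
    rng = np.random.default_rng(seed)
    if kind == "periodic_train":
        isi = params.get("isi_ms", 10.0)
        total = params.get("total_ms", 10000.0)
        times = np.arange(isi, total, isi)
        return ax.SpikeTrain(times, meta={"kind": kind, "isi_ms": isi})
    if kind == "poisson_train":
        rate = params.get("rate_sps", 100.0)
        total = params.get("total_ms", 10000.0)
        n_exp = rate * total / 1000.0
        n = rng.poisson(n_exp)
        times = np.sort(rng.uniform(0, total, size=n))
        return ax.SpikeTrain(times, meta={"kind": kind, "rate_sps": rate})
    if kind == "sinusoidal_poisson_train":
        # inhomogeneous Poisson with rate R0 + R1 sin(2 pi f t + phase), by thinning
        R0 = params.get("R0_sps", 100.0)
        R1 = params.get("R1_sps", 30.0)
        f = params.get("freq_hz", 1.0)
        phase_deg = params.get("phase_deg", 0.0)
        total = params.get("total_ms", 20000.0)
        rmax = R0 + abs(R1)
        n = rng.poisson(rmax * total / 1000.0)
        cand = np.sort(rng.uniform(0, total, size=n))
        lam = R0 + R1 * np.sin(2 * np.pi * f * cand / 1000.0
                               + np.deg2rad(phase_deg))
        keep = rng.uniform(0, rmax, size=n) < lam
        return ax.SpikeTrain(cand[keep], meta={"kind": kind, **params})
    if kind == "double_exp_rate_trace":
        G_f = params.get("G_f", 20.0)
        G_s = params.get("G_s", 5.0)
        tau_f = params.get("tau_f", 0.15)
        tau_s = params.get("tau_s", 2.0)
        offset = params.get("offset", 0.0)
        baseline = params.get("baseline", 50.0)
        onset = params.get("onset_ms", 1000.0)
        total = params.get("total_ms", 12000.0)
        dt = params.get("dt_ms", 100.0)
        noise = params.get("noise_sps", 0.0)
        t = np.arange(0.0, total, dt)
        ts = (t - onset) / 1000.0
        y = np.where(ts >= 0,
                     baseline + offset + G_f * np.exp(-np.maximum(ts, 0) / tau_f)
                     + G_s * np.exp(-np.maximum(ts, 0) / tau_s),
                     baseline)
        if noise > 0:
            y = y + rng.normal(0, noise, size=y.size)
        return t, y
    if kind == "epsc_train":
        p = synapse.EPSCParams(**params.get("epsc", {}))
        total = params.get("total_ms", 1000.0)
        dt = params.get("dt_ms", 0.01)
        grid = np.arange(0.0, total, dt)
        return synapse.make_epsc_train(p, grid, seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
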