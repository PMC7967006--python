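"""Single-compartment conductance model of the irregular vestibular afferent axon.

Channels: a transient sodium current (m^3 h), a high-voltage-gated potassium
current KH (phi n^2 + (1 - phi) p), a low-voltage-gated potassium current KL
(w^4 z) and an ohmic leak.  Kinetics follow the Rothman-Manis ventral
cochlear nucleus formulation that the vestibular-afferent point-model
framework adapts; KL density is what separates irregular (calyx-bearing)
from regular afferents, and is held at its published irregular-afferent
value across variants.

Membrane equation (V in mV, t in ms, conductances in mS/cm^2, specific
capacitance in uF/cm^2, injected currents in pA spread over ``area`` cm^2):

    C_m dV/dt = -(I_Na + I_KH + I_KL + I_leak) + (i_syn + i_gvs) * 1e-6 / area

Integration is exponential Euler on the gating variables (exact for the
locally linear relaxation to x_inf) with a forward step on V, at
dt = 0.01 ms.  Gating steady states and relaxation factors are tabulated on
a fine voltage grid once per (params, dt) and linearly interpolated inside a
numba-compiled loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "AxonParams",
    "AxonState",
    "MembraneTrace",
    "SpikeTrain",
    "IntegrationError",
    "gating_steady_state_and_tau",
    "membrane_derivative",
    "resting_state",
    "simulate",
    "detect_spikes",
]

GATE_NAMES = ("m", "h", "n", "p", "w", "z")
PHI_KH = 0.85  # fast/slow split of the KH current
ZETA_KL = 0.5  # voltage-independent fraction of KL inactivation

SPIKE_THRESHOLD_MV = -20.0
REFRACTORY_MS = 1.0


class IntegrationError(RuntimeError):
    """Numerical blow-up (NaN or |V| > bound) during integration."""


@dataclass(frozen=True)
class AxonParams:
    """Maximal conductances (mS/cm^2), reversals (mV) and geometry."""

    g_Na: float = 13.0
    g_KH: float = 2.8
    g_KL: float = 1.1
    g_leak: float = 0.03
    E_Na: float = 55.0
    E_K: float = -81.0
    E_leak: float = -65.0
    C_m: float = 0.9  # uF/cm^2
    area: float = 1.0e-5  # cm^2 (~9 pF cell)
    variant: str = "original_hk"

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_KH", "g_KL", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C_m <= 0 or self.area <= 0:
            raise ValueError("C_m and area must be positive")

    def scaled(self, na_scale: float = 1.0, kh_scale: float = 1.0,
               variant: str | None = None) -> "AxonParams":
        """Return a copy with g_Na / g_KH scaled (g_KL stays fixed)."""
        return replace(
            self,
            g_Na=self.g_Na * na_scale,
            g_KH=self.g_KH * kh_scale,
            variant=variant or self.variant,
        )


@dataclass
class AxonState:
    """Membrane potential and gating variables (each in [0, 1])."""

    V: float
    gates: np.ndarray  # order: m, h, n, p, w, z

    def as_dict(self) -> dict:
        return {"V": self.V, **dict(zip(GATE_NAMES, self.gates))}


@dataclass(frozen=True)
class MembraneTrace:
    t: np.ndarray  # ms
    V: np.ndarray  # mV

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class SpikeTrain:
    """Detected action-potential times for one simulated neuron."""

    spike_times: np.ndarray  # ms, strictly increasing
    neuron_id: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack(
            [np.full(self.n_spikes, self.neuron_id), self.spike_times]),
            delimiter=",", header="neuron_id,t_ms", comments="")


# --------------------------------------------------------------------------
# gating kinetics


def gating_steady_state_and_tau(V_mV):
    """Steady states and time constants (ms) for all six gating variables.

    Vectorized over V.  Activation steady states increase with V,
    inactivation steady states decrease; all values lie in [0, 1] (x_inf)
    or are strictly positive (tau).
    """
    V = np.asarray(V_mV, dtype=float)

    m_inf = 1.0 / (1.0 + np.exp(-(V + 38.0) / 7.0))
    tau_m = 10.0 / (5.0 * np.exp((V + 60.0) / 18.0)
                    + 36.0 * np.exp(-(V + 60.0) / 25.0)) + 0.04

    h_inf = 1.0 / (1.0 + np.exp((V + 65.0) / 6.0))
    tau_h = 100.0 / (7.0 * np.exp((V + 60.0) / 11.0)
                     + 10.0 * np.exp(-(V + 60.0) / 25.0)) + 0.6

    n_inf = (1.0 + np.exp(-(V + 15.0) / 5.0)) ** -0.5
    tau_n = 100.0 / (11.0 * np.exp((V + 60.0) / 24.0)
                     + 21.0 * np.exp(-(V + 60.0) / 23.0)) + 0.7

    p_inf = 1.0 / (1.0 + np.exp(-(V + 23.0) / 6.0))
    tau_p = 100.0 / (4.0 * np.exp((V + 60.0) / 32.0)
                     + 5.0 * np.exp(-(V + 60.0) / 22.0)) + 5.0

    w_inf = (1.0 + np.exp(-(V + 48.0) / 6.0)) ** -0.25
    tau_w = 100.0 / (6.0 * np.exp((V + 60.0) / 6.0)
                     + 16.0 * np.exp(-(V + 60.0) / 45.0)) + 1.5

    z_inf = ZETA_KL + (1.0 - ZETA_KL) / (1.0 + np.exp((V + 71.0) / 10.0))
    tau_z = 1000.0 / (np.exp((V + 60.0) / 20.0)
                      + np.exp(-(V + 60.0) / 8.0)) + 50.0

    x_inf = {"m": m_inf, "h": h_inf, "n": n_inf, "p": p_inf, "w": w_inf, "z": z_inf}
    tau_x = {"m": tau_m, "h": tau_h, "n": tau_n, "p": tau_p, "w": tau_w, "z": tau_z}
    return x_inf, tau_x


def channel_currents(V: float, gates: np.ndarray, p: AxonParams) -> dict:
    """Per-channel membrane current densities (uA/cm^2) at a clamped state."""
    m, h, n, nn, w, z = gates
    return {
        "Na": p.g_Na * m ** 3 * h * (V - p.E_Na),
        "KH": p.g_KH * (PHI_KH * n ** 2 + (1 - PHI_KH) * nn) * (V - p.E_K),
        "KL": p.g_KL * w ** 4 * z * (V - p.E_K),
        "leak": p.g_leak * (V - p.E_leak),
    }


def membrane_derivative(state: AxonState, i_syn_pA: float, i_gvs_pA: float,
                        p: AxonParams) -> tuple[float, np.ndarray]:
    """Time derivative (dV/dt in mV/ms, dgates/dt in 1/ms) of the full state."""
    ionic = sum(channel_currents(state.V, state.gates, p).values())
    i_inj = (i_syn_pA + i_gvs_pA) * 1e-6 / p.area  # pA -> uA/cm^2
    dV = (-ionic + i_inj) / p.C_m
    x_inf, tau_x = gating_steady_state_and_tau(state.V)
    dg = np.array([(x_inf[g] - state.gates[i]) / tau_x[g]
                   for i, g in enumerate(GATE_NAMES)])
    return float(dV), dg


def resting_state(p: AxonParams, v_lo: float = -90.0, v_hi: float = -40.0) -> AxonState:
    """Quiescent steady state: gates at x_inf(V) with total current zero."""

    def balance(V):
        x_inf, _ = gating_steady_state_and_tau(V)
        gates = np.array([x_inf[g] for g in GATE_NAMES])
        return sum(channel_currents(V, gates, p).values())

    V_rest = brentq(balance, v_lo, v_hi, xtol=1e-10)
    x_inf, _ = gating_steady_state_and_tau(V_rest)
    return AxonState(V_rest, np.array([x_inf[g] for g in GATE_NAMES]))


# --------------------------------------------------------------------------
# integration

_V_TABLE_MIN = -150.0
_V_TABLE_MAX = 100.0
_V_TABLE_STEP = 0.02

_table_cache: dict = {}


def _gate_tables(dt: float):
    """(x_inf, 1 - exp(-dt/tau)) per gate, tabulated on the voltage grid."""
    key = round(dt, 12)
    if key not in _table_cache:
        Vg = np.arange(_V_TABLE_MIN, _V_TABLE_MAX + _V_TABLE_STEP, _V_TABLE_STEP)
        x_inf, tau_x = gating_steady_state_and_tau(Vg)
        inf = np.vstack([x_inf[g] for g in GATE_NAMES])
        efac = np.vstack([1.0 - np.exp(-dt / tau_x[g]) for g in GATE_NAMES])
        _table_cache[key] = (np.ascontiguousarray(inf), np.ascontiguousarray(efac))
    return _table_cache[key]


@njit(cache=True, fastmath=True)
def _integrate_kernel(V0, gates0, inf_tab, efac_tab, i_inj_pA, dt,
                      g_Na, g_KH, g_KL, g_leak, E_Na, E_K, E_leak,
                      C_m, inj_scale, v_min, v_step):  # pragma: no cover
    n = i_inj_pA.size
    V_out = np.empty(n)
    V = V0
    m, h, ng, pg, w, z = gates0[0], gates0[1], gates0[2], gates0[3], gates0[4], gates0[5]
    n_tab = inf_tab.shape[1]
    status = 0
    for k in range(n):
        # table lookup with linear interpolation
        x = (V - v_min) / v_step
        if x < 0.0:
            x = 0.0
        elif x > n_tab - 2:
            x = float(n_tab - 2)
        i0 = int(x)
        fr = x - i0
        m += (inf_tab[0, i0] * (1 - fr) + inf_tab[0, i0 + 1] * fr - m) * \
             (efac_tab[0, i0] * (1 - fr) + efac_tab[0, i0 + 1] * fr)
        h += (inf_tab[1, i0] * (1 - fr) + inf_tab[1, i0 + 1] * fr - h) * \
             (efac_tab[1, i0] * (1 - fr) + efac_tab[1, i0 + 1] * fr)
        ng += (inf_tab[2, i0] * (1 - fr) + inf_tab[2, i0 + 1] * fr - ng) * \
              (efac_tab[2, i0] * (1 - fr) + efac_tab[2, i0 + 1] * fr)
        pg += (inf_tab[3, i0] * (1 - fr) + inf_tab[3, i0 + 1] * fr - pg) * \
              (efac_tab[3, i0] * (1 - fr) + efac_tab[3, i0 + 1] * fr)
        w += (inf_tab[4, i0] * (1 - fr) + inf_tab[4, i0 + 1] * fr - w) * \
             (efac_tab[4, i0] * (1 - fr) + efac_tab[4, i0 + 1] * fr)
        z += (inf_tab[5, i0] * (1 - fr) + inf_tab[5, i0 + 1] * fr - z) * \
             (efac_tab[5, i0] * (1 - fr) + efac_tab[5, i0 + 1] * fr)

        ionic = (g_Na * m * m * m * h * (V - E_Na)
                 + g_KH * (0.85 * ng * ng + 0.15 * pg) * (V - E_K)
                 + g_KL * w * w * w * w * z * (V - E_K)
                 + g_leak * (V - E_leak))
        V = V + dt * (-ionic + i_inj_pA[k] * inj_scale) / C_m
        # Depolarization beyond +300 mV is a numerical blow-up.  Deep
        # hyperpolarization is *not*: the model has no inward rectifier, so
        # strong anodic current legitimately drives V far negative (gates
        # pinned at their limits, dynamics passive and stable); only an
        # absurd excursion is treated as failure.
        if not (-10000.0 < V < 300.0):
            status = k + 1
            break
        V_out[k] = V
    gates_out = np.array([m, h, ng, pg, w, z])
    return V_out, gates_out, status


def simulate(
    params: AxonParams,
    i_syn_pA: np.ndarray,
    i_gvs_pA: np.ndarray | float = 0.0,
    dt: float = 0.01,
    state0: AxonState | None = None,
) -> MembraneTrace:
    """Integrate the membrane equation over the input traces.

    ``i_syn_pA`` and ``i_gvs_pA`` are in pA on the simulation grid (a scalar
    GVS current is broadcast).  Deterministic given its inputs: all
    stochasticity lives upstream in the EPSC train.
    """
    i_syn = np.asarray(i_syn_pA, dtype=float)
    i_gvs = np.broadcast_to(np.asarray(i_gvs_pA, dtype=float), i_syn.shape)
    i_inj = np.ascontiguousarray(i_syn + i_gvs)
    if state0 is None:
        state0 = resting_state(params)
    inf_tab, efac_tab = _gate_tables(dt)
    V_out, _, status = _integrate_kernel(
        state0.V, np.ascontiguousarray(state0.gates, dtype=float),
        inf_tab, efac_tab, i_inj, dt,
        params.g_Na, params.g_KH, params.g_KL, params.g_leak,
        params.E_Na, params.E_K, params.E_leak,
        params.C_m, 1e-6 / params.area,
        _V_TABLE_MIN, _V_TABLE_STEP,
    )
    if status != 0:
        raise IntegrationError(
            f"membrane potential left (-200, 200) mV at step {status - 1} "
            f"(t = {(status - 1) * dt:.3f} ms)")
    t = np.arange(i_inj.size) * dt
    return MembraneTrace(t, V_out)


def detect_spikes(
    trace: MembraneTrace,
    threshold_mV: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = REFRACTORY_MS,
    neuron_id: int = 0,
    meta: dict | None = None,
) -> SpikeTrain:
    """One spike per upward threshold crossing, crossings within the
    refractory window merged into the first."""
    V = trace.V
    up = np.flatnonzero((V[1:] >= threshold_mV) & (V[:-1] < threshold_mV)) + 1
    if up.size == 0:
        return SpikeTrain(np.empty(0), neuron_id, meta or {})
    times = trace.t[up]
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] >= refractory_ms:
            kept.append(tt)
    return SpikeTrain(np.asarray(kept), neuron_id, meta or {})
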