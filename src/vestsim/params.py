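"""Versioned model-variant parameter files.

Three variants ship with the package:

``original_hk``
    The unmodified published point-model parameterization (mu0 = 3 ms),
    spontaneous rate ~53 sps, cathodic block near -45 uA.
``invivo``
    High-conductance parameterization of the in vivo irregular afferent:
    g_Na and g_KH scaled up (g_KL fixed at 1.1 mS/cm^2), mu0 = 0.75 ms,
    non-quantal gain on GVS current.  Reproduces the ~100 sps spontaneous
    rate and 0-188 sps induced range.
``invitro``
    Low-conductance explant preparation: g_Na scaled down and the NQ gain
    removed, spontaneous rate 15-20 sps, firing range clipped at 55 sps.

Constants not printed in the source literature (EPSC amplitude K, the
electrode-to-membrane coupling scalar, conductance scale factors, NQ gain)
are calibrated once against the printed firing statistics by
``scripts/calibrate_variants.py`` and committed here; they are never
re-tuned per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .axon import AxonParams
from .haircell import AdaptationParams
from .synapse import EPSCParams

__all__ = ["ModelVariant", "load_variant", "available_variants"]

_VARIANTS = ("original_hk", "invivo", "invitro")


@dataclass(frozen=True)
class ModelVariant:
    """Everything needed to simulate one preparation."""

    name: str
    axon: AxonParams
    epsc: EPSCParams
    adaptation: AdaptationParams
    coupling_pA_per_uA: float
    nq_gain: float
    fr_o: float  # nominal spontaneous rate (sps) used as the mu-modulation anchor
    fr_max: float | None  # firing-range ceiling (sps); None = unclipped
    dt_ms: float = 0.01

    def with_mu0(self, mu0: float, fr_o: float | None = None) -> "ModelVariant":
        """Copy with a different resting EPSC interval (and rate anchor)."""
        return replace(self, epsc=replace(self.epsc, mu0=mu0),
                       fr_o=self.fr_o if fr_o is None else fr_o)


def available_variants() -> tuple:
    return _VARIANTS


def load_variant(name: str) -> ModelVariant:
    """Load a shipped variant parameter file by name."""
    if name not in _VARIANTS:
        raise KeyError(f"unknown variant {name!r}; choose from {_VARIANTS}")
    text = resources.files("vestsim.params_data").joinpath(f"{name}.yaml").read_text()
    return variant_from_dict(yaml.safe_load(text))


def variant_from_dict(cfg: dict) -> ModelVariant:
    ax = AxonParams(**cfg["axon"], variant=cfg["name"])
    ep = EPSCParams(**cfg["epsc"])
    ad = AdaptationParams(**cfg["adaptation"])
    return ModelVariant(
        name=cfg["name"],
        axon=ax,
        epsc=ep,
        adaptation=ad,
        coupling_pA_per_uA=float(cfg["coupling_pA_per_uA"]),
        nq_gain=float(cfg["nq_gain"]),
        fr_o=float(cfg["fr_o"]),
        fr_max=None if cfg.get("fr_max") is None else float(cfg["fr_max"]),
        dt_ms=float(cfg.get("dt_ms", 0.01)),
    )

# The complete in vivo model (hair-cell adaptation + axon + NQ) runs the
# invivo variant at a faster resting EPSC interval, calibrated so the
# spontaneous rate is 120 sps (scripts/calibrate_variants.py, stage 3).
FULL_INVIVO_MU0 = 0.48  # ms
FULL_INVIVO_FR_O = 120.0  # sps
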