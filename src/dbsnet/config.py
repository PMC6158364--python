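"""Experiment configuration: defaults, YAML files, resolved-config JSON.

An `ExperimentConfig` gathers every knob of a simulation campaign — network
structure, drive, stimulus, attribution, sweep plan, output options — in one
serializable object.  Every CLI run writes its fully resolved configuration
as JSON next to its outputs, so any artifact on disk can be reproduced from
the sibling JSON alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import (
    DEFAULT_THALAMIC_BIAS,
    DEFAULT_THALAMIC_SIGMA,
    DriveConfig,
    SimulationConfig,
)
from .metrics import DEFAULT_SWEEP_FREQUENCIES, AttributionConfig
from .network import NetworkSpec, build_default_network, calibrate_weights

__all__ = ["ExperimentConfig", "load_config", "save_resolved_config"]


@dataclass
class ExperimentConfig:
    """All settings of a simulation campaign (flat, serializable)."""

    # network
    network_seed: int = 1
    base_weights: dict = field(default_factory=dict)  # (pre, post) -> weight
    tau_inh_ms: float = 10.0
    g_exc: float | None = None  # None -> run weight calibration
    g_inh: float | None = None
    # simulation
    dt: float = 0.1
    duration_ms: float = 2000.0
    burn_in_ms: float = 500.0
    seed: int = 0
    drive_bias: dict = field(
        default_factory=lambda: {"thalamus": DEFAULT_THALAMIC_BIAS}
    )
    drive_sigma: dict = field(
        default_factory=lambda: {"thalamus": DEFAULT_THALAMIC_SIGMA}
    )
    # stimulus
    dbs_frequency_hz: float = 185.0
    dbs_pulse_width_us: float = 180.0
    dbs_amplitude_mode: str = "clinical_auto"  # or "model_units"
    dbs_amplitude_value: float = 1.5  # mA if clinical_auto, else model units
    dbs_t_start_ms: float = 0.0
    dbs_t_end_ms: float | None = None  # None -> duration
    # attribution
    attribution_window_ms: float = 3.0
    # sweep
    sweep_frequencies: tuple = DEFAULT_SWEEP_FREQUENCIES
    sweep_seeds: tuple = (0, 1, 2)
    fig4_frequencies: tuple = (10.0, 60.0, 185.0)
    # output
    out_dir: str = "dbsnet_out"
    figures: bool = True

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            dt=self.dt,
            duration=self.duration_ms,
            burn_in=self.burn_in_ms,
            seed=self.seed if seed is None else seed,
            drive=DriveConfig(bias=dict(self.drive_bias), sigma=dict(self.drive_sigma)),
        )

    def attribution_config(self) -> AttributionConfig:
        return AttributionConfig(window=self.attribution_window_ms)

    def build_network(self, calibrate: bool = True) -> NetworkSpec:
        """Build (and by default calibrate) the network this config describes."""
        base = {tuple(k.split("->")) if isinstance(k, str) else tuple(k): v
                for k, v in self.base_weights.items()}
        net = build_default_network(
            seed=self.network_seed,
            base_weights=base or None,
            tau_inh_ms=self.tau_inh_ms,
        )
        if self.g_exc is not None and self.g_inh is not None:
            net = dataclasses.replace(
                net, g_exc=self.g_exc, g_inh=self.g_inh, calibrated=True
            )
        elif calibrate:
            net = calibrate_weights(
                net,
                drive=DriveConfig(
                    bias=dict(self.drive_bias), sigma=dict(self.drive_sigma)
                ),
                seed=self.network_seed,
            )
        return net

    def amplitude_model(self) -> float:
        """DBS pulse amplitude in model units per the configured mode."""
        if self.dbs_amplitude_mode == "model_units":
            return float(self.dbs_amplitude_value)
        if self.dbs_amplitude_mode == "clinical_auto":
            from .neuron import make_preset
            from .stimulation import calibrate_pulse_amplitude

            return calibrate_pulse_amplitude(
                make_preset("thalamocortical"),
                dt=self.dt,
                pulse_width_us=self.dbs_pulse_width_us,
            )
        raise ValueError(
            f"unknown dbs_amplitude_mode {self.dbs_amplitude_mode!r} "
            "(expected clinical_auto or model_units)"
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["base_weights"] = {
            "->".join(k) if isinstance(k, tuple) else k: v
            for k, v in doc["base_weights"].items()
        }
        doc["sweep_frequencies"] = list(doc["sweep_frequencies"])
        doc["sweep_seeds"] = list(doc["sweep_seeds"])
        doc["fig4_frequencies"] = list(doc["fig4_frequencies"])
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("sweep_frequencies", "sweep_seeds", "fig4_frequencies"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def load_config(path) -> ExperimentConfig:
    """Load an `ExperimentConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(doc)


def save_resolved_config(
    cfg: ExperimentConfig, path, extra: dict | None = None
) -> None:
    """Write the fully resolved configuration (plus provenance) as JSON."""
    doc = cfg.to_dict()
    if extra:
        doc["resolved"] = extra
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
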