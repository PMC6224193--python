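"""Structured configuration with explicit unit suffixes, and seed management.

One YAML format carries every model parameter under its published symbol
with a unit suffix in the key name (``C_pF``, ``gL_nS``, ``R_lgn_Hz`` ...)
to prevent silent unit bugs.  Unknown keys are rejected; defaults are
filled only for the documented decision parameters (reset potential,
refractory period, synaptic delay, integration step, analysis windows) —
never for the in-vivo rate targets, which must be user-supplied.

Randomness is managed from a single master seed: each pipeline stage
derives its own 31-bit sub-seed by stable hashing of the stage name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .factors import ScenarioFactors, make_factors
from .network import InputSpec, NetworkSpec, NeuronParams

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "derive_seed",
    "load_config",
    "table1_config",
]


class ConfigError(ValueError):
    """Named validation failure in a pipeline configuration."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit sub-seed for a named pipeline stage."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


_NEURON_KEYS = {
    "C_pF": ("C", True),
    "gL_nS": ("gL", True),
    "VL_mV": ("VL", True),
    "Vexc_mV": ("Vexc", True),
    "Vinh_mV": ("Vinh", True),
    "Vtheta_mV": ("Vtheta", True),
    "tau_syn_ms": ("tau_syn", True),
    "Vreset_mV": ("Vreset", False),  # decision parameter, default -70
    "t_ref_ms": ("t_ref", False),  # decision parameter, default 2 ms
}
_NETWORK_KEYS = {
    "N": ("N", True),
    "NE": ("NE", True),
    "NI": ("NI", True),
    "in_degree_e": ("in_degree_e", True),
    "in_degree_i": ("in_degree_i", True),
    "j_nS": ("j", True),
    "g_rc": ("g_rc", True),
    "delay_ms": ("delay", False),  # decision parameter, default 1 ms
}
_INPUT_KEYS = {
    "js_nS": ("j_s", True),
    "g_fw": ("g_fw", True),
    "n_lgn": ("n_lgn", True),
    "R_lgn_Hz": ("R_lgn", True),
    "n_bkg": ("n_bkg", True),
    "R_bkg_Hz": ("R_bkg", True),
}
_SIM_DEFAULTS = {"dt_ms": 0.1, "duration_ms": 9000.0, "transient_ms": 500.0}
_TOP_KEYS = {"neuron", "network", "input", "factors", "sweep_ranges", "rate_targets", "sim"}


@dataclass
class PipelineConfig:
    """Validated model/pipeline configuration."""

    neuron: NeuronParams
    network: NetworkSpec
    input: InputSpec
    factors: Optional[ScenarioFactors] = None
    sweep_ranges: Optional[dict] = None  # range name -> (lo, hi)
    rate_targets: Optional[dict] = None  # target_e_Hz, target_i_Hz, tolerance
    sim: dict = field(default_factory=lambda: dict(_SIM_DEFAULTS))
    raw: dict = field(default_factory=dict)
    config_hash: str = ""


def _build_block(name: str, data: dict, keymap: dict, cls):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(data) - set(keymap)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    missing = [k for k, (_f, req) in keymap.items() if req and k not in data]
    if missing:
        raise ConfigError(f"missing required key(s) in '{name}': {missing}")
    kwargs = {keymap[k][0]: data[k] for k in data}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load and fully validate a pipeline configuration file."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    return parse_config(data)


def parse_config(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for req in ("neuron", "network", "input"):
        if req not in data:
            raise ConfigError(f"missing required section '{req}'")
    neuron = _build_block("neuron", data["neuron"], _NEURON_KEYS, NeuronParams)
    network = _build_block("network", data["network"], _NETWORK_KEYS, NetworkSpec)
    input_spec = _build_block("input", data["input"], _INPUT_KEYS, InputSpec)

    factors = None
    if "factors" in data:
        f = data["factors"]
        unknown = set(f) - {"delta_e", "delta_i", "pi"}
        if unknown:
            raise ConfigError(f"unknown key(s) in 'factors': {sorted(unknown)}")
        try:
            factors = make_factors(f["delta_e"], f["delta_i"], f["pi"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"invalid 'factors' block: {exc}") from exc

    sweep_ranges = None
    if "sweep_ranges" in data:
        sr = data["sweep_ranges"]
        allowed = {"j_nS", "g_rc", "R_lgn_Hz", "R_bkg_Hz"}
        unknown = set(sr) - allowed
        if unknown:
            raise ConfigError(f"unknown key(s) in 'sweep_ranges': {sorted(unknown)}")
        sweep_ranges = {}
        for k in allowed:
            if k not in sr:
                raise ConfigError(f"missing range '{k}' in 'sweep_ranges'")
            lo, hi = sr[k]
            if not (0 < lo <= hi):
                raise ConfigError(f"range '{k}' must satisfy 0 < min <= max")
            sweep_ranges[k] = (float(lo), float(hi))

    rate_targets = None
    if "rate_targets" in data:
        rt = data["rate_targets"]
        unknown = set(rt) - {"target_e_Hz", "target_i_Hz", "tolerance"}
        if unknown:
            raise ConfigError(f"unknown key(s) in 'rate_targets': {sorted(unknown)}")
        for req in ("target_e_Hz", "target_i_Hz"):
            if req not in rt:
                raise ConfigError(
                    f"missing '{req}' in 'rate_targets' (no defaults exist)"
                )
        rate_targets = {
            "target_e_Hz": float(rt["target_e_Hz"]),
            "target_i_Hz": float(rt["target_i_Hz"]),
            "tolerance": float(rt.get("tolerance", 0.10)),
        }

    sim = dict(_SIM_DEFAULTS)
    if "sim" in data:
        unknown = set(data["sim"]) - set(_SIM_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown key(s) in 'sim': {sorted(unknown)}")
        sim.update({k: float(v) for k, v in data["sim"].items()})
        if sim["dt_ms"] <= 0 or sim["duration_ms"] <= 0:
            raise ConfigError("sim dt_ms and duration_ms must be positive")
        if sim["transient_ms"] >= sim["duration_ms"]:
            raise ConfigError("sim transient_ms must be smaller than duration_ms")

    cfg_hash = hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return PipelineConfig(
        neuron=neuron,
        network=network,
        input=input_spec,
        factors=factors,
        sweep_ranges=sweep_ranges,
        rate_targets=rate_targets,
        sim=sim,
        raw=data,
        config_hash=cfg_hash,
    )


def table1_config() -> PipelineConfig:
    """The shipped published parameter set (full-size network)."""
    ref = resources.files("l4ei").joinpath("data/table1.yaml")
    return parse_config(yaml.safe_load(ref.read_text()))
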