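"""YAML configuration files and run manifests.

A config file mirrors the NetworkConfig / PlasticityConfig / protocol
blocks; every default is overridable.  A RunManifest captures everything
needed to re-run a CLI invocation bit-identically.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict, fields

import yaml

from . import __version__
from .network import NetworkConfig
from .neurons import NeuronParams
from .plasticity import LongTermConfig, PlasticityConfig, ShortTermConfig
from .protocols import StimulusProtocol


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {path}: {sorted(unknown)}")
    return cls(**data)


def network_config_from_dict(data: dict) -> NetworkConfig:
    data = dict(data)
    for key in ("rs", "fs"):
        if key in data and isinstance(data[key], dict):
            data[key] = NeuronParams(**data[key])
    if "exc_delay_range" in data:
        data["exc_delay_range"] = tuple(data["exc_delay_range"])
    return _build(NetworkConfig, data, "network")


def plasticity_config_from_dict(data: dict) -> PlasticityConfig:
    lt = _build(LongTermConfig, dict(data.get("longterm", {})), "plasticity.longterm")
    st = _build(ShortTermConfig, dict(data.get("shortterm", {})), "plasticity.shortterm")
    return PlasticityConfig(longterm=lt, shortterm=st)


def protocol_from_dict(data: dict) -> StimulusProtocol:
    return _build(StimulusProtocol, dict(data), "protocol")


def load_config(path) -> dict:
    """Load a YAML config; returns {'network': NetworkConfig,
    'plasticity': PlasticityConfig, 'protocol': StimulusProtocol, 'raw': dict}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        "network": network_config_from_dict(raw.get("network", {})),
        "plasticity": plasticity_config_from_dict(raw.get("plasticity", {})),
        "protocol": protocol_from_dict(raw.get("protocol", {})),
        "raw": raw,
    }


def dump_config(network: NetworkConfig, plasticity: PlasticityConfig,
                protocol: StimulusProtocol | None = None) -> dict:
    out = {"network": asdict(network),
           "plasticity": {"longterm": asdict(plasticity.longterm),
                          "shortterm": asdict(plasticity.shortterm)}}
    out["network"]["exc_delay_range"] = list(network.exc_delay_range)
    if protocol is not None:
        out["protocol"] = asdict(protocol)
    return out


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    wall_time_s: float = 0.0
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(manifest), fh, sort_keys=False)


def read_manifest(path) -> RunManifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunManifest(**data)
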