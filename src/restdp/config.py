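"""Run configuration: defaults, YAML round-trip, validation.

A :class:`RunConfig` bundles the four parameter groups (network, neuron,
plasticity, protocol).  An empty config file yields the published model
defaults; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import NeuronParams
from .network import NetworkParams
from .plasticity import STDPParams
from .protocols import ProtocolConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_GROUPS = {
    "network": NetworkParams,
    "neuron": NeuronParams,
    "stdp": STDPParams,
    "protocol": ProtocolConfig,
}


@dataclass
class RunConfig:
    network: NetworkParams = field(default_factory=NetworkParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def validate(self) -> None:
        self.network.validate()
        self.neuron.validate()
        self.stdp.validate()
        self.protocol.validate()

    def to_dict(self) -> dict:
        return {g: dataclasses.asdict(getattr(self, g)) for g in _GROUPS}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the model defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - set(_GROUPS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for group, cls in _GROUPS.items():
        section = data.get(group, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - names
        if bad:
            raise ValueError(f"unknown keys in [{group}]: {sorted(bad)}")
        kwargs[group] = cls(**section)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
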