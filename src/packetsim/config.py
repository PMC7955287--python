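"""Simulation configuration: validation, defaults, (de)serialisation.

A configuration document (YAML or JSON) has the sections ``model``,
``init``, ``stimulus``, ``integration`` and ``output``, or simply
``{preset: 1}`` to pull one of the experiment presets.  Every default is
filled in on load, and the fully-resolved config is echoed into each
run's manifest for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .core_model import GenerativeModelParams, default_box_size

__all__ = ["SimulationConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent simulation configuration."""


_INTEGRATION_KEYS = {"dt", "steps"}
_INIT_KEYS = {"kind", "box_size"}
_OUTPUT_KEYS = {"stride", "dir"}
_STIMULUS_KEYS = {"kind", "t_onset", "t_switch", "radius", "softness", "center_a", "center_b"}
_TOP_KEYS = {"preset", "N", "seed", "model", "init", "stimulus", "integration", "output"}


@dataclass
class SimulationConfig:
    """Fully-resolved parameters of one simulation run."""

    N: int = 256
    dt: float = 0.1
    steps: int = 400
    seed: int = 0
    init: dict = field(default_factory=dict)
    model: GenerativeModelParams = field(default_factory=GenerativeModelParams)
    stimulus: Optional[dict] = None
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.N = int(self.N)
        self.dt = float(self.dt)
        self.steps = int(self.steps)
        self.seed = int(self.seed)
        if self.N < 2:
            raise ConfigError("N must be >= 2")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.steps < 1:
            raise ConfigError("steps must be >= 1")
        if isinstance(self.model, dict):
            self.model = GenerativeModelParams.from_dict(self.model)
        init = {"kind": "uniform", "box_size": default_box_size(self.N)}
        init.update(self.init)
        _reject_unknown(init, _INIT_KEYS, "init")
        self.init = init
        output = {"stride": 10, "dir": "runs"}
        output.update(self.output)
        _reject_unknown(output, _OUTPUT_KEYS, "output")
        if not 1 <= int(output["stride"]):
            raise ConfigError("output.stride must be >= 1")
        self.output = output
        if self.stimulus is not None:
            _reject_unknown(self.stimulus, _STIMULUS_KEYS, "stimulus")

    @property
    def stride(self) -> int:
        return int(self.output["stride"])

    def protocol(self):
        """Instantiate the stimulus protocol, or None when unstimulated."""
        if self.stimulus is None:
            return None
        from .stimulus import build_protocol

        return build_protocol(self.stimulus)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "seed": self.seed,
            "model": self.model.to_dict(),
            "init": dict(self.init),
            "stimulus": None if self.stimulus is None else dict(self.stimulus),
            "integration": {"dt": self.dt, "steps": self.steps},
            "output": dict(self.output),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        _reject_unknown(doc, _TOP_KEYS, "config")
        preset = doc.pop("preset", None)
        integration = doc.pop("integration", {}) or {}
        _reject_unknown(integration, _INTEGRATION_KEYS, "integration")
        if preset is not None:
            from .stimulus import preset_experiment

            base = preset_experiment(int(preset), N=int(doc.pop("N", 256)),
                                     seed=int(doc.pop("seed", 0)))
            merged = base.to_dict()
            merged_int = merged.pop("integration")
            merged_int.update(integration)
            for key, value in doc.items():
                if isinstance(value, dict) and isinstance(merged.get(key), dict):
                    merged[key].update(value)
                else:
                    merged[key] = value
            merged["integration"] = merged_int
            return cls.from_dict(merged)
        kwargs = dict(doc)
        kwargs.update(integration)
        try:
            return cls(**kwargs)
        except TypeError as exc:  # unexpected keyword
            raise ConfigError(str(exc)) from exc

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _reject_unknown(doc: dict, allowed: set, section: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown {section} keys: {sorted(unknown)}")


def load_config(path) -> SimulationConfig:
    """Read and validate a YAML/JSON configuration document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"config document {path} must be a mapping")
    return SimulationConfig.from_dict(doc)
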