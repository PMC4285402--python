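"""Run configuration: a YAML-serialisable bundle of every module's parameters.

A run is reproducible from its archived config plus master seed; the master
seed spawns per-repeat substreams through a counter-based scheme so any
repeat can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bg_network import NetworkProfile
from .experiment import DopamineParams, ScheduleConfig
from .msn import DopamineModulation, MSNParams, SynapseParams
from .plasticity import (
    DEFAULT_COEFFICIENT_VALUES,
    KernelCoefficients,
    MixingParams,
    TimingParams,
    default_mixing,
)

__all__ = ["RunConfig", "load_config", "save_config", "spawn_rng", "config_hash"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All tunables of the modelling stack, with a master seed."""

    seed: int = 0
    n_repeats: int = 10
    out_dir: str = "results"
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENT_VALUES))
    mixing_d1: MixingParams = field(default_factory=lambda: default_mixing()["D1"])
    mixing_d2: MixingParams = field(default_factory=lambda: default_mixing()["D2"])
    timing: TimingParams = field(default_factory=TimingParams)
    msn: MSNParams = field(default_factory=MSNParams)
    synapses: SynapseParams = field(default_factory=SynapseParams)
    modulation: DopamineModulation = field(default_factory=DopamineModulation)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    dopamine: DopamineParams = field(default_factory=DopamineParams)
    network: NetworkProfile = field(default_factory=NetworkProfile)
    version: int = SCHEMA_VERSION

    def kernel_coefficients(self, enforce_mask: bool = False) -> KernelCoefficients:
        from .plasticity import DEFAULT_SIGN_MASK

        return KernelCoefficients.from_flat(
            self.coefficients,
            sign_mask=DEFAULT_SIGN_MASK if enforce_mask else None,
        )

    def mixing(self) -> dict:
        return {"D1": self.mixing_d1, "D2": self.mixing_d2}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    data = _to_plain(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


_SECTION_TYPES = {
    "mixing_d1": MixingParams,
    "mixing_d2": MixingParams,
    "timing": TimingParams,
    "msn": MSNParams,
    "synapses": SynapseParams,
    "modulation": DopamineModulation,
    "schedule": ScheduleConfig,
    "dopamine": DopamineParams,
    "network": NetworkProfile,
}

_TUPLE_FIELDS = {
    "schedule": ("trials",),
    "network": ("w_cs_d1", "w_cs_d2", "eps_cs_d1", "eps_cs_d2",
                "unsaturated_msn", "lam_off"),
}


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if raw.get("version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {raw.get('version')}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            for tf in _TUPLE_FIELDS.get(key, ()):
                if tf in value and value[tf] is not None:
                    value[tf] = tuple(value[tf])
            kwargs[key] = _SECTION_TYPES[key](**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration, for provenance records."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for sub-task ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), *map(int, key)]))
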