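"""Run configuration: loading, defaults, unit normalization, seed splitting.

Configs are JSON or YAML.  Internally everything is seconds and Hz; keys
with an ``_ms`` suffix are accepted and converted.  All randomness in a run
derives from the single ``seed`` via ``numpy.random.SeedSequence`` spawning,
so identical configs reproduce identical artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("isnkit")

__all__ = ["RunConfig", "load_config", "dump_config"]

_DEFAULTS = {
    "seed": 0,
    "pairs": 1,
    "dt": 1e-5,
    "settle_dt": 1e-4,
    "settle_time": 12.0,
    "tau": 0.010,
    "family": "lognormal",
    "cv": 0.5,
    "beta": 1.0,
    "amplitude": None,
    "duration": None,
    "amp_grid": None,
    "dur_grid": None,
    "out": None,
}

_MS_KEYS = {"duration_ms": "duration", "dur_ms": "duration",
            "settle_time_ms": "settle_time", "dt_ms": "dt",
            "settle_dt_ms": "settle_dt", "tau_ms": "tau"}


@dataclass
class RunConfig:
    seed: int = 0
    pairs: int = 1
    dt: float = 1e-5
    settle_dt: float = 1e-4
    settle_time: float = 12.0
    tau: float = 0.010
    family: str = "lognormal"
    cv: float = 0.5
    beta: float = 1.0
    amplitude: float = None
    duration: float = None
    amp_grid: list = None
    dur_grid: list = None
    out: str = None
    extras: dict = field(default_factory=dict)

    def seed_sequence(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed)

    def spawn_seed(self, ss: np.random.SeedSequence) -> int:
        """Derive one child integer seed (< 2^31) and log it."""
        child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        log.info("derived child seed %d", child)
        return child

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("extras"))
        return d


def _normalize(raw: dict) -> dict:
    out = {}
    for key, value in raw.items():
        if key in _MS_KEYS:
            out[_MS_KEYS[key]] = float(value) / 1000.0
        elif key in _DEFAULTS or key == "extras":
            out[key] = value
        else:
            raise KeyError(f"unknown config key {key!r}")
    return out


def load_config(path) -> RunConfig:
    """Load and validate a JSON/YAML config, applying documented defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    norm = _normalize(raw)
    extras = norm.pop("extras", {})
    merged = dict(_DEFAULTS)
    merged.update(norm)
    return RunConfig(extras=extras, **merged)


def dump_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=True))
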