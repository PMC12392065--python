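"""Run configuration: YAML-backed parameter blocks with explicit seeds."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for malformed run configurations (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Parameters for the seeded end-to-end experiment drivers.

    The per-module blocks (``subject``, ``gate``, ``hunt``,
    ``patterns``) hold keyword overrides for the corresponding
    dataclasses; omitted keys keep the module defaults.  Every
    stochastic stage derives its own stream from ``seed``.
    """

    experiment: str = "mifind"
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    n_participants: int = 8
    replicates: int = 100
    subject: dict = field(default_factory=dict)
    control_subject: dict = field(default_factory=lambda: {"session_gain": 1.0})
    gate: dict = field(default_factory=dict)
    hunt: dict = field(default_factory=lambda: {
        "threshold": 45.0, "slope": 2.0, "start_intensity": 40.0,
        "n_trials": 20, "reps": 500,
    })
    patterns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")

    def rng(self, *key: str | int) -> np.random.Generator:
        """A dedicated, reproducible random stream for one stage.

        Keys are hashed with CRC32 so streams are stable across
        processes (Python's builtin hash is salted per interpreter).
        """
        spawn = tuple(zlib.crc32(str(k).encode()) % (2**31) for k in key)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn))

    # ---- persistence -------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
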