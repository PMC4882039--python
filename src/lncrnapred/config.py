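"""Run configuration: every tunable of the pipeline with its default.

Stage seeds are derived deterministically from the master seed so a single
integer reproduces the whole run; each derived seed is recorded in the
provenance block of every run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

_STAGES = ("som", "draw", "forest", "importance", "simulate", "split")


@dataclass
class RunConfig:
    min_len: int = 200
    max_len: int = 20000
    p: int = 30
    som_rows: int = 8
    som_cols: int = 8
    som_epochs: int = 10
    L: int = 2000
    n_trees: int = 300
    orf_shortcut: int = 54
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ConfigurationError("min_len exceeds max_len")
        if self.p < 1:
            raise ConfigurationError("p must be >= 1")

    def stage_seeds(self) -> dict[str, int]:
        """One reproducible sub-seed per stochastic stage, all < 2**31."""
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
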