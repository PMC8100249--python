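"""Run configuration: one serializable object that re-executes to identical
outputs, plus the master-seed splitting rule.

Stage seeds are derived from the master seed by hashing the stage name into
a seed sequence (``SeedSequence([master, crc32(name)])``), so the cohort
and the bout-selection draws have independent streams and any stage can be
re-run on its own without disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .paradigms import PARADIGM_NAMES, ParadigmSpec
from .synthetic import CohortConfig, EventTiming
from .windows import WindowSpec


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full simulate → featurize → evaluate run needs."""

    seed: int = 0
    output_dir: str = "locomode_run"
    shrinkage: float = 0.01
    #: window lengths in ms; the full sweep is 100-600 in steps of 25
    window_lengths_ms: list = field(default_factory=lambda: [float(w) for w in range(100, 625, 25)])
    increment_ms: float = 25.0
    nominal_length_ms: float = 300.0
    paradigms: list = field(default_factory=lambda: list(PARADIGM_NAMES))
    log_level: str = "INFO"
    #: overrides for CohortConfig fields (n_subjects, sigma_trial_UA, ...)
    cohort: dict = field(default_factory=dict)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        if "event_timing" in kwargs and isinstance(kwargs["event_timing"], dict):
            kwargs["event_timing"] = EventTiming(**kwargs["event_timing"])
        kwargs["seed"] = stage_seed(self.seed, "cohort")
        return CohortConfig(**kwargs)

    def window_specs(self) -> list[WindowSpec]:
        return [WindowSpec(float(w), self.increment_ms) for w in self.window_lengths_ms]

    def nominal_spec(self) -> WindowSpec:
        return WindowSpec(self.nominal_length_ms, self.increment_ms)

    def paradigm_specs(self) -> list[ParadigmSpec]:
        bout_seed = stage_seed(self.seed, "bouts")
        return [ParadigmSpec(name, bout_selection_seed=bout_seed) for name in self.paradigms]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
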