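"""Flat run configuration: every analysis convention is visible and overridable.

Each default corresponds to a stated convention of the analysis (idle
cutoff, window margin, straddle policy, workday rule, top-k, high-user
threshold, administrative fraction); the point of surfacing them all is
that any gap-filling choice can be switched without touching code.
Configs load from a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    idle_cutoff_minutes: float = 15.0
    idle_policy: str = "drop"               # or "zero_duration"
    margin_minutes: float = 30.0
    straddle_policy: str = "proportional"   # or "start"
    workday_rule: str = "either"            # "events" | "visits" | "either"
    unmapped_policy: str = "strict"         # or "uncategorized"
    k_top: int = 3
    high_user_threshold_hours: float = 1.5
    admin_fraction: float = 0.11
    aggregations: tuple[str, ...] = ("daily", "weekly")
    outcomes: tuple[str, ...] = ("during", "outside", "total")
    transform: str = "none"
    skew_threshold: float = 1.0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aggregations"] = list(self.aggregations)
        d["outcomes"] = list(self.outcomes)
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a flat YAML mapping onto :class:`PipelineConfig` (unknown keys rejected)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a flat mapping, got {type(raw).__name__}")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("aggregations", "outcomes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
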