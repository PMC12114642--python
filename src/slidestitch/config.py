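"""Run configuration: one validated schema shared by all commands.

JSON config file < CLI flags (flags win).  One seed governs every
stochastic component (robust estimation, region sampling, synthetic data).
"""

from __future__ import annotations

import json

from pydantic import BaseModel, ConfigDict, Field, field_validator


class ComposeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    distortion: bool = True
    seams: bool = True
    exposure: bool = False
    blend: bool = False
    chunk_px: int = Field(default=1024, ge=256)


class WatchOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    poll_interval_ms: float = Field(default=50.0, gt=0)
    stability_window_ms: float = Field(default=200.0, ge=0)
    ordering: str = "event_time"
    channels: dict[str, str] = {}
    ref_channel: str | None = None

    @field_validator("ordering")
    @classmethod
    def _ordering(cls, v):
        if v not in ("event_time", "lexicographic"):
            raise ValueError("ordering must be event_time or lexicographic")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    detector: str = "sift"
    mode: str = "T"
    ba_interval: int = Field(default=10, ge=1)
    ba_iterations: int = Field(default=1, ge=1)
    matching: str = "seq+add"
    overlap_min_frac: float = Field(default=0.05, gt=0, lt=1)
    preview_scale: float = Field(default=0.1, gt=0, le=1)
    seed: int = 0
    log_path: str | None = None
    compose: ComposeConfig = ComposeConfig()
    watch: WatchOptions = WatchOptions()

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        v = v.upper()
        if v not in ("T", "TR", "TRS"):
            raise ValueError("mode must be one of T, TR, TRS")
        return v

    @field_validator("matching")
    @classmethod
    def _matching(cls, v):
        aliases = {
            "seq": "sequential_only",
            "seq+add": "sequential_plus_additional",
            "brute": "brute_force",
        }
        if v in aliases:
            return v
        if v in aliases.values():
            inv = {val: k for k, val in aliases.items()}
            return inv[v]
        raise ValueError("matching must be one of seq, seq+add, brute")

    @property
    def matching_mode(self) -> str:
        return {
            "seq": "sequential_only",
            "seq+add": "sequential_plus_additional",
            "brute": "brute_force",
        }[self.matching]


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build the resolved config: documented defaults ← file ← flags."""
    data: dict = {}
    if path:
        with open(path) as fh:
            data = json.load(fh)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, sub = key.split(".", 1)
            data.setdefault(section, {})[sub] = value
        else:
            data[key] = value
    return RunConfig(**data)
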