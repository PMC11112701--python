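"""Hierarchical run configuration.

Every procedural constant of the measurement protocol lives here with its
study default rather than being hard-coded: 70 dB SPL masker level, 7 dB SNR
test start (10 dB for practice), 20 trials per track (16 practice trials),
4 dB initial step reduced to 2 dB after the first reversal, the 4-SD outlier
rule and alpha = 0.05.  Configs round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .listeners import CohortConfig
from .staircase import TrackConfig, lax_track, practice_track, strict_track


@dataclass
class CorpusBlock:
    seed_offset: int = 0  # corpus stream is derived from the run seed
    duration_mean_s: float = 1.8
    duration_sd_s: float = 0.3
    duration_min_s: float = 1.0


@dataclass
class AnalysisBlock:
    exclusion_sd_multiplier: float = 4.0
    alpha: float = 0.05
    interaction: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    schedule: str = "random"  # interleave schedule: "random" or "alternate"
    include_practice: bool = True
    n_replicates: int = 200  # for recovery experiments
    corpus: CorpusBlock = field(default_factory=CorpusBlock)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    track_lax: TrackConfig = field(default_factory=lax_track)
    track_strict: TrackConfig = field(default_factory=strict_track)
    track_practice: TrackConfig = field(default_factory=practice_track)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)

    def __post_init__(self) -> None:
        if self.schedule not in ("random", "alternate"):
            raise ValueError("schedule must be 'random' or 'alternate'")


def _build(cls, block: dict[str, Any] | None, label: str):
    block = dict(block or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown keys in {label} block: {sorted(unknown)}")
    # tolerate lists where tuples are expected (YAML has no tuples)
    for f in dataclasses.fields(cls):
        if f.name in block and isinstance(block[f.name], list):
            block[f.name] = tuple(block[f.name])
    return cls(**block)


def config_from_dict(d: dict[str, Any]) -> RunConfig:
    d = dict(d or {})
    kwargs: dict[str, Any] = {}
    for key, cls in (
        ("corpus", CorpusBlock),
        ("cohort", CohortConfig),
        ("analysis", AnalysisBlock),
    ):
        if key in d:
            kwargs[key] = _build(cls, d.pop(key), key)
    for key, default_kw in (
        ("track_lax", {"criterion_min_correct": 1}),
        ("track_strict", {"criterion_min_correct": 3}),
        ("track_practice", {"criterion_min_correct": 1, "n_trials": 16, "start_snr_db": 10.0}),
    ):
        if key in d:
            block = {**default_kw, **(d.pop(key) or {})}
            kwargs[key] = _build(TrackConfig, block, key)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs.update(d)
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = config_to_dict(cfg)
    # YAML-friendly tuples
    d["cohort"]["age_range_years"] = list(d["cohort"]["age_range_years"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
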