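"""End-to-end per-user pipelines: ingest -> prepare -> tune -> evaluate.

Glue used by both the command-line interface and the reproduction
script: every stage is a thin call into the corresponding module, with
run provenance (resolved configuration, seeds, input hashes) written
next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dietplan import STANDARD_EB_LEVELS, STANDARD_SPLIT
from .energy import UserSeries, prepare_series
from .tuning import TuningResult, grid_search

__all__ = ["RunConfig", "TunedUser", "prepare_and_tune", "write_provenance"]


@dataclass
class RunConfig:
    """Resolved run settings, serializable to/from flat YAML."""

    inputs: list[str] = field(default_factory=list)
    outdir: str = "runs"
    test_days: int = 7
    train_fraction: float | None = None
    budget: int = 60
    retrain: str = "every_step"
    eb_levels: tuple = STANDARD_EB_LEVELS
    macro_split: tuple = STANDARD_SPLIT
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.test_days < 1:
            raise ValueError("test_days must be >= 1")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.retrain not in ("every_step", "frozen"):
            raise ValueError("retrain must be every_step or frozen")
        if self.train_fraction is not None and not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eb_levels"] = list(self.eb_levels)
        d["macro_split"] = list(self.macro_split)
        return d


def write_provenance(outdir: Path, config: RunConfig, extra: dict | None = None) -> None:
    """Serialize resolved config + input hashes into the run directory."""
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.to_dict(), "input_sha256": {}}
    for p in config.inputs:
        p = Path(p)
        if p.exists():
            payload["input_sha256"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    if extra:
        payload.update(extra)
    (outdir / "run.json").write_text(json.dumps(payload, indent=2, default=str))


@dataclass
class TunedUser:
    """A prepared user series with its tuned forecaster."""

    series: UserSeries  # prepared: imputed, bias-corrected, seasonal features
    tuning: TuningResult
    train_days: int
    bias_b: float | None


def prepare_and_tune(
    series: UserSeries,
    test_days: int = 7,
    budget: int = 60,
    seed: int = 0,
    correct_bias: bool = True,
    space=None,
) -> TunedUser:
    """Standard preprocessing followed by constraint-filtered tuning.

    The imputation segment boundary, the bias regression and the feature
    scaler all see only the training days (everything before the last
    ``test_days``).
    """
    train_days = len(series) - test_days
    if train_days < 30:
        raise ValueError(f"need >= 30 training days, got {train_days}")
    prepared, bias = prepare_series(series, train_days, correct_bias=correct_bias)
    tuning = grid_search(prepared, space=space, budget=budget, seed=seed, test_len=test_days)
    return TunedUser(
        series=prepared, tuning=tuning, train_days=train_days,
        bias_b=bias.b if bias is not None else None,
    )
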