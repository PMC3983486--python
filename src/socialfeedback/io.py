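"""Canonical file formats, pipeline configuration, and run manifests.

All tables are UTF-8, comma-delimited text with a header row.  The trial
log has one row per trial:

    participant_id, run, order_index, target, adjective, valence,
    first_rating, feedback, second_rating, recollection

with integer ratings 1..8 (empty = missing response), feedback on the
1.0-8.0 display grid, and recollection on the same grid (empty = missing).
Numbers are serialized at fixed precision (ratings integer, feedback and
recollection one decimal, scores six decimals) so that file hashes are
reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AgentParams, CohortConfig
from .task import FEEDBACK_GRID, FeedbackEngineParams

__all__ = [
    "PipelineConfig",
    "read_trial_log",
    "write_trial_log",
    "read_participants",
    "write_participants",
    "write_scores",
    "write_manifest",
    "TrialLogError",
]

log = logging.getLogger("socialfeedback")

TRIAL_COLUMNS = [
    "participant_id",
    "run",
    "order_index",
    "target",
    "adjective",
    "valence",
    "first_rating",
    "feedback",
    "second_rating",
    "recollection",
]


class TrialLogError(ValueError):
    """Raised when a trial log violates the declared schema."""


def _bad_rows(msg: str, mask: pd.Series) -> str:
    rows = (mask[mask].index + 2).tolist()  # +2: header line and 0-base
    shown = ", ".join(map(str, rows[:10])) + (" ..." if len(rows) > 10 else "")
    return f"{msg} (file line(s) {shown})"


def validate_trial_log(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"trial log lacks required columns: {missing}")
    problems = []
    for col in ("first_rating", "second_rating"):
        v = df[col]
        bad = v.notna() & (
            (v < 1) | (v > 8) | (np.rint(v.fillna(1)) != v.fillna(1))
        )
        if bad.any():
            problems.append(_bad_rows(f"{col} must be an integer in 1..8", bad))
    fb = df["feedback"]
    on_grid = fb.round(1).isin(np.round(FEEDBACK_GRID, 1))
    if (~on_grid | fb.isna()).any():
        problems.append(
            _bad_rows("feedback must be on the 1.0-8.0 grid", ~on_grid | fb.isna())
        )
    rec = df["recollection"]
    bad_rec = rec.notna() & ~rec.round(1).isin(np.round(FEEDBACK_GRID, 1))
    if bad_rec.any():
        problems.append(_bad_rows("recollection must be on the 1.0-8.0 grid", bad_rec))
    bad_t = ~df["target"].isin(["self", "other"])
    if bad_t.any():
        problems.append(_bad_rows("target must be 'self' or 'other'", bad_t))
    bad_v = ~df["valence"].isin(["positive", "negative"])
    if bad_v.any():
        problems.append(_bad_rows("valence must be 'positive' or 'negative'", bad_v))
    if problems:
        raise TrialLogError("; ".join(problems))


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "adjective": str})
    validate_trial_log(df)
    return df[TRIAL_COLUMNS]


def write_trial_log(df: pd.DataFrame, path) -> None:
    validate_trial_log(df)
    out = df[TRIAL_COLUMNS].copy()
    for col in ("first_rating", "second_rating"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in ("feedback", "recollection"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def write_participants(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, index=False)


def write_scores(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, index=False)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end configuration: cohort, feedback engine, analysis options."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    engine: FeedbackEngineParams = dataclasses.field(
        default_factory=FeedbackEngineParams
    )
    within: list = dataclasses.field(default_factory=lambda: ["target", "desirability"])
    between: list = dataclasses.field(default_factory=lambda: ["culture", "place"])
    alpha_level: float = 0.05
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        cfg.seed = seed
        cfg.cohort = dataclasses.replace(cfg.cohort, rng_seed=seed)
        cfg.engine = dataclasses.replace(cfg.engine, rng_seed=seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["group_sizes"] = {
            f"{c}|{p}": n for (c, p), n in self.cohort.group_sizes.items()
        }
        d["cohort"]["agent"]["alpha"] = {
            f"{t}|{de}": a for (t, de), a in self.cohort.agent.alpha.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ch = dict(d.get("cohort", {}))
        if "group_sizes" in ch:
            ch["group_sizes"] = {
                tuple(k.split("|")): v for k, v in ch["group_sizes"].items()
            }
        if "agent" in ch:
            ag = dict(ch["agent"])
            if "alpha" in ag:
                ag["alpha"] = {tuple(k.split("|")): v for k, v in ag["alpha"].items()}
            ch["agent"] = AgentParams(**ag)
        eng = d.get("engine", {})
        if "discrepancy_magnitude_range" in eng:
            eng = dict(eng)
            eng["discrepancy_magnitude_range"] = tuple(
                eng["discrepancy_magnitude_range"]
            )
        return cls(
            cohort=CohortConfig(**ch),
            engine=FeedbackEngineParams(**eng),
            within=list(d.get("within", ["target", "desirability"])),
            between=list(d.get("between", ["culture", "place"])),
            alpha_level=float(d.get("alpha_level", 0.05)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: PipelineConfig, tables: dict) -> dict:
    """Write a plain-text run manifest; ``tables`` maps name -> file path."""
    from . import __version__

    manifest = {
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "tables": {},
    }
    for name, p in tables.items():
        p = Path(p)
        n_rows = sum(1 for _ in open(p)) - 1
        manifest["tables"][name] = {
            "path": p.name,
            "rows": n_rows,
            "sha256": file_sha256(p),
        }
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tmp.replace(path)
    return manifest
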