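"""Trial-table schema, run configuration, and atomic file I/O.

Trial tables are plain CSV, one row per presented item.  All indices are
1-based, matching the experiment's trial numbering (overall trials 1-120);
``correct`` and ``dual_task`` are 0/1 integers for cross-language safety.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import BlockSchedule, LearningTrajectory
from .hierarchical import ModelSpec
from .synthetic_data import (
    CONDITIONS,
    CohortConfig,
    ConditionSpec,
    N_BLOCKS,
    TRIALS_PER_BLOCK,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "RunConfig",
]

REQUIRED_COLUMNS = [
    "participant_id", "condition", "block", "trial_in_block", "trial_overall",
    "set_size", "item_position", "correct", "shape_family", "dual_task",
]
OPTIONAL_COLUMNS = ["rotation_deg", "button"]


class SchemaError(ValueError):
    """A trial table violated the file schema."""


def _fail(row: int, rule: str):
    raise SchemaError(f"trial table invalid at row {row}: {rule}")


def validate_trial_table(frame: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` with row number and rule on any violation."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    checks = [
        (~frame["condition"].isin(CONDITIONS), f"condition must be one of {CONDITIONS}"),
        (~frame["block"].between(1, N_BLOCKS), "block must be in 1..4"),
        (~frame["trial_in_block"].between(1, TRIALS_PER_BLOCK), "trial_in_block must be in 1..30"),
        (frame["trial_overall"] != TRIALS_PER_BLOCK * (frame["block"] - 1)
         + frame["trial_in_block"],
         "trial_overall must equal 30*(block-1) + trial_in_block"),
        (~frame["set_size"].between(2, 6), "set_size must be in 2..6"),
        (~frame["item_position"].between(1, frame["set_size"]),
         "item_position must be in 1..set_size"),
        (~frame["correct"].isin([0, 1]), "correct must be 0 or 1"),
        (~frame["dual_task"].isin([0, 1]), "dual_task must be 0 or 1"),
    ]
    for bad, rule in checks:
        if bad.any():
            _fail(int(frame.index[bad][0]) + 2, rule)  # +2: header + 1-based
    counts = frame.groupby(["participant_id", "trial_overall"]).agg(
        n=("item_position", "size"), ss=("set_size", "first"),
        npos=("item_position", "nunique"))
    wrong = counts[(counts["n"] != counts["ss"]) | (counts["npos"] != counts["n"])]
    if len(wrong):
        pid, tr = wrong.index[0]
        raise SchemaError(
            f"participant {pid} trial {tr}: expected exactly set_size distinct "
            "item positions")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    validate_trial_table(frame)
    return frame


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_trial_table(frame: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(frame)
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in frame.columns]
    _atomic_write(Path(path), lambda tmp: frame[cols].to_csv(tmp, index=False))


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    _atomic_write(Path(path), lambda tmp: frame.to_csv(tmp, index=False))


def write_json(obj: dict, path: str | Path) -> None:
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(
        json.dumps(obj, indent=2, sort_keys=True)))


# -- run configuration --------------------------------------------------


@dataclass
class RunConfig:
    """JSON-serializable configuration of a full pipeline run."""

    seed: int = 0
    cohort: CohortConfig | None = None
    spec: ModelSpec = field(default_factory=ModelSpec)
    method: str = "nuts"
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    #: random-effect keys sampled in centered parameterization
    centered: tuple = ()
    output_dir: str = "runs/default"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "spec": self.spec.to_dict(),
            "method": self.method,
            "chains": self.chains,
            "warmup": self.warmup,
            "draws": self.draws,
            "target_accept": self.target_accept,
            "centered": sorted(self.centered),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        if self.cohort is not None:
            d["cohort"] = _cohort_to_dict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            seed=d.get("seed", 0),
            cohort=_cohort_from_dict(d["cohort"]) if "cohort" in d else None,
            spec=ModelSpec.from_dict(d["spec"]) if "spec" in d else ModelSpec(),
            method=d.get("method", "nuts"),
            chains=d.get("chains", 4),
            warmup=d.get("warmup", 1000),
            draws=d.get("draws", 1000),
            target_accept=d.get("target_accept", 0.8),
            centered=tuple(d.get("centered", ())),
            output_dir=d.get("output_dir", "runs/default"),
            log_level=d.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _traj_to_dict(t: LearningTrajectory) -> dict:
    return {
        "log_start_threshold": t.log_start_threshold,
        "log_half_time": t.log_half_time,
        "log_asym_threshold": t.log_asym_threshold,
        "shape": t.shape,
    }


def _traj_from_dict(d: dict) -> LearningTrajectory:
    return LearningTrajectory(
        log_start_threshold=d["log_start_threshold"],
        log_half_time=d["log_half_time"],
        log_asym_threshold=d["log_asym_threshold"],
        shape=d["shape"],
    )


def _cohort_to_dict(cfg: CohortConfig) -> dict:
    conds = {}
    for name, spec in cfg.conditions.items():
        entry = {"n_participants": spec.n_participants,
                 "trajectory": _traj_to_dict(spec.trajectory)}
        if spec.schedule is not None:
            entry["schedule"] = {
                "total_delta": list(spec.schedule.total_delta),
                "interior_weights": [list(w) for w in spec.schedule.interior_weights],
            }
        conds[name] = entry
    return {
        "conditions": conds,
        "random_effect_sds": list(cfg.random_effect_sds),
        "seed": cfg.seed,
        "timescale": cfg.timescale,
    }


def _cohort_from_dict(d: dict) -> CohortConfig:
    conds = {}
    for name, entry in d["conditions"].items():
        traj = _traj_from_dict(entry["trajectory"])
        sched = None
        if "schedule" in entry:
            sched = BlockSchedule(
                reference_values=traj,
                total_delta=tuple(entry["schedule"]["total_delta"]),
                interior_weights=tuple(tuple(w) for w in
                                       entry["schedule"]["interior_weights"]),
            )
        conds[name] = ConditionSpec(
            n_participants=entry["n_participants"], trajectory=traj, schedule=sched)
    return CohortConfig(
        conditions=conds,
        random_effect_sds=tuple(d.get("random_effect_sds", (0.3, 0.3, 0.3))),
        seed=d.get("seed", 0),
        timescale=d.get("timescale", "overall_1_120"),
    )
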