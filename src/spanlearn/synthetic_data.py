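"""Seeded synthetic span-task data mirroring the study design.

A session is 4 blocks x 30 trials.  Set sizes 2-6 each occur six times per
block, with the first five trials of every block fixed to the ascending
order (2, 3, 4, 5, 6).  Each block uses six stimuli of one of two shape
families (oval-with-wedge or irregular pentagon, alternating across blocks),
rotated to six angles 28 degrees apart; the two same-shape blocks use
disjoint angle sets 180 degrees apart.  Stimuli map to six response buttons
under a constant, per-block, or per-trial-random bijection depending on
condition.

Item responses are Bernoulli draws from the core psychometric model; the
generator is purely descriptive (condition differences enter only through
the supplied trajectory parameters, not through a mechanistic learner).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    BlockSchedule,
    GUESS_RATE,
    LearningTrajectory,
    accuracy,
    threshold_at_trial,
)

__all__ = [
    "CONDITIONS",
    "DUAL_TASK_CONDITIONS",
    "ROTATION_SPACING_DEG",
    "N_BLOCKS",
    "TRIALS_PER_BLOCK",
    "SET_SIZES",
    "DesignTrial",
    "CohortConfig",
    "ConditionSpec",
    "generate_design",
    "assign_mapping",
    "canonical_mapping",
    "simulate_responses",
    "generate_cohort",
    "chance_responder",
    "participant_rng",
    "default_cohort_config",
]

CONDITIONS = ("constant", "constant_search", "random", "blocked", "blocked_search")
DUAL_TASK_CONDITIONS = frozenset({"constant_search", "blocked_search"})
#: Conditions whose stimulus-button mapping is redrawn at the start of each block.
BLOCKED_MAPPING_CONDITIONS = frozenset({"blocked", "blocked_search"})

N_BLOCKS = 4
TRIALS_PER_BLOCK = 30
SET_SIZES = (2, 3, 4, 5, 6)
OPENING_SET_SIZES = (2, 3, 4, 5, 6)
ROTATION_SPACING_DEG = 28.0
N_STIMULI = 6
N_BUTTONS = 6
SHAPE_FAMILIES = ("oval_wedge", "pentagon")


@dataclass(frozen=True)
class DesignTrial:
    """One presented trial, before any responses are simulated."""

    participant_id: str
    condition: str
    block: int
    trial_in_block: int
    trial_overall: int
    set_size: int
    shape_family: str
    stimulus_rotations: tuple[float, ...]
    mapping: dict[float, int]
    dual_task: bool


@dataclass(frozen=True)
class ConditionSpec:
    """Generating parameters for one between-subject condition."""

    n_participants: int
    trajectory: LearningTrajectory
    #: Optional per-block offsets (blocked-mapping conditions, E2-style data).
    schedule: BlockSchedule | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``random_effect_sds`` are the SDs of independent normal participant
    deviations on (log_start, log_half_time, log_asym).
    """

    conditions: dict[str, ConditionSpec]
    random_effect_sds: tuple[float, float, float] = (0.3, 0.3, 0.3)
    seed: int = 0
    timescale: str = "overall_1_120"

    def __post_init__(self) -> None:
        for name, spec in self.conditions.items():
            if name not in CONDITIONS:
                raise ValueError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
            if spec.n_participants < 1:
                raise ValueError(f"condition {name!r} needs >= 1 participants")
        if any(sd < 0 for sd in self.random_effect_sds):
            raise ValueError("random-effect SDs must be >= 0")
        if self.timescale not in ("overall_1_120", "within_block_1_30"):
            raise ValueError(f"unknown timescale {self.timescale!r}")


def participant_rng(master_seed: int, participant_id: str) -> np.random.Generator:
    """Stable per-participant RNG stream, independent of generation order."""
    tag = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def canonical_mapping(rotations) -> dict[float, int]:
    """The fixed stimulus-to-button bijection of the constant conditions.

    Buttons are numbered 1-6 left to right (1-3 left hand, 4-6 right hand).
    The most-counterclockwise stimulus (smallest angle) goes to the left
    hand's middle button (2) and the most-clockwise to the right hand's left
    button (4); intermediate stimuli fill the remaining buttons in
    counterclockwise-to-clockwise order (1, 3, 5, 6).
    """
    order = sorted(rotations)
    buttons = [2, 1, 3, 5, 6, 4]
    return {rot: btn for rot, btn in zip(order, buttons)}


def _random_mapping(rotations, rng: np.random.Generator) -> dict[float, int]:
    buttons = rng.permutation(N_BUTTONS) + 1
    return {rot: int(btn) for rot, btn in zip(sorted(rotations), buttons)}


def assign_mapping(condition: str, rotations, rng: np.random.Generator,
                   block_mapping: dict[float, int] | None = None) -> dict[float, int]:
    """Stimulus-to-button bijection for one trial.

    Constant conditions always return the canonical mapping; blocked
    conditions reuse ``block_mapping`` (drawn once per block by the caller);
    the random condition draws a fresh uniform bijection.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition in BLOCKED_MAPPING_CONDITIONS:
        if block_mapping is None:
            raise ValueError("blocked conditions require a per-block mapping")
        return block_mapping
    if condition == "random":
        return _random_mapping(rotations, rng)
    return canonical_mapping(rotations)


def _block_set_sizes(rng: np.random.Generator) -> list[int]:
    """30 set sizes: fixed ascending opening, then the balanced remainder."""
    remainder = [s for s in SET_SIZES for _ in range(TRIALS_PER_BLOCK // len(SET_SIZES) - 1)]
    rng.shuffle(remainder)
    return list(OPENING_SET_SIZES) + remainder


def _rotation_sets(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint six-angle sets, 28 deg spacing, 180 deg apart."""
    base = float(rng.uniform(0.0, ROTATION_SPACING_DEG))
    first = (base + ROTATION_SPACING_DEG * np.arange(N_STIMULI)) % 360.0
    second = (first + 180.0) % 360.0
    if rng.random() < 0.5:
        first, second = second, first
    return np.round(first, 6), np.round(second, 6)


def generate_design(condition: str, participant_id: str, seed: int) -> list[DesignTrial]:
    """One participant's full 120-trial session design."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = participant_rng(seed, participant_id)
    dual = condition in DUAL_TASK_CONDITIONS

    # Shape families alternate across blocks; a fair coin decides whether the
    # oval family takes blocks (1, 3) or (2, 4).
    oval_first = bool(rng.random() < 0.5)
    families = ["oval_wedge" if (b % 2 == (1 if oval_first else 0)) else "pentagon"
                for b in range(1, N_BLOCKS + 1)]

    per_family_sets = {fam: _rotation_sets(rng) for fam in SHAPE_FAMILIES}
    family_use_count = {fam: 0 for fam in SHAPE_FAMILIES}

    trials: list[DesignTrial] = []
    for block in range(1, N_BLOCKS + 1):
        fam = families[block - 1]
        rotations = per_family_sets[fam][family_use_count[fam]]
        family_use_count[fam] += 1
        set_sizes = _block_set_sizes(rng)
        block_mapping = (_random_mapping(rotations, rng)
                         if condition in BLOCKED_MAPPING_CONDITIONS else None)
        for t, ss in enumerate(set_sizes, start=1):
            shown = rotations[rng.choice(N_STIMULI, size=ss, replace=False)]
            mapping = assign_mapping(condition, rotations, rng, block_mapping)
            trials.append(DesignTrial(
                participant_id=participant_id,
                condition=condition,
                block=block,
                trial_in_block=t,
                trial_overall=TRIALS_PER_BLOCK * (block - 1) + t,
                set_size=ss,
                shape_family=fam,
                stimulus_rotations=tuple(float(r) for r in shown),
                mapping=mapping,
                dual_task=dual,
            ))
    return trials


def _design_frame(trials: list[DesignTrial]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        for pos in range(1, tr.set_size + 1):
            rot = tr.stimulus_rotations[pos - 1]
            rows.append({
                "participant_id": tr.participant_id,
                "condition": tr.condition,
                "block": tr.block,
                "trial_in_block": tr.trial_in_block,
                "trial_overall": tr.trial_overall,
                "set_size": tr.set_size,
                "item_position": pos,
                "shape_family": tr.shape_family,
                "dual_task": int(tr.dual_task),
                "rotation_deg": rot,
                "button": tr.mapping[rot],
            })
    return pd.DataFrame(rows)


def _item_probabilities(frame: pd.DataFrame,
                        model: LearningTrajectory | BlockSchedule,
                        timescale: str) -> np.ndarray:
    """Per-item correct-response probability under a trajectory or schedule."""
    if isinstance(model, BlockSchedule):
        probs = np.empty(len(frame))
        for block in range(1, N_BLOCKS + 1):
            mask = frame["block"].to_numpy() == block
            if not mask.any():
                continue
            traj = model.trajectory_for_block(block)
            th = threshold_at_trial(frame.loc[mask, "trial_in_block"].to_numpy(), traj)
            probs[mask] = accuracy(frame.loc[mask, "set_size"].to_numpy(),
                                   threshold50=th, shape=traj.shape)
        return probs
    traj = model
    trial_col = "trial_overall" if timescale == "overall_1_120" else "trial_in_block"
    th = threshold_at_trial(frame[trial_col].to_numpy(), traj)
    return np.asarray(accuracy(frame["set_size"].to_numpy(), threshold50=th,
                               shape=traj.shape))


def simulate_responses(design: list[DesignTrial],
                       model: LearningTrajectory | BlockSchedule,
                       seed: int,
                       timescale: str = "overall_1_120") -> pd.DataFrame:
    """Draw per-item Bernoulli outcomes for a session design.

    Returns the disaggregated item table (one row per presented item) with a
    0/1 ``correct`` column.
    """
    frame = _design_frame(design)
    rng = participant_rng(seed, design[0].participant_id + "/responses")
    p = _item_probabilities(frame, model, timescale)
    frame["correct"] = (rng.random(len(frame)) < p).astype(int)
    return frame


def chance_responder(design: list[DesignTrial], seed: int) -> pd.DataFrame:
    """Item table in which every response is correct with probability 1/6."""
    frame = _design_frame(design)
    rng = participant_rng(seed, design[0].participant_id + "/chance")
    frame["correct"] = (rng.random(len(frame)) < GUESS_RATE).astype(int)
    return frame


def _perturbed(traj: LearningTrajectory, dev: np.ndarray) -> LearningTrajectory:
    return LearningTrajectory(
        log_start_threshold=traj.log_start_threshold + dev[0],
        log_half_time=traj.log_half_time + dev[1],
        log_asym_threshold=traj.log_asym_threshold + dev[2],
        shape=traj.shape,
    )


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(items, truth)``: the disaggregated item table for all
    participants, and a per-participant table of the generating parameters
    (for recovery testing).  Fully reproducible from ``config.seed``.
    """
    sds = np.asarray(config.random_effect_sds)
    item_frames = []
    truth_rows = []
    for cond in sorted(config.conditions):
        spec = config.conditions[cond]
        for j in range(spec.n_participants):
            pid = f"{cond}_{j + 1:03d}"
            rng = participant_rng(config.seed, pid + "/effects")
            dev = rng.normal(0.0, 1.0, size=3) * sds
            traj = _perturbed(spec.trajectory, dev)
            if spec.schedule is not None:
                model: LearningTrajectory | BlockSchedule = BlockSchedule(
                    reference_values=traj,
                    total_delta=spec.schedule.total_delta,
                    interior_weights=spec.schedule.interior_weights,
                )
            else:
                model = traj
            design = generate_design(cond, pid, config.seed)
            item_frames.append(simulate_responses(design, model, config.seed,
                                                  timescale=config.timescale))
            truth_rows.append({
                "participant_id": pid,
                "condition": cond,
                "log_start_threshold": traj.log_start_threshold,
                "log_half_time": traj.log_half_time,
                "log_asym_threshold": traj.log_asym_threshold,
                "shape": traj.shape,
            })
    items = pd.concat(item_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return items, truth


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Five-condition cohort with the study's sample sizes (31/31/30/30/29).

    Learnable-mapping conditions improve (asymptote above start); the random
    condition is flat; dual-task conditions start lower.
    """
    shape = 3.0

    def traj(start, asym, half):
        return LearningTrajectory(
            log_start_threshold=float(np.log(start)),
            log_asym_threshold=float(np.log(asym)),
            log_half_time=float(np.log(half)),
            shape=shape,
        )

    conditions = {
        "constant": ConditionSpec(31, traj(3.0, 4.5, 25.0)),
        "constant_search": ConditionSpec(31, traj(2.4, 4.3, 25.0)),
        "random": ConditionSpec(30, traj(3.0, 3.0, 25.0)),
        "blocked": ConditionSpec(30, traj(3.0, 4.2, 30.0)),
        "blocked_search": ConditionSpec(29, traj(2.4, 3.4, 30.0)),
    }
    return CohortConfig(conditions=conditions, seed=seed)
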