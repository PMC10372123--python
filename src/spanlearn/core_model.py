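"""Closed-form core of the span-task learning model.

Accuracy of a single item response is described by a Weibull (Quick)
psychometric function of memory set size, anchored so that accuracy is 1
at set size 0, decays to the 6-alternative guessing floor of 1/6 for very
large set sizes, and equals exactly 0.5 at the threshold parameter.  The
threshold evolves over trials as a saturating exponential (start value,
asymptote, and a half-time expressed in trials), optionally rescheduled
across blocks by a monotone per-block offset.

All functions are pure and vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GUESS_RATE",
    "DECAY_BASE",
    "PsychometricParams",
    "LearningTrajectory",
    "BlockSchedule",
    "accuracy",
    "threshold_at_trial",
    "block_value",
    "block_weights",
    "capacity",
    "loglik",
    "bernoulli_loglik",
    "clamp_probability",
]

#: Probability of a correct response by guessing among six alternatives.
GUESS_RATE = 1.0 / 6.0

#: Base of the Weibull decay term.  The value (0.5 - 1/6) / (1 - 1/6) = 0.4
#: is the unique choice for which accuracy passes through exactly 0.5 at the
#: threshold parameter given the 1/6 guessing floor.
DECAY_BASE = (0.5 - GUESS_RATE) / (1.0 - GUESS_RATE)

#: Probabilities entering Bernoulli log-likelihoods are clamped to this range
#: so the log-likelihood and its gradient stay finite.
PROB_CLAMP = 1e-9


@dataclass(frozen=True)
class PsychometricParams:
    """Static Weibull accuracy function of set size.

    Parameters
    ----------
    threshold50
        Set size at which item accuracy equals 0.5.  Must be positive.
    shape
        Dimensionless steepness of the psychometric function.  Must be
        positive.
    """

    threshold50: float
    shape: float

    #: Guessing floor; fixed by the six-alternative response design.
    guess_rate: float = field(default=GUESS_RATE, init=False)
    #: Accuracy at set size zero; fixed at 1.
    ceiling: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold50) or self.threshold50 <= 0:
            raise ValueError(f"threshold50 must be positive, got {self.threshold50}")
        if not np.isfinite(self.shape) or self.shape <= 0:
            raise ValueError(f"shape must be positive, got {self.shape}")

    @property
    def capacity(self) -> float:
        return capacity(self.threshold50)


@dataclass(frozen=True)
class LearningTrajectory:
    """Exponential time course of the 50% threshold.

    All three trajectory parameters live on the log scale; the threshold at
    trial ``t`` is::

        asym + (start - asym) * 2 ** (-(t - 1) / half_time)

    so the value at trial 1 is exactly ``exp(log_start_threshold)``, the
    limit is ``exp(log_asym_threshold)``, and at trial ``1 + half_time`` the
    threshold sits exactly midway between the two.
    """

    log_start_threshold: float
    log_asym_threshold: float
    log_half_time: float
    shape: float

    def __post_init__(self) -> None:
        for name in ("log_start_threshold", "log_asym_threshold", "log_half_time"):
            v = getattr(self, name)
            if not np.isfinite(v) or not np.isfinite(np.exp(v)):
                raise ValueError(f"{name} must give a finite positive value, got {v}")
        if not np.isfinite(self.shape) or self.shape <= 0:
            raise ValueError(f"shape must be positive, got {self.shape}")

    @property
    def start_threshold(self) -> float:
        return float(np.exp(self.log_start_threshold))

    @property
    def asym_threshold(self) -> float:
        return float(np.exp(self.log_asym_threshold))

    @property
    def half_time(self) -> float:
        return float(np.exp(self.log_half_time))

    def params_at_trial(self, trial) -> PsychometricParams:
        th = threshold_at_trial(trial, self)
        return PsychometricParams(threshold50=float(th), shape=self.shape)


@dataclass(frozen=True)
class BlockSchedule:
    """Monotone per-block offsets applied to a reference trajectory.

    Block 4 is the reference; block 1 equals reference plus ``total_delta``.
    Blocks 2 and 3 are placed between the endpoints by ordered interior
    weights ``1 >= w2 >= w3 >= 0`` so each log-scale parameter is monotone
    (in either direction) across blocks 1 -> 4.

    ``total_delta`` and ``interior_weights`` are indexed by trajectory
    parameter in the order (log_start, log_half_time, log_asym).
    """

    reference_values: LearningTrajectory
    total_delta: tuple[float, float, float]
    interior_weights: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.total_delta) != 3:
            raise ValueError("total_delta must have 3 entries")
        if len(self.interior_weights) != 3:
            raise ValueError("interior_weights must have one (w2, w3) pair per parameter")
        for w2, w3 in self.interior_weights:
            if not (1.0 >= w2 >= w3 >= 0.0):
                raise ValueError(
                    f"interior weights must satisfy 1 >= w2 >= w3 >= 0, got ({w2}, {w3})"
                )

    def trajectory_for_block(self, block: int) -> LearningTrajectory:
        ref = self.reference_values
        vals = [
            block_value(block, self, k)
            for k in range(3)
        ]
        return LearningTrajectory(
            log_start_threshold=vals[0],
            log_half_time=vals[1],
            log_asym_threshold=vals[2],
            shape=ref.shape,
        )


def block_weights(w2: float, w3: float) -> np.ndarray:
    """Weight of ``total_delta`` for blocks 1..4: (1, w2, w3, 0)."""
    if not (1.0 >= w2 >= w3 >= 0.0):
        raise ValueError(f"interior weights must satisfy 1 >= w2 >= w3 >= 0, got ({w2}, {w3})")
    return np.array([1.0, w2, w3, 0.0])


def block_value(block, schedule: BlockSchedule, param_index: int) -> float:
    """Log-scale trajectory parameter value for one block.

    ``param_index`` is 0, 1, 2 for (log_start, log_half_time, log_asym).
    """
    block = np.asarray(block)
    if np.any((block < 1) | (block > 4) | (block != np.floor(block))):
        raise ValueError(f"block must be an integer in 1..4, got {block}")
    if param_index not in (0, 1, 2):
        raise ValueError(f"param_index must be 0, 1 or 2, got {param_index}")
    ref = (
        schedule.reference_values.log_start_threshold,
        schedule.reference_values.log_half_time,
        schedule.reference_values.log_asym_threshold,
    )[param_index]
    w2, w3 = schedule.interior_weights[param_index]
    weights = block_weights(w2, w3)
    out = ref + schedule.total_delta[param_index] * weights[block.astype(int) - 1]
    return float(out) if np.isscalar(block) or block.ndim == 0 else out


def accuracy(set_size, params: PsychometricParams | None = None, *,
             threshold50=None, shape=None):
    """Probability of a correct item response at a given set size.

    ``p(s) = 1/6 + (5/6) * 0.4 ** ((s / threshold50) ** shape)``

    Accepts either a :class:`PsychometricParams` or explicit keyword
    arrays, and broadcasts over all inputs.
    """
    if params is not None:
        threshold50 = params.threshold50
        shape = params.shape
    set_size = np.asarray(set_size, dtype=float)
    threshold50 = np.asarray(threshold50, dtype=float)
    shape = np.asarray(shape, dtype=float)
    if np.any(set_size < 0):
        raise ValueError("set_size must be non-negative")
    if np.any(threshold50 <= 0) or np.any(shape <= 0):
        raise ValueError("threshold50 and shape must be positive")
    u = (set_size / threshold50) ** shape
    p = GUESS_RATE + (1.0 - GUESS_RATE) * DECAY_BASE ** u
    return p if p.ndim else float(p)


def threshold_at_trial(trial, traj: LearningTrajectory):
    """Threshold at a 1-based trial index under an exponential trajectory."""
    trial = np.asarray(trial, dtype=float)
    if np.any(trial < 1):
        raise ValueError("trial must be >= 1")
    start = np.exp(traj.log_start_threshold)
    asym = np.exp(traj.log_asym_threshold)
    half = np.exp(traj.log_half_time)
    th = asym + (start - asym) * 2.0 ** (-(trial - 1.0) / half)
    return th if th.ndim else float(th)


def capacity(threshold50):
    """Heuristic item capacity: the 50% threshold divided by two."""
    threshold50 = np.asarray(threshold50, dtype=float)
    if np.any(threshold50 <= 0):
        raise ValueError("threshold50 must be positive")
    out = threshold50 / 2.0
    return out if out.ndim else float(out)


def clamp_probability(p):
    """Clamp probabilities into [1e-9, 1 - 1e-9] for finite log-likelihoods."""
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


def bernoulli_loglik(correct, p):
    """Sum of Bernoulli log-likelihood terms with the numeric clamp applied."""
    correct = np.asarray(correct, dtype=float)
    p = clamp_probability(np.asarray(p, dtype=float))
    return float(np.sum(correct * np.log(p) + (1.0 - correct) * np.log1p(-p)))


def loglik(set_size, correct, threshold50, shape):
    """Disaggregated Bernoulli log-likelihood.

    One term per presented item: ``set_size``, ``correct`` (0/1),
    ``threshold50`` and ``shape`` are aligned, broadcastable arrays giving
    each item's set size, outcome, and the psychometric parameters resolved
    at that item's trial.
    """
    set_size = np.asarray(set_size, dtype=float)
    if np.any(set_size < 1):
        raise ValueError("every item's set size must be >= 1")
    p = accuracy(set_size, threshold50=threshold50, shape=shape)
    p = np.broadcast_to(np.asarray(p, dtype=float), np.broadcast_shapes(
        np.shape(p), np.shape(np.asarray(correct))))
    return bernoulli_loglik(correct, p)
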