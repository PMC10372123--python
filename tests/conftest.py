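import numpy as np
import pytest

from spanlearn.core_model import BlockSchedule, LearningTrajectory
from spanlearn.synthetic_data import CohortConfig, ConditionSpec, generate_cohort


def make_trajectory(start=3.0, asym=4.5, half=25.0, shape=3.0) -> LearningTrajectory:
    return LearningTrajectory(
        log_start_threshold=float(np.log(start)),
        log_asym_threshold=float(np.log(asym)),
        log_half_time=float(np.log(half)),
        shape=shape,
    )


def make_two_condition_config(n_per=6, seed=0, asym_offset=0.4,
                              sds=(0.2, 0.3, 0.2)) -> CohortConfig:
    """Constant condition learns; random condition's asymptote is offset."""
    base = make_trajectory()
    shifted = LearningTrajectory(
        log_start_threshold=base.log_start_threshold,
        log_asym_threshold=base.log_asym_threshold - asym_offset,
        log_half_time=base.log_half_time,
        shape=base.shape,
    )
    return CohortConfig(
        conditions={
            "constant": ConditionSpec(n_per, base),
            "random": ConditionSpec(n_per, shifted),
        },
        random_effect_sds=sds,
        seed=seed,
    )


def make_moderate_effects_config(n_per=6, seed=11) -> CohortConfig:
    """Two learning conditions with moderate offsets and sizeable random
    effects; the standard cohort for full-MCMC convergence checks."""
    return CohortConfig(
        conditions={
            "constant": ConditionSpec(n_per, make_trajectory(3.0, 4.5, 20.0)),
            "random": ConditionSpec(n_per, make_trajectory(2.8, 3.6, 30.0)),
        },
        random_effect_sds=(0.35, 0.5, 0.35),
        seed=seed,
    )


def make_rate_only_schedule(rate_delta=1.6) -> BlockSchedule:
    """Within-block trajectories whose half-time shrinks across blocks."""
    ref = make_trajectory(start=3.0, asym=4.2, half=6.0)
    return BlockSchedule(
        reference_values=ref,
        total_delta=(0.0, rate_delta, 0.0),
        interior_weights=((1.0, 0.0), (0.7, 0.35), (1.0, 0.0)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, 2 conditions, E1-style learning data."""
    cfg = make_two_condition_config(n_per=6, seed=11)
    items, truth = generate_cohort(cfg)
    return cfg, items, truth
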