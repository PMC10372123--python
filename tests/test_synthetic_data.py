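import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spanlearn.core_model import GUESS_RATE, accuracy, PsychometricParams
from spanlearn.synthetic_data import (
    CONDITIONS,
    CohortConfig,
    ConditionSpec,
    ROTATION_SPACING_DEG,
    canonical_mapping,
    chance_responder,
    default_cohort_config,
    generate_cohort,
    generate_design,
    simulate_responses,
)
from tests.conftest import make_trajectory, make_two_condition_config


class TestDesign:
    @pytest.mark.parametrize("condition", CONDITIONS)
    def test_session_has_120_trials(self, condition):
        design = generate_design(condition, "p01", seed=3)
        assert len(design) == 120
        blocks = pd.Series([t.block for t in design]).value_counts()
        assert all(blocks[b] == 30 for b in (1, 2, 3, 4))

    def test_opening_set_sizes_ascend(self):
        design = generate_design("constant", "p01", seed=5)
        for block in (1, 2, 3, 4):
            first5 = [t.set_size for t in design
                      if t.block == block and t.trial_in_block <= 5]
            assert first5 == [2, 3, 4, 5, 6]

    def test_balanced_set_sizes_per_block(self):
        design = generate_design("random", "p02", seed=7)
        for block in (1, 2, 3, 4):
            sizes = pd.Series([t.set_size for t in design if t.block == block])
            assert sizes.value_counts().to_dict() == {s: 6 for s in (2, 3, 4, 5, 6)}

    def test_trial_index_arithmetic(self):
        design = generate_design("blocked", "p03", seed=9)
        for t in design:
            assert t.trial_overall == 30 * (t.block - 1) + t.trial_in_block

    def test_rotations_28_apart_and_disjoint_within_family(self):
        design = generate_design("constant", "p04", seed=11)
        by_block = {}
        for t in design:
            by_block.setdefault(t.block, (t.shape_family, set(t.mapping)))
        fams = {}
        for block, (fam, rots) in by_block.items():
            angles = np.sort(np.array(sorted(rots)))
            gaps = np.diff(angles) % 360.0
            # six angles on a circle, consecutive spacing 28 degrees
            assert np.allclose(np.sort(gaps)[:5], ROTATION_SPACING_DEG) or \
                np.allclose(gaps, ROTATION_SPACING_DEG)
            fams.setdefault(fam, []).append(rots)
        for fam, sets in fams.items():
            assert len(sets) == 2
            assert sets[0].isdisjoint(sets[1])

    def test_shape_families_alternate(self):
        design = generate_design("constant", "p05", seed=13)
        fams = [next(t.shape_family for t in design if t.block == b)
                for b in (1, 2, 3, 4)]
        assert fams[0] == fams[2] != fams[1] == fams[3]

    def test_mapping_is_bijection(self):
        design = generate_design("random", "p06", seed=15)
        for t in design:
            assert sorted(t.mapping.values()) == [1, 2, 3, 4, 5, 6]

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            generate_design("bogus", "p01", seed=1)


class TestMappings:
    def test_constant_condition_identical_mappings(self):
        design = generate_design("constant", "p07", seed=17)
        for block in (1, 2, 3, 4):
            maps = [t.mapping for t in design if t.block == block]
            assert all(m == maps[0] for m in maps)

    def test_constant_mapping_is_canonical(self):
        design = generate_design("constant", "p07", seed=17)
        t0 = design[0]
        assert t0.mapping == canonical_mapping(t0.mapping.keys())
        # most-counterclockwise stimulus -> left hand's middle button (2)
        assert t0.mapping[min(t0.mapping)] == 2
        # most-clockwise stimulus -> right hand's left button (4)
        assert t0.mapping[max(t0.mapping)] == 4

    def test_blocked_condition_fixed_within_block(self):
        design = generate_design("blocked", "p08", seed=19)
        per_block = {}
        for t in design:
            per_block.setdefault(t.block, []).append(tuple(sorted(t.mapping.items())))
        for block, maps in per_block.items():
            assert len(set(maps)) == 1

    def test_blocked_condition_varies_across_blocks_and_participants(self):
        hits = 0
        for pid in [f"q{i}" for i in range(8)]:
            design = generate_design("blocked", pid, seed=21)
            maps = {b: next(tuple(t.mapping[k] for k in sorted(t.mapping))
                            for t in design if t.block == b) for b in (1, 2, 3, 4)}
            if len(set(maps.values())) > 1:
                hits += 1
        assert hits >= 6  # collisions have probability 1/720 per pair

    def test_random_condition_collision_rate(self):
        # expected identical-mapping trial pairs ~ C(120,2)/720; pool seeds
        # and check the count against binomial 99% bounds
        total_pairs = 0
        collisions = 0
        for pid in [f"r{i}" for i in range(30)]:
            design = generate_design("random", pid, seed=23)
            sigs = [tuple(t.mapping[k] for k in sorted(t.mapping)) for t in design]
            n = len(sigs)
            total_pairs += n * (n - 1) // 2
            from collections import Counter
            for c in Counter(sigs).values():
                collisions += c * (c - 1) // 2
        pexp = 1.0 / 720.0
        lo, hi = stats.binom.interval(0.99, total_pairs, pexp)
        assert lo <= collisions <= hi


class TestResponses:
    def test_flat_trajectory_no_trend(self):
        traj = make_trajectory(start=4.0, asym=4.0, half=20.0)
        frames = [simulate_responses(generate_design("constant", f"s{i}", 2), traj, 2)
                  for i in range(20)]
        items = pd.concat(frames)
        # logistic regression of correctness on trial: slope ~ 0
        from statsmodels.api import GLM, add_constant, families
        model = GLM(items["correct"].to_numpy(),
                    add_constant(items["trial_overall"].to_numpy() / 120.0),
                    family=families.Binomial()).fit()
        assert abs(model.params[1]) < 3.0 * model.bse[1] + 0.05

    def test_threshold_four_gives_half_accuracy_at_set_size_four(self):
        traj = make_trajectory(start=4.0, asym=4.0, half=20.0)
        frames = [simulate_responses(generate_design("constant", f"t{i}", 4), traj, 4)
                  for i in range(30)]
        items = pd.concat(frames)
        four = items[items["set_size"] == 4]
        phat = four["correct"].mean()
        se = np.sqrt(0.25 / len(four))
        assert abs(phat - 0.5) < 4 * se

    def test_monte_carlo_matches_closed_form(self):
        traj = make_trajectory(start=3.0, asym=3.0, half=20.0, shape=2.5)
        frames = [simulate_responses(generate_design("random", f"u{i}", 6), traj, 6)
                  for i in range(30)]
        items = pd.concat(frames)
        for s in (2, 4, 6):
            sub = items[items["set_size"] == s]
            p_true = accuracy(float(s), PsychometricParams(3.0, 2.5))
            se = np.sqrt(p_true * (1 - p_true) / len(sub))
            assert abs(sub["correct"].mean() - p_true) < 4 * se


class TestCohort:
    def test_default_config_has_study_sample_sizes(self):
        cfg = default_cohort_config(seed=1)
        sizes = {c: s.n_participants for c, s in cfg.conditions.items()}
        assert sizes == {"constant": 31, "constant_search": 31, "random": 30,
                         "blocked": 30, "blocked_search": 29}
        assert sum(sizes.values()) == 151

    def test_zero_sds_share_parameters(self):
        cfg = make_two_condition_config(n_per=3, seed=5, sds=(0.0, 0.0, 0.0))
        _, truth = generate_cohort(cfg)
        for _, grp in truth.groupby("condition"):
            assert grp["log_asym_threshold"].nunique() == 1
            assert grp["log_start_threshold"].nunique() == 1

    def test_same_seed_identical_tables(self):
        cfg = make_two_condition_config(n_per=3, seed=9)
        items1, truth1 = generate_cohort(cfg)
        items2, truth2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(items1, items2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self):
        a, _ = generate_cohort(make_two_condition_config(n_per=2, seed=1))
        b, _ = generate_cohort(make_two_condition_config(n_per=2, seed=2))
        assert not a["correct"].equals(b["correct"])

    def test_items_per_trial_equals_set_size(self):
        items, _ = generate_cohort(make_two_condition_config(n_per=2, seed=3))
        counts = items.groupby(["participant_id", "trial_overall"]).agg(
            n=("item_position", "size"), ss=("set_size", "first"))
        assert (counts["n"] == counts["ss"]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(conditions={"nope": ConditionSpec(3, make_trajectory())})
        with pytest.raises(ValueError):
            CohortConfig(
                conditions={"constant": ConditionSpec(0, make_trajectory())})


class TestChanceResponder:
    def test_mean_accuracy_near_one_sixth(self):
        frames = [chance_responder(generate_design("random", f"c{i}", 31), 31)
                  for i in range(10)]
        items = pd.concat(frames)
        phat = items["correct"].mean()
        se = np.sqrt(GUESS_RATE * (1 - GUESS_RATE) / len(items))
        assert abs(phat - GUESS_RATE) < 4 * se

    def test_accuracy_independent_of_set_size(self):
        frames = [chance_responder(generate_design("random", f"d{i}", 37), 37)
                  for i in range(20)]
        items = pd.concat(frames)
        table = pd.crosstab(items["set_size"], items["correct"])
        _, pval, *_ = stats.chi2_contingency(table)
        assert pval > 0.001
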