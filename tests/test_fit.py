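import numpy as np
import pandas as pd
import pytest

from spanlearn.fit import (
    ModelSpec,
    PosteriorDraws,
    apply_exclusion,
    diagnostics,
    fit_learning_model,
    fit_static,
    fit_static_table,
)
from spanlearn.hierarchical import HierarchicalModel
from spanlearn.synthetic_data import (
    chance_responder,
    generate_design,
    simulate_responses,
)
from tests.conftest import make_trajectory, make_two_condition_config
from spanlearn.synthetic_data import generate_cohort


def _static_items(threshold, shape, n_sessions, seed=0, condition="constant"):
    traj = make_trajectory(start=threshold, asym=threshold, half=10.0, shape=shape)
    frames = [simulate_responses(generate_design(condition, f"p{i}", seed), traj, seed)
              for i in range(n_sessions)]
    items = pd.concat(frames, ignore_index=True)
    items["participant_id"] = "pooled"
    return items


class TestStaticFit:
    def test_parameter_recovery_large_n(self):
        # ~25 sessions x ~480 items ~ 1.2e4 items at a flat threshold of 4
        items = _static_items(4.0, 3.0, 25, seed=1)
        res = fit_static(items)
        assert res.threshold50 == pytest.approx(4.0, abs=0.1)
        assert not res.excluded

    def test_chance_responder_is_excluded(self):
        design = generate_design("random", "guesser", seed=2)
        items = chance_responder(design, seed=2)
        res = fit_static(items)
        assert res.capacity < 1.0
        assert res.excluded

    def test_all_correct_hits_upper_bound(self):
        design = generate_design("constant", "ace", seed=3)
        items = simulate_responses(design, make_trajectory(), seed=3)
        items["correct"] = 1
        res = fit_static(items)
        assert res.threshold50 == pytest.approx(50.0, rel=1e-3)
        assert not res.excluded

    def test_multiple_participants_rejected(self):
        items, _ = generate_cohort(make_two_condition_config(n_per=2, seed=4))
        with pytest.raises(ValueError):
            fit_static(items)


class TestExclusion:
    def test_well_performing_cohort_retained(self):
        # tight random effects keep every generated threshold well above 2
        items, _ = generate_cohort(make_two_condition_config(
            n_per=3, seed=5, sds=(0.05, 0.1, 0.05)))
        table = fit_static_table(items)
        retained, report = apply_exclusion(table)
        assert report["n_excluded"] == 0
        assert report["n_retained"] == 6

    def test_chance_responders_counted_per_condition(self):
        items, _ = generate_cohort(make_two_condition_config(n_per=2, seed=6))
        guessers = []
        for i in range(3):
            d = generate_design("random", f"guess_{i}", seed=60 + i)
            g = chance_responder(d, seed=60 + i)
            guessers.append(g)
        combined = pd.concat([items] + guessers, ignore_index=True)
        table = fit_static_table(combined)
        retained, report = apply_exclusion(table)
        assert report["n_excluded"] == 3
        assert report["excluded_by_condition"] == {"random": 3}
        assert set(retained["participant_id"]) == set(items["participant_id"])

    def test_boundary_capacity_retained(self):
        table = pd.DataFrame([
            {"participant_id": "a", "condition": "constant", "threshold50": 2.0,
             "shape": 3.0, "capacity": 1.0, "loglik": -1.0, "converged": True,
             "excluded": False},
            {"participant_id": "b", "condition": "constant", "threshold50": 1.9,
             "shape": 3.0, "capacity": 0.95, "loglik": -1.0, "converged": True,
             "excluded": True},
        ])
        retained, report = apply_exclusion(table)
        assert list(retained["participant_id"]) == ["a"]
        assert report["n_excluded"] == 1

    def test_duplicate_participant_rejected(self):
        table = pd.DataFrame([
            {"participant_id": "a", "condition": "constant", "excluded": False},
            {"participant_id": "a", "condition": "constant", "excluded": False},
        ])
        with pytest.raises(ValueError):
            apply_exclusion(table)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((1, 500, 2))
        theta = np.repeat(draws, 4, axis=0)
        rhat, ess, _ = diagnostics(theta, ["a", "b"])
        assert rhat["a"] == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            diagnostics(np.zeros((1, 100, 2)), ["a", "b"])

    def test_two_iteration_run_not_converged(self, small_cohort):
        _, items, _ = small_cohort
        post = fit_learning_model(items, ModelSpec(reference_condition="constant"),
                                  method="nuts", chains=2, warmup=10, draws=2, seed=0)
        assert not post.converged

    def test_disjoint_chains_flagged(self):
        theta = np.zeros((2, 400, 1))
        theta[0, :, 0] = np.random.default_rng(1).standard_normal(400)
        theta[1, :, 0] = 50.0 + np.random.default_rng(2).standard_normal(400)
        rhat, _, converged = diagnostics(theta, ["a"])
        assert rhat["a"] > 1.5
        assert not converged


class TestLearningModel:
    def test_logp_equals_loglik_plus_prior(self, small_cohort):
        # identity between the sampler's target and the core likelihood
        _, items, _ = small_cohort
        model = HierarchicalModel(items, ModelSpec(reference_condition="constant"))
        rng = np.random.default_rng(7)
        for _ in range(20):
            theta = model.initial_point(rng, jitter=0.4)
            lp, _ = model.logp_and_grad(theta)
            assert lp == pytest.approx(model.loglik(theta) + model.log_prior(theta),
                                       rel=1e-10)

    def test_item_loglik_matches_core_model(self, small_cohort):
        from spanlearn import core_model
        _, items, _ = small_cohort
        spec = ModelSpec(reference_condition="constant")
        model = HierarchicalModel(items, spec)
        theta = model.initial_point()
        total = model.loglik(theta)
        # reconstruct per-item parameters independently and use core loglik
        b = theta[:4]
        traj = make_trajectory()
        th = core_model.threshold_at_trial(
            items["trial_overall"].to_numpy(),
            make_trajectory(start=np.exp(b[0]), asym=np.exp(b[2]),
                            half=np.exp(b[1]), shape=np.exp(b[3])))
        expected = core_model.loglik(items["set_size"].to_numpy(),
                                     items["correct"].to_numpy(), th, np.exp(b[3]))
        assert total == pytest.approx(expected, rel=1e-9)

    def test_laplace_recovers_asym_offset(self):
        cfg = make_two_condition_config(n_per=8, seed=21, asym_offset=0.5,
                                        sds=(0.15, 0.2, 0.15))
        items, _ = generate_cohort(cfg)
        post = fit_learning_model(items, ModelSpec(reference_condition="constant"),
                                  method="laplace", chains=4, draws=500, seed=3)
        est = float(np.median(post.stacked("d_asym__random")))
        assert est == pytest.approx(-0.5, abs=0.3)

    def test_reduced_spec_has_no_extra_block_terms(self):
        from tests.conftest import make_rate_only_schedule
        from spanlearn.synthetic_data import CohortConfig, ConditionSpec
        sched = make_rate_only_schedule()
        cfg = CohortConfig(
            conditions={"blocked": ConditionSpec(3, sched.reference_values,
                                                 schedule=sched)},
            random_effect_sds=(0.1, 0.1, 0.1), seed=8,
            timescale="within_block_1_30")
        items, _ = generate_cohort(cfg)
        spec = ModelSpec(timescale="within_block_1_30", cross_block="rate_only",
                         reference_condition="blocked")
        post = fit_learning_model(items, spec, method="laplace", chains=2,
                                  draws=50, seed=4)
        names = post.param_names
        assert any(n.startswith("blk_rate__") for n in names)
        assert not any(n.startswith("blk_start__") for n in names)
        assert not any(n.startswith("blk_asym__") for n in names)

    def test_posterior_sd_shrinks_with_more_data(self):
        small = make_two_condition_config(n_per=3, seed=31)
        big = make_two_condition_config(n_per=12, seed=31)
        sds = []
        for cfg in (small, big):
            items, _ = generate_cohort(cfg)
            post = fit_learning_model(items, ModelSpec(reference_condition="constant"),
                                      method="laplace", chains=2, draws=400, seed=5)
            sds.append(float(post.stacked("d_asym__random").std()))
        assert sds[1] < sds[0]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(timescale="overall_1_120", cross_block="full")
        with pytest.raises(ValueError):
            ModelSpec(timescale="nope")

    def test_reference_condition_must_exist(self, small_cohort):
        _, items, _ = small_cohort
        with pytest.raises(ValueError):
            HierarchicalModel(items, ModelSpec(reference_condition="blocked"))


class TestPosteriorDrawsRoundtrip:
    def test_save_load(self, tmp_path, small_cohort):
        _, items, _ = small_cohort
        post = fit_learning_model(items, ModelSpec(reference_condition="constant"),
                                  method="laplace", chains=2, draws=40, seed=6)
        post.save(tmp_path / "draws.csv", tmp_path / "meta.json")
        back = PosteriorDraws.load(tmp_path / "draws.csv", tmp_path / "meta.json")
        np.testing.assert_allclose(back.theta, post.theta)
        assert back.param_names == post.param_names
        assert back.spec == post.spec
        assert back.data_fingerprint == post.data_fingerprint

    def test_unknown_parameter_error_lists_names(self, small_cohort):
        _, items, _ = small_cohort
        post = fit_learning_model(items, ModelSpec(reference_condition="constant"),
                                  method="laplace", chains=2, draws=20, seed=6)
        with pytest.raises(KeyError, match="b_start"):
            post.stacked("nonexistent")
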