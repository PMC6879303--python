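import math

import numpy as np
import pytest

import choicekit as ck
from choicekit.models import get_model

from conftest import make_dataset


class TestStayProbability:
    def test_alternating_choices_never_stay(self):
        ds = make_dataset([0, 1, 0, 1, 0, 1], [1, 0, 1, 0, 1, 0])
        stay = ck.stay_probability(ds)
        assert stay["stay_given_reward"] == 0.0
        assert stay["stay_given_no_reward"] == 0.0

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError):
            ck.stay_probability(make_dataset([0], [1]))

    def test_empty_cell_is_flagged_nan(self):
        ds = make_dataset([0, 0, 0], [1, 1, 1])  # never unrewarded
        stay = ck.stay_probability(ds)
        assert math.isnan(stay["stay_given_no_reward"])
        assert "stay_given_no_reward" in stay["undefined"]

    def test_block_boundaries_excluded(self):
        # the only stay event crosses a block boundary and must not count
        ds = make_dataset([0, 1, 1, 0], [1, 1, 1, 1],
                          blocks=[0, 0, 1, 1])
        stay = ck.stay_probability(ds)
        assert stay["n_stay_given_reward"] == 2

    def test_random_responder_shows_no_reward_dependence(self, bandit_task):
        ds = get_model("M1").simulate({"b": 0.5}, bandit_task, 31)
        stay = ck.stay_probability(ds)
        assert abs(stay["stay_given_reward"] - stay["stay_given_no_reward"]) < 0.1

    def test_wsls_matches_analytic_values(self, bandit_task):
        ds = get_model("M2").simulate({"epsilon": 0.05}, bandit_task, 77)
        stay = ck.stay_probability(ds)
        for key, expected in (("stay_given_reward", 0.975),
                              ("stay_given_no_reward", 0.025)):
            n = stay[f"n_{key}"]
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(stay[key] - expected) < 3 * se


class TestPerformanceCurves:
    def test_chance_level_for_random_responder(self, bandit_task, rng):
        sims = [get_model("M1").simulate({"b": 0.5}, bandit_task, rng)
                for _ in range(30)]
        perf = ck.performance_curves(sims, bandit_task)
        assert abs(perf["perf_early"] - 0.5) < 0.1
        assert abs(perf["perf_late"] - 0.5) < 0.1

    def test_learning_curve_rises_for_learner(self, bandit_task, rng):
        sims = [get_model("M3").simulate({"alpha": 0.1, "beta": 5.0},
                                         bandit_task, rng)
                for _ in range(30)]
        perf = ck.performance_curves(sims, bandit_task)
        assert perf["perf_late"] > perf["perf_early"] + 0.2

    def test_early_performance_nonmonotone_in_alpha_at_high_beta(self, bandit_task, rng):
        # at high inverse temperature the learning-rate / early-performance
        # relation is non-monotone: an interior learning rate beats both a
        # very small and the maximal one
        early = {}
        for alpha in (0.02, 0.6, 1.0):
            sims = [get_model("M3").simulate({"alpha": alpha, "beta": 20.0},
                                             bandit_task, rng)
                    for _ in range(400)]
            early[alpha] = ck.performance_curves(sims, bandit_task)["perf_early"]
        assert early[0.6] > early[0.02]
        assert early[0.6] > early[1.0]

    def test_blind_agent_caps_at_two_thirds(self, rng):
        task = ck.StimulusTaskConfig(n_trials=300)
        sims = [get_model("blind-RL").simulate({"alpha": 0.3, "beta": 8.0},
                                               task, rng)
                for _ in range(40)]
        perf = ck.performance_curves(sims, task)
        assert abs(perf["perf_late"] - 2 / 3) < 0.08

    def test_tied_arms_rejected(self, rng):
        task = ck.make_bandit_task(2, 20, [0.5, 0.5])
        ds = get_model("M1").simulate({"b": 0.5}, task, rng)
        with pytest.raises(ValueError):
            ck.performance_curves(ds, task)


class TestTrialLikelihoods:
    def test_uniform_model_gives_half(self, short_bandit):
        ds = get_model("M3").simulate({"alpha": 0.2, "beta": 3.0}, short_bandit, 3)
        atl = ck.average_trial_likelihood({"alpha": 0.2, "beta": 0.0}, "M3", ds)
        assert atl == pytest.approx(0.5, abs=1e-12)

    def test_perfect_predictor_reaches_one(self, bandit_task):
        ds = get_model("M1").simulate({"b": 1.0}, bandit_task, 0)
        atl = ck.average_trial_likelihood({"b": 1.0}, "M1", ds)
        assert atl == pytest.approx(1.0)

    def test_geometric_mean_identity(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        ds = get_model("M3").simulate(params, short_bandit, 9)
        nll = ck.negative_log_likelihood(params, "M3", ds)
        atl = ck.average_trial_likelihood(params, "M3", ds)
        assert atl == pytest.approx(math.exp(-nll / ds.n_trials), rel=1e-12)

    def test_arithmetic_mean_exceeds_geometric(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        ds = get_model("M3").simulate(params, short_bandit, 9)
        assert (ck.arithmetic_trial_likelihood(params, "M3", ds)
                >= ck.average_trial_likelihood(params, "M3", ds))


class TestOneStepPredictions:
    def test_product_equals_likelihood(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        ds = get_model("M3").simulate(params, short_bandit, 9)
        probs = ck.one_step_predictions(params, "M3", ds)
        nll = ck.negative_log_likelihood(params, "M3", ds)
        assert -np.log(probs).sum() == pytest.approx(nll, abs=1e-9)

    def test_history_free_model_is_constant(self, short_bandit):
        ds = get_model("M1").simulate({"b": 0.7}, short_bandit, 2)
        probs = ck.one_step_predictions({"b": 0.7}, "M1", ds)
        assert set(np.round(probs, 12)) <= {0.7, 0.3}

    def test_symmetric_first_trial(self, short_bandit):
        ds = get_model("M3").simulate({"alpha": 0.3, "beta": 5.0}, short_bandit, 4)
        probs = ck.one_step_predictions({"alpha": 0.3, "beta": 5.0}, "M3", ds)
        assert probs[0] == pytest.approx(0.5)


class TestPosteriorPredictive:
    def test_self_consistency(self, bandit_task):
        params = {"alpha": 0.15, "beta": 4.0}
        observed = get_model("M3").simulate(params, bandit_task, 41)
        report = ck.posterior_predictive(params, "M3", bandit_task,
                                         n_sims=80, seed=7, observed=observed)
        inside = [report.measure_inside_band(m)
                  for m in ("stay_given_reward", "stay_given_no_reward",
                            "perf_early", "perf_late")]
        assert sum(inside) >= 3

    def test_bit_reproducible(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        observed = get_model("M3").simulate(params, short_bandit, 5)
        a = ck.posterior_predictive(params, "M3", short_bandit, 1, 3, observed)
        b = ck.posterior_predictive(params, "M3", short_bandit, 1, 3, observed)
        assert a.to_json() == b.to_json()


class TestExtractLatents:
    def test_first_trial_prediction_error(self, short_bandit):
        params = {"alpha": 0.1, "beta": 5.0}
        ds = get_model("M3").simulate(params, short_bandit, 6)
        traj = ck.extract_latents(params, "M3", ds)
        c0, r0 = ds.choices[0], ds.rewards[0]
        assert traj.prediction_errors[0] == r0  # Q0 = 0
        assert traj.q_values[1][c0] == pytest.approx(0.1 * r0)

    def test_frozen_learner_has_constant_values(self, short_bandit):
        ds = get_model("M3").simulate({"alpha": 0.3, "beta": 2.0}, short_bandit, 6)
        traj = ck.extract_latents({"alpha": 0.0, "beta": 2.0}, "M3", ds)
        assert np.all(traj.q_values == 0)
        assert np.all(np.abs(traj.prediction_errors) == ds.rewards)

    def test_deterministic_and_rng_independent(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        ds = get_model("M3").simulate(params, short_bandit, 6)
        a = ck.extract_latents(params, "M3", ds)
        np.random.seed(0)
        b = ck.extract_latents(params, "M3", ds)
        assert np.array_equal(a.q_values, b.q_values)
        assert np.array_equal(a.prediction_errors, b.prediction_errors)

    def test_chosen_probabilities_match_one_step(self, short_bandit):
        params = {"alpha": 0.3, "beta": 2.0}
        ds = get_model("M3").simulate(params, short_bandit, 6)
        traj = ck.extract_latents(params, "M3", ds)
        kernel = ck.one_step_predictions(params, "M3", ds)
        assert np.allclose(traj.chosen_probabilities, kernel, atol=1e-12)

    def test_prediction_errors_bounded(self, short_bandit):
        ds = get_model("M5").simulate(
            {"alpha": 0.5, "beta": 2.0, "alpha_c": 0.3, "beta_c": 1.0},
            short_bandit, 10)
        traj = ck.extract_latents(
            {"alpha": 0.5, "beta": 2.0, "alpha_c": 0.3, "beta_c": 1.0},
            "M5", ds)
        assert np.all(traj.prediction_errors >= -1)
        assert np.all(traj.prediction_errors <= 1)
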