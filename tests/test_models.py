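import math

import numpy as np
import pytest

import choicekit as ck
from choicekit.models import get_model

from conftest import make_dataset, sequence_probability_sum

ALL_PARAMS = {
    "M1": {"b": 0.6},
    "M2": {"epsilon": 0.3},
    "M3": {"alpha": 0.3, "beta": 2.0},
    "M4": {"alpha_c": 0.4, "beta_c": 1.5},
    "M5": {"alpha": 0.3, "beta": 2.0, "alpha_c": 0.4, "beta_c": 1.5},
    "M3-bias": {"alpha": 0.3, "beta": 2.0, "bias": 0.7},
}


def fresh_state(model_id, task, **kw):
    return get_model(model_id, **kw).initial_state(task)


class TestInitialState:
    def test_fresh_state_is_zeroed(self, bandit_task):
        state = fresh_state("M3", bandit_task)
        assert np.all(state.q_values == 0)
        assert np.all(state.choice_kernel == 0)
        assert state.last_choice is None and state.last_reward is None

    def test_q0_override(self, bandit_task):
        state = fresh_state("M3-bias", bandit_task, q0=0.5)
        assert np.all(state.q_values == 0.5)

    def test_state_rl_dimensionality(self, stimulus_task):
        state = fresh_state("state-RL", stimulus_task)
        assert state.q_values.shape == (3, 3)

    def test_state_rl_rejects_bandit_task(self, bandit_task):
        with pytest.raises(ck.UnsupportedModelError):
            fresh_state("state-RL", bandit_task)

    @pytest.mark.parametrize("model_id", ["M1", "M2"])
    def test_binary_models_reject_many_arms(self, model_id):
        task = ck.make_bandit_task(3, 10, [0.2, 0.5, 0.8])
        with pytest.raises(ck.UnsupportedModelError):
            fresh_state(model_id, task)


class TestChoiceProbs:
    def test_unbiased_random_responder(self, bandit_task):
        model = get_model("M1")
        p = model.choice_probs({"b": 0.5}, fresh_state("M1", bandit_task))
        assert np.allclose(p, [0.5, 0.5])

    def test_wsls_after_rewarded_choice(self, bandit_task):
        model = get_model("M2")
        state = fresh_state("M2", bandit_task)
        model.update_state({"epsilon": 0.05}, state, choice=1, reward=1)
        p = model.choice_probs({"epsilon": 0.05}, state)
        assert np.allclose(p, [0.025, 0.975])

    def test_wsls_first_trial_uniform(self, bandit_task):
        model = get_model("M2")
        p = model.choice_probs({"epsilon": 0.05}, fresh_state("M2", bandit_task))
        assert np.allclose(p, [0.5, 0.5])

    def test_softmax_closed_form(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        state.q_values[:] = [0.2, 0.8]
        p = model.choice_probs({"alpha": 0.1, "beta": 5.0}, state)
        assert p[1] == pytest.approx(1.0 / (1.0 + math.exp(-3.0)), abs=1e-12)

    def test_zero_inverse_temperature_is_uniform(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        state.q_values[:] = [0.1, 0.9]
        assert np.allclose(model.choice_probs({"alpha": 0.5, "beta": 0.0}, state),
                           [0.5, 0.5])

    def test_side_bias_logistic(self, bandit_task):
        # equal values, beta*B = ln 3 -> p(left) = 0.75
        model = get_model("M3-bias")
        state = fresh_state("M3-bias", bandit_task)
        params = {"alpha": 0.1, "beta": 1.0, "bias": math.log(3.0)}
        p = model.choice_probs(params, state)
        assert p[0] == pytest.approx(0.75, abs=1e-12)

    def test_greedy_limit(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        state.q_values[:] = [0.2, 0.8]
        p = model.choice_probs({"alpha": 0.1, "beta": 30.0}, state)
        assert p[1] > 0.9999

    @pytest.mark.parametrize("model_id", list(ALL_PARAMS))
    def test_normalization(self, model_id, bandit_task, rng):
        model = get_model(model_id)
        state = fresh_state(model_id, bandit_task)
        for trial in range(20):
            p = model.choice_probs(ALL_PARAMS[model_id], state)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)
            c = int(rng.integers(2))
            model.update_state(ALL_PARAMS[model_id], state, c, int(rng.integers(2)))


class TestUpdateState:
    def test_delta_rule_single_step(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        model.update_state({"alpha": 0.1, "beta": 5.0}, state, choice=0, reward=1)
        assert state.q_values[0] == pytest.approx(0.1)
        assert state.q_values[1] == 0.0

    def test_choice_kernel_updates_all_options(self, bandit_task):
        model = get_model("M4")
        state = fresh_state("M4", bandit_task)
        model.update_state({"alpha_c": 0.1, "beta_c": 3.0}, state, choice=0, reward=0)
        assert np.allclose(state.choice_kernel, [0.1, 0.0])
        model.update_state({"alpha_c": 0.1, "beta_c": 3.0}, state, choice=1, reward=0)
        # unchosen option decays toward zero
        assert np.allclose(state.choice_kernel, [0.09, 0.1])

    def test_unit_kernel_rate_tracks_last_choice(self, bandit_task):
        model = get_model("M4")
        state = fresh_state("M4", bandit_task)
        for c in (1, 1, 0):
            model.update_state({"alpha_c": 1.0, "beta_c": 3.0}, state, c, 0)
        assert np.allclose(state.choice_kernel, [1.0, 0.0])

    def test_zero_learning_rate_freezes_values(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        for r in (1, 1, 0, 1):
            model.update_state({"alpha": 0.0, "beta": 5.0}, state, 0, r)
        assert np.all(state.q_values == 0)

    def test_unit_learning_rate_tracks_last_reward(self, bandit_task):
        model = get_model("M3")
        state = fresh_state("M3", bandit_task)
        for r in (1, 0, 1):
            model.update_state({"alpha": 1.0, "beta": 5.0}, state, 0, r)
        assert state.q_values[0] == 1.0


class TestNesting:
    """Richer models with a component switched off equal the nested model."""

    def _shared_dataset(self, bandit_task):
        return get_model("M5").simulate(
            {"alpha": 0.4, "beta": 3.0, "alpha_c": 0.3, "beta_c": 1.0},
            bandit_task, seed=11)

    def test_m5_without_kernel_equals_m3(self, bandit_task):
        ds = self._shared_dataset(bandit_task)
        full = get_model("M5").nll(
            {"alpha": 0.25, "beta": 4.0, "alpha_c": 0.6, "beta_c": 0.0}, ds)
        nested = get_model("M3").nll({"alpha": 0.25, "beta": 4.0}, ds)
        assert full == nested

    def test_m5_without_values_equals_m4(self, bandit_task):
        ds = self._shared_dataset(bandit_task)
        full = get_model("M5").nll(
            {"alpha": 0.25, "beta": 0.0, "alpha_c": 0.6, "beta_c": 2.0}, ds)
        nested = get_model("M4").nll({"alpha_c": 0.6, "beta_c": 2.0}, ds)
        assert full == nested

    def test_unbiased_m3_bias_equals_m3(self, bandit_task):
        ds = self._shared_dataset(bandit_task)
        full = get_model("M3-bias").nll(
            {"alpha": 0.25, "beta": 4.0, "bias": 0.0}, ds)
        nested = get_model("M3").nll({"alpha": 0.25, "beta": 4.0}, ds)
        assert full == nested


class TestSequenceNormalization:
    """Summed probability of every possible choice sequence equals one."""

    @pytest.mark.parametrize("model_id", list(ALL_PARAMS))
    def test_bandit_models(self, model_id):
        task = ck.make_bandit_task(2, 6, [0.2, 0.8])
        total = sequence_probability_sum(
            get_model(model_id), ALL_PARAMS[model_id], 6, task,
            reward_fn=lambda c: int(c == 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("model_id", ["blind-RL", "state-RL"])
    def test_stimulus_models(self, model_id):
        task = ck.StimulusTaskConfig(
            n_stimuli=2, n_actions=2, correct_action=(0, 1), n_trials=6,
            stimulus_schedule=np.array([0, 1, 0, 1, 0, 1]))
        total = sequence_probability_sum(
            get_model(model_id), {"alpha": 0.3, "beta": 2.0}, 6, task,
            reward_fn=lambda c: int(c == 0))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestProbabilityLawProperties:
    """Property-based checks over random parameters and histories."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _run_history(model_id, params, history):
        task = ck.make_bandit_task(2, max(len(history), 1), [0.2, 0.8])
        model = get_model(model_id)
        state = model.initial_state(task)
        for choice, reward in history:
            p = model.choice_probs(params, state)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0) and np.all(p <= 1)
            model.update_state(params, state, choice, reward)
        return model, state

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        alpha=st.floats(0, 1), beta=st.floats(0, 30),
        alpha_c=st.floats(0, 1), beta_c=st.floats(0, 30),
        history=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                         max_size=25),
    )
    def test_hybrid_probabilities_stay_normalized(self, alpha, beta, alpha_c,
                                                  beta_c, history):
        params = {"alpha": alpha, "beta": beta,
                  "alpha_c": alpha_c, "beta_c": beta_c}
        self._run_history("M5", params, history)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        alpha=st.floats(0, 1), beta=st.floats(0, 30),
        bias=st.floats(-10, 10),
        history=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                         max_size=25),
    )
    def test_biased_value_state_stays_bounded(self, alpha, beta, bias, history):
        params = {"alpha": alpha, "beta": beta, "bias": bias}
        _, state = self._run_history("M3-bias", params, history)
        assert np.all(state.q_values >= 0) and np.all(state.q_values <= 1)


class TestSimulate:
    def test_degenerate_bias_always_chooses_first(self, short_bandit):
        ds = get_model("M1").simulate({"b": 1.0}, short_bandit, seed=0)
        assert np.all(ds.choices == 0)

    def test_reproducible_for_fixed_seed(self, short_bandit):
        a = get_model("M3").simulate({"alpha": 0.2, "beta": 4.0}, short_bandit, 9)
        b = get_model("M3").simulate({"alpha": 0.2, "beta": 4.0}, short_bandit, 9)
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.rewards, b.rewards)

    def test_learner_prefers_better_arm(self, bandit_task):
        ds = get_model("M3").simulate({"alpha": 0.1, "beta": 5.0}, bandit_task, 4)
        late = (ds.choices[-10:] == 1).mean()
        assert late >= 0.8

    def test_first_trial_frequencies_match_fresh_probs(self):
        task = ck.make_bandit_task(2, 1, [0.5, 0.5])
        model = get_model("M3-bias")
        params = {"alpha": 0.1, "beta": 1.0, "bias": 0.5}
        expected = model.choice_probs(params, model.initial_state(task))[0]
        rng = np.random.default_rng(13)
        n = 4000
        first = [model.simulate(params, task, rng).choices[0] == 0
                 for _ in range(n)]
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(np.mean(first) - expected) < 3 * se

    def test_likelihood_of_own_simulation_matches_replay(self, bandit_task):
        model = get_model("M5")
        params = {"alpha": 0.3, "beta": 3.0, "alpha_c": 0.2, "beta_c": 1.0}
        ds = model.simulate(params, bandit_task, 21)
        probs = ck.one_step_predictions(params, model, ds)
        assert model.nll(params, ds) == pytest.approx(
            -np.log(probs).sum(), abs=1e-9)

    def test_block_reset_in_reversal_task(self):
        task = ck.make_reversal_task(4, 25, [(0.2, 0.8), (0.8, 0.2)])
        model = get_model("M3-bias", q0=0.5)
        params = {"alpha": 0.5, "beta": 5.0, "bias": 0.2}
        ds = model.simulate(params, task, 3)
        latents = ck.extract_latents(params, model, ds)
        starts = ds.block_start_mask()
        # value state returns to Q0 at every block start
        assert np.all(latents.q_values[starts] == 0.5)


class TestParameterSet:
    def test_exact_parameter_names_enforced(self):
        with pytest.raises(ValueError, match="exactly"):
            get_model("M3").coerce_params({"alpha": 0.1})
        with pytest.raises(ValueError, match="exactly"):
            get_model("M3").coerce_params({"alpha": 0.1, "beta": 1.0, "bias": 0.0})

    def test_bounded_parameters_validated(self):
        with pytest.raises(ValueError):
            get_model("M3").coerce_params({"alpha": 1.4, "beta": 1.0})
        with pytest.raises(ValueError):
            get_model("M3").coerce_params({"alpha": 0.4, "beta": -1.0})

    def test_json_round_trip(self):
        pset = ck.ParameterSet("M3", {"alpha": 0.25, "beta": 3.5})
        again = ck.ParameterSet.from_json(pset.to_json())
        assert again.model_id == "M3" and again.values == pset.values
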