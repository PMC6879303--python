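"""Generative models of trial-level choice in bandit and stimulus tasks.

Each model defines (i) a per-trial choice rule mapping its internal state to
a probability vector over options, and (ii) a state-update rule applied
after observing the chosen option's outcome.  The same two rules drive both
free simulation (sampling choices) and likelihood evaluation (replaying a
dataset's own choices), which keeps simulation and fitting consistent by
construction.

The model set
-------------
* ``M1`` — random responding with a bias ``b``: p = (b, 1-b).
* ``M2`` — noisy win-stay-lose-shift: the WSLS-consistent option is chosen
  with probability 1 - eps/2, the other with eps/2.
* ``M3`` — Rescorla-Wagner: delta-rule value learning
  Q_{t+1}(c) = Q_t(c) + alpha * (r_t - Q_t(c)) with softmax choice
  p(k) ∝ exp(beta * Q_t(k)).
* ``M4`` — choice kernel: a delta rule on past-choice indicators,
  CK_{t+1}(k) = CK_t(k) + alpha_c * (1[k = c_t] - CK_t(k)) for every k,
  with softmax p(k) ∝ exp(beta_c * CK_t(k)); captures perseveration
  independent of reward.
* ``M5`` — Rescorla-Wagner + choice kernel:
  p(k) ∝ exp(beta * Q_t(k) + beta_c * CK_t(k)).
* ``M3-bias`` — Rescorla-Wagner with a side bias ``B`` added to the first
  ("left") option's value inside the softmax:
  p(left) = 1 / (1 + exp(beta * (Q(right) - Q(left) - B))).
* ``blind-RL`` — delta-rule learner on a stimulus task that ignores the
  stimulus and learns one value per action.
* ``state-RL`` — delta-rule learner with a value per (stimulus, action)
  pair, softmax over the shown stimulus's action values.

Models follow the estimation-library convention: a model object is a
parameterised family; ``model.fit(dataset, ...)`` returns a
:class:`~choicekit.fitting.FitResult` results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import (
    nll_state_kernel,
    nll_value_kernel,
    simulate_state_kernel,
    simulate_value_kernel,
)
from .data import BehavioralDataset
from .priors import ExponentialMean, Uniform
from .tasks import StimulusTaskConfig, TaskConfig, draw_reward

__all__ = [
    "ParameterSet",
    "ModelState",
    "ChoiceModel",
    "RandomResponder",
    "NoisyWinStayLoseShift",
    "RescorlaWagner",
    "ChoiceKernel",
    "RescorlaWagnerChoiceKernel",
    "BiasedRescorlaWagner",
    "BlindRL",
    "StateRL",
    "MODEL_IDS",
    "get_model",
    "UnsupportedModelError",
]

DEFAULT_PROB_FLOOR = 1e-12

# [0,1] for probabilities/learning rates; inverse temperatures capped at 30
# (well above the identifiable range while keeping exponentials finite);
# the side bias on the Q-value scale.
UNIT = (0.0, 1.0)
BETA_BOUNDS = (0.0, 30.0)
BIAS_BOUNDS = (-10.0, 10.0)


class UnsupportedModelError(ValueError):
    """Model applied to a task structure it is not defined for."""


@dataclass
class ParameterSet:
    """Named parameter values for one model, e.g. ``{'alpha': .1, 'beta': 5}``."""

    model_id: str
    values: dict

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_json(self) -> str:
        return json.dumps({"model_id": self.model_id, **self.values})

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        payload = json.loads(text)
        model_id = payload.pop("model_id")
        return cls(model_id=model_id, values=payload)


@dataclass
class ModelState:
    """Evolving internal variables of a model mid-session.

    ``q_values`` has one entry per option (shape ``(K,)``) except for the
    state-based learner, where it has one per (stimulus, action) pair
    (shape ``(S, K)``).  A fresh state has all Q at ``q0``, all choice-kernel
    entries at 0, and no previous choice/outcome.
    """

    q_values: np.ndarray
    choice_kernel: np.ndarray
    last_choice: int | None = None
    last_reward: int | None = None

    def copy(self) -> "ModelState":
        return ModelState(self.q_values.copy(), self.choice_kernel.copy(),
                          self.last_choice, self.last_reward)


def _softmax(drive: np.ndarray) -> np.ndarray:
    # max-subtraction keeps exp() finite for any inverse temperature
    z = np.exp(drive - drive.max())
    return z / z.sum()


class ChoiceModel:
    """Base class for generative choice models.

    Subclasses define ``model_id``, ``param_names``, ``bounds`` and the
    choice/update rules.  ``q0`` sets the initial option value (default 0;
    some designs reset to 0.5 at each block start) and is not a fitted
    parameter.
    """

    model_id: str = ""
    param_names: tuple[str, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()
    requires_stimuli: bool = False
    binary_only: bool = False

    def __init__(self, q0: float = 0.0):
        self.q0 = float(q0)

    # -- parameter plumbing ----------------------------------------------
    @property
    def k(self) -> int:
        """Number of free parameters (BIC penalty count)."""
        return len(self.param_names)

    def coerce_params(self, params) -> np.ndarray:
        """Accept a dict, ParameterSet or ordered array; validate names."""
        if isinstance(params, ParameterSet):
            params = params.values
        if isinstance(params, dict):
            missing = set(self.param_names) - set(params)
            extra = set(params) - set(self.param_names)
            if missing or extra:
                raise ValueError(
                    f"{self.model_id} takes exactly {self.param_names}; "
                    f"missing={sorted(missing)}, unexpected={sorted(extra)}"
                )
            vec = np.array([float(params[n]) for n in self.param_names])
        else:
            vec = np.asarray(params, dtype=float)
            if vec.shape != (self.k,):
                raise ValueError(f"expected {self.k} parameters, got {vec.shape}")
        for name, value in zip(self.param_names, vec):
            if name in ("b", "epsilon", "alpha", "alpha_c") and not 0 <= value <= 1:
                raise ValueError(f"{name}={value} outside [0, 1]")
            if name in ("beta", "beta_c") and value < 0:
                raise ValueError(f"{name}={value} must be non-negative")
        return vec

    def params_dict(self, vec) -> dict:
        return {n: float(v) for n, v in zip(self.param_names, np.asarray(vec))}

    def parameter_set(self, vec) -> ParameterSet:
        return ParameterSet(self.model_id, self.params_dict(vec))

    def default_priors(self) -> dict:
        """Broad simulation priors; also the optimizer start sampler."""
        priors = {}
        for name in self.param_names:
            if name in ("b", "epsilon", "alpha", "alpha_c"):
                priors[name] = Uniform(0.0, 1.0)
            elif name in ("beta", "beta_c"):
                priors[name] = ExponentialMean(1.0)
            elif name == "bias":
                priors[name] = Uniform(-2.0, 2.0)
        return priors

    # -- state machine ----------------------------------------------------
    def _check_task(self, task) -> None:
        if self.requires_stimuli and not isinstance(task, StimulusTaskConfig):
            raise UnsupportedModelError(
                f"{self.model_id} requires a stimulus task"
            )
        if self.binary_only and task.n_arms != 2:
            raise UnsupportedModelError(
                f"{self.model_id} is defined for two options only, "
                f"task has {task.n_arms}"
            )

    def initial_state(self, task) -> ModelState:
        self._check_task(task)
        n = task.n_arms
        return ModelState(
            q_values=np.full(n, self.q0),
            choice_kernel=np.zeros(n),
        )

    def choice_probs(self, params, state: ModelState, stimulus: int | None = None) -> np.ndarray:
        raise NotImplementedError

    def update_state(self, params, state: ModelState, choice: int, reward: int,
                     stimulus: int | None = None) -> ModelState:
        """Apply the post-outcome update in place and return the state."""
        raise NotImplementedError

    # -- simulation --------------------------------------------------------
    def simulate(self, params, task, seed) -> BehavioralDataset:
        """Generate a full session by alternating choose / reward / update.

        ``seed`` may be an int or a ``numpy.random.Generator``; outputs are
        bit-reproducible for a fixed integer seed.  When the task carries
        block bounds the state is reset to fresh at each block start.
        """
        vec = self.coerce_params(params)
        self._check_task(task)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        T = task.n_trials
        starts = task.block_start_mask()
        stimuli = task.stimulus_schedule if isinstance(task, StimulusTaskConfig) else None
        choices = np.empty(T, dtype=np.int64)
        rewards = np.empty(T, dtype=np.int64)
        if self._simulate_fast(vec, task, rng, choices, rewards):
            blocks = task.block_ids() if task.block_bounds else None
            return BehavioralDataset(
                choices=choices, rewards=rewards, blocks=blocks,
                stimuli=stimuli.copy() if stimuli is not None else None,
                task=task,
            )
        state = self.initial_state(task)
        for t in range(T):
            if t > 0 and starts[t]:
                state = self.initial_state(task)
            stim = int(stimuli[t]) if stimuli is not None else None
            p = self.choice_probs(vec, state, stim)
            c = int(np.searchsorted(np.cumsum(p), rng.random()))
            if c >= p.size:  # guard against cumsum rounding just below 1
                c = p.size - 1
            r = draw_reward(task, t, c, rng)
            self.update_state(vec, state, c, r, stim)
            choices[t] = c
            rewards[t] = r
        blocks = task.block_ids() if task.block_bounds else None
        return BehavioralDataset(
            choices=choices, rewards=rewards, blocks=blocks,
            stimuli=stimuli.copy() if stimuli is not None else None, task=task,
        )

    def _simulate_fast(self, vec, task, rng, choices_out, rewards_out) -> bool:
        """Compiled simulation fast path; False means use the generic loop."""
        return False

    # -- likelihood --------------------------------------------------------
    def _check_dataset(self, dataset: BehavioralDataset) -> None:
        if self.requires_stimuli and dataset.stimuli is None:
            raise UnsupportedModelError(f"{self.model_id} requires stimulus records")
        if self.binary_only and dataset.n_options > 2:
            raise UnsupportedModelError(f"{self.model_id} is defined for two options only")
        if dataset.choices.max() >= dataset.n_options:
            raise ValueError("choices exceed the task's number of options")

    def trial_probabilities(self, params, dataset: BehavioralDataset) -> np.ndarray:
        """Per-trial probability of the observed choice (unfloored).

        These are one-step posterior predictions p(c_t | d_{1:t-1}, s_t,
        theta): the conditioning history is the dataset's *actual* choices
        and outcomes, not choices resampled from the model.
        """
        _, probs = self._nll_impl(self.coerce_params(params), dataset, DEFAULT_PROB_FLOOR)
        return probs

    def nll(self, params, dataset: BehavioralDataset,
            prob_floor: float = DEFAULT_PROB_FLOOR) -> float:
        """Negative log-likelihood -sum_t log p(c_t | d_{1:t-1}, s_t, theta).

        Per-trial probabilities are floored at ``prob_floor`` before the
        log, so the result is finite for every parameter point inside the
        bounds (including degenerate boundary values).
        """
        value, _ = self._nll_impl(self.coerce_params(params), dataset, prob_floor)
        return value

    def _nll_impl(self, vec, dataset, prob_floor):
        raise NotImplementedError

    # -- fitting ------------------------------------------------------------
    def fit(self, dataset: BehavioralDataset, options=None, **kwargs):
        """Maximum-likelihood fit via guarded multistart; see fitting module."""
        from .fitting import fit_mle

        return fit_mle(self, dataset, options, **kwargs)


class RandomResponder(ChoiceModel):
    """M1 — bias-only random responding: p = (b, 1 - b), no learning."""

    model_id = "M1"
    param_names = ("b",)
    bounds = (UNIT,)
    binary_only = True

    def choice_probs(self, params, state, stimulus=None):
        b = self.coerce_params(params)[0]
        return np.array([b, 1.0 - b])

    def update_state(self, params, state, choice, reward, stimulus=None):
        state.last_choice = choice
        state.last_reward = reward
        return state

    def _nll_impl(self, vec, dataset, prob_floor):
        self._check_dataset(dataset)
        b = vec[0]
        probs = np.where(dataset.choices == 0, b, 1.0 - b)
        return float(-np.log(np.maximum(probs, prob_floor)).sum()), probs


class NoisyWinStayLoseShift(ChoiceModel):
    """M2 — noisy win-stay-lose-shift.

    Repeats rewarded choices and switches after unrewarded ones, applying
    the rule with probability 1 - eps and choosing at random with
    probability eps.  With no previous outcome (the first trial of a
    session or block) the model chooses uniformly.
    """

    model_id = "M2"
    param_names = ("epsilon",)
    bounds = (UNIT,)
    binary_only = True

    def choice_probs(self, params, state, stimulus=None):
        eps = self.coerce_params(params)[0]
        if state.last_choice is None:
            return np.array([0.5, 0.5])
        p_stay = 1.0 - eps / 2.0 if state.last_reward == 1 else eps / 2.0
        probs = np.full(2, 1.0 - p_stay)
        probs[state.last_choice] = p_stay
        return probs

    def update_state(self, params, state, choice, reward, stimulus=None):
        state.last_choice = choice
        state.last_reward = reward
        return state

    def _nll_impl(self, vec, dataset, prob_floor):
        self._check_dataset(dataset)
        eps = vec[0]
        c, r = dataset.choices, dataset.rewards
        first = dataset.block_start_mask()
        stay = np.zeros_like(c, dtype=bool)
        stay[1:] = c[1:] == c[:-1]
        prev_win = np.zeros_like(c, dtype=bool)
        prev_win[1:] = r[:-1] == 1
        consistent = stay == prev_win  # stay after win or shift after loss
        probs = np.where(consistent, 1.0 - eps / 2.0, eps / 2.0)
        probs[first] = 0.5
        return float(-np.log(np.maximum(probs, prob_floor)).sum()), probs


class _ValueFamily(ChoiceModel):
    """Shared machinery for the Q / choice-kernel softmax family."""

    # per-model (alpha, beta, alpha_c, beta_c, bias) slot map; None -> 0
    _slots: tuple[str | None, str | None, str | None, str | None, str | None] = (
        None, None, None, None, None)

    def _kernel_args(self, vec) -> tuple[float, float, float, float, float]:
        named = self.params_dict(vec)
        return tuple(named.get(slot, 0.0) if slot else 0.0 for slot in self._slots)

    def choice_probs(self, params, state, stimulus=None):
        alpha, beta, alpha_c, beta_c, bias = self._kernel_args(self.coerce_params(params))
        drive = beta * state.q_values + beta_c * state.choice_kernel
        drive[0] += beta * bias
        return _softmax(drive)

    def update_state(self, params, state, choice, reward, stimulus=None):
        alpha, beta, alpha_c, beta_c, bias = self._kernel_args(self.coerce_params(params))
        state.q_values[choice] += alpha * (reward - state.q_values[choice])
        indicator = np.zeros_like(state.choice_kernel)
        indicator[choice] = 1.0
        state.choice_kernel += alpha_c * (indicator - state.choice_kernel)
        state.last_choice = choice
        state.last_reward = reward
        return state

    def _simulate_fast(self, vec, task, rng, choices_out, rewards_out) -> bool:
        if isinstance(task, StimulusTaskConfig):
            return False
        alpha, beta, alpha_c, beta_c, bias = self._kernel_args(vec)
        T = task.n_trials
        simulate_value_kernel(
            rng.random(T), rng.random(T), task.reward_probs,
            task.block_start_mask(), task.n_arms,
            alpha, beta, alpha_c, beta_c, bias, self.q0,
            choices_out, rewards_out,
        )
        return True

    def _nll_impl(self, vec, dataset, prob_floor):
        self._check_dataset(dataset)
        alpha, beta, alpha_c, beta_c, bias = self._kernel_args(vec)
        probs = np.empty(dataset.n_trials)
        value = nll_value_kernel(
            dataset.choices, dataset.rewards.astype(np.float64),
            dataset.block_start_mask(), dataset.n_options,
            alpha, beta, alpha_c, beta_c, bias, self.q0, prob_floor, probs,
        )
        return float(value), probs


class RescorlaWagner(_ValueFamily):
    """M3 — delta-rule value learning with softmax choice."""

    model_id = "M3"
    param_names = ("alpha", "beta")
    bounds = (UNIT, BETA_BOUNDS)
    _slots = ("alpha", "beta", None, None, None)


class ChoiceKernel(_ValueFamily):
    """M4 — reward-blind perseveration via a choice kernel."""

    model_id = "M4"
    param_names = ("alpha_c", "beta_c")
    bounds = (UNIT, BETA_BOUNDS)
    _slots = (None, None, "alpha_c", "beta_c", None)


class RescorlaWagnerChoiceKernel(_ValueFamily):
    """M5 — Rescorla-Wagner values mixed with a choice kernel."""

    model_id = "M5"
    param_names = ("alpha", "beta", "alpha_c", "beta_c")
    bounds = (UNIT, BETA_BOUNDS, UNIT, BETA_BOUNDS)
    _slots = ("alpha", "beta", "alpha_c", "beta_c", None)


class BiasedRescorlaWagner(_ValueFamily):
    """M3-bias — Rescorla-Wagner with a constant side bias.

    The bias ``B`` acts as an addition to the first option's learned value
    inside the softmax, so p(left) = sigma(beta * (Q_left + B - Q_right))
    in the two-option case.  A nuisance parameter: usually of no interest
    itself, but omitting it from the fit degrades estimates of alpha and
    beta when it is present in behavior.
    """

    model_id = "M3-bias"
    param_names = ("alpha", "beta", "bias")
    bounds = (UNIT, BETA_BOUNDS, BIAS_BOUNDS)
    _slots = ("alpha", "beta", None, None, "bias")


class _StimulusRL(ChoiceModel):
    requires_stimuli = True
    param_names = ("alpha", "beta")
    bounds = (UNIT, BETA_BOUNDS)
    n_states_for: staticmethod = None

    def _n_states(self, n_stimuli: int) -> int:
        raise NotImplementedError

    def initial_state(self, task) -> ModelState:
        self._check_task(task)
        S = self._n_states(task.n_stimuli)
        q = np.full((S, task.n_actions), self.q0)
        return ModelState(q_values=q if S > 1 else q[0],
                          choice_kernel=np.zeros(task.n_actions))

    def _state_index(self, stimulus: int | None) -> int:
        raise NotImplementedError

    def choice_probs(self, params, state, stimulus=None):
        alpha, beta = self.coerce_params(params)
        q = state.q_values
        row = q if q.ndim == 1 else q[self._state_index(stimulus)]
        return _softmax(beta * row)

    def update_state(self, params, state, choice, reward, stimulus=None):
        alpha, beta = self.coerce_params(params)
        q = state.q_values
        row = q if q.ndim == 1 else q[self._state_index(stimulus)]
        row[choice] += alpha * (reward - row[choice])
        state.last_choice = choice
        state.last_reward = reward
        return state

    def _simulate_fast(self, vec, task, rng, choices_out, rewards_out) -> bool:
        alpha, beta = vec
        simulate_state_kernel(
            rng.random(task.n_trials), task.stimulus_schedule,
            np.asarray(task.correct_action, dtype=np.int64),
            self._n_states(task.n_stimuli), task.n_actions,
            alpha, beta, self.q0, choices_out, rewards_out,
        )
        return True

    def _nll_impl(self, vec, dataset, prob_floor):
        self._check_dataset(dataset)
        alpha, beta = vec
        n_actions = dataset.n_options
        S = self._n_states(int(dataset.stimuli.max()) + 1)
        stimuli = dataset.stimuli if S > 1 else np.zeros_like(dataset.choices)
        probs = np.empty(dataset.n_trials)
        value = nll_state_kernel(
            dataset.choices, dataset.rewards.astype(np.float64), stimuli,
            S, n_actions, alpha, beta, self.q0, prob_floor, probs,
        )
        return float(value), probs


class BlindRL(_StimulusRL):
    """Stimulus-blind delta-rule learner: one value per action.

    Sees only its own choices and outcomes, so it learns the marginal
    value of each action across stimuli.  On the default 3x3 task its
    best achievable accuracy is 2/3 (always take the action correct for
    two of the three stimuli).
    """

    model_id = "blind-RL"

    def _n_states(self, n_stimuli: int) -> int:
        return 1

    def _state_index(self, stimulus):
        return 0


class StateRL(_StimulusRL):
    """State-based delta-rule learner: a value per (stimulus, action) pair."""

    model_id = "state-RL"

    def _n_states(self, n_stimuli: int) -> int:
        return n_stimuli

    def _state_index(self, stimulus):
        if stimulus is None:
            raise UnsupportedModelError("state-RL needs the trial's stimulus")
        return int(stimulus)


_MODEL_CLASSES = {
    cls.model_id: cls
    for cls in (
        RandomResponder, NoisyWinStayLoseShift, RescorlaWagner, ChoiceKernel,
        RescorlaWagnerChoiceKernel, BiasedRescorlaWagner, BlindRL, StateRL,
    )
}

MODEL_IDS = tuple(_MODEL_CLASSES)


def get_model(model: str | ChoiceModel, q0: float = 0.0) -> ChoiceModel:
    """Resolve a model id (e.g. ``"M3"``) to a model instance."""
    if isinstance(model, ChoiceModel):
        return model
    try:
        return _MODEL_CLASSES[model](q0=q0)
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; available: {sorted(_MODEL_CLASSES)}"
        ) from None
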