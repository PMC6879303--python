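import numpy as np
import pytest

import choicekit as ck


@pytest.fixture
def bandit_task():
    """The reference two-armed bandit: T=1000, means 0.2/0.8."""
    return ck.make_bandit_task(2, 1000, [0.2, 0.8])


@pytest.fixture
def short_bandit():
    return ck.make_bandit_task(2, 50, [0.2, 0.8])


@pytest.fixture
def stimulus_task():
    return ck.StimulusTaskConfig(n_trials=120)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def make_dataset(choices, rewards, **kwargs):
    return ck.BehavioralDataset(np.asarray(choices), np.asarray(rewards), **kwargs)


def sequence_probability_sum(model, params, n_trials, task, reward_fn):
    """Total probability the model assigns to all K^T choice sequences.

    Rewards are a fixed deterministic function of the choice, so the model's
    per-trial probabilities define a proper distribution over sequences and
    the total must equal 1.  Brute-force enumeration; use only for tiny T.
    """
    import itertools
    import math

    K = task.n_arms
    stimuli = getattr(task, "stimulus_schedule", None)
    total = 0.0
    for seq in itertools.product(range(K), repeat=n_trials):
        choices = np.asarray(seq)
        rewards = np.asarray([reward_fn(c) for c in seq])
        ds = ck.BehavioralDataset(choices, rewards, stimuli=stimuli, task=task)
        total += math.exp(-model.nll(params, ds))
    return total
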