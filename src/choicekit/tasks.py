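"""Task environments: bandit schedules, reversal blocks, and a
stimulus–action learning task.

A task owns the reward contingencies only.  Agents (see
:mod:`choicekit.models`) own the learning and decision rules; a task turns a
(trial, choice) pair into a binary reward.  Only the chosen option's outcome
is ever realised — no counterfactual outcomes are generated or stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "StimulusTaskConfig",
    "make_bandit_task",
    "make_reversal_task",
    "draw_reward",
]


@dataclass(frozen=True)
class TaskConfig:
    """A (possibly block-structured) K-armed Bernoulli bandit.

    Parameters
    ----------
    n_arms : int
        Number of options K (>= 2).
    n_trials : int
        Number of trials T (>= 1).
    reward_probs : ndarray, shape (T, K)
        Per-trial, per-arm Bernoulli success probabilities.  Stationary
        tasks are stored in expanded per-trial form.
    block_bounds : tuple of int, optional
        Strictly increasing 0-based start indices of independent blocks;
        must start at 0 and end before T.  Agents reset their internal
        state at each block start.
    """

    n_arms: int
    n_trials: int
    reward_probs: np.ndarray
    block_bounds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ValueError(f"n_arms must be >= 2, got {self.n_arms}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        probs = np.asarray(self.reward_probs, dtype=float)
        if probs.shape != (self.n_trials, self.n_arms):
            raise ValueError(
                f"reward_probs must have shape ({self.n_trials}, {self.n_arms}), "
                f"got {probs.shape}"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("reward probabilities must lie in [0, 1]")
        object.__setattr__(self, "reward_probs", probs)
        if self.block_bounds is not None:
            bounds = tuple(int(b) for b in self.block_bounds)
            if bounds[0] != 0:
                raise ValueError("block_bounds must start at trial 0")
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError("block_bounds must be strictly increasing")
            if bounds[-1] >= self.n_trials:
                raise ValueError("block_bounds must end before n_trials")
            object.__setattr__(self, "block_bounds", bounds)

    def block_ids(self) -> np.ndarray:
        """Per-trial 0-based block identifier (all zeros if unblocked)."""
        ids = np.zeros(self.n_trials, dtype=np.int64)
        if self.block_bounds is not None:
            for b in self.block_bounds[1:]:
                ids[b:] += 1
        return ids

    def block_start_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_trials, dtype=bool)
        mask[0] = True
        if self.block_bounds is not None:
            mask[list(self.block_bounds)] = True
        return mask

    def correct_arm(self) -> np.ndarray:
        """Per-trial index of the uniquely best arm.

        Raises
        ------
        ValueError
            If any trial has a tied maximum (no unique correct option).
        """
        probs = self.reward_probs
        best = probs.max(axis=1, keepdims=True)
        n_best = (probs == best).sum(axis=1)
        if np.any(n_best > 1):
            raise ValueError("no unique correct option on some trials")
        return probs.argmax(axis=1)

    def to_json(self) -> str:
        payload = {
            "kind": "bandit",
            "n_arms": self.n_arms,
            "n_trials": self.n_trials,
            "reward_probs": self.reward_probs.tolist(),
            "block_bounds": list(self.block_bounds) if self.block_bounds else None,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        payload = json.loads(text)
        if payload.get("kind") not in (None, "bandit"):
            raise ValueError(f"not a bandit task config: {payload.get('kind')}")
        bounds = payload.get("block_bounds")
        return cls(
            n_arms=payload["n_arms"],
            n_trials=payload["n_trials"],
            reward_probs=np.asarray(payload["reward_probs"], dtype=float),
            block_bounds=tuple(bounds) if bounds else None,
        )


# Default stimulus->action map: a1 rewarded for s1 and s2, a3 for s3; a2 is
# never correct for any stimulus.
DEFAULT_CORRECT_ACTION = (0, 0, 2)


@dataclass(frozen=True)
class StimulusTaskConfig:
    """Deterministic stimulus–action learning task.

    On each trial one of ``n_stimuli`` stimuli is shown and exactly one of
    ``n_actions`` actions is rewarded for it (reward 1 iff the chosen action
    equals ``correct_action[stimulus]``, else 0).  The default instantiation
    is 3 stimuli / 3 actions with map (s1->a1, s2->a1, s3->a3), so one action
    is never correct.
    """

    n_stimuli: int = 3
    n_actions: int = 3
    correct_action: tuple[int, ...] = DEFAULT_CORRECT_ACTION
    n_trials: int = 300
    stimulus_schedule: np.ndarray | None = None
    schedule_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli < 1 or self.n_actions < 2:
            raise ValueError("need >= 1 stimulus and >= 2 actions")
        if len(self.correct_action) != self.n_stimuli:
            raise ValueError("correct_action must map every stimulus")
        if any(a < 0 or a >= self.n_actions for a in self.correct_action):
            raise ValueError("correct_action entries out of range")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.stimulus_schedule is None:
            # Presentation order is not part of the task definition; default
            # to a seeded permuted-block schedule (each consecutive group of
            # n_stimuli trials shows every stimulus once, in random order) so
            # the schedule is frozen and every trial window has a comparable
            # stimulus composition.
            rng = np.random.default_rng(self.schedule_seed)
            n_blocks = -(-self.n_trials // self.n_stimuli)
            sched = np.concatenate(
                [rng.permutation(self.n_stimuli) for _ in range(n_blocks)]
            )[: self.n_trials]
        else:
            sched = np.asarray(self.stimulus_schedule, dtype=np.int64)
            if sched.shape != (self.n_trials,):
                raise ValueError("stimulus_schedule must have length n_trials")
            if sched.min() < 0 or sched.max() >= self.n_stimuli:
                raise ValueError("stimulus_schedule entries out of range")
        object.__setattr__(self, "stimulus_schedule", np.asarray(sched, dtype=np.int64))

    # Shared surface with TaskConfig -------------------------------------
    @property
    def n_arms(self) -> int:
        return self.n_actions

    @property
    def block_bounds(self) -> None:
        return None

    def block_ids(self) -> np.ndarray:
        return np.zeros(self.n_trials, dtype=np.int64)

    def block_start_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_trials, dtype=bool)
        mask[0] = True
        return mask

    def correct_arm(self) -> np.ndarray:
        return np.asarray(self.correct_action, dtype=np.int64)[self.stimulus_schedule]

    def to_json(self) -> str:
        payload = {
            "kind": "stimulus",
            "n_stimuli": self.n_stimuli,
            "n_actions": self.n_actions,
            "correct_action": list(self.correct_action),
            "n_trials": self.n_trials,
            "stimulus_schedule": self.stimulus_schedule.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "StimulusTaskConfig":
        payload = json.loads(text)
        if payload.get("kind") != "stimulus":
            raise ValueError("not a stimulus task config")
        return cls(
            n_stimuli=payload["n_stimuli"],
            n_actions=payload["n_actions"],
            correct_action=tuple(payload["correct_action"]),
            n_trials=payload["n_trials"],
            stimulus_schedule=np.asarray(payload["stimulus_schedule"], dtype=np.int64),
        )


def make_bandit_task(n_arms: int, n_trials: int, means) -> TaskConfig:
    """Stationary K-armed Bernoulli bandit with constant per-arm means.

    ``make_bandit_task(2, 1000, [0.2, 0.8])`` is the canonical two-armed
    example: 1000 trials in which arm 1 pays with probability 0.2 and arm 2
    with probability 0.8.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (n_arms,):
        raise ValueError(f"need exactly {n_arms} means, got shape {means.shape}")
    if np.any(means < 0) or np.any(means > 1):
        raise ValueError("reward probabilities must lie in [0, 1]")
    probs = np.tile(means, (n_trials, 1))
    return TaskConfig(n_arms=n_arms, n_trials=n_trials, reward_probs=probs)


def make_reversal_task(n_blocks: int, block_len: int, mean_pairs) -> TaskConfig:
    """Blocked bandit in which per-arm means alternate across blocks.

    ``mean_pairs`` is cycled across blocks, e.g. ``[(0.2, 0.8), (0.8, 0.2)]``
    yields the classic reversal design: 0.2/0.8 in odd blocks, 0.8/0.2 in
    even ones.  ``block_bounds`` is populated so agents can treat each block
    as an independent bandit.
    """
    if n_blocks < 1 or block_len < 1:
        raise ValueError("n_blocks and block_len must be positive")
    pairs = [np.asarray(p, dtype=float) for p in mean_pairs]
    if not pairs:
        raise ValueError("mean_pairs must not be empty")
    n_arms = len(pairs[0])
    if any(p.shape != (n_arms,) for p in pairs):
        raise ValueError("all mean pairs must have the same number of arms")
    rows = []
    for b in range(n_blocks):
        rows.append(np.tile(pairs[b % len(pairs)], (block_len, 1)))
    probs = np.vstack(rows)
    bounds = tuple(range(0, n_blocks * block_len, block_len))
    return TaskConfig(
        n_arms=n_arms,
        n_trials=n_blocks * block_len,
        reward_probs=probs,
        block_bounds=bounds if n_blocks > 1 else (0,),
    )


def draw_reward(task, trial: int, choice: int, rng: np.random.Generator) -> int:
    """Realise the binary reward of ``choice`` on ``trial``.

    Bernoulli(mu_t^choice) for bandit tasks; deterministic 0/1 for the
    stimulus task.  Only the chosen option's outcome is drawn.
    """
    if trial < 0 or trial >= task.n_trials:
        raise IndexError(f"trial {trial} out of range [0, {task.n_trials})")
    if isinstance(task, StimulusTaskConfig):
        if choice < 0 or choice >= task.n_actions:
            raise IndexError(f"action {choice} out of range")
        stim = int(task.stimulus_schedule[trial])
        return int(choice == task.correct_action[stim])
    if choice < 0 or choice >= task.n_arms:
        raise IndexError(f"arm {choice} out of range")
    p = task.reward_probs[trial, choice]
    return int(rng.random() < p)
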