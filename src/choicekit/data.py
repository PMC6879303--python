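"""Trial-level behavioral data containers.

Internally choices, stimuli and blocks are 0-based integer arrays; file
formats use the 1-based codes conventional in the field (see
:mod:`choicekit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BehavioralDataset"]


@dataclass
class BehavioralDataset:
    """Ordered trial records for one agent or subject.

    Parameters
    ----------
    choices : ndarray of int, shape (T,)
        0-based chosen option per trial.
    rewards : ndarray of int, shape (T,)
        Binary outcome per trial.
    agent_id : str
        Label of the agent/subject.
    blocks : ndarray of int, shape (T,), optional
        0-based block id per trial; non-decreasing.  Models reset their
        internal state at every block change.
    stimuli : ndarray of int, shape (T,), optional
        0-based stimulus identity per trial (stimulus–action tasks only).
    task : TaskConfig or StimulusTaskConfig, optional
        The generating task, when known.
    """

    choices: np.ndarray
    rewards: np.ndarray
    agent_id: str = "agent0"
    blocks: np.ndarray | None = None
    stimuli: np.ndarray | None = None
    task: object | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.int64)
        if self.choices.ndim != 1:
            raise ValueError("choices must be one-dimensional")
        if self.rewards.shape != self.choices.shape:
            raise ValueError("choices and rewards must have equal length")
        if self.choices.size == 0:
            raise ValueError("dataset must contain at least one trial")
        if np.any(self.choices < 0):
            raise ValueError("choices must be non-negative (0-based)")
        if np.any((self.rewards != 0) & (self.rewards != 1)):
            raise ValueError("rewards must be binary (0 or 1)")
        if self.blocks is not None:
            self.blocks = np.asarray(self.blocks, dtype=np.int64)
            if self.blocks.shape != self.choices.shape:
                raise ValueError("blocks must align with trials")
            if np.any(np.diff(self.blocks) < 0):
                raise ValueError("block ids must be non-decreasing")
        if self.stimuli is not None:
            self.stimuli = np.asarray(self.stimuli, dtype=np.int64)
            if self.stimuli.shape != self.choices.shape:
                raise ValueError("stimuli must align with trials")
            if np.any(self.stimuli < 0):
                raise ValueError("stimuli must be non-negative (0-based)")

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)

    @property
    def n_options(self) -> int:
        """Number of options, from the task when known else from the data."""
        if self.task is not None:
            return int(self.task.n_arms)
        return int(self.choices.max()) + 1

    def block_start_mask(self) -> np.ndarray:
        """Boolean mask marking the first trial of each block."""
        mask = np.zeros(self.n_trials, dtype=bool)
        mask[0] = True
        if self.blocks is not None:
            mask[1:] = np.diff(self.blocks) > 0
            mask[0] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        """Export with 1-based choice/stimulus/block/trial codes."""
        frame = pd.DataFrame(
            {
                "agent_id": self.agent_id,
                "trial": np.arange(1, self.n_trials + 1),
                "block": (self.blocks + 1) if self.blocks is not None else 1,
                "stimulus": (self.stimuli + 1) if self.stimuli is not None else pd.NA,
                "choice": self.choices + 1,
                "reward": self.rewards,
            }
        )
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, agent_id: str | None = None,
                   task: object | None = None) -> "BehavioralDataset":
        """Build from a 1-based tabular record (inverse of :meth:`to_frame`)."""
        frame = frame.sort_values("trial")
        trials = frame["trial"].to_numpy(dtype=np.int64)
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise ValueError("trial indices must be contiguous from 1")
        stim = None
        if "stimulus" in frame.columns and frame["stimulus"].notna().all():
            stim = frame["stimulus"].to_numpy(dtype=np.int64) - 1
        blocks = None
        if "block" in frame.columns and frame["block"].notna().all():
            blocks = frame["block"].to_numpy(dtype=np.int64) - 1
        if agent_id is None:
            agent_id = str(frame["agent_id"].iloc[0]) if "agent_id" in frame else "agent0"
        return cls(
            choices=frame["choice"].to_numpy(dtype=np.int64) - 1,
            rewards=frame["reward"].to_numpy(dtype=np.int64),
            agent_id=agent_id,
            blocks=blocks,
            stimuli=stim,
            task=task,
        )
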