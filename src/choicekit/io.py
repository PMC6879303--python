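"""CSV/JSON input and output.

Files use 1-based choice/stimulus/block codes and 1-based contiguous trial
indices (the field's convention); the internal containers are 0-based.
The conversion happens here and only here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import BehavioralDataset

__all__ = ["read_datasets", "write_datasets"]

REQUIRED_COLUMNS = ("agent_id", "trial", "choice", "reward")


class DatasetParseError(ValueError):
    """Malformed behavioral data file."""


def read_datasets(path) -> list[BehavioralDataset]:
    """Read per-agent behavioral datasets from a CSV file.

    Requires columns ``agent_id, trial, choice, reward``; ``block`` and
    ``stimulus`` are optional.  Rewards must be binary and each agent's
    trial indices contiguous from 1.  Errors name the offending row
    (1-based, excluding the header).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetParseError(f"{path}: missing required column(s) {missing}")
    bad_reward = frame.index[~frame["reward"].isin((0, 1))]
    if len(bad_reward):
        raise DatasetParseError(
            f"{path}: non-binary reward at row {int(bad_reward[0]) + 1}"
        )
    bad_choice = frame.index[frame["choice"] < 1]
    if len(bad_choice):
        raise DatasetParseError(
            f"{path}: choice codes are 1-based; bad value at row "
            f"{int(bad_choice[0]) + 1}"
        )
    datasets = []
    for agent_id, group in frame.groupby("agent_id", sort=False):
        trials = group.sort_values("trial")["trial"].to_numpy()
        expected = np.arange(1, len(trials) + 1)
        if not np.array_equal(trials, expected):
            where = int(group.index[0]) + 1
            raise DatasetParseError(
                f"{path}: agent {agent_id!r} has non-contiguous trial indices "
                f"(records start at row {where})"
            )
        datasets.append(BehavioralDataset.from_frame(group, agent_id=str(agent_id)))
    return datasets


def write_datasets(datasets, path) -> None:
    """Write one or more datasets to a single CSV (inverse of read)."""
    if isinstance(datasets, BehavioralDataset):
        datasets = [datasets]
    frame = pd.concat([ds.to_frame() for ds in datasets], ignore_index=True)
    frame.to_csv(path, index=False)
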