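"""Model-independent behavioral measures, posterior predictive validation,
absolute fit, and yoked latent-variable extraction.

Two distinct notions of "prediction" live here and must not be conflated:

* ``one_step_predictions`` conditions on the subject's *actual* history —
  the per-trial likelihoods whose product is the fit likelihood.
* ``posterior_predictive`` lets the model make its *own* choices with the
  fitted parameters and compares summary measures of the simulations with
  the observed data.  The two can disagree dramatically when the subject's
  choice path differs from paths the model would take on its own, which is
  exactly what the posterior predictive check is for.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BehavioralDataset
from .models import ChoiceModel, get_model
from .tasks import StimulusTaskConfig

__all__ = [
    "stay_probability",
    "performance_curves",
    "average_trial_likelihood",
    "arithmetic_trial_likelihood",
    "one_step_predictions",
    "ValidationReport",
    "posterior_predictive",
    "LatentTrajectories",
    "extract_latents",
]


def stay_probability(dataset: BehavioralDataset) -> dict:
    """p(repeat previous choice), split by whether it was rewarded.

    Only consecutive trial pairs within a block count (the first trial of
    each block has no previous choice).  An empty conditioning cell yields
    NaN and is listed under ``undefined``.
    """
    if dataset.n_trials < 2:
        raise ValueError("stay probabilities need at least two trials")
    c, r = dataset.choices, dataset.rewards
    valid = ~dataset.block_start_mask()
    valid[0] = False
    stay = np.zeros(dataset.n_trials, dtype=bool)
    stay[1:] = c[1:] == c[:-1]
    prev_win = np.zeros(dataset.n_trials, dtype=bool)
    prev_win[1:] = r[:-1] == 1
    out = {}
    undefined = []
    for label, cell in (("stay_given_reward", valid & prev_win),
                        ("stay_given_no_reward", valid & ~prev_win)):
        n = int(cell.sum())
        if n == 0:
            out[label] = float("nan")
            undefined.append(label)
        else:
            out[label] = float(stay[cell].mean())
        out[f"n_{label}"] = n
    out["undefined"] = tuple(undefined)
    return out


def performance_curves(datasets, task, window: int = 10) -> dict:
    """Per-trial p(correct) averaged over sessions, plus early/late means.

    "Correct" is the option with the uniquely highest reward probability on
    that trial (for stimulus tasks, the rewarded action of the shown
    stimulus).  ``window`` trials at each end give the early/late summary
    (default 10).
    """
    if isinstance(datasets, BehavioralDataset):
        datasets = [datasets]
    correct = task.correct_arm()
    hits = []
    for ds in datasets:
        if ds.n_trials != task.n_trials:
            raise ValueError("dataset length does not match the task")
        hits.append((ds.choices == correct).astype(float))
    curve = np.mean(hits, axis=0)
    w = min(window, curve.size)
    return {
        "learning_curve": curve,
        "perf_early": float(curve[:w].mean()),
        "perf_late": float(curve[-w:].mean()),
        "window": w,
        "n_sessions": len(hits),
    }


def average_trial_likelihood(params, model, dataset: BehavioralDataset) -> float:
    """Geometric-mean per-trial likelihood, exp(LL / T).

    An absolute measure of fit: 1 only for perfect prediction, 1/K for a
    K-option uniform guesser.  Shares the likelihood code path with
    fitting, so ``exp(-nll / T)`` holds exactly.
    """
    model = get_model(model)
    return math.exp(-model.nll(params, dataset) / dataset.n_trials)


def arithmetic_trial_likelihood(params, model, dataset: BehavioralDataset) -> float:
    """Arithmetic mean of the per-trial likelihoods (companion measure)."""
    model = get_model(model)
    return float(model.trial_probabilities(params, dataset).mean())


def one_step_predictions(params, model, dataset: BehavioralDataset) -> np.ndarray:
    """Per-trial p(c_t | d_{1:t-1}, s_t, theta) given the subject's history."""
    return get_model(model).trial_probabilities(params, dataset)


@dataclass
class ValidationReport:
    """Observed vs simulated model-independent measures, with bands.

    ``observed`` and ``simulated`` hold the same scalar measures;
    simulated entries map measure -> (2.5%, 50%, 97.5%) quantiles across
    simulations.  Learning curves are per-trial p(correct): the observed
    curve, the across-simulation mean, and central-95% band edges.
    """

    observed: dict
    simulated: dict
    observed_curve: np.ndarray
    simulated_curve_mean: np.ndarray
    simulated_curve_lo: np.ndarray
    simulated_curve_hi: np.ndarray
    n_sims: int
    avg_trial_likelihood: float

    def measure_inside_band(self, name: str) -> bool:
        lo, _, hi = self.simulated[name]
        return bool(lo <= self.observed[name] <= hi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": self.observed,
                "simulated_quantiles": {k: list(v) for k, v in self.simulated.items()},
                "observed_curve": self.observed_curve.tolist(),
                "simulated_curve_mean": self.simulated_curve_mean.tolist(),
                "simulated_curve_lo": self.simulated_curve_lo.tolist(),
                "simulated_curve_hi": self.simulated_curve_hi.tolist(),
                "n_sims": self.n_sims,
                "avg_trial_likelihood": self.avg_trial_likelihood,
            },
            indent=2,
        )


_MEASURES = ("stay_given_reward", "stay_given_no_reward", "perf_early", "perf_late")


def _session_measures(dataset: BehavioralDataset, task, window: int) -> dict:
    stay = stay_probability(dataset)
    perf = performance_curves(dataset, task, window=window)
    return {
        "stay_given_reward": stay["stay_given_reward"],
        "stay_given_no_reward": stay["stay_given_no_reward"],
        "perf_early": perf["perf_early"],
        "perf_late": perf["perf_late"],
    }, perf["learning_curve"]


def posterior_predictive(params, model, task, n_sims: int,
                         seed, observed: BehavioralDataset,
                         window: int = 10) -> ValidationReport:
    """Posterior predictive check at the (typically fitted) parameters.

    Simulates ``n_sims`` sessions, computes the model-independent measures
    on simulated and observed data alike, and reports simulation-band
    quantiles next to the observed values.  Reproducible bit-exactly for a
    fixed integer seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    model = get_model(model)
    observed_measures, observed_curve = _session_measures(observed, task, window)
    rng = np.random.default_rng(seed)
    sim_rows = []
    sim_curves = []
    for _ in range(n_sims):
        sim = model.simulate(params, task, rng)
        measures, curve = _session_measures(sim, task, window)
        sim_rows.append(measures)
        sim_curves.append(curve)
    frame = pd.DataFrame(sim_rows)
    quantiles = {
        name: tuple(np.nanquantile(frame[name], [0.025, 0.5, 0.975]))
        for name in _MEASURES
    }
    curves = np.vstack(sim_curves)
    return ValidationReport(
        observed=observed_measures,
        simulated=quantiles,
        observed_curve=observed_curve,
        simulated_curve_mean=curves.mean(axis=0),
        simulated_curve_lo=np.quantile(curves, 0.025, axis=0),
        simulated_curve_hi=np.quantile(curves, 0.975, axis=0),
        n_sims=n_sims,
        avg_trial_likelihood=average_trial_likelihood(params, model, observed),
    )


@dataclass
class LatentTrajectories:
    """Trial-by-trial hidden variables from a yoked replay.

    All arrays are aligned to the input dataset's trials and recorded
    *before* the trial's update: ``q_values[t]`` is the value state the
    model held when choice t was made, ``prediction_errors[t] = r_t -
    Q_t(c_t)`` is the delta-rule learning signal, and
    ``choice_probabilities[t]`` the model's probability vector over
    options.  Deterministic functions of (dataset, params): no choice
    sampling occurs.
    """

    q_values: np.ndarray
    choice_kernels: np.ndarray
    prediction_errors: np.ndarray
    choice_probabilities: np.ndarray
    chosen_probabilities: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.prediction_errors.size


def extract_latents(params, model, dataset: BehavioralDataset) -> LatentTrajectories:
    """Replay the subject's own choices/outcomes through the model.

    The model's choices are yoked to the dataset: its state evolves
    according to the experience the subject actually had, which is the
    right conditioning for relating latent variables (values, prediction
    errors) to trial-by-trial physiological or behavioral signals.
    """
    model = get_model(model)
    vec = model.coerce_params(params)
    task = dataset.task
    if model.requires_stimuli and task is None:
        raise ValueError(f"{model.model_id} needs the dataset's stimulus task")
    if task is not None:
        state = model.initial_state(task)
    else:
        n = dataset.n_options
        state = model.initial_state(_BareBandit(n))
    starts = dataset.block_start_mask()
    T = dataset.n_trials
    q_traj = np.empty((T,) + state.q_values.shape)
    ck_traj = np.empty((T,) + state.choice_kernel.shape)
    pe = np.empty(T)
    probs = np.empty((T, dataset.n_options))
    chosen = np.empty(T)
    fresh = state
    for t in range(T):
        if t > 0 and starts[t]:
            state = fresh = model.initial_state(task if task is not None
                                                else _BareBandit(dataset.n_options))
        stim = int(dataset.stimuli[t]) if dataset.stimuli is not None else None
        c = int(dataset.choices[t])
        r = int(dataset.rewards[t])
        q_traj[t] = state.q_values
        ck_traj[t] = state.choice_kernel
        p = model.choice_probs(vec, state, stim)
        probs[t] = p
        chosen[t] = p[c]
        if state.q_values.ndim == 2:
            pe[t] = r - state.q_values[stim, c]
        else:
            pe[t] = r - state.q_values[c]
        model.update_state(vec, state, c, r, stim)
    return LatentTrajectories(
        q_values=q_traj, choice_kernels=ck_traj, prediction_errors=pe,
        choice_probabilities=probs, chosen_probabilities=chosen,
    )


class _BareBandit:
    """Minimal stand-in task carrying only the option count."""

    def __init__(self, n_arms: int):
        self.n_arms = n_arms
        self.block_bounds = None
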