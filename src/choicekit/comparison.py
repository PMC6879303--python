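"""BIC model comparison and model-recovery audits.

Model selection uses the Bayesian information criterion,
``BIC = -2 LL + k ln(T)``, with the best-fitting log-likelihood ``LL``, the
model's free-parameter count ``k`` and the number of trials ``T``.  Whether
selection can be trusted is itself an empirical question, answered by a
model-recovery experiment: simulate each candidate model, fit every
candidate to every simulated dataset, and tally which model wins.  The
result is a confusion matrix p(fit model | simulated model); Bayes rule
turns it into the inversion matrix p(simulated model | fit model), which is
what one actually wants to know after fitting real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BehavioralDataset
from .fitting import FitOptions, FitResult, fit_mle
from .models import ChoiceModel, get_model

__all__ = [
    "bic",
    "ComparisonResult",
    "compare_models",
    "ConfusionMatrix",
    "InversionMatrix",
    "model_recovery",
    "invert_confusion",
]

_BIC_TIE_TOL = 1e-6


def bic(best_loglik: float, k: int, n_trials: int) -> float:
    """Bayesian information criterion, natural log: -2*LL + k*ln(T)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if k < 0:
        raise ValueError("parameter count must be >= 0")
    return -2.0 * best_loglik + k * np.log(n_trials)


@dataclass
class ComparisonResult:
    """Per-model fit scores and the BIC-selected model."""

    table: pd.DataFrame  # columns: model_id, k, loglik, bic
    selected_model: str
    fits: dict[str, FitResult]

    def summary(self) -> str:
        lines = ["Model comparison (smaller BIC is better)", "=" * 44]
        lines.append(f"{'model':<10}{'k':>4}{'loglik':>14}{'BIC':>14}")
        for _, row in self.table.iterrows():
            marker = " *" if row.model_id == self.selected_model else ""
            lines.append(
                f"{row.model_id:<10}{int(row.k):>4}{row.loglik:>14.4f}"
                f"{row.bic:>14.4f}{marker}"
            )
        lines.append("=" * 44)
        lines.append(f"selected: {self.selected_model}")
        return "\n".join(lines)


def compare_models(dataset: BehavioralDataset, models,
                   options: FitOptions | None = None) -> ComparisonResult:
    """Fit every candidate model and select the smallest BIC.

    Ties within 1e-6 are broken toward the model with fewer parameters.
    A model whose fit fails is excluded with a warning; if every model
    fails, a ``RuntimeError`` is raised.
    """
    instances = [get_model(m) for m in models]
    if not instances:
        raise ValueError("need at least one candidate model")
    rows = []
    fits = {}
    for model in instances:
        try:
            fit = fit_mle(model, dataset, options)
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"fit of {model.model_id} failed: {err}", stacklevel=2)
            continue
        fits[model.model_id] = fit
        rows.append(
            {"model_id": model.model_id, "k": model.k,
             "loglik": fit.best_loglik, "bic": fit.bic}
        )
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    contenders = table[table["bic"] <= best_bic + _BIC_TIE_TOL]
    selected = contenders.sort_values(["k", "bic"]).iloc[0]["model_id"]
    return ComparisonResult(table=table, selected_model=str(selected), fits=fits)


@dataclass
class ConfusionMatrix:
    """p(fit model | simulated model) from a simulate-then-fit experiment."""

    models: tuple[str, ...]
    counts: np.ndarray  # (sim, fit) integer tallies
    n_reps: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.models)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the model list")
        if np.any(self.counts < 0) or np.any(self.counts.sum(axis=1) != self.n_reps):
            raise ValueError("each row must tally exactly n_reps simulations")

    @property
    def probabilities(self) -> np.ndarray:
        """Row-stochastic matrix; rows index the simulating model."""
        return self.counts / self.n_reps

    def diagonal(self) -> dict[str, float]:
        return dict(zip(self.models, np.diag(self.probabilities)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=list(self.models),
                            columns=list(self.models))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_reps: int) -> "ConfusionMatrix":
        counts = np.rint(frame.to_numpy() * n_reps).astype(np.int64)
        return cls(models=tuple(frame.index), counts=counts, n_reps=n_reps)


@dataclass
class InversionMatrix:
    """p(simulated model | fit model), from Bayes rule on a confusion matrix.

    ``probabilities[i, j]`` is p(sim = models[i] | fit = models[j]); each
    column with non-zero fit-model mass sums to 1.  Columns for models that
    never win are undefined (NaN) and listed in ``undefined_columns``.
    """

    models: tuple[str, ...]
    probabilities: np.ndarray
    model_prior: np.ndarray
    undefined_columns: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=list(self.models),
                            columns=list(self.models))


def invert_confusion(cm: ConfusionMatrix, model_prior=None) -> InversionMatrix:
    """Apply Bayes rule: p(sim=A | fit=B) ∝ p(fit=B | sim=A) p(A).

    ``model_prior`` defaults to uniform over the candidate models.
    """
    n = len(cm.models)
    if model_prior is None:
        prior = np.full(n, 1.0 / n)
    else:
        prior = np.asarray(model_prior, dtype=float)
        if prior.shape != (n,) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("model_prior must be a length-n simplex vector")
    joint = cm.probabilities * prior[:, None]
    fit_marginal = joint.sum(axis=0)
    probs = np.full((n, n), np.nan)
    nonzero = fit_marginal > 0
    probs[:, nonzero] = joint[:, nonzero] / fit_marginal[nonzero]
    undefined = tuple(m for m, ok in zip(cm.models, nonzero) if not ok)
    return InversionMatrix(models=cm.models, probabilities=probs,
                           model_prior=prior, undefined_columns=undefined)


def model_recovery(models, priors=None, n_reps: int = 100,
                   task=None, options: FitOptions | None = None,
                   seed: int = 0) -> ConfusionMatrix:
    """Simulate-then-fit audit of BIC model selection.

    For each candidate model: draw parameters from its prior, simulate a
    session on ``task``, fit every candidate, and tally the BIC winner.
    ``priors`` maps model id -> {param -> prior}; unspecified models use
    their default priors.

    Returns the confusion matrix with rows indexing the simulating model.
    """
    from .recovery import sample_parameters

    instances = [get_model(m) for m in models]
    ids = [m.model_id for m in instances]
    if task is None:
        raise ValueError("a task configuration is required")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    priors = priors or {}
    base = options or FitOptions()
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    master = np.random.SeedSequence(seed)
    for i, sim_model in enumerate(instances):
        model_priors = priors.get(sim_model.model_id, sim_model.default_priors())
        for rep, child in enumerate(master.spawn(n_reps)):
            rng = np.random.default_rng(child)
            params = sample_parameters(sim_model, model_priors, rng)
            dataset = sim_model.simulate(params, task, rng)
            dataset.agent_id = f"{sim_model.model_id}-rep{rep}"
            rep_options = FitOptions(
                n_starts=base.n_starts, bounds=base.bounds,
                start_sampler=base.start_sampler, prob_floor=base.prob_floor,
                tolerance=base.tolerance,
                seed=int(rng.integers(2**31)),
            )
            winner = compare_models(dataset, instances, rep_options).selected_model
            counts[i, ids.index(winner)] += 1
    return ConfusionMatrix(models=tuple(ids), counts=counts, n_reps=n_reps)
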