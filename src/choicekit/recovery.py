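"""Parameter-recovery audits: simulate with known parameters, refit, compare.

Good recovery — a tight, unbiased relation between simulated and fitted
parameter values — is a precondition for interpreting fits to real data.
Poor recovery can reflect a bug, an underpowered design, or a parameter
regime (e.g. extreme inverse temperatures) where behavior is insensitive to
the parameter.  ``compare_nested_recovery`` additionally quantifies how
omitting a nuisance parameter (such as a side bias) from the fitted model
degrades recovery of the parameters of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitOptions, fit_mle
from .models import ChoiceModel, get_model

__all__ = [
    "sample_parameters",
    "RecoveryReport",
    "recover_parameters",
    "flag_poor_recovery",
    "compare_nested_recovery",
]


def sample_parameters(model: str | ChoiceModel, priors: dict,
                      rng: np.random.Generator) -> dict:
    """Draw one parameter set from independent per-parameter priors."""
    model = get_model(model)
    missing = set(model.param_names) - set(priors)
    if missing:
        raise ValueError(f"missing priors for {sorted(missing)}")
    return {name: priors[name].sample(rng) for name in model.param_names}


def _safe_corr(x: np.ndarray, y: np.ndarray, kind: str = "pearson") -> float:
    """Correlation that returns NaN (instead of raising) on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if kind == "spearman":
        x = pd.Series(x).rank().to_numpy()
        y = pd.Series(y).rank().to_numpy()
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RecoveryReport:
    """Replicate-level simulated vs fitted parameters plus summaries.

    ``records`` has one row per replicate with columns ``sim_<param>``,
    ``fit_<param>`` and ``loglik``.  Summaries report Pearson and Spearman
    correlations and mean signed bias (fit - sim) per parameter, and the
    correlations *among* fitted parameters (trade-off diagnostics).
    """

    model_id: str
    param_names: tuple[str, ...]
    records: pd.DataFrame
    n_failed: int = 0

    def correlation(self, param: str, kind: str = "pearson") -> float:
        return _safe_corr(self.records[f"sim_{param}"],
                          self.records[f"fit_{param}"], kind)

    def bias(self, param: str) -> float:
        return float((self.records[f"fit_{param}"]
                      - self.records[f"sim_{param}"]).mean())

    def summaries(self) -> pd.DataFrame:
        rows = []
        for p in self.param_names:
            rows.append(
                {
                    "param": p,
                    "pearson_r": self.correlation(p),
                    "spearman_r": self.correlation(p, "spearman"),
                    "mean_bias": self.bias(p),
                }
            )
        return pd.DataFrame(rows)

    def fitted_correlations(self) -> pd.DataFrame:
        """Pairwise correlations of the *fitted* values across replicates."""
        cols = [f"fit_{p}" for p in self.param_names]
        mat = np.full((len(cols), len(cols)), np.nan)
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                mat[i, j] = _safe_corr(self.records[a], self.records[b])
        return pd.DataFrame(mat, index=list(self.param_names),
                            columns=list(self.param_names))

    def scatter_frame(self, flag_param: str | None = None,
                      flag_threshold: float = np.inf) -> pd.DataFrame:
        """Long-format table (replicate, param, sim, fit, flagged) for plotting."""
        flagged_idx = set()
        if flag_param is not None:
            flagged_idx = set(flag_poor_recovery(self, flag_param, flag_threshold))
        rows = []
        for idx, row in self.records.iterrows():
            for p in self.param_names:
                rows.append(
                    {
                        "replicate": int(idx),
                        "param": p,
                        "sim": row[f"sim_{p}"],
                        "fit": row[f"fit_{p}"],
                        "flagged": int(idx) in flagged_idx,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "n_replicates": int(len(self.records)),
                "n_failed": self.n_failed,
                "summaries": self.summaries().to_dict(orient="records"),
                "fitted_correlations": self.fitted_correlations().to_dict(),
                "records": self.records.to_dict(orient="records"),
            },
            indent=2,
        )


def recover_parameters(model: str | ChoiceModel, priors: dict | None = None,
                       n_reps: int = 1000, task=None,
                       options: FitOptions | None = None,
                       seed: int = 0) -> RecoveryReport:
    """Simulate-then-fit ``n_reps`` sessions with fresh parameter draws.

    Individual fit failures are excluded from the records and counted in
    ``n_failed``.
    """
    model = get_model(model)
    if task is None:
        raise ValueError("a task configuration is required")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    priors = priors or model.default_priors()
    base = options or FitOptions()
    rows = []
    n_failed = 0
    master = np.random.SeedSequence(seed)
    for rep, child in enumerate(master.spawn(n_reps)):
        rng = np.random.default_rng(child)
        sim_params = sample_parameters(model, priors, rng)
        dataset = model.simulate(sim_params, task, rng)
        dataset.agent_id = f"{model.model_id}-rep{rep}"
        rep_options = FitOptions(
            n_starts=base.n_starts, bounds=base.bounds,
            start_sampler=base.start_sampler, prob_floor=base.prob_floor,
            tolerance=base.tolerance, seed=int(rng.integers(2**31)),
        )
        try:
            fit = fit_mle(model, dataset, rep_options)
        except RuntimeError:
            n_failed += 1
            continue
        row = {"replicate": rep, "loglik": fit.best_loglik}
        for p in model.param_names:
            row[f"sim_{p}"] = sim_params[p]
            row[f"fit_{p}"] = fit.best_params[p]
        rows.append(row)
    records = pd.DataFrame(rows).set_index("replicate")
    return RecoveryReport(model_id=model.model_id,
                          param_names=model.param_names,
                          records=records, n_failed=n_failed)


def flag_poor_recovery(report: RecoveryReport, parameter: str,
                       threshold: float) -> np.ndarray:
    """Replicate indices where |simulated - fitted| exceeds ``threshold``."""
    if parameter not in report.param_names:
        raise ValueError(f"{parameter!r} is not a parameter of {report.model_id}")
    err = (report.records[f"sim_{parameter}"]
           - report.records[f"fit_{parameter}"]).abs()
    return report.records.index[err > threshold].to_numpy()


def compare_nested_recovery(model_full, model_reduced, generating_model=None,
                            priors: dict | None = None, n_reps: int = 100,
                            task=None, options: FitOptions | None = None,
                            seed: int = 0) -> dict[str, RecoveryReport]:
    """Recovery with and without a nuisance parameter in the fitted model.

    Data are simulated from ``generating_model`` (default: the full model)
    and fitted by both the full and the reduced model; the reduced model's
    parameters must be a subset of the full model's.  Returns one
    :class:`RecoveryReport` per fitted model, keyed by model id; the
    reduced report covers the shared parameters only.
    """
    full = get_model(model_full)
    reduced = get_model(model_reduced)
    gen = full if generating_model is None else get_model(generating_model)
    if not set(reduced.param_names) <= set(full.param_names):
        raise ValueError("reduced model's parameters must nest in the full model's")
    if task is None:
        raise ValueError("a task configuration is required")
    priors = priors or gen.default_priors()
    base = options or FitOptions()
    rows = {full.model_id: [], reduced.model_id: []}
    failed = {full.model_id: 0, reduced.model_id: 0}
    master = np.random.SeedSequence(seed)
    for rep, child in enumerate(master.spawn(n_reps)):
        rng = np.random.default_rng(child)
        sim_params = sample_parameters(gen, priors, rng)
        dataset = gen.simulate(sim_params, task, rng)
        dataset.agent_id = f"{gen.model_id}-rep{rep}"
        for fit_model in (full, reduced):
            rep_options = FitOptions(
                n_starts=base.n_starts, bounds=base.bounds,
                start_sampler=base.start_sampler, prob_floor=base.prob_floor,
                tolerance=base.tolerance, seed=int(rng.integers(2**31)),
            )
            try:
                fit = fit_mle(fit_model, dataset, rep_options)
            except RuntimeError:
                failed[fit_model.model_id] += 1
                continue
            row = {"replicate": rep, "loglik": fit.best_loglik}
            for p in fit_model.param_names:
                if p in sim_params:
                    row[f"sim_{p}"] = sim_params[p]
                row[f"fit_{p}"] = fit.best_params[p]
            rows[fit_model.model_id].append(row)
    reports = {}
    for fit_model in (full, reduced):
        mid = fit_model.model_id
        records = pd.DataFrame(rows[mid]).set_index("replicate")
        shared = tuple(p for p in fit_model.param_names if f"sim_{p}" in records)
        reports[mid] = RecoveryReport(model_id=mid, param_names=shared,
                                      records=records, n_failed=failed[mid])
    return reports
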