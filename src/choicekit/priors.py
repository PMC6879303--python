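"""Prior distributions for simulation parameters and optimizer starts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Uniform", "ExponentialMean", "shift_softmax_priors"]


@dataclass(frozen=True)
class Uniform:
    """Uniform(lo, hi)."""

    lo: float = 0.0
    hi: float = 1.0

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class ExponentialMean:
    """Exponential distribution parameterised by its MEAN, plus a shift.

    ``ExponentialMean(1.0)`` has mean 1 (rate 1); ``ExponentialMean(1.0,
    shift=1.0)`` is the same distribution translated up by 1.  The mean
    parameterisation is explicit because Exp(λ) is ambiguous between rate
    and mean readings.
    """

    mean_: float = 1.0
    shift: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.shift + rng.exponential(self.mean_))

    @property
    def mean(self) -> float:
        return self.mean_ + self.shift


def shift_softmax_priors(priors: dict, delta: float = 1.0) -> dict:
    """Return a copy with every inverse-temperature prior shifted by ``delta``.

    Applies to parameters named ``beta`` and ``beta_c``; used to move between
    a high-noise and a low-noise simulation regime.
    """
    out = {}
    for name, prior in priors.items():
        if name in ("beta", "beta_c"):
            if isinstance(prior, ExponentialMean):
                out[name] = ExponentialMean(prior.mean_, prior.shift + delta)
            elif isinstance(prior, Uniform):
                out[name] = Uniform(prior.lo + delta, prior.hi + delta)
            else:
                raise TypeError(f"cannot shift prior of type {type(prior)!r}")
        else:
            out[name] = prior
    return out
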