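"""Synthetic cohorts with planted per-SD logistic effects."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["CohortSimParams", "gen_cohort", "solve_intercept"]


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator parameters.

    ``or_per_sd`` maps feature name -> odds ratio per SD of that feature;
    features are drawn standard-normal so per-SD and per-unit coincide.
    """

    n: int
    event_rate: float
    or_per_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 < self.event_rate < 1.0:
            raise ValueError("event_rate must lie strictly in (0, 1)")
        for name, orr in self.or_per_sd.items():
            if orr <= 0:
                raise ValueError(f"odds ratio for {name!r} must be positive, got {orr}")


def solve_intercept(X: np.ndarray, beta: np.ndarray, target_rate: float) -> float:
    """Intercept b0 such that mean(expit(b0 + X @ beta)) == target_rate."""
    eta = X @ beta if X.size else np.zeros(len(X))

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target_rate

    return brentq(f, -30.0, 30.0, xtol=1e-12)


def gen_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Standard-normal features + Bernoulli outcome from a logistic model.

    The intercept is solved numerically on the drawn design so the expected
    event rate matches ``params.event_rate`` exactly (the realised rate then
    fluctuates binomially).  Planted log-odds per SD equal ln(or_per_sd).
    """
    rng = np.random.default_rng(params.seed)
    names = list(params.or_per_sd)
    X = rng.standard_normal((params.n, len(names)))
    beta = np.log([params.or_per_sd[k] for k in names]) if names else np.zeros(0)
    b0 = solve_intercept(X, beta, params.event_rate)
    p = expit(b0 + (X @ beta if names else 0.0))
    y = rng.random(params.n) < p

    df = pd.DataFrame(X, columns=names)
    df.insert(0, "patient_id", [f"pt_{i:05d}" for i in range(params.n)])
    df["outcome"] = y.astype(int)
    df.attrs["intercept"] = b0
    df.attrs["log_or"] = dict(zip(names, np.atleast_1d(beta)))
    return df
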