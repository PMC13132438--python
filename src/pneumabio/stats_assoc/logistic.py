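"""Per-SD simple logistic odds ratios (Wald CIs)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = ["OrRow", "logistic_or_per_sd"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class OrRow:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    p_value: float
    scaling: str                 # "per_sd" | "binary"
    n: int
    status: str = "ok"           # "ok" | "separation"


def logistic_or_per_sd(
    values,
    outcome,
    feature: str = "feature",
    binary: bool = False,
) -> OrRow:
    """Simple logistic regression of a binary outcome on one feature.

    Continuous features are standardised to unit sample SD (ddof 1) before
    the fit so the OR is per SD increase; binary features are left unscaled.
    Wald 95% CI = exp(beta +/- 1.96 * SE).  Complete separation returns a
    ``status='separation'`` row (NaN estimates) pointing at firth_logistic.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise ValueError("feature and outcome must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    scaling = "binary" if binary else "per_sd"
    if not binary:
        sd = np.std(x, ddof=1)
        if sd == 0:
            raise ValueError(f"feature {feature!r} is constant")
        x = (x - np.mean(x)) / sd

    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or np.abs(fit.params[1]) > 20:
            raise PerfectSeparationError("implausible slope; treating as separation")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return OrRow(
            feature=feature, odds_ratio=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), beta=float("nan"), se=float("nan"),
            p_value=float("nan"), scaling=scaling, n=len(y), status="separation",
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return OrRow(
        feature=feature,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        beta=beta,
        se=se,
        p_value=float(fit.pvalues[1]),
        scaling=scaling,
        n=len(y),
    )
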