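"""Random-intercept linear mixed models for beat-level features."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fdr import bh_fdr

__all__ = ["MixedModelResult", "lmm_random_intercept"]


@dataclass
class MixedModelResult:
    """Per-feature fixed effects from response ~ outcome + (1 | patient)."""

    table: pd.DataFrame          # feature, beta, se, p_raw, q, re_var, resid_var
    n_beats: int
    n_patients: int

    def __getitem__(self, feature: str) -> pd.Series:
        return self.table.set_index("feature").loc[feature]


def lmm_random_intercept(
    features: pd.DataFrame,
    outcome: Sequence[int] | np.ndarray | pd.Series,
    patient_ids: Sequence | np.ndarray | pd.Series,
    feature_cols: Sequence[str] | None = None,
    standardise: bool = True,
    reml: bool = True,
) -> MixedModelResult:
    """Fit, per feature, a REML linear mixed model with the (standardised)
    feature as response, the binary outcome as fixed effect, and a patient
    random intercept.  q-values are BH-adjusted across features.

    ``outcome`` is beat-level but must be constant within each patient;
    each outcome group needs at least 2 patients.
    """
    y_out = np.asarray(outcome, dtype=float)
    pid = np.asarray(patient_ids)
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c not in ("patient_id", "lead")]
    if len(y_out) != len(features) or len(pid) != len(features):
        raise ValueError("features, outcome and patient_ids must align row-wise")

    per_patient = pd.DataFrame({"pid": pid, "y": y_out}).groupby("pid")["y"].nunique()
    if (per_patient > 1).any():
        raise ValueError("outcome label varies within a patient")
    patient_outcome = pd.DataFrame({"pid": pid, "y": y_out}).groupby("pid")["y"].first()
    for cls in (0.0, 1.0):
        if (patient_outcome == cls).sum() < 2:
            raise ValueError(
                f"degenerate design: fewer than 2 patients with outcome {int(cls)}"
            )

    rows = []
    for col in feature_cols:
        resp = features[col].to_numpy(dtype=float)
        ok = np.isfinite(resp)
        r, o, g = resp[ok], y_out[ok], pid[ok]
        if standardise:
            sd = np.std(r, ddof=1)
            if sd > 0:
                r = (r - np.mean(r)) / sd
        if np.std(r) == 0:
            rows.append({"feature": col, "beta": 0.0, "se": 0.0, "p_raw": 1.0,
                         "re_var": 0.0, "resid_var": 0.0})
            continue
        exog = sm.add_constant(o)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(r, exog, groups=g)
            fit = model.fit(reml=reml, maxiter=500)
        rows.append({
            "feature": col,
            "beta": float(fit.fe_params[1]),
            "se": float(fit.bse_fe[1]),
            "p_raw": float(fit.pvalues[1]),
            "re_var": float(np.asarray(fit.cov_re)[0, 0]),
            "resid_var": float(fit.scale),
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p_raw"].to_numpy())
    table = table[["feature", "beta", "se", "p_raw", "q", "re_var", "resid_var"]]
    return MixedModelResult(
        table=table, n_beats=len(features), n_patients=int(patient_outcome.size)
    )
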