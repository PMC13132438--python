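"""Descriptive group-comparison ("table one") builder."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranks import rank_compare

__all__ = ["table_one"]


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk for n < 50, D'Agostino-Pearson otherwise."""
    x = x[np.isfinite(x)]
    if x.size < 3 or np.std(x) == 0:
        return False
    try:
        if x.size < 50:
            p = stats.shapiro(x).pvalue
        else:
            p = stats.normaltest(x).pvalue
    except Exception:
        return False
    return bool(p > alpha)


def _fisher_needed(tbl: np.ndarray) -> bool:
    """Fisher when any expected cell count is below 5."""
    total = tbl.sum()
    if total == 0:
        return True
    expected = np.outer(tbl.sum(axis=1), tbl.sum(axis=0)) / total
    return bool((expected < 5).any())


def table_one(
    cohort: pd.DataFrame,
    group_col: str,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable descriptive comparison between two groups.

    Continuous variables: median [Q1, Q3] per group with a Mann-Whitney
    p-value (means and a t-test when both groups screen normal).
    Categorical variables (<= 10 unique non-numeric or binary values):
    n (%) with Fisher's exact test when any expected cell is < 5, else
    chi-squared.
    """
    groups = cohort[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"group column {group_col!r} must be binary")
    g0, g1 = sorted(groups)
    if variables is None:
        variables = [c for c in cohort.columns if c != group_col]

    rows = []
    for var in variables:
        col = cohort[var]
        in0 = cohort[group_col] == g0
        in1 = cohort[group_col] == g1
        numeric = pd.api.types.is_numeric_dtype(col)
        n_unique = col.nunique(dropna=True)
        categorical = (not numeric) or n_unique <= 2
        if categorical:
            # compare distribution of categories between groups
            tbl = pd.crosstab(col, cohort[group_col]).to_numpy()
            if tbl.size == 0 or tbl.shape[0] < 2:
                p, test = 1.0, "degenerate"
            elif tbl.shape == (2, 2) and _fisher_needed(tbl):
                p, test = float(stats.fisher_exact(tbl)[1]), "fisher"
            else:
                try:
                    p = float(stats.chi2_contingency(tbl)[1])
                    test = "chi2"
                except ValueError:
                    p, test = 1.0, "degenerate"
            top = col.value_counts().index[0] if n_unique else None
            for level in sorted(col.dropna().unique(), key=str):
                n_all = int((col == level).sum())
                rows.append({
                    "variable": var, "level": str(level), "type": "categorical",
                    "overall": f"{n_all} ({100.0 * n_all / len(col):.1f})",
                    f"group_{g0}": f"{int(((col == level) & in0).sum())} "
                                   f"({100.0 * ((col == level) & in0).sum() / max(in0.sum(), 1):.1f})",
                    f"group_{g1}": f"{int(((col == level) & in1).sum())} "
                                   f"({100.0 * ((col == level) & in1).sum() / max(in1.sum(), 1):.1f})",
                    "p_value": p, "test": test,
                })
        else:
            x0 = col[in0].to_numpy(dtype=float)
            x1 = col[in1].to_numpy(dtype=float)
            x0 = x0[np.isfinite(x0)]
            x1 = x1[np.isfinite(x1)]
            if np.std(col.to_numpy(dtype=float)) == 0:
                p, test = 1.0, "degenerate"
                summ = lambda x: f"{np.median(x):.1f} [{np.percentile(x, 25):.1f}, {np.percentile(x, 75):.1f}]"
            elif _is_normal(x0) and _is_normal(x1):
                p = float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)
                test = "t"
                summ = lambda x: f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})"
            else:
                p = rank_compare(x0, x1).p_value
                test = "mannwhitney"
                summ = lambda x: f"{np.median(x):.1f} [{np.percentile(x, 25):.1f}, {np.percentile(x, 75):.1f}]"
            rows.append({
                "variable": var, "level": "", "type": "continuous",
                "overall": summ(np.concatenate([x0, x1])),
                f"group_{g0}": summ(x0), f"group_{g1}": summ(x1),
                "p_value": p, "test": test,
            })
    return pd.DataFrame(rows)
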