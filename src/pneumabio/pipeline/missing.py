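"""Per-variable missingness report."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["missingness_report"]


def missingness_report(
    table: pd.DataFrame,
    threshold: float = 0.20,
    subset_col: str | None = None,
) -> pd.DataFrame:
    """Fraction of missing values per column, flagged when STRICTLY above
    ``threshold``.  With ``subset_col`` (boolean), missingness is also
    reported within that subset (e.g. the ECG sub-cohort).
    """
    if table.empty:
        raise ValueError("table is empty")
    rows = []
    subset = table[subset_col].astype(bool) if subset_col else None
    for col in table.columns:
        if col == subset_col:
            continue
        frac = float(table[col].isna().mean())
        row = {
            "variable": col,
            "missing_frac": frac,
            "missing_pct": 100.0 * frac,
            "flagged": bool(frac > threshold),
        }
        if subset is not None and subset.any():
            sub_frac = float(table.loc[subset, col].isna().mean())
            row["missing_frac_subset"] = sub_frac
            row["flagged_subset"] = bool(sub_frac > threshold)
        rows.append(row)
    return pd.DataFrame(rows)
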