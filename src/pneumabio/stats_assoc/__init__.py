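from dataclasses import asdict

import pandas as pd

from .fdr import bh_fdr
from .logistic import OrRow, logistic_or_per_sd
from .firth import FirthResult, firth_logistic, penalised_loglik
from .mixed import MixedModelResult, lmm_random_intercept
from .permutation import PermutationResult, pointwise_permutation
from .ranks import RankCompareResult, rank_compare
from .tableone import table_one

__all__ = [
    "bh_fdr",
    "OrRow",
    "logistic_or_per_sd",
    "FirthResult",
    "firth_logistic",
    "penalised_loglik",
    "MixedModelResult",
    "lmm_random_intercept",
    "PermutationResult",
    "pointwise_permutation",
    "RankCompareResult",
    "rank_compare",
    "table_one",
    "association_table",
]


def association_table(rows: list[OrRow], apply_fdr: bool = False) -> pd.DataFrame:
    """Assemble OrRow results into a long-format table.

    No multiplicity correction by default (the primary bivariate table is
    uncorrected); pass ``apply_fdr=True`` to add BH q-values.
    """
    df = pd.DataFrame([asdict(r) for r in rows])
    if apply_fdr and len(df):
        ok = df["status"] == "ok"
        q = pd.Series(float("nan"), index=df.index)
        if ok.any():
            q.loc[ok] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
        df["q_value"] = q
    return df
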