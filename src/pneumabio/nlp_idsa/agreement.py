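"""Agreement statistics: per-criterion confusion matrices and Cohen's kappa."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dictionary import CRITERIA

__all__ = ["CriterionAgreement", "AgreementReport", "cohen_kappa", "agreement_stats"]


@dataclass(frozen=True)
class CriterionAgreement:
    criterion: str
    tp: int
    fp: int
    fn: int
    tn: int
    agreement_pct: float
    kappa: float              # NaN when degenerate (p_e = 1)
    kappa_ci: tuple[float, float]
    kappa_status: str         # "ok" | "undefined"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementReport:
    per_criterion: dict[str, CriterionAgreement]
    overall_kappa: float
    overall_kappa_ci: tuple[float, float]
    n_notes: int
    human_kappa: float | None = None
    human_kappa_ci: tuple[float, float] | None = None

    def total_fp(self) -> int:
        return sum(c.fp for c in self.per_criterion.values())

    def total_fn(self) -> int:
        return sum(c.fn for c in self.per_criterion.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(c) for c in self.per_criterion.values()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_criterion": {k: asdict(v) for k, v in self.per_criterion.items()},
            "overall_kappa": self.overall_kappa,
            "overall_kappa_ci": list(self.overall_kappa_ci),
            "n_notes": self.n_notes,
            "human_kappa": self.human_kappa,
            "human_kappa_ci": (
                list(self.human_kappa_ci) if self.human_kappa_ci is not None else None
            ),
        }


def cohen_kappa(tp: int, fp: int, fn: int, tn: int) -> tuple[float, tuple[float, float], str]:
    """Cohen's kappa for a 2x2 confusion matrix with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e); SE = sqrt(p_o (1 - p_o) / (N (1 - p_e)^2)).
    Returns (kappa, (lo, hi), status); status is "undefined" when p_e = 1.
    """
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_yes_a = (tp + fn) / n     # gold positive rate
    p_yes_b = (tp + fp) / n     # prediction positive rate
    p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        return float("nan"), (float("nan"), float("nan")), "undefined"
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(max(p_o * (1 - p_o), 0.0) / (n * (1 - p_e) ** 2))
    return kappa, (kappa - 1.96 * se, kappa + 1.96 * se), "ok"


def _confusion(pred: np.ndarray, gold: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(pred & gold))
    fp = int(np.sum(pred & ~gold))
    fn = int(np.sum(~pred & gold))
    tn = int(np.sum(~pred & ~gold))
    return tp, fp, fn, tn


def agreement_stats(
    predictions: pd.DataFrame,
    gold: pd.DataFrame,
    second_rater: pd.DataFrame | None = None,
    criteria: Sequence[str] = CRITERIA,
) -> AgreementReport:
    """Per-criterion confusion matrices, agreement % and kappa vs gold.

    ``predictions`` and ``gold`` are indexed (or indexable) by ``note_id``
    and carry one boolean column per criterion.  The overall kappa pools the
    per-criterion confusion matrices.  If ``second_rater`` is given, an
    inter-rater kappa (second_rater vs gold, pooled) is reported too.
    """
    pred = _aligned(predictions, gold, criteria)
    gld = _aligned(gold, gold, criteria)

    per: dict[str, CriterionAgreement] = {}
    pooled = np.zeros(4, dtype=int)
    for crit in criteria:
        tp, fp, fn, tn = _confusion(pred[crit].to_numpy(), gld[crit].to_numpy())
        pooled += (tp, fp, fn, tn)
        kappa, ci, status = cohen_kappa(tp, fp, fn, tn)
        per[crit] = CriterionAgreement(
            criterion=crit,
            tp=tp, fp=fp, fn=fn, tn=tn,
            agreement_pct=100.0 * (tp + tn) / (tp + fp + fn + tn),
            kappa=kappa, kappa_ci=ci, kappa_status=status,
        )
    overall_kappa, overall_ci, _ = cohen_kappa(*pooled)

    human_kappa = human_ci = None
    if second_rater is not None:
        rater = _aligned(second_rater, gold, criteria)
        hp = np.zeros(4, dtype=int)
        for crit in criteria:
            hp += _confusion(rater[crit].to_numpy(), gld[crit].to_numpy())
        human_kappa, human_ci, _ = cohen_kappa(*hp)

    return AgreementReport(
        per_criterion=per,
        overall_kappa=overall_kappa,
        overall_kappa_ci=overall_ci,
        n_notes=len(gld),
        human_kappa=human_kappa,
        human_kappa_ci=human_ci,
    )


def _aligned(df: pd.DataFrame, ref: pd.DataFrame, criteria: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    if "note_id" in out.columns:
        out = out.set_index("note_id")
    ref_idx = ref.set_index("note_id").index if "note_id" in ref.columns else ref.index
    if not set(ref_idx).issubset(set(out.index)):
        raise ValueError("prediction/gold note ids are not aligned")
    out = out.loc[ref_idx]
    missing = [c for c in criteria if c not in out.columns]
    if missing:
        raise ValueError(f"missing criterion columns: {missing}")
    return out[list(criteria)].astype(bool)
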