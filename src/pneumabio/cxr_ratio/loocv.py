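"""CAM threshold selection by leave-one-out cross-validation against gold masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ThresholdEvaluation", "dice_coefficient", "threshold_loocv", "default_grid"]


def default_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 0.951, 0.05), 10)


def dice_coefficient(pred: np.ndarray, gold: np.ndarray) -> float:
    """Dice overlap of two binary masks; empty-vs-empty is defined as 1."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gold).astype(bool)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(p & g)) / float(denom)


@dataclass
class ThresholdEvaluation:
    grid: np.ndarray
    selected_threshold: float          # modal LOOCV selection
    per_image_threshold: np.ndarray    # T chosen for each held-out image
    per_image_dice: np.ndarray         # held-out Dice at that T
    per_image_auroc: np.ndarray        # threshold-free pixelwise AUROC
    dice_mean: float = field(init=False)
    dice_sd: float = field(init=False)
    auroc_mean: float = field(init=False)
    auroc_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.dice_mean = float(np.mean(self.per_image_dice))
        self.dice_sd = float(np.std(self.per_image_dice, ddof=1)) if len(self.per_image_dice) > 1 else 0.0
        finite = self.per_image_auroc[np.isfinite(self.per_image_auroc)]
        self.auroc_mean = float(np.mean(finite)) if finite.size else float("nan")
        self.auroc_sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0


def _dice_at(activation: np.ndarray, mask: np.ndarray, gold: np.ndarray, t: float) -> float:
    inside = np.asarray(mask).astype(bool)
    pred = (np.asarray(activation, dtype=float) > t) & inside
    return dice_coefficient(pred[inside], np.asarray(gold).astype(bool)[inside])


def threshold_loocv(
    images: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: np.ndarray | None = None,
) -> ThresholdEvaluation:
    """Select the activation threshold maximising mean Dice, leave-one-out.

    ``images`` is a sequence of (activation, lung_mask, gold_consolidation)
    triples.  For each held-out image the threshold maximising the mean Dice
    over the remaining images is chosen (ties -> lowest T), and the held-out
    Dice is scored at that threshold.  Pixelwise AUROC per image uses the
    raw activation values inside the lung mask against the gold labels
    (threshold-free); images with single-class gold get NaN AUROC.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = len(images)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 images")
    if all(not np.asarray(g).astype(bool).any() for _, _, g in images):
        raise ValueError("gold consolidation mask empty on every image")

    # precompute Dice for every (image, threshold)
    dice_table = np.empty((n, len(grid)))
    for i, (act, mask, gold) in enumerate(images):
        for j, t in enumerate(grid):
            dice_table[i, j] = _dice_at(act, mask, gold, t)

    sel_t = np.empty(n)
    heldout_dice = np.empty(n)
    auroc = np.empty(n)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        mean_dice = dice_table[rest].mean(axis=0)
        j = int(np.argmax(mean_dice))        # argmax takes the lowest index on ties
        sel_t[i] = grid[j]
        heldout_dice[i] = dice_table[i, j]
        act, mask, gold = images[i]
        inside = np.asarray(mask).astype(bool)
        y = np.asarray(gold).astype(bool)[inside].ravel()
        s = np.asarray(act, dtype=float)[inside].ravel()
        auroc[i] = roc_auc_score(y, s) if 0 < y.sum() < y.size else float("nan")

    values, counts = np.unique(sel_t, return_counts=True)
    selected = float(values[np.argmax(counts)])
    return ThresholdEvaluation(
        grid=grid,
        selected_threshold=selected,
        per_image_threshold=sel_t,
        per_image_dice=heldout_dice,
        per_image_auroc=auroc,
    )
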