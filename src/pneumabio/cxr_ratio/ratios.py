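"""Lung splitting and activation compromise ratios.

A pixel counts as activated when its activation value strictly exceeds the
threshold T ("exceeded" => boundary pixels at exactly T are excluded).
Ratios are reported in percent.  Under the radiographic convention the
image-left lung component is the patient's right lung (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["LungPartition", "CompromiseResult", "split_lungs", "compromise_ratios"]


@dataclass
class LungPartition:
    mask: np.ndarray
    left_lung: np.ndarray       # patient left
    right_lung: np.ndarray      # patient right
    split_method: str           # "component" | "midline"
    warning: str | None = None


@dataclass(frozen=True)
class CompromiseResult:
    cr_left: float              # percent
    cr_right: float             # percent
    tcr: float                  # percent
    threshold: float
    act_left: int
    act_right: int
    px_left: int
    px_right: int


def split_lungs(mask: np.ndarray, image_left_is_patient_right: bool = True) -> LungPartition:
    """Partition a binary lung mask into left/right lungs.

    With exactly two connected components, assignment is by component
    centroid column (the smaller-column component is the patient's right
    lung under the radiographic convention).  Otherwise the mask is split at
    its bounding-box midline column; pixels whose column is strictly below
    the midline go to the smaller-column side, the rest (midline included)
    to the other.  More than two components fall back to the midline split
    with a warning; an empty mask is an error.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty lung mask")
    labels, n = ndimage.label(m)
    warning = None
    if n == 2:
        method = "component"
        cols = ndimage.center_of_mass(m, labels, [1, 2])
        order = np.argsort([c[1] for c in cols]) + 1  # label ids by centroid column
        low_col = labels == order[0]
        high_col = labels == order[1]
    else:
        method = "midline"
        if n > 2:
            warning = f"{n} connected components; falling back to midline split"
        cols_any = np.flatnonzero(m.any(axis=0))
        c0, c1 = cols_any[0], cols_any[-1]
        mid = (c0 + c1 + 1) // 2   # deterministic tie-break: midline column goes right side
        colgrid = np.arange(m.shape[1])[None, :]
        low_col = m & (colgrid < mid)
        high_col = m & (colgrid >= mid)
    if image_left_is_patient_right:
        right_lung, left_lung = low_col, high_col
    else:
        left_lung, right_lung = low_col, high_col
    return LungPartition(
        mask=m, left_lung=left_lung, right_lung=right_lung,
        split_method=method, warning=warning,
    )


def compromise_ratios(
    activation: np.ndarray,
    partition: LungPartition,
    threshold: float,
) -> CompromiseResult:
    """Per-lung and total compromise ratios at threshold T (strict >)."""
    act = np.asarray(activation, dtype=float)
    if act.shape != partition.mask.shape:
        raise ValueError(
            f"activation shape {act.shape} != mask shape {partition.mask.shape}"
        )
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    supra = act > threshold
    act_l = int(np.sum(supra & partition.left_lung))
    act_r = int(np.sum(supra & partition.right_lung))
    px_l = int(partition.left_lung.sum())
    px_r = int(partition.right_lung.sum())
    cr_l = 100.0 * act_l / px_l if px_l else float("nan")
    cr_r = 100.0 * act_r / px_r if px_r else float("nan")
    tcr = 100.0 * (act_l + act_r) / (px_l + px_r)
    return CompromiseResult(
        cr_left=cr_l, cr_right=cr_r, tcr=tcr, threshold=threshold,
        act_left=act_l, act_right=act_r, px_left=px_l, px_right=px_r,
    )
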