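"""Trace extraction: grid-suppressed, intensity-weighted column centroids."""

from __future__ import annotations

import numpy as np

__all__ = ["TraceExtractionError", "extract_trace"]


class TraceExtractionError(RuntimeError):
    """Raised when too few columns contain trace pixels."""


def extract_trace(
    image: np.ndarray,
    panel: tuple[int, int, int, int],
    trace_threshold: float = 128.0,
    max_empty_frac: float = 0.5,
) -> np.ndarray:
    """Per-column trace ordinate inside a panel box (x0, y0, x1, y1).

    Pixels darker than ``trace_threshold`` count as trace (the grid is
    rendered lighter, so thresholding suppresses it); each column's ordinate
    is the darkness-weighted centroid row.  Columns with no trace pixel are
    linearly interpolated from their neighbours.  Returned ordinates are
    absolute image rows, one per panel column.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    x0, y0, x1, y1 = panel
    if not (0 <= x0 < x1 <= img.shape[1] and 0 <= y0 < y1 <= img.shape[0]):
        raise ValueError(f"panel {panel} outside image of shape {img.shape}")
    region = img[y0:y1, x0:x1]
    weight = np.clip(trace_threshold - region, 0.0, None)
    col_mass = weight.sum(axis=0)
    rows = np.arange(region.shape[0], dtype=float)

    ordinates = np.full(region.shape[1], np.nan)
    nonempty = col_mass > 0
    if nonempty.any():
        ordinates[nonempty] = (weight[:, nonempty] * rows[:, None]).sum(axis=0) / col_mass[nonempty]

    empty_frac = 1.0 - nonempty.mean()
    if empty_frac > max_empty_frac:
        raise TraceExtractionError(
            f"{empty_frac:.0%} of columns contain no trace pixels (limit {max_empty_frac:.0%})"
        )
    if not nonempty.all():
        idx = np.arange(region.shape[1])
        ordinates = np.interp(idx, idx[nonempty], ordinates[nonempty])
    return ordinates + y0
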