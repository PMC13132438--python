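"""Benjamini-Hochberg step-up FDR adjustment."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_fdr"]


def bh_fdr(p_values) -> np.ndarray:
    """Step-up adjusted q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.

    Returned in the input order.  p-values outside [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
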