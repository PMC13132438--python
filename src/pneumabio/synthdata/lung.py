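"""Synthetic lung masks and activation maps with planted compromise fractions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LungActivationSim", "gen_lung_activation"]


@dataclass
class LungActivationSim:
    mask: np.ndarray            # bool, both lungs
    left: np.ndarray            # bool, image-left component
    right: np.ndarray           # bool, image-right component
    activation: np.ndarray      # float in [0, 1]
    threshold: float            # planted decision threshold T
    n_supra_left: int
    n_supra_right: int
    frac_left: float            # requested fractions
    frac_right: float


def _ellipse(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def gen_lung_activation(
    shape: tuple[int, int] = (128, 128),
    true_fraction_left: float = 0.0,
    true_fraction_right: float = 0.0,
    seed: int = 0,
    threshold: float = 0.2,
    margin: float = 0.05,
    center_offset: float = 0.22,
    semi_frac: tuple[float, float] = (0.32, 0.16),
) -> LungActivationSim:
    """Two disjoint elliptical lungs; exactly the planted fraction of each
    lung's pixels is supra-threshold (up to 1-pixel rounding).

    Supra pixels get values in ``(threshold + margin, 1]``, all other pixels
    values in ``[0, threshold - margin)`` (clipped at 0), so the planted
    count is recoverable by strict thresholding at ``threshold``.
    """
    for name, f in (("true_fraction_left", true_fraction_left),
                    ("true_fraction_right", true_fraction_right)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    h, w = shape
    semi = (semi_frac[0] * h, semi_frac[1] * w)
    right = _ellipse(shape, (h / 2.0, w / 2.0 - center_offset * w), semi)  # image-left
    left = _ellipse(shape, (h / 2.0, w / 2.0 + center_offset * w), semi)   # image-right
    if np.any(left & right):
        raise ValueError("lung ellipses overlap; reduce semi axes or increase offset")
    mask = left | right

    rng = np.random.default_rng(seed)
    lo_sub = 0.0
    hi_sub = max(threshold - margin, 1e-6)
    lo_sup = min(threshold + margin, 1.0 - 1e-6)
    activation = rng.uniform(lo_sub, hi_sub, size=shape)

    counts = {}
    for key, lung, frac in (("right", right, true_fraction_right),
                            ("left", left, true_fraction_left)):
        idx = np.flatnonzero(lung.ravel())
        k = int(round(frac * idx.size))
        chosen = rng.choice(idx, size=k, replace=False) if k else np.empty(0, dtype=int)
        flat = activation.ravel()
        flat[chosen] = rng.uniform(lo_sup, 1.0, size=k)
        counts[key] = k

    return LungActivationSim(
        mask=mask,
        left=left,
        right=right,
        activation=activation,
        threshold=threshold,
        n_supra_left=counts["left"],
        n_supra_right=counts["right"],
        frac_left=true_fraction_left,
        frac_right=true_fraction_right,
    )
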