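"""Whole-page digitisation convenience: calibrate, extract, convert each panel."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .calibrate import GridCalibration, calibrate_grid
from .signal import CalibratedSignal, to_signal
from .trace import extract_trace

__all__ = ["digitise_page", "load_image"]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF page as a grayscale array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def digitise_page(
    image: np.ndarray,
    panels: list[dict],
    calibration: GridCalibration | None = None,
    trace_threshold: float = 128.0,
    band: tuple[float, float] = (0.5, 40.0),
    filter_order: int = 5,
) -> dict[str, CalibratedSignal]:
    """Digitise every panel of a page.

    ``panels`` entries need ``lead``, ``x0``/``y0``/``x1``/``y1`` and
    ``baseline_row`` (a render manifest or a panel-config YAML both fit).
    When ``calibration`` is None the grid is auto-calibrated from the page.
    """
    if calibration is None:
        calibration = calibrate_grid(image)
    out: dict[str, CalibratedSignal] = {}
    for panel in panels:
        box = (int(panel["x0"]), int(panel["y0"]), int(panel["x1"]), int(panel["y1"]))
        rows = extract_trace(image, box, trace_threshold=trace_threshold)
        out[panel["lead"]] = to_signal(
            rows,
            calibration,
            baseline_row=float(panel["baseline_row"]),
            lead=panel["lead"],
            band=band,
            filter_order=filter_order,
            source_panel=box,
        )
    return out
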