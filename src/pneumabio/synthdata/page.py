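"""Render synthetic ECG traces onto a gridded raster page.

Pages mimic standard clinical ECG paper: a small/big millimetre grid drawn
in a light luminance, traces drawn dark, at 25 mm/s and 10 mm/mV by
default.  The render manifest records panel geometry and the ground-truth
signal so the digitisation round trip can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .ecg import SimulatedEcg

__all__ = ["PageRenderSpec", "render_ecg_page", "default_layout", "save_manifest"]

STANDARD_12_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


@dataclass(frozen=True)
class PageRenderSpec:
    """Geometry and colour of a rendered ECG page."""

    px_per_mm: float = 5.0
    paper_speed: float = 25.0     # mm/s
    amp_scale: float = 10.0       # mm/mV
    grid_small: float = 1.0       # mm
    grid_big: float = 5.0         # mm
    panel_height_mm: float = 40.0
    margin_mm: float = 5.0
    background_lum: int = 255
    grid_small_lum: int = 225
    grid_big_lum: int = 190
    trace_lum: int = 10
    trace_width_px: int = 2
    # "dots": one mark per sample (thermal-printhead style; column ink is
    # dwell-time weighted, so centroid extraction is unbiased on steep
    # slopes).  "line": connected pen stroke (arc-length ink weighting).
    trace_style: str = "dots"

    def __post_init__(self) -> None:
        if self.px_per_mm < 3:
            raise ValueError(
                f"px_per_mm={self.px_per_mm} too low to resolve the mm grid (need >= 3)"
            )
        if not np.isclose(self.grid_big, 5.0 * self.grid_small):
            raise ValueError("grid_big must equal 5 * grid_small")
        if self.grid_small_lum <= self.trace_lum + 60:
            raise ValueError("grid luminance must exceed trace luminance by a clear margin")


def default_layout(leads: Sequence[str]) -> list[list[str]]:
    """3x4 panel grid for the 12 standard leads plus a full-width rhythm row.

    Leads not in the standard set (e.g. ``II-rhythm``) each get their own
    full-width row at the bottom.
    """
    grid = [l for l in leads if l in STANDARD_12_LEADS]
    extra = [l for l in leads if l not in STANDARD_12_LEADS]
    rows: list[list[str]] = []
    for i in range(0, len(grid), 4):
        rows.append(list(grid[i : i + 4]))
    for l in extra:
        rows.append([l])
    return rows


def render_ecg_page(
    traces: Mapping[str, SimulatedEcg],
    spec: PageRenderSpec = PageRenderSpec(),
    layout: Sequence[Sequence[str]] | None = None,
    include_ground_truth: bool = True,
) -> tuple[np.ndarray, dict]:
    """Render traces to a grayscale page (uint8 array) plus a manifest.

    The manifest records, per panel: the lead, pixel bounding box
    (x0, y0, x1, y1; exclusive upper bounds), baseline row, sampling rate
    and duration, and (optionally) the ground-truth samples and R times.
    """
    if layout is None:
        layout = default_layout(list(traces))
    for row in layout:
        for lead in row:
            if lead not in traces:
                raise KeyError(f"layout references unknown lead {lead!r}")

    ppm = spec.px_per_mm
    margin_px = spec.margin_mm * ppm
    panel_h_px = spec.panel_height_mm * ppm

    # panel widths from trace durations
    row_widths = []
    for row in layout:
        w = sum(traces[l].duration_s * spec.paper_speed * ppm for l in row)
        row_widths.append(w)
    page_w = int(np.ceil(max(row_widths) + 2 * margin_px))
    page_h = int(np.ceil(len(layout) * panel_h_px + 2 * margin_px))

    canvas = np.full((page_h, page_w), spec.background_lum, dtype=np.uint8)
    _draw_grid(canvas, spec)

    img = Image.fromarray(canvas, mode="L")
    draw = ImageDraw.Draw(img)

    panels = []
    for r, row in enumerate(layout):
        x_cursor = margin_px
        y0 = margin_px + r * panel_h_px
        baseline_row = y0 + panel_h_px / 2.0
        for lead in row:
            tr = traces[lead]
            n = len(tr.samples)
            width_px = tr.duration_s * spec.paper_speed * ppm
            t_s = np.arange(n) / tr.fs
            xs = x_cursor + t_s * spec.paper_speed * ppm
            ys = baseline_row - tr.samples * spec.amp_scale * ppm
            if spec.trace_style == "line":
                pts = list(zip(xs.tolist(), ys.tolist()))
                draw.line(pts, fill=spec.trace_lum, width=spec.trace_width_px)
            elif spec.trace_style == "dots":
                half = (spec.trace_width_px - 1) / 2.0
                if half > 0:
                    for x, y in zip(xs.tolist(), ys.tolist()):
                        draw.ellipse(
                            (x - half, y - half, x + half, y + half),
                            fill=spec.trace_lum,
                        )
                else:
                    draw.point(list(zip(xs.tolist(), ys.tolist())), fill=spec.trace_lum)
            else:
                raise ValueError(f"unknown trace_style {spec.trace_style!r}")
            panel = {
                "lead": lead,
                "x0": int(round(x_cursor)),
                "y0": int(round(y0)),
                "x1": int(round(x_cursor + width_px)),
                "y1": int(round(y0 + panel_h_px)),
                "baseline_row": float(baseline_row),
                "fs": float(tr.fs),
                "duration_s": float(tr.duration_s),
            }
            if include_ground_truth:
                panel["ground_truth_mv"] = np.asarray(tr.samples).tolist()
                panel["r_peak_times_ms"] = np.asarray(tr.r_peak_times_ms).tolist()
            panels.append(panel)
            x_cursor += width_px

    manifest = {
        "px_per_mm": float(ppm),
        "paper_speed": float(spec.paper_speed),
        "amp_scale": float(spec.amp_scale),
        "grid_small_mm": float(spec.grid_small),
        "grid_big_mm": float(spec.grid_big),
        "page_width_px": page_w,
        "page_height_px": page_h,
        "panels": panels,
        "render_spec": asdict(spec),
    }
    return np.asarray(img), manifest


def _draw_grid(canvas: np.ndarray, spec: PageRenderSpec) -> None:
    """Draw the small/big mm grid in place (light over background)."""
    h, w = canvas.shape
    small_px = spec.grid_small * spec.px_per_mm
    big_px = spec.grid_big * spec.px_per_mm
    for x in np.arange(0.0, w, small_px):
        i = int(round(x))
        if i < w:
            canvas[:, i] = spec.grid_small_lum
    for y in np.arange(0.0, h, small_px):
        i = int(round(y))
        if i < h:
            canvas[i, :] = spec.grid_small_lum
    for x in np.arange(0.0, w, big_px):
        i = int(round(x))
        if i < w:
            canvas[:, i] = spec.grid_big_lum
    for y in np.arange(0.0, h, big_px):
        i = int(round(y))
        if i < h:
            canvas[i, :] = spec.grid_big_lum


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh)
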