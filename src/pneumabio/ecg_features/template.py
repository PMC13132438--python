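"""Group beat templates: pointwise mean +/- SD, and |difference| of means."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .beats import BeatSet

__all__ = ["GroupTemplate", "TemplateComparison", "beat_template"]


@dataclass
class GroupTemplate:
    group: str
    mean: np.ndarray
    sd: np.ndarray
    n_beats: int


@dataclass
class TemplateComparison:
    templates: dict[str, GroupTemplate]
    abs_diff: np.ndarray | None     # |mean_A - mean_B| when exactly 2 groups
    diff: np.ndarray | None         # mean_A - mean_B (first minus second)
    time_rel_ms: np.ndarray


def beat_template(groups: Mapping[str, BeatSet | np.ndarray | Sequence[np.ndarray]]) -> TemplateComparison:
    """Pointwise mean and SD across beats per group.

    Accepts BeatSets or raw (n_beats, seg_len) matrices.  With exactly two
    groups the pointwise difference of group means (first minus second, in
    mapping order) and its absolute value are reported.
    """
    templates: dict[str, GroupTemplate] = {}
    t_rel = None
    for name, beats in groups.items():
        if isinstance(beats, BeatSet):
            mat = beats.segments
            t_rel = beats.time_rel_ms
        else:
            mat = np.atleast_2d(np.asarray(beats, dtype=float))
        if mat.shape[0] == 0:
            raise ValueError(f"group {name!r} has no beats")
        templates[name] = GroupTemplate(
            group=name,
            mean=mat.mean(axis=0),
            sd=mat.std(axis=0, ddof=0),
            n_beats=mat.shape[0],
        )
    names = list(templates)
    diff = abs_diff = None
    if len(names) == 2:
        diff = templates[names[0]].mean - templates[names[1]].mean
        abs_diff = np.abs(diff)
    if t_rel is None:
        seg_len = len(next(iter(templates.values())).mean)
        t_rel = np.arange(seg_len, dtype=float)
    return TemplateComparison(templates=templates, abs_diff=abs_diff, diff=diff, time_rel_ms=t_rel)
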