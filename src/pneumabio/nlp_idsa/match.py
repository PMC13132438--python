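"""Criterion matching (dictionary V1, context-window V2) and severity scoring.

Both matcher versions are purely lexical: a criterion can only fire when a
dictionary token is present, so an absent keyword yields a false negative,
never a false positive.  V2 strictly extends V1 (context rules only add
detections).  Negation is deliberately not handled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .dictionary import CRITERIA, CriterionDictionary
from .normalise import normalise_text

__all__ = ["CriterionMatchSet", "match_criteria", "severity_score"]

_TOKEN_RE = re.compile(r"\S+")


@dataclass
class CriterionMatchSet:
    """Per-note detection result for the nine criteria."""

    note_id: str
    version: str                                   # "v1" | "v2"
    detected: dict[str, bool]
    spans: dict[str, list[tuple[int, int]]]        # char offsets in the RAW note
    severity_score: float | None = None
    age_component: float = 0.0

    def n_detected(self) -> int:
        return sum(bool(v) for v in self.detected.values())


def _token_index(token_starts: list[int], char_pos: int) -> int:
    """Index of the token containing (or nearest before) a character offset."""
    lo, hi = 0, len(token_starts) - 1
    ans = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if token_starts[mid] <= char_pos:
            ans = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return ans


def match_criteria(
    note: str,
    dictionary: CriterionDictionary,
    version: str = "v2",
    note_id: str = "",
) -> CriterionMatchSet:
    """Detect the nine criteria in a raw note.

    V1: a criterion is detected iff any dictionary pattern matches the
    normalised text.  V2: additionally detected when a context rule's anchor
    and companion co-occur within the rule's token distance.
    Matched spans are reported as character offsets into the raw note.
    """
    if version not in ("v1", "v2"):
        raise ValueError(f"version must be 'v1' or 'v2', got {version!r}")
    norm, offmap = normalise_text(note)
    tokens = list(_TOKEN_RE.finditer(norm))
    token_starts = [t.start() for t in tokens]

    detected: dict[str, bool] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for crit in CRITERIA:
        entry = dictionary[crit]
        crit_spans: list[tuple[int, int]] = []
        for pat in entry.patterns:
            for m in pat.finditer(norm):
                crit_spans.append(_raw_span(m.start(), m.end(), offmap, note))
        if version == "v2" and tokens:
            for rule in entry.context_rules:
                anchors = [
                    (_token_index(token_starts, m.start()), m)
                    for m in rule.anchor.finditer(norm)
                ]
                companions = [
                    (_token_index(token_starts, m.start()), m)
                    for m in rule.companion.finditer(norm)
                ]
                for ia, ma in anchors:
                    for ic, mc in companions:
                        if abs(ia - ic) <= rule.max_distance:
                            lo = min(ma.start(), mc.start())
                            hi = max(ma.end(), mc.end())
                            crit_spans.append(_raw_span(lo, hi, offmap, note))
        crit_spans = sorted(set(crit_spans))
        detected[crit] = bool(crit_spans)
        spans[crit] = crit_spans
    return CriterionMatchSet(note_id=note_id, version=version, detected=detected, spans=spans)


def _raw_span(norm_start: int, norm_end: int, offmap: list[int], raw: str) -> tuple[int, int]:
    if not offmap:
        return (0, 0)
    start = offmap[min(norm_start, len(offmap) - 1)]
    end = offmap[min(norm_end - 1, len(offmap) - 1)] + 1
    return (start, min(end, len(raw)))


def severity_score(
    matches: CriterionMatchSet,
    age: float,
    dictionary: CriterionDictionary,
) -> float:
    """Total score = sum of detected-criterion weights + age component.

    Defaults: unit weights, +``age_points`` when age >= ``age_threshold``
    (both from the dictionary config).  The result is also written back onto
    ``matches.severity_score``.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    score = sum(
        dictionary[crit].weight for crit, hit in matches.detected.items() if hit
    )
    age_component = dictionary.age_points if age >= dictionary.age_threshold else 0.0
    matches.age_component = age_component
    matches.severity_score = score + age_component
    return matches.severity_score
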