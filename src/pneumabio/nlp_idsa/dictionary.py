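"""Criterion dictionary: nine IDSA/ATS criteria as Spanish regex patterns."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CRITERIA",
    "ContextRule",
    "CriterionEntry",
    "CriterionDictionary",
    "DictionaryError",
    "load_dictionary",
]

CRITERIA = (
    "invasive_ventilation",
    "septic_shock",
    "tachypnea",
    "pao2_fio2",
    "multilobar_opacities",
    "confusion",
    "uremia",
    "leukopenia",
    "hypotension",
)


class DictionaryError(ValueError):
    """Raised when a dictionary file is malformed or a pattern fails to compile."""


@dataclass(frozen=True)
class ContextRule:
    anchor: re.Pattern
    companion: re.Pattern
    max_distance: int


@dataclass(frozen=True)
class CriterionEntry:
    criterion: str
    patterns: tuple[re.Pattern, ...]
    weight: float
    plant_phrases: tuple[str, ...] = ()
    context_rules: tuple[ContextRule, ...] = ()


@dataclass(frozen=True)
class CriterionDictionary:
    entries: dict[str, CriterionEntry]
    age_threshold: float = 65.0
    age_points: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(CRITERIA) - set(self.entries)
        extra = set(self.entries) - set(CRITERIA)
        if missing or extra:
            raise DictionaryError(
                f"dictionary must define exactly the nine criteria; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )

    def __getitem__(self, criterion: str) -> CriterionEntry:
        return self.entries[criterion]

    def __iter__(self):
        return iter(CRITERIA)


def _compile(pattern: str, criterion: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise DictionaryError(f"bad pattern for {criterion!r}: {pattern!r} ({exc})") from exc


def load_dictionary(path: str | Path | None = None) -> CriterionDictionary:
    """Load a YAML criterion dictionary; defaults to the bundled one."""
    if path is None:
        ref = resources.files("pneumabio.nlp_idsa").joinpath("data/idsa_dictionary.yaml")
        text = ref.read_text(encoding="utf-8")
        source = str(ref)
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    spec = yaml.safe_load(text)
    if not isinstance(spec, dict) or "criteria" not in spec:
        raise DictionaryError("dictionary YAML must contain a 'criteria' mapping")

    entries: dict[str, CriterionEntry] = {}
    for name, block in spec["criteria"].items():
        patterns = tuple(_compile(p, name) for p in block.get("patterns", []))
        if not patterns:
            raise DictionaryError(f"criterion {name!r} has no patterns")
        weight = float(block.get("weight", 1.0))
        if weight < 0:
            raise DictionaryError(f"criterion {name!r} has negative weight")
        rules = tuple(
            ContextRule(
                anchor=_compile(r["anchor"], name),
                companion=_compile(r["companion"], name),
                max_distance=int(r["max_distance"]),
            )
            for r in block.get("context_rules", [])
        )
        entries[name] = CriterionEntry(
            criterion=name,
            patterns=patterns,
            weight=weight,
            plant_phrases=tuple(block.get("plant_phrases", [])),
            context_rules=rules,
        )
    return CriterionDictionary(
        entries=entries,
        age_threshold=float(spec.get("age_threshold", 65)),
        age_points=float(spec.get("age_points", 1)),
        source=source,
    )
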