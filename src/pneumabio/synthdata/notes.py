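"""Synthetic Spanish clinical notes with gold criterion labels.

Phrases planted for gold-positive criteria come from the same YAML
dictionary the scorer uses, so detection is guaranteed unless a false
negative is deliberately planted (``fn_plant_rate``).  Gold-negative
criteria never receive a dictionary phrase; with ``negation_rate > 0``,
distractor sentences may embed *negated* dictionary phrases, which the
(negation-blind) scorer will still match — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ..nlp_idsa.dictionary import CRITERIA, CriterionDictionary, load_dictionary

__all__ = ["NotesCorpus", "gen_notes_corpus"]

_OPENINGS = (
    "paciente de {age} años ingresa por cuadro respiratorio agudo.",
    "se valora paciente de {age} años en el servicio de urgencias.",
    "paciente de {age} años con cuadro de varios dias de evolucion.",
)

_FILLERS = (
    "se solicitan paraclinicos de control.",
    "continua manejo antibiotico segun protocolo institucional.",
    "se comenta el caso con el servicio tratante.",
    "evolucion clinica en seguimiento estrecho.",
    "familiares informados del estado del paciente.",
    "pendiente resultado de cultivos.",
)

_POSITIVE_TEMPLATES = (
    "al examen se documenta {phrase}.",
    "paciente presenta {phrase}.",
    "se evidencia {phrase} durante la valoracion.",
)

_NEGATION_TEMPLATES = (
    "se descarta {phrase}.",
    "sin evidencia de {phrase}.",
    "no se documenta {phrase}.",
)


@dataclass
class NotesCorpus:
    notes: list[str]
    gold: pd.DataFrame          # note_id, age, one bool column per criterion, gold_score
    dictionary: CriterionDictionary
    planted_fn: pd.DataFrame    # note_id x criterion bool: gold-positive but phrase omitted


def gen_notes_corpus(
    n: int,
    criterion_prevalence: Mapping[str, float],
    fn_plant_rate: float = 0.0,
    negation_rate: float = 0.0,
    seed: int = 0,
    dictionary: CriterionDictionary | None = None,
    age_range: tuple[int, int] = (35, 92),
) -> NotesCorpus:
    """Generate ``n`` notes with gold labels for the nine criteria.

    For each gold-positive criterion a dictionary phrase is embedded with
    probability ``1 - fn_plant_rate`` (otherwise deliberately omitted: a
    planted false negative).  Gold score = sum of gold-criterion weights
    plus the age component.
    """
    for crit, p in criterion_prevalence.items():
        if crit not in CRITERIA:
            raise ValueError(f"unknown criterion {crit!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {crit!r} must be in [0, 1]")
    if dictionary is None:
        dictionary = load_dictionary()

    rng = np.random.default_rng(seed)
    notes: list[str] = []
    gold_rows: list[dict] = []
    fn_rows: list[dict] = []
    for i in range(n):
        age = int(rng.integers(age_range[0], age_range[1] + 1))
        sentences = [rng.choice(_OPENINGS).format(age=age)]
        gold_row: dict = {"note_id": f"note_{i:05d}", "age": age}
        fn_row: dict = {"note_id": f"note_{i:05d}"}
        score = 0.0
        for crit in CRITERIA:
            p = float(criterion_prevalence.get(crit, 0.0))
            positive = bool(rng.random() < p)
            gold_row[crit] = positive
            planted_fn = False
            if positive:
                score += dictionary[crit].weight
                if rng.random() < fn_plant_rate:
                    planted_fn = True   # omit the phrase: scorer must miss it
                else:
                    phrase = str(rng.choice(dictionary[crit].plant_phrases))
                    sentences.append(rng.choice(_POSITIVE_TEMPLATES).format(phrase=phrase))
            fn_row[crit] = planted_fn
        # distractors; optionally negated dictionary phrases
        for _ in range(int(rng.integers(1, 4))):
            if negation_rate > 0 and rng.random() < negation_rate:
                crit = str(rng.choice(CRITERIA))
                phrase = str(rng.choice(dictionary[crit].plant_phrases))
                sentences.append(rng.choice(_NEGATION_TEMPLATES).format(phrase=phrase))
            else:
                sentences.append(str(rng.choice(_FILLERS)))
        if age >= dictionary.age_threshold:
            score += dictionary.age_points
        gold_row["gold_score"] = score
        order = list(range(1, len(sentences)))
        rng.shuffle(order)
        body = [sentences[0]] + [sentences[j] for j in order]
        notes.append(" ".join(body).capitalize())
        gold_rows.append(gold_row)
        fn_rows.append(fn_row)

    return NotesCorpus(
        notes=notes,
        gold=pd.DataFrame(gold_rows),
        dictionary=dictionary,
        planted_fn=pd.DataFrame(fn_rows),
    )
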