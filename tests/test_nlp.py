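import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pneumabio.nlp_idsa import (
    CRITERIA,
    DictionaryError,
    agreement_stats,
    cohen_kappa,
    load_dictionary,
    match_criteria,
    normalise_text,
    severity_score,
)
from pneumabio.synthdata import gen_notes_corpus


class TestNormalise:
    def test_lowercase_and_punct(self):
        norm, _ = normalise_text("Taquipnea Severa.")
        assert norm == "taquipnea severa"

    def test_subscript_and_slash(self):
        norm, _ = normalise_text("PaO₂/FiO₂ < 250")
        assert norm == "pao2/fio2 < 250"

    def test_empty(self):
        assert normalise_text("") == ("", [])

    def test_accents_folded_enye_kept(self):
        norm, _ = normalise_text("Años de evolución")
        assert norm == "años de evolucion"

    def test_offset_map_recovers_raw_span(self):
        raw = "  Choque   SÉPTICO. fin"
        norm, offsets = normalise_text(raw)
        start = norm.index("choque septico")
        end = start + len("choque septico")
        lo, hi = offsets[start], offsets[end - 1] + 1
        assert raw[lo:hi] == "Choque   SÉPTICO"


class TestMatchCriteria:
    def test_septic_shock_detected_both_versions(self, dictionary):
        note = "paciente en choque septico con vasopresores"
        for version in ("v1", "v2"):
            m = match_criteria(note, dictionary, version=version)
            assert m.detected["septic_shock"]

    def test_no_token_no_detection(self, dictionary):
        note = "paciente estable sin hallazgos relevantes"
        m = match_criteria(note, dictionary, version="v2")
        assert not any(m.detected.values())

    def test_context_rule_v2_only(self, dictionary):
        note = "pafi de 230 en gases arteriales"
        v1 = match_criteria(note, dictionary, version="v1")
        v2 = match_criteria(note, dictionary, version="v2")
        assert not v1.detected["pao2_fio2"]
        assert v2.detected["pao2_fio2"]

    def test_context_rule_respects_distance(self, dictionary):
        filler = "y " * 10
        note = f"pafi dentro de limites {filler} valor 230"
        v2 = match_criteria(note, dictionary, version="v2")
        assert not v2.detected["pao2_fio2"]

    def test_spans_point_into_raw_note(self, dictionary):
        note = "Paciente con CHOQUE SÉPTICO severo"
        m = match_criteria(note, dictionary, version="v1")
        (lo, hi), = m.spans["septic_shock"]
        assert "CHOQUE" in note[lo:hi]

    def test_v2_superset_of_v1_on_random_corpus(self, dictionary):
        corpus = gen_notes_corpus(
            60, {c: 0.5 for c in CRITERIA}, fn_plant_rate=0.2, negation_rate=0.3, seed=4
        )
        for note in corpus.notes:
            v1 = match_criteria(note, dictionary, version="v1")
            v2 = match_criteria(note, dictionary, version="v2")
            for c in CRITERIA:
                assert v2.detected[c] or not v1.detected[c]

    def test_bad_version(self, dictionary):
        with pytest.raises(ValueError):
            match_criteria("x", dictionary, version="v3")

    def test_bad_dictionary_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "criteria:\n"
            + "".join(
                f"  {c}:\n    patterns: ['ok']\n" for c in list(CRITERIA)[:-1]
            )
            + "  hypotension:\n    patterns: ['(unclosed']\n"
        )
        with pytest.raises(DictionaryError):
            load_dictionary(bad)


class TestSeverityScore:
    def test_no_detection_young(self, dictionary):
        m = match_criteria("sin hallazgos", dictionary)
        assert severity_score(m, age=40, dictionary=dictionary) == 0.0

    def test_two_criteria_plus_age(self, dictionary):
        m = match_criteria(
            "choque septico y ventilacion mecanica invasiva", dictionary
        )
        assert severity_score(m, age=70, dictionary=dictionary) == 3.0

    def test_all_nine_plus_age(self, dictionary):
        note = " ".join(dictionary[c].plant_phrases[0] for c in CRITERIA)
        m = match_criteria(note, dictionary)
        assert m.n_detected() == 9
        assert severity_score(m, age=70, dictionary=dictionary) == 10.0

    def test_negative_age_rejected(self, dictionary):
        m = match_criteria("x", dictionary)
        with pytest.raises(ValueError):
            severity_score(m, age=-1, dictionary=dictionary)

    def test_score_attenuation_under_planted_fn(self, dictionary):
        corpus = gen_notes_corpus(
            80, {c: 0.6 for c in CRITERIA}, fn_plant_rate=0.4, seed=6
        )
        for note, (_, gold) in zip(corpus.notes, corpus.gold.iterrows()):
            m = match_criteria(note, dictionary, version="v2")
            score = severity_score(m, age=float(gold["age"]), dictionary=dictionary)
            assert score <= gold["gold_score"]


class TestKappa:
    def test_perfect_agreement(self):
        k, _, status = cohen_kappa(40, 0, 0, 60)
        assert k == pytest.approx(1.0)
        assert status == "ok"

    def test_worked_example(self):
        # [[40, 5], [10, 45]]: p_o = 0.85, p_e = 0.5, kappa = 0.70
        k, ci, _ = cohen_kappa(40, 5, 10, 45)
        assert k == pytest.approx(0.70, abs=1e-12)
        assert ci[0] < 0.70 < ci[1]

    def test_perfect_disagreement(self):
        k, _, _ = cohen_kappa(0, 50, 50, 0)
        assert k == pytest.approx(-1.0)

    def test_degenerate_margins(self):
        k, _, status = cohen_kappa(100, 0, 0, 0)
        assert status == "undefined"
        assert np.isnan(k)

    @settings(max_examples=250, deadline=None)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_matches_bruteforce(self, cells):
        tp, fp, fn, tn = cells
        n = tp + fp + fn + tn
        if n == 0:
            return
        k, _, status = cohen_kappa(tp, fp, fn, tn)
        p_o = (tp + tn) / n
        p_e = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / n**2
        if abs(1 - p_e) < 1e-15:
            assert status == "undefined"
        else:
            assert k == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)


class TestAgreementStats:
    def _frames(self, dictionary, n=120, seed=2):
        corpus = gen_notes_corpus(
            n, {c: 0.5 for c in CRITERIA}, fn_plant_rate=0.3, seed=seed
        )
        preds = []
        for i, note in enumerate(corpus.notes):
            m = match_criteria(note, dictionary, version="v2")
            preds.append({"note_id": f"note_{i:05d}", **m.detected})
        return pd.DataFrame(preds), corpus.gold

    def test_zero_fp_structural_property(self, dictionary):
        pred, gold = self._frames(dictionary)
        report = agreement_stats(pred, gold)
        assert report.total_fp() == 0
        for crit in CRITERIA:
            assert report.per_criterion[crit].fp == 0

    def test_confusion_sums_to_n(self, dictionary):
        pred, gold = self._frames(dictionary)
        report = agreement_stats(pred, gold)
        for c in report.per_criterion.values():
            assert c.n == len(gold)

    def test_second_rater_kappa(self, dictionary):
        pred, gold = self._frames(dictionary)
        rater = gold.copy()
        report = agreement_stats(pred, gold, second_rater=rater)
        assert report.human_kappa == pytest.approx(1.0)

    def test_misaligned_ids_rejected(self, dictionary):
        pred, gold = self._frames(dictionary, n=10)
        with pytest.raises(ValueError):
            agreement_stats(pred.iloc[:5], gold)
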