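import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GENERATIVE_EXPANSIONS, make_corpus, prepared_records
from radconcept.corpus_io import ReportRecord
from radconcept.lexicon import Lexicon, default_lexicon
from radconcept.ner_rules import (
    NA,
    brute_force_first_concept,
    classify_corpus,
    classify_report,
    compile_patterns,
    extract_first_concept,
)


class TestCompilePatterns:
    def test_sclc_never_fires_inside_nsclc(self, pats):
        for pattern in pats.groups[3]:
            assert pattern.search("nsclc") is None

    def test_nsclc_comma_is_concept2(self, pats):
        m = extract_first_concept("nsclc,", pats)
        assert m.concept_index == 2 and m.surface == "nsclc,"

    def test_empty_lexicon(self):
        pats = compile_patterns(Lexicon(entries=()))
        assert pats.groups == {}

    def test_entry_without_synonyms_warns(self, tmp_path):
        from radconcept.lexicon import load_lexicon

        p = tmp_path / "lex.csv"
        p.write_text(
            "preferred_label,cui,concept_index,synonyms\n"
            "Lung carcinoma,C0684249,1,\n"
        )
        pats = compile_patterns(load_lexicon(p), enable_generative=False)
        assert pats.groups[1] == []
        assert pats.warnings

    def test_every_synonym_matchable(self, lex, pats):
        for entry in lex.entries:
            for phrase in entry.synonyms:
                m = extract_first_concept(f"prefix words {phrase} suffix", pats)
                assert m is not None and m.concept_index == entry.concept_index

    def test_generative_extracts_unlisted_phrases(self, pats, strict_pats):
        m = extract_first_concept("known adenocarcinoma lung primary", pats)
        assert m.concept_index == 1 and m.surface == "adenocarcinoma lung"
        assert extract_first_concept("isolated lung adenoca finding", strict_pats) is None


class TestExtractFirstConcept:
    def test_table_example(self, pats):
        m = extract_first_concept("known case of ca lung with nodal disease", pats)
        assert (m.concept_index, m.cui, m.surface) == (1, "C0684249", "ca lung")

    def test_interrupted_phrase_misses(self, pats):
        assert extract_first_concept("this is a case of ca left lung", pats) is None

    def test_empty_text(self, pats):
        assert extract_first_concept("", pats) is None

    def test_offset_points_into_text(self, pats):
        text = "follow up case of nsclc. stable disease"
        m = extract_first_concept(text, pats)
        assert text[m.offset : m.offset + len(m.surface)] == m.surface

    def test_earliest_wins_across_concepts(self, pats):
        text = "known nsclc with prior ca lung history"
        m = extract_first_concept(text, pats)
        assert m.concept_index == 2

    def test_tie_longest_surface_wins(self, pats):
        # at the same offset "nsclc," is longer than "nsclc"
        m = extract_first_concept("nsclc, on treatment", pats)
        assert m.surface == "nsclc,"

    def test_500_random_texts_match_oracle(self, lex, pats):
        rng = random.Random(99)
        vocab = [
            "ca", "lung", "carcinoma", "nsclc", "sclc", "left", "mass", "adenoca",
            "non", "small", "cell", "known", "case", "of", "nsclc,", "nsclc.",
            "sclc", "lesion", "upper", "lobe", "ca.", "adenocarcinoma", "with",
        ]
        for _ in range(500):
            text = " ".join(rng.choices(vocab, k=rng.randint(0, 25)))
            got = extract_first_concept(text, pats)
            want = brute_force_first_concept(text, lex, GENERATIVE_EXPANSIONS)
            if want is None:
                assert got is None, text
            else:
                assert got is not None, text
                assert (got.offset, got.concept_index) == (want.offset, want.concept_index), text
                assert len(got.surface) == len(want.surface), text


@settings(max_examples=300, deadline=None)
@given(
    st.lists(
        st.sampled_from(
            ["ca", "lung", "carcinoma", "nsclc", "sclc", "sclc,", "left", "cell",
             "small", "non", "adenoca", ".", ",", ";", ")", "mass", "ca."]
        ),
        max_size=30,
    )
)
def test_matcher_equals_oracle_property(tokens):
    lex = default_lexicon()
    pats = compile_patterns(lex)
    text = " ".join(tokens)[:200]
    got = extract_first_concept(text, pats)
    want = brute_force_first_concept(text, lex, GENERATIVE_EXPANSIONS)
    assert (got is None) == (want is None)
    if got is not None:
        assert (got.offset, -len(got.surface), got.concept_index) == (
            want.offset,
            -len(want.surface),
            want.concept_index,
        )


class TestClassifyReport:
    def _record(self, impression, findings="routine study."):
        return ReportRecord(
            case_number="C1", findings=findings, impression=impression,
            unified_text=f"{findings} {impression}",
        )

    def test_standalone_sclc(self, pats):
        label, term, cui = classify_report(self._record("features of sclc noted."), pats)
        assert (label, cui) == (3, "C0149925")

    def test_documented_miss_is_na(self, pats):
        label, term, cui = classify_report(
            self._record("soft tissue mass in left upper lobe"), pats
        )
        assert (label, term, cui) == (0, NA, NA)

    def test_earliest_mention_labels_report(self, pats):
        text = "a" * 10 + " nsclc " + "b" * 20 + " ca lung"
        rec = ReportRecord(case_number="C1", unified_text=text)
        label, term, _ = classify_report(rec, pats)
        assert label == 2 and term == "nsclc"

    def test_requires_unified_text(self, pats):
        with pytest.raises(ValueError):
            classify_report(ReportRecord(case_number="C1"), pats)


class TestClassifyCorpus:
    def test_counts_and_binary_labels(self, pats):
        spec, records = make_corpus(n=60, seed=13, hard_negative_rate=0.0)
        recs = prepared_records(records, spec.doctor_names)
        table = classify_corpus(recs, pats)
        assert len(table) == len(recs)
        expected_positive = sum(1 for r in recs if (r.rule_expected or 0) > 0)
        assert int(table["binary_label"].sum()) == expected_positive

    def test_permutation_equivariance(self, pats):
        spec, records = make_corpus(n=30, seed=14)
        recs = prepared_records(records, spec.doctor_names)
        table = classify_corpus(recs, pats)
        perm = list(reversed(range(len(recs))))
        table_perm = classify_corpus([recs[i] for i in perm], pats)
        for out_row, src in zip(table_perm.itertuples(index=False), perm):
            orig = table.iloc[src]
            assert out_row.concept_label == orig["concept_label"]
            assert out_row.extracted_term == orig["extracted_term"]

    def test_all_negative_corpus(self, pats):
        spec, records = make_corpus(n=30, seed=15, class_mix=(1.0, 0.0, 0.0, 0.0))
        recs = prepared_records(records, spec.doctor_names)
        table = classify_corpus(recs, pats)
        assert (table["extracted_term"] == NA).all()
        assert (table["concept_label"] == 0).all()


class TestDocumentedBehaviorProperties:
    def test_zero_false_positives_on_clean_negatives(self, pats):
        spec, records = make_corpus(n=300, seed=16, class_mix=(1.0, 0.0, 0.0, 0.0))
        recs = prepared_records(records, spec.doctor_names)
        table = classify_corpus(recs, pats)
        assert int(table["binary_label"].sum()) == 0

    def test_full_sensitivity_on_clean_injections(self, pats):
        spec, records = make_corpus(
            n=300, seed=17, variant_rate=0.4, hard_negative_rate=0.0
        )
        recs = prepared_records(records, spec.doctor_names)
        table = classify_corpus(recs, pats)
        for rec, label in zip(recs, table["concept_label"]):
            assert label == rec.rule_expected == rec.gold_concept

    def test_nsclc_variants_never_concept3(self, pats):
        for variant in ("nsclc", "nsclc,", "nsclc;", "nsclc.", "nsclc)"):
            m = extract_first_concept(f"history of {variant} under review", pats)
            assert m is not None and m.concept_index == 2
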