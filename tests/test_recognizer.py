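"""Recognizer semantics, checked against an independent brute-force oracle.

The oracle scans every dictionary surface over every position of the
normalized text with str.find (an O(n*m) naive scan), applying the same
documented option semantics; the implementation under test is the
Aho-Corasick automaton.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frannot.annotations import Span
from frannot.dictionary import (BuildOptions, Dictionary, DictionaryEntry,
                                build_dictionary)
from frannot.normalize import normalize_text, tokenize
from frannot.recognizer import (RecognitionOptions, compile_matcher,
                                recognize)
from frannot.terminology import Concept, Terminology


def naive_scan(dictionary: Dictionary, text: str, ro: RecognitionOptions):
    """Brute-force oracle: every surface at every position."""
    norm = normalize_text(text)
    surface_sources: dict[str, set] = {}
    for e in dictionary.entries:
        surface_sources.setdefault(e.surface, set()).add(e.source)
    hits = set()
    for surface, sources in surface_sources.items():
        start = 0
        while True:
            i = norm.text.find(surface, start)
            if i < 0:
                break
            j = i + len(surface)
            boundary_ok = ro.partial_words or (
                norm.is_token_start(i) and norm.is_token_end(j))
            suppressed = all(
                tok in ro.stopwords or len(tok) < ro.min_token_length
                for tok in tokenize(surface))
            if boundary_ok and not suppressed:
                ob, oe = norm.to_original(i, j)
                for src in sources:
                    hits.add((ob, oe, src))
            start = i + 1
    if ro.longest_only:
        spans = {(b, e) for b, e, _ in hits}
        hits = {(b, e, s) for b, e, s in hits
                if not any(b2 <= b and e <= e2 and (b2, e2) != (b, e)
                           for b2, e2 in spans)}
    return sorted(hits)


def as_tuples(anns):
    return sorted((a.span.begin, a.span.end, a.concept) for a in anns)


def make_dictionary(surfaces):
    entries = []
    for i, s in enumerate(sorted(set(surfaces)), start=1):
        entries.append(DictionaryEntry(entry_id=i, surface=s,
                                       source=("SYN", f"C{i}")))
    return Dictionary(entries)


PERMISSIVE = dict(stopwords=frozenset(), min_token_length=1)


class TestWorkedExamples:
    @pytest.fixture()
    def matcher(self):
        return compile_matcher(
            make_dictionary(["cancer du sein", "cancer", "sein"]))

    def test_overlapping_constituents_all_reported(self, matcher):
        anns = recognize(matcher, "cancer du sein", RecognitionOptions())
        assert len(anns) == 3

    def test_longest_only_discards_constituents(self, matcher):
        anns = recognize(matcher, "cancer du sein",
                         RecognitionOptions(longest_only=True))
        assert [a.matched_text for a in anns] == ["cancer du sein"]
        assert anns[0].span == Span(0, 14)

    def test_partial_words_substring_match(self):
        m = compile_matcher(make_dictionary(["vasculaire"]))
        on = recognize(m, "système cardiovasculaire",
                       RecognitionOptions(partial_words=True))
        off = recognize(m, "système cardiovasculaire",
                        RecognitionOptions(partial_words=False))
        assert len(on) == 1 and len(off) == 0
        assert on[0].matched_text == "vasculaire"

    def test_empty_text(self, matcher):
        assert recognize(matcher, "", RecognitionOptions()) == []

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            compile_matcher(Dictionary([]))

    def test_stopword_and_short_token_suppression(self):
        m = compile_matcher(make_dictionary(["du", "de la", "cancer du sein"]))
        anns = recognize(m, "cancer du sein de la peau", RecognitionOptions())
        assert {a.matched_text for a in anns} == {"cancer du sein"}

    def test_accented_text_matches_folded_dictionary(self):
        t = Terminology("T")
        t.add(Concept(concept_id="1", pref_label="arrêt respiratoire"))
        m = compile_matcher(build_dictionary([t]))
        anns = recognize(m, "ARRET CARDIO RESPIRATOIRE ET ARRÊT RESPIRATOIRE",
                         RecognitionOptions())
        assert len(anns) == 1
        assert anns[0].matched_text == "ARRÊT RESPIRATOIRE"

    def test_elision_exposes_inner_token(self):
        m = compile_matcher(make_dictionary(["uretre"]))
        anns = recognize(m, "absence de l'urètre", RecognitionOptions())
        assert len(anns) == 1
        assert anns[0].matched_text == "urètre"

    def test_duplicate_surface_one_match_per_concept(self):
        d = Dictionary([
            DictionaryEntry(entry_id=1, surface="cancer", source=("A", "1")),
            DictionaryEntry(entry_id=2, surface="cancer", source=("B", "2")),
        ])
        anns = recognize(compile_matcher(d), "cancer", RecognitionOptions())
        assert {a.concept for a in anns} == {("A", "1"), ("B", "2")}


TOKENS = ["ab", "abc", "b", "bc", "cab", "de", "x", "xyz", "ca"]


def random_instance(rng):
    n_surf = rng.randint(1, 30)
    surfaces = [" ".join(rng.choice(TOKENS)
                         for _ in range(rng.randint(1, 3)))
                for _ in range(n_surf)]
    words = [rng.choice(TOKENS + ["zz", "qq"]) for _ in range(rng.randint(5, 60))]
    sep_pool = [" ", ", ", "-", ". ", "'"]
    text = ""
    for w in words:
        text += w + rng.choice(sep_pool)
    return surfaces, text[:300]


class TestOracleEquivalence:
    @pytest.mark.parametrize("longest_only", [False, True])
    def test_randomized_instances_match_oracle(self, longest_only):
        rng = random.Random(20240917)
        for _ in range(120):
            surfaces, text = random_instance(rng)
            d = make_dictionary(surfaces)
            ro = RecognitionOptions(longest_only=longest_only, **PERMISSIVE)
            got = as_tuples(recognize(compile_matcher(d), text, ro))
            want = naive_scan(d, text, ro)
            assert got == want, (surfaces, text)

    def test_partial_words_against_oracle(self):
        rng = random.Random(7)
        for _ in range(60):
            surfaces, text = random_instance(rng)
            d = make_dictionary(surfaces)
            ro = RecognitionOptions(partial_words=True, **PERMISSIVE)
            got = as_tuples(recognize(compile_matcher(d), text, ro))
            assert got == naive_scan(d, text, ro)


class TestProperties:
    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_longest_only_antichain_and_subset(self, data):
        token = st.sampled_from(TOKENS)
        surfaces = data.draw(st.lists(
            st.builds(" ".join, st.lists(token, min_size=1, max_size=3)),
            min_size=1, max_size=15))
        text = data.draw(st.builds(
            " ".join, st.lists(token, min_size=1, max_size=40)))
        d = make_dictionary(surfaces)
        m = compile_matcher(d)
        loose = recognize(m, text, RecognitionOptions(**PERMISSIVE))
        strict = recognize(
            m, text, RecognitionOptions(longest_only=True, **PERMISSIVE))
        loose_set, strict_set = set(as_tuples(loose)), set(as_tuples(strict))
        assert strict_set <= loose_set
        spans = [a.span for a in strict]
        for s1 in spans:
            for s2 in spans:
                assert not s1.strictly_contains(s2)

    def test_self_recognition_of_every_label(self, mesh_breast):
        m = compile_matcher(build_dictionary([mesh_breast]))
        for label in mesh_breast.concepts["D001943"].labels:
            anns = recognize(m, label, RecognitionOptions())
            assert any(a.span == Span(0, len(label)) for a in anns), label

    def test_matched_text_round_trips_through_slice(self):
        text = "Le cancer du sein, et l'arrêt !"
        m = compile_matcher(make_dictionary(
            ["cancer du sein", "cancer", "arret"]))
        for a in recognize(m, text, RecognitionOptions()):
            assert text[a.span.begin:a.span.end] == a.matched_text
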