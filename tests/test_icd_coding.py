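"""Death-certificate coding: CépiDC I/O, code index, MFC, SKOS, post-filters."""

import pytest

from frannot.icd_coding import (CepidcFormatError, CertificateCoder,
                                CertificateLine, CodeFrequencyTable,
                                assign_ambiguous_labels, build_code_index,
                                code_certificates, emit_skos, read_cepidc,
                                select_preferred_label)
from frannot.terminology import load_terminology

# the printed CausesBrutes / Ident sample rows
CAUSES_SAMPLE = (
    "DocID ; YearCoded; LineID; RawText; IntType; IntValue\n"
    "161477; 2014 ; 1 ; INSUFFISANCE RESPIRATOIRE AIGUE; 3; 5\n"
    "161477; 2014 ; 2 ; PNEUMOPATHIE D INHALATION; 3; 5\n"
    "161477; 2014 ; 5 ; PSYCHOSE CHRONIQUE;NULL;NULL\n")
IDENT_SAMPLE = (
    "DocID; YearCoded; Gender; Age; LocationOfDeath\n"
    "93715; 2014 ; 2 ; 80; 2\n")


class TestReader:
    def test_printed_sample_parses_exactly(self, tmp_path):
        causes = tmp_path / "CausesBrutes.csv"
        causes.write_text(CAUSES_SAMPLE, encoding="utf-8")
        ident = tmp_path / "Ident.csv"
        ident.write_text(IDENT_SAMPLE, encoding="utf-8")
        lines, idents = read_cepidc({"causes": causes, "ident": ident},
                                    layout="raw")
        assert len(lines) == 3
        assert [l.line_id for l in lines] == [1, 2, 5]
        assert all(l.doc_id == "161477" and l.year_coded == 2014
                   for l in lines)
        assert [(l.int_type, l.int_value) for l in lines] == \
            [(3, 5), (3, 5), (None, None)]
        assert lines[2].raw_text == "PSYCHOSE CHRONIQUE"
        assert len(idents) == 1
        assert (idents[0].doc_id, idents[0].gender, idents[0].age) == \
            ("93715", 2, 80)

    def test_wrong_column_count_names_the_line(self, tmp_path):
        causes = tmp_path / "bad.csv"
        causes.write_text("161477; 2014 ; 1 ; TEXTE; 3\n", encoding="utf-8")
        with pytest.raises(CepidcFormatError, match=":1"):
            read_cepidc({"causes": causes}, layout="raw")

    def test_aligned_layout_with_and_without_standard_text(self, tmp_path):
        with_std = tmp_path / "al1.csv"
        with_std.write_text(
            "1; 2014; 1; ARRET RESPIRATOIRE; NULL; NULL; "
            "Arrêt respiratoire; R09.2\n", encoding="utf-8")
        lines, _ = read_cepidc({"causes": with_std}, layout="aligned")
        assert lines[0].gold_codes == ["R09.2"]
        assert lines[0].standard_text == "Arrêt respiratoire"
        without = tmp_path / "al2.csv"
        without.write_text("1; 2014; 1; ARRET RESPIRATOIRE; NULL; NULL; "
                           "R09.2|J96.0\n", encoding="utf-8")
        lines, _ = read_cepidc({"causes": without}, layout="aligned")
        assert lines[0].gold_codes == ["R09.2", "J96.0"]
        assert lines[0].standard_text is None

    def test_invalid_code_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("1; 2014; 1; X; NULL; NULL; 123A\n", encoding="utf-8")
        with pytest.raises(CepidcFormatError, match="invalid ICD-10"):
            read_cepidc({"causes": bad}, layout="aligned")


class TestPreferredLabel:
    def test_acronym_run_disqualifies(self):
        labels = ["INSUFFISANCE RESPIRATOIRE AIGUE",
                  "insuf. respiratoire aiguë"]
        assert select_preferred_label(labels) == "insuf. respiratoire aiguë"

    def test_single_label(self):
        assert select_preferred_label(["choc septique"]) == "choc septique"

    def test_all_acronymic_falls_back_to_shortest(self):
        assert select_preferred_label(["ABCDEF", "ABC"]) == "ABC"

    def test_tie_first_in_input_order(self):
        assert select_preferred_label(["bb aa", "aa bb"]) == "bb aa"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_preferred_label([])


class TestCodeIndex:
    def test_dictionary_then_corpus_labels(self):
        aligned = [CertificateLine(
            doc_id="1", year_coded=2014, line_id=1,
            raw_text="ARRET CARDIO RESPIRATOIRE", gold_codes=["R09.2"])]
        index = build_code_index([("R09.2", "arrêt respiratoire")], aligned)
        assert index["R09.2"] == ["arret respiratoire",
                                  "arret cardio respiratoire"]

    def test_empty_corpus_dictionary_only(self):
        index = build_code_index([("A10", "choléra")], [])
        assert index == {"A10": ["cholera"]}

    def test_duplicate_label_stored_once(self):
        index = build_code_index(
            [("A10", "choléra"), ("A10", "CHOLERA")], [])
        assert index["A10"] == ["cholera"]

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            build_code_index([("10A", "x")], [])


class TestAmbiguityResolution:
    def test_label_kept_under_most_frequent_code(self):
        index = {"A41.9": ["choc septique", "sepsis"],
                 "R57.2": ["choc septique"],
                 "A40.9": ["choc septique"]}
        freqs = CodeFrequencyTable({"A41.9": 50, "R57.2": 30, "A40.9": 5})
        resolved = assign_ambiguous_labels(index, freqs)
        assert resolved == {"A41.9": ["choc septique", "sepsis"]}

    def test_unambiguous_index_unchanged(self):
        index = {"A10": ["cholera"], "B20": ["autre"]}
        assert assign_ambiguous_labels(index, CodeFrequencyTable()) == index

    def test_equal_frequency_smaller_code_wins(self):
        index = {"B20": ["label"], "A10": ["label"]}
        resolved = assign_ambiguous_labels(index, CodeFrequencyTable())
        assert resolved == {"A10": ["label"]}

    def test_resolution_makes_label_to_code_functional(self):
        index = {"A10": ["x", "y"], "B20": ["y", "z"], "C30": ["z"]}
        resolved = assign_ambiguous_labels(
            index, CodeFrequencyTable({"A10": 1, "B20": 9, "C30": 2}))
        seen = {}
        for code, labels in resolved.items():
            for label in labels:
                assert label not in seen, (label, seen[label], code)
                seen[label] = code


class TestSkosEmission:
    def test_round_trip_through_minimal_skos_reader(self, tmp_path):
        index = {"G12.1": ["amyotrophie spinale", "ASI tardive"],
                 "A10": ["paludisme induit"]}
        out = tmp_path / "cim10dc.ttl"
        emit_skos(index, out)
        term = load_terminology(out, format="skos_min", acronym="CIM10DC")
        assert set(term.concepts) == {"G12.1", "A10"}
        c = term.concepts["G12.1"]
        assert set((c.pref_label, *c.synonyms)) == set(index["G12.1"])
        assert c.pref_label == "amyotrophie spinale"  # ASI is acronymic
        assert c.code == "G12.1"

    def test_empty_index_empty_vocabulary(self, tmp_path):
        out = tmp_path / "empty.ttl"
        emit_skos({}, out)
        term = load_terminology(out, format="skos_min", acronym="E")
        assert term.concepts == {}


class TestCoding:
    @pytest.fixture()
    def coder(self):
        index = {"R09.2": ["arret respiratoire"],
                 "A41.9": ["choc septique"],
                 "J96.0": ["insuffisance respiratoire aigue"]}
        freqs = CodeFrequencyTable({"R09.2": 10, "A41.9": 30, "J96.0": 5})
        return CertificateCoder(index, freqs)

    def test_line_equal_to_label_recovers_code(self, coder):
        assert coder.code_line("ARRET RESPIRATOIRE") == {"R09.2"}
        assert coder.code_line("Arrêt respiratoire") == {"R09.2"}

    def test_unmatched_line_empty(self, coder):
        assert coder.code_line("etat de mal epileptique") == set()

    def test_mfc_post_filter_keeps_most_frequent(self, coder):
        line = CertificateLine(doc_id="1", year_coded=2014, line_id=1,
                               raw_text="choc septique et arret respiratoire")
        [(_, none_codes)] = code_certificates([line], coder, post="none")
        [(_, mfc_codes)] = code_certificates([line], coder, post="mfc")
        assert none_codes == {"A41.9", "R09.2"}
        assert mfc_codes == {"A41.9"}

    def test_cutoff_keeps_at_least_one_code(self, coder):
        line = CertificateLine(doc_id="1", year_coded=2014, line_id=1,
                               raw_text="choc septique et arret respiratoire")
        [(_, codes)] = code_certificates([line], coder,
                                         post=("cutoff", 0.01))
        assert codes == {"A41.9"}  # minimal prefix, most probable first
        [(_, codes)] = code_certificates([line], coder, post=("cutoff", 1.0))
        assert codes == {"A41.9", "R09.2"}

    def test_post_filters_never_add_codes(self, coder):
        line = CertificateLine(doc_id="1", year_coded=2014, line_id=1,
                               raw_text="choc septique et arret respiratoire")
        [(_, base)] = code_certificates([line], coder, post="none")
        for post in ("mfc", ("cutoff", 0.5), ("cutoff", 1.0)):
            [(_, filtered)] = code_certificates([line], coder, post=post)
            assert filtered <= base and filtered
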