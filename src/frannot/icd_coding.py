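"""ICD-10 death-certificate coding pipeline.

Death certificates arrive as semicolon-separated CépiDC-style files: a
CausesBrutes file (one row per certificate line of free text) and an Ident
file (demographics and the primary cause); the aligned layout additionally
carries the gold ICD-10 codes (and optionally a StandardText column). The
pipeline:

1. builds a code index: for each ICD-10 code, the labels from the provided
   code dictionary (DiagnosisText) plus text harvested from gold-coded
   corpus lines;
2. resolves ambiguous labels — a label listed under several codes is kept
   only under its most frequent code (MFC), frequencies estimated from
   training gold; ties go to the lexicographically smallest code;
3. emits the resolved index as a SKOS vocabulary (one skos:Concept per
   code, preferred label chosen as the shortest label without a run of 3+
   consecutive capitals, i.e. avoiding acronyms);
4. codes certificate lines by dictionary annotation (longest-match), with
   optional post-filters: keep only the most frequent matched code, or keep
   the minimal prefix of matched codes whose cumulative training
   probability reaches a threshold (never fewer than one code).

Demographic fields (age, gender) are read but deliberately not used for
coding.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .dictionary import Dictionary, DictionaryEntry, normalize_label
from .recognizer import RecognitionOptions, compile_matcher, recognize

ICD_CODE_RE = re.compile(r"[A-Z][0-9][0-9]\.?[0-9]?")
_ACRONYM_RUN_RE = re.compile(r"[A-ZÀÂÄÇÉÈÊËÎÏÔÖÙÛÜ]{3,}")

CAUSES_COLUMNS = ("DocID", "YearCoded", "LineID", "RawText", "IntType",
                  "IntValue")
IDENT_COLUMNS = ("DocID", "YearCoded", "Gender", "Age", "LocationOfDeath")


class CepidcFormatError(ValueError):
    pass


@dataclass
class CertificateLine:
    doc_id: str
    year_coded: int
    line_id: int
    raw_text: str
    int_type: int | None = None
    int_value: int | None = None
    standard_text: str | None = None
    gold_codes: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise CepidcFormatError("RawText must be non-empty")

    @property
    def key(self) -> tuple[str, int]:
        return (self.doc_id, self.line_id)


@dataclass
class IdentRecord:
    doc_id: str
    year_coded: int
    gender: int
    age: int
    location_of_death: int
    primary_cause: str | None = None


def _cell(value: str) -> str | None:
    value = value.strip()
    return None if value.upper() == "NULL" or value == "" else value


def _int_or_none(value: str) -> int | None:
    v = _cell(value)
    return int(v) if v is not None else None


def _read_semicolon(path: Path, expected: int,
                    allow_extra: int = 0) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=";")
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and row and row[0].strip().lower() == "docid":
                continue  # header
            if not (expected <= len(row) <= expected + allow_extra):
                raise CepidcFormatError(
                    f"{path}:{lineno}: expected {expected} fields "
                    f"(got {len(row)}): {';'.join(row)!r}")
            yield lineno, [c.strip() for c in row]


def read_cepidc(paths: dict[str, str | Path], layout: str = "raw",
                ) -> tuple[list[CertificateLine], list[IdentRecord]]:
    """Read CépiDC-style files.

    ``paths['causes']`` is required; ``paths['ident']`` optional. In the
    ``aligned`` layout the causes file carries two or three extra columns
    (optional StandardText, then ICD10; several codes separated by ``|``).
    """
    if layout not in ("raw", "aligned"):
        raise ValueError(f"unknown layout {layout!r}")
    causes_path = Path(paths["causes"])
    lines: list[CertificateLine] = []
    if layout == "raw":
        for lineno, row in _read_semicolon(causes_path, len(CAUSES_COLUMNS)):
            try:
                lines.append(CertificateLine(
                    doc_id=row[0], year_coded=int(row[1]), line_id=int(row[2]),
                    raw_text=row[3], int_type=_int_or_none(row[4]),
                    int_value=_int_or_none(row[5])))
            except (ValueError, CepidcFormatError) as err:
                raise CepidcFormatError(f"{causes_path}:{lineno}: {err}")
    else:
        n = len(CAUSES_COLUMNS)
        for lineno, row in _read_semicolon(causes_path, n + 1, allow_extra=1):
            std = row[n] if len(row) == n + 2 else None
            codes_cell = row[-1]
            codes = [c.strip() for c in codes_cell.split("|") if c.strip()]
            for code in codes:
                if not ICD_CODE_RE.fullmatch(code):
                    raise CepidcFormatError(
                        f"{causes_path}:{lineno}: invalid ICD-10 code {code!r}")
            try:
                lines.append(CertificateLine(
                    doc_id=row[0], year_coded=int(row[1]), line_id=int(row[2]),
                    raw_text=row[3], int_type=_int_or_none(row[4]),
                    int_value=_int_or_none(row[5]), standard_text=std,
                    gold_codes=codes))
            except (ValueError, CepidcFormatError) as err:
                raise CepidcFormatError(f"{causes_path}:{lineno}: {err}")
    idents: list[IdentRecord] = []
    if paths.get("ident"):
        ident_path = Path(paths["ident"])
        for lineno, row in _read_semicolon(ident_path, len(IDENT_COLUMNS),
                                           allow_extra=1):
            try:
                idents.append(IdentRecord(
                    doc_id=row[0], year_coded=int(row[1]), gender=int(row[2]),
                    age=int(row[3]), location_of_death=int(row[4]),
                    primary_cause=_cell(row[5]) if len(row) > 5 else None))
            except ValueError as err:
                raise CepidcFormatError(f"{ident_path}:{lineno}: {err}")
    return lines, idents


def select_preferred_label(labels: list[str]) -> str:
    """Shortest label without a run of 3+ consecutive capitals (likely an
    acronym); fallback: shortest overall. Ties: first in input order."""
    if not labels:
        raise ValueError("empty label list")
    clean = [l for l in labels if not _ACRONYM_RUN_RE.search(l)]
    pool = clean or labels
    return min(pool, key=lambda l: len(l))  # min is stable: first wins ties


@dataclass
class CodeFrequencyTable:
    counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_aligned(cls, lines: list[CertificateLine]) -> "CodeFrequencyTable":
        counter: Counter[str] = Counter()
        for line in lines:
            for code in line.gold_codes or []:
                counter[code] += 1
        return cls(dict(counter))

    def get(self, code: str) -> int:
        return self.counts.get(code, 0)

    def most_frequent(self, codes) -> str:
        return min(codes, key=lambda c: (-self.get(c), c))


def build_code_index(dict_rows: Iterable[tuple[str, str]],
                     aligned_lines: list[CertificateLine] | None = None,
                     ) -> dict[str, list[str]]:
    """code -> ordered labels: DiagnosisText first, then corpus text.

    Labels are normalized and de-duplicated per code.
    """
    index: dict[str, list[str]] = {}

    def add(code: str, label: str) -> None:
        if not ICD_CODE_RE.fullmatch(code):
            raise ValueError(f"invalid ICD-10 code {code!r}")
        surface = normalize_label(label)
        if not surface:
            return
        bucket = index.setdefault(code, [])
        if surface not in bucket:
            bucket.append(surface)

    for code, text in dict_rows:
        add(code, text)
    for line in aligned_lines or []:
        for code in line.gold_codes or []:
            add(code, line.raw_text)
            if line.standard_text:
                add(code, line.standard_text)
    return index


def assign_ambiguous_labels(index: dict[str, list[str]],
                            freqs: CodeFrequencyTable) -> dict[str, list[str]]:
    """Keep each ambiguous label only under its most frequent code (MFC)."""
    owners: dict[str, str] = {}
    label_codes: dict[str, list[str]] = {}
    for code, labels in index.items():
        for label in labels:
            label_codes.setdefault(label, []).append(code)
    for label, codes in label_codes.items():
        owners[label] = freqs.most_frequent(codes) if len(codes) > 1 else codes[0]
    resolved: dict[str, list[str]] = {}
    for code, labels in index.items():
        kept = [l for l in labels if owners[l] == code]
        if kept:
            resolved[code] = kept
    return resolved


def emit_skos(index: dict[str, list[str]], path: str | Path,
              base_uri: str = "http://purl.org/frannot/icd10dc#") -> None:
    """Write the resolved index as a SKOS Turtle vocabulary.

    One skos:Concept per code (URI = base + code), preferred label via
    ``select_preferred_label``, remaining labels as altLabel. The file is
    reloadable through the minimal SKOS terminology reader.
    """
    import rdflib
    from rdflib.namespace import RDF, SKOS

    g = rdflib.Graph()
    g.bind("skos", SKOS)
    for code in sorted(index):
        uri = rdflib.URIRef(base_uri + code)
        g.add((uri, RDF.type, SKOS.Concept))
        pref = select_preferred_label(index[code])
        g.add((uri, SKOS.prefLabel, rdflib.Literal(pref, lang="fr")))
        g.add((uri, SKOS.notation, rdflib.Literal(code)))
        for label in index[code]:
            if label != pref:
                g.add((uri, SKOS.altLabel, rdflib.Literal(label, lang="fr")))
    g.serialize(destination=str(path), format="turtle")


class CertificateCoder:
    """Annotation-based line coder over a resolved code index.

    Matching follows the recognizer's longest-match semantics (diacritic
    and case folding included), as in the evaluation runs.
    """

    def __init__(self, index: dict[str, list[str]],
                 freqs: CodeFrequencyTable | None = None) -> None:
        if not index:
            raise ValueError("empty code index")
        self.index = index
        self.freqs = freqs or CodeFrequencyTable()
        entries = []
        for i, code in enumerate(sorted(index), start=1):
            for label in index[code]:
                entries.append(DictionaryEntry(
                    entry_id=i, surface=label, source=("CIM10DC", code)))
        self._matcher = compile_matcher(Dictionary(entries))
        self._options = RecognitionOptions(longest_only=True)

    def code_line(self, text: str) -> set[str]:
        anns = recognize(self._matcher, text, self._options)
        return {a.concept[1] for a in anns}


def _apply_post(codes: set[str], post, freqs: CodeFrequencyTable) -> set[str]:
    if not codes or post is None or post == "none":
        return set(codes)
    if post == "mfc":
        return {freqs.most_frequent(codes)}
    if isinstance(post, tuple) and post and post[0] == "cutoff":
        threshold = float(post[1])
        ordered = sorted(codes, key=lambda c: (-freqs.get(c), c))
        total = sum(freqs.get(c) for c in ordered)
        if total == 0:
            return {ordered[0]}
        kept, cum = [], 0.0
        for code in ordered:
            kept.append(code)
            cum += freqs.get(code) / total
            if cum >= threshold:
                break
        return set(kept)
    raise ValueError(f"unknown post-filter {post!r}")


def code_certificates(lines: list[CertificateLine], coder: CertificateCoder,
                      post="none") -> list[tuple[CertificateLine, set[str]]]:
    """Code each line; ``post`` is 'none', 'mfc' or ('cutoff', threshold)."""
    out = []
    for line in lines:
        codes = _apply_post(coder.code_line(line.raw_text), post, coder.freqs)
        out.append((line, codes))
    return out
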