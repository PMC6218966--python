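"""Compile the flat matching dictionary from terminologies.

The matching dictionary is a list of (entry id, surface form) rows in the
Mgrep TSV dialect: one numeric id per concept, repeated across all that
concept's surface forms. Identical surfaces contributed by different
concepts keep distinct entry ids — ambiguity is resolved downstream.

Recall-extension heuristics (off by default, as they trade precision for
recall):

* drop trailing qualifiers ("SAI", "sans précision(s)", "sans autre
  précision(s)", "sans explication(s)", "non classé(e)s ailleurs");
* split conjunctive labels on coordinating conjunctions (et/ou), with
  shared-head reconstruction for the pattern "A de X et de Y";
* remove parenthesized or bracketed precisions.

An optional lemmatized twin dictionary maps surfaces through a pluggable
lemmatizer; the default is a rule-based French plural stripper (final s/x
removed from tokens of 4+ characters).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .normalize import normalize, tokenize
from .terminology import Terminology

LABEL_KINDS = ("preferred", "synonym", "heuristic_variant", "lemmatized")

# trailing qualifiers compared on the normalized (folded) label
_QUALIFIER_RE = re.compile(
    r"[\s,;:]*\b(sai|sans precisions?|sans autres? precisions?|"
    r"sans explications?|non classe?e?s ailleurs)\s*$")
_PAREN_RE = re.compile(r"\s*[(\[][^()\[\]]*[)\]]")
_DE_MARKERS = (" de ", " du ", " des ", " d'", " d’")


@dataclass(frozen=True)
class BuildOptions:
    heuristics: bool = False
    fold_diacritics: bool = True
    lemmatize: bool = False
    lemmatizer: Callable[[str], str] | None = None

    def fingerprint(self) -> str:
        payload = (
            f"heuristics={self.heuristics};fold={self.fold_diacritics};"
            f"lemmatize={self.lemmatize};"
            f"lemmatizer={'default' if self.lemmatizer is None else 'custom'}")
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DictionaryEntry:
    entry_id: int
    surface: str
    source: tuple[str, str] | None  # (terminology acronym, concept_id)
    label_kind: str = "synonym"

    def __post_init__(self) -> None:
        if self.entry_id <= 0:
            raise ValueError("entry_id must be positive")
        if not self.surface:
            raise ValueError("surface must be non-empty after normalization")
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"unknown label kind {self.label_kind!r}")


@dataclass
class Dictionary:
    entries: list[DictionaryEntry] = field(default_factory=list)
    options_fingerprint: str = ""

    @property
    def id_to_source(self) -> dict[int, tuple[str, str] | None]:
        out: dict[int, tuple[str, str] | None] = {}
        for e in self.entries:
            prev = out.setdefault(e.entry_id, e.source)
            if prev != e.source:
                raise ValueError(
                    f"entry_id {e.entry_id} maps to both {prev} and {e.source}")
        return out

    def surfaces(self) -> set[str]:
        return {e.surface for e in self.entries}


def normalize_label(label: str, opts: BuildOptions | None = None) -> str:
    """Normalize a label exactly as the matcher normalizes text (idempotent)."""
    opts = opts or BuildOptions()
    return normalize(label, fold_diacritics=opts.fold_diacritics)


def default_french_lemmatizer(surface: str) -> str:
    """Strip final s/x from tokens of 4+ characters (French plural rule)."""
    out = []
    for tok in tokenize(surface):
        if len(tok) >= 4 and tok[-1] in "sx":
            tok = tok[:-1]
        out.append(tok)
    return " ".join(out)


def _strip_qualifier(label: str) -> str | None:
    norm_probe = normalize(label)
    if not _QUALIFIER_RE.search(norm_probe):
        return None
    # remove on the raw label: fold-insensitively match the trailing piece
    raw_re = re.compile(
        r"[\s,;:]*\b(sai|sans\s+pr[ée]cisions?|sans\s+autres?\s+pr[ée]cisions?|"
        r"sans\s+explications?|non\s+class[ée]?e?s\s+ailleurs)\s*$",
        re.IGNORECASE)
    stripped = raw_re.sub("", label).strip(" ,;:")
    return stripped or None


def _split_conjunction(label: str) -> list[str]:
    for conj in (" et ", " ou "):
        if conj in label:
            left, right = label.split(conj, 1)
            left, right = left.strip(), right.strip()
            variants = [v for v in (left,) if v]
            # shared-head pattern "A de X et de Y" -> "A de X", "A de Y"
            head = None
            if any(right.startswith(m.strip() + " ") or right.startswith("d'")
                   or right.startswith("d’") for m in _DE_MARKERS):
                positions = [left.rfind(m) for m in _DE_MARKERS]
                cut = max(positions)
                if cut > 0:
                    head = left[:cut].strip()
            if head:
                variants.append(f"{head} {right}")
            elif right:
                variants.append(right)
            return variants
    return []


def _strip_parentheticals(label: str) -> str | None:
    if not _PAREN_RE.search(label):
        return None
    stripped = _PAREN_RE.sub("", label).strip()
    return stripped if stripped and stripped != label else None


def apply_recall_heuristics(label: str) -> set[str]:
    """Label variants from the recall-extension heuristics.

    The original label is always included (no rule ever fully consumes it).
    """
    variants = {label}
    q = _strip_qualifier(label)
    if q:
        variants.add(q)
    p = _strip_parentheticals(label)
    if p:
        variants.add(p)
        q2 = _strip_qualifier(p)
        if q2:
            variants.add(q2)
    for base in list(variants):
        variants.update(_split_conjunction(base))
    return variants


def build_dictionary(terminologies: Iterable[Terminology],
                     opts: BuildOptions | None = None) -> Dictionary:
    """One entry per (concept, distinct normalized surface).

    Entry ids are sequential integers assigned in deterministic
    (acronym, concept_id) sort order, so identical inputs and options give
    byte-identical dictionaries.
    """
    opts = opts or BuildOptions()
    terms = list(terminologies)
    if not terms:
        raise ValueError("at least one terminology is required")
    lemmatizer = opts.lemmatizer or default_french_lemmatizer
    entries: list[DictionaryEntry] = []
    next_id = 1
    for term in sorted(terms, key=lambda t: t.acronym):
        for cid in sorted(term.concepts):
            concept = term.concepts[cid]
            entry_id = next_id
            next_id += 1
            labelled: list[tuple[str, str]] = [(concept.pref_label, "preferred")]
            labelled += [(s, "synonym") for s in concept.synonyms]
            if opts.heuristics:
                for lab, _ in list(labelled):
                    for var in sorted(apply_recall_heuristics(lab)):
                        labelled.append((var, "heuristic_variant"))
            if opts.lemmatize:
                for lab, _ in list(labelled):
                    labelled.append(
                        (lemmatizer(normalize_label(lab, opts)), "lemmatized"))
            seen: set[str] = set()
            for label, kind in labelled:
                surface = normalize_label(label, opts)
                if not surface or surface in seen:
                    continue
                seen.add(surface)
                entries.append(DictionaryEntry(
                    entry_id=entry_id, surface=surface,
                    source=(term.acronym, cid), label_kind=kind))
    return Dictionary(entries=entries, options_fingerprint=opts.fingerprint())


def write_mgrep_tsv(d: Dictionary, path: str | Path) -> None:
    """Two-column TSV: entry_id TAB surface (the Mgrep dictionary dialect)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in d.entries:
            fh.write(f"{e.entry_id}\t{e.surface}\n")


def read_mgrep_tsv(path: str | Path) -> Dictionary:
    """Read an Mgrep TSV; label kinds and sources are not serialized."""
    entries: list[DictionaryEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: want entry_id<TAB>surface, got {line!r}")
            try:
                entry_id = int(parts[0])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric entry id {parts[0]!r}")
            entries.append(DictionaryEntry(
                entry_id=entry_id, surface=parts[1], source=None))
    return Dictionary(entries=entries)


def load_stopwords() -> frozenset[str]:
    """The small shipped French stopword list (normalized forms)."""
    from importlib import resources

    text = resources.files("frannot.data").joinpath(
        "stopwords_fr.txt").read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())
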