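"""Clinical context detection (negation, experiencer, temporality).

A ConText/NegEx-style rule engine: trigger phrases open a directional scope
(forward from after the trigger, backward up to the trigger) that closes at
the sentence end, at a colon, or at the nearest termination term. An
annotation whose span intersects an open scope of a category receives that
category's non-default value; with no trigger in scope a condition is
affirmed, about the patient, and recent. Pseudo-trigger phrases mask the
real triggers they contain (e.g. "sans doute" neutralizes "sans"); at a
given position the longest trigger phrase wins. Scopes never cross sentence
boundaries.

The shipped French trigger lexicon is a documented seed — deliberately
small, meant for tests and as a starting point, not a complete clinical
inventory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .annotations import Annotation, ContextLabels, Span
from .normalize import normalize, normalize_text

logger = logging.getLogger(__name__)

CATEGORIES = ("negation", "experiencer_other", "temporality_historical",
              "temporality_hypothetical")
DIRECTIONS = ("forward", "backward", "both")
KINDS = ("trigger", "pseudo", "termination")

_CATEGORY_DIMENSION = {
    "negation": ("negation", "negated"),
    "experiencer_other": ("experiencer", "other"),
    "temporality_historical": ("temporality", "historical"),
    "temporality_hypothetical": ("temporality", "hypothetical"),
}
_SENTENCE_TERMINATORS = ".!?\n"


@dataclass(frozen=True)
class TriggerTerm:
    phrase: str  # normalized, possibly multi-token
    category: str | None
    direction: str | None
    kind: str = "trigger"

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("trigger phrase must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"unknown trigger kind {self.kind!r}")
        if self.kind == "termination":
            return  # termination terms close all scopes, category-free
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown trigger category {self.category!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown trigger direction {self.direction!r}")


def load_trigger_lexicon(path: str | Path | None = None) -> list[TriggerTerm]:
    """Load a TSV lexicon (phrase/category/direction/kind); ``None`` loads
    the shipped seed. Duplicate (phrase, category) pairs: last wins."""
    if path is None:
        text = resources.files("frannot.data").joinpath(
            "triggers_fr.tsv").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    terms: dict[tuple[str, str | None], TriggerTerm] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line.lower().startswith("phrase\t"):
            continue
        parts = (line.split("\t") + ["", "", ""])[:4]
        phrase = normalize(parts[0])
        kind = parts[3].strip() or "trigger"
        category = parts[1].strip() or None
        direction = parts[2].strip() or None
        term = TriggerTerm(phrase=phrase, category=category,
                           direction=direction, kind=kind)
        key = (phrase, category)
        if key in terms:
            logger.warning("duplicate trigger %r (%s): last wins",
                           phrase, category)
        terms[key] = term
    return list(terms.values())


def segment_sentences(text: str) -> list[Span]:
    """Split on ., !, ? and newline; spans cover all non-whitespace text."""
    spans: list[Span] = []
    start = None
    for i, ch in enumerate(text):
        if start is None:
            if not ch.isspace():
                start = i
        if ch in _SENTENCE_TERMINATORS and start is not None:
            end = i if ch == "\n" else i + 1
            if end > start:
                spans.append(Span(start, end))
            start = None
    if start is not None and len(text) > start:
        spans.append(Span(start, len(text)))
    return spans


@dataclass(frozen=True)
class _Occurrence:
    begin: int  # original offsets
    end: int
    term: TriggerTerm


def _find_occurrences(sentence: str, offset: int,
                      lexicon: list[TriggerTerm]) -> list[_Occurrence]:
    norm = normalize_text(sentence)
    if not norm.text:
        return []
    found: list[tuple[int, int, TriggerTerm]] = []  # norm offsets
    for term in lexicon:
        start = 0
        while True:
            i = norm.text.find(term.phrase, start)
            if i < 0:
                break
            j = i + len(term.phrase)
            if norm.is_token_start(i) and norm.is_token_end(j):
                found.append((i, j, term))
            start = i + 1
    # longest phrase wins at a shared start position
    found.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    kept: list[tuple[int, int, TriggerTerm]] = []
    for i, j, term in found:
        if term.kind == "pseudo":
            kept.append((i, j, term))
            continue
        if any(i == ki and (j - i) < (kj - ki) and kterm.kind != "pseudo"
               for ki, kj, kterm in found
               if (ki, kj, kterm) != (i, j, term)):
            continue
        kept.append((i, j, term))
    # pseudo occurrences mask the triggers they contain
    pseudo_spans = [(i, j) for i, j, t in kept if t.kind == "pseudo"]
    final = []
    for i, j, term in kept:
        if term.kind != "pseudo" and any(
                pi <= i and j <= pj and (pi, pj) != (i, j)
                for pi, pj in pseudo_spans):
            continue
        final.append((i, j, term))
    out = []
    for i, j, term in final:
        ob, oe = norm.to_original(i, j)
        out.append(_Occurrence(offset + ob, offset + oe, term))
    return sorted(out, key=lambda o: (o.begin, o.end))


@dataclass(frozen=True)
class _Scope:
    begin: int
    end: int
    category: str
    trigger: _Occurrence


def _scopes_for_sentence(text: str, sent: Span,
                         occurrences: list[_Occurrence]) -> list[_Scope]:
    terminations = [o for o in occurrences if o.term.kind == "termination"]
    colons = [i for i in range(sent.begin, sent.end) if text[i] == ":"]
    scopes: list[_Scope] = []
    for occ in occurrences:
        if occ.term.kind != "trigger":
            continue
        directions = (occ.term.direction,) if occ.term.direction != "both" \
            else ("forward", "backward")
        for direction in directions:
            if direction == "forward":
                end = sent.end
                for t in terminations:
                    if t.begin >= occ.end:
                        end = min(end, t.begin)
                        break
                nxt_colon = [c for c in colons if c >= occ.end]
                if nxt_colon:
                    end = min(end, nxt_colon[0])
                if end > occ.end:
                    scopes.append(_Scope(occ.end, end, occ.term.category, occ))
            else:
                begin = sent.begin
                for t in reversed(terminations):
                    if t.end <= occ.begin:
                        begin = max(begin, t.end)
                        break
                prev_colon = [c for c in colons if c < occ.begin]
                if prev_colon:
                    begin = max(begin, prev_colon[-1] + 1)
                if begin < occ.begin:
                    scopes.append(_Scope(begin, occ.begin,
                                         occ.term.category, occ))
    return scopes


def detect_context(anns: list[Annotation], text: str,
                   lexicon: list[TriggerTerm] | None = None,
                   negation: bool = True, experiencer: bool = True,
                   temporality: bool = True) -> list[Annotation]:
    """Assign context labels to annotations; disabled flags stay default."""
    if lexicon is None:
        lexicon = load_trigger_lexicon()
    flags = {"negation": negation, "experiencer": experiencer,
             "temporality": temporality}
    sentences = segment_sentences(text)
    all_scopes: list[_Scope] = []
    for sent in sentences:
        occurrences = _find_occurrences(
            text[sent.begin:sent.end], sent.begin, lexicon)
        all_scopes.extend(_scopes_for_sentence(text, sent, occurrences))
    out: list[Annotation] = []
    for ann in anns:
        values = {"negation": "affirmed", "experiencer": "patient",
                  "temporality": "recent"}
        nearest: dict[str, int] = {}
        for scope in all_scopes:
            dimension, value = _CATEGORY_DIMENSION[scope.category]
            if not flags[dimension]:
                continue
            s = Span(scope.begin, scope.end)
            if not s.intersects(ann.span):
                continue
            distance = min(abs(ann.span.begin - scope.trigger.end),
                           abs(scope.trigger.begin - ann.span.end))
            if dimension not in nearest or distance < nearest[dimension]:
                nearest[dimension] = distance
                values[dimension] = value
        out.append(ann.with_(context=ContextLabels(
            negation=values["negation"], experiencer=values["experiencer"],
            temporality=values["temporality"])))
    return out
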