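"""Multi-pattern concept recognition over normalized text.

This is the in-repo replacement for the closed-source Mgrep recognizer: an
Aho-Corasick automaton over the normalized dictionary surfaces, run on the
normalized view of the input text, with spans mapped back to the original
string. Option semantics:

* ``partial_words=False`` (default): match boundaries must coincide with
  token boundaries of the normalized text; ``True`` allows in-token
  substring matches (e.g. "vasculaire" inside "cardiovasculaire").
* matches whose every token is a stopword or shorter than
  ``min_token_length`` are suppressed;
* ``longest_only=True`` removes annotations whose span is strictly
  contained in another annotation's span (identical spans all survive).

Equal-length overlapping matches from different concepts are all kept:
ambiguity is resolved downstream (semantic filtering, DAA/DBP).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .annotations import Annotation, Span
from .dictionary import Dictionary, load_stopwords
from .normalize import normalize_text, tokenize


@dataclass(frozen=True)
class RecognitionOptions:
    longest_only: bool = False
    partial_words: bool = False
    stopwords: frozenset[str] = field(default_factory=load_stopwords)
    min_token_length: int = 3

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


class _AhoCorasick:
    """Classic Aho-Corasick automaton (goto/fail/output) over characters."""

    def __init__(self, patterns: list[str]) -> None:
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.output: list[list[int]] = [[]]
        self.patterns = patterns
        for pid, pat in enumerate(patterns):
            state = 0
            for ch in pat:
                nxt = self.goto[state].get(ch)
                if nxt is None:
                    nxt = len(self.goto)
                    self.goto[state][ch] = nxt
                    self.goto.append({})
                    self.fail.append(0)
                    self.output.append([])
                state = nxt
            self.output[state].append(pid)
        queue: deque[int] = deque()
        for state in self.goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self.goto[state].items():
                queue.append(nxt)
                f = self.fail[state]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[nxt] = self.goto[f].get(ch, 0) if self.goto[f].get(
                    ch, 0) != nxt else 0
                self.output[nxt] = self.output[nxt] + self.output[self.fail[nxt]]

    def finditer(self, text: str):
        """Yield (begin, end, pattern_id) for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self.goto[state]:
                state = self.fail[state]
            state = self.goto[state].get(ch, 0)
            for pid in self.output[state]:
                end = i + 1
                yield end - len(self.patterns[pid]), end, pid


@dataclass
class Matcher:
    automaton: _AhoCorasick
    surface_entries: dict[str, list[tuple[tuple[str, str] | None, str]]]
    fold_diacritics: bool = True


def compile_matcher(d: Dictionary, fold_diacritics: bool = True) -> Matcher:
    """Compile the dictionary into an automaton over its distinct surfaces."""
    if not d.entries:
        raise ValueError("cannot compile a matcher from an empty dictionary")
    surface_entries: dict[str, list[tuple[tuple[str, str] | None, str]]] = {}
    for e in d.entries:
        bucket = surface_entries.setdefault(e.surface, [])
        ref = (e.source, e.label_kind)
        if ref not in bucket:
            bucket.append(ref)
    patterns = sorted(surface_entries)
    return Matcher(_AhoCorasick(patterns), surface_entries, fold_diacritics)


def _suppressed(surface: str, ro: RecognitionOptions) -> bool:
    tokens = tokenize(surface)
    return all(
        tok in ro.stopwords or len(tok) < ro.min_token_length for tok in tokens)


def filter_longest_only(annotations: list[Annotation]) -> list[Annotation]:
    """Keep annotations not strictly contained in another annotation's span."""
    spans = {a.span for a in annotations}
    return [a for a in annotations
            if not any(s.strictly_contains(a.span) for s in spans)]


def recognize(m: Matcher, text: str,
              ro: RecognitionOptions | None = None) -> list[Annotation]:
    """All dictionary matches in ``text`` as annotations on original offsets.

    One annotation per (occurrence, concept): a surface shared by several
    concepts yields one annotation per concept at each occurrence.
    """
    ro = ro or RecognitionOptions()
    if not text:
        return []
    norm = normalize_text(text, fold_diacritics=m.fold_diacritics)
    if not norm.text:
        return []
    out: list[Annotation] = []
    for nb, ne, pid in m.automaton.finditer(norm.text):
        surface = m.automaton.patterns[pid]
        if not ro.partial_words and not (
                norm.is_token_start(nb) and norm.is_token_end(ne)):
            continue
        if _suppressed(surface, ro):
            continue
        ob, oe = norm.to_original(nb, ne)
        span = Span(ob, oe)
        for source, kind in m.surface_entries[surface]:
            match_type = "direct_pref" if kind == "preferred" else "direct_syn"
            out.append(Annotation(
                span=span, matched_text=text[ob:oe],
                concept=source if source is not None else ("?", surface),
                match_type=match_type))
    out.sort(key=lambda a: (a.span.begin, a.span.end, a.concept))
    if ro.longest_only:
        out = filter_longest_only(out)
    return out


def attach_semantics(annotations: list[Annotation], terminologies,
                     table=None) -> list[Annotation]:
    """Fill CUIs/TUIs (from the concepts) and groups (via the table)."""
    by_acr = {t.acronym: t for t in terminologies}
    out = []
    for ann in annotations:
        acr, cid = ann.concept
        term = by_acr.get(acr)
        concept = term.concepts.get(cid) if term else None
        if concept is None:
            out.append(ann)
            continue
        groups = table.groups_for(concept.tuis) if table else ann.groups
        out.append(ann.with_(cuis=concept.cuis, tuis=concept.tuis,
                             groups=groups))
    return out
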