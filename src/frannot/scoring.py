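"""Annotation scoring and score-based pruning.

Three scoring methods, selected by name:

* ``old`` — the legacy weighted-frequency method: each concept's score is
  the sum over its matches in the document of a per-match-type weight
  (defaults: direct preferred label 10, synonym 8, hierarchy at level L
  max(1, 8 - 2*(L-1)), mapping 7; configurable).
* ``cvalue`` — a C-value adaptation rewarding multi-word terms. For a
  distinct matched term a with token count |a| and in-document occurrence
  frequency f(a):

      cvalue(a) = log2(|a| + 1) * f(a)                        if a is not
                                                              nested
      cvalue(a) = log2(|a| + 1) * (f(a) - mean_{b∈Ta} f(b))   otherwise

  where Ta is the set of longer matched terms containing a (token-boundary
  substring containment between normalized surfaces). log2(|a|+1) rather
  than log2|a| keeps single-token terms at a non-zero score. Scores are
  clamped at 0.
* ``cvalueh`` — C-value computed on direct matches only; hierarchy and
  mapping annotations inherit the score of the term they were expanded
  from (same span and matched text).

Pruning supports an absolute threshold (keep score >= t, inclusive) and a
relative one: keep annotations at or above the p-th nearest-rank percentile
of the set's score distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotations import Annotation, Span
from .normalize import normalize, tokenize

METHODS = ("old", "cvalue", "cvalueh")

DEFAULT_OLD_WEIGHTS = {"direct_pref": 10.0, "direct_syn": 8.0, "mapping": 7.0}


def _old_weight(ann: Annotation, weights: dict[str, float]) -> float:
    if ann.match_type == "hierarchy":
        return max(1.0, 8.0 - 2.0 * (ann.hierarchy_level - 1))
    return weights[ann.match_type]


@dataclass
class ScoredAnnotationSet:
    annotations: list[Annotation]
    method: str

    def scores(self) -> list[float]:
        return [a.score for a in self.annotations]


def _term_occurrences(anns: list[Annotation]) -> dict[str, set[Span]]:
    """Distinct occurrence spans per normalized matched term."""
    occ: dict[str, set[Span]] = {}
    for a in anns:
        occ.setdefault(normalize(a.matched_text), set()).add(a.span)
    return occ


def _cvalue_scores(anns: list[Annotation]) -> dict[str, float]:
    occ = _term_occurrences(anns)
    freq = {t: len(spans) for t, spans in occ.items()}
    terms = sorted(freq)
    scores: dict[str, float] = {}
    for a in terms:
        na = len(tokenize(a))
        containers = [b for b in terms
                      if b != a and f" {a} " in f" {b} "]
        base = math.log2(na + 1)
        if containers:
            discount = sum(freq[b] for b in containers) / len(containers)
            score = base * (freq[a] - discount)
        else:
            score = base * freq[a]
        scores[a] = max(0.0, score)
    return scores


def score_annotations(anns: list[Annotation], method: str = "cvalue",
                      old_weights: dict[str, float] | None = None,
                      ) -> ScoredAnnotationSet:
    """Score one document's annotations; scores compare within one method."""
    if method not in METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    if method == "old":
        weights = dict(DEFAULT_OLD_WEIGHTS, **(old_weights or {}))
        per_concept: dict[tuple, float] = {}
        for a in anns:
            per_concept[a.concept] = per_concept.get(a.concept, 0.0) + \
                _old_weight(a, weights)
        scored = [a.with_(score=per_concept[a.concept]) for a in anns]
        return ScoredAnnotationSet(scored, method)
    direct = [a for a in anns if a.match_type in ("direct_pref", "direct_syn")]
    basis = anns if method == "cvalue" else (direct or anns)
    term_scores = _cvalue_scores(basis)
    scored = []
    for a in anns:
        term = normalize(a.matched_text)
        # expanded annotations inherit their source term's score (same span
        # and matched text by construction)
        scored.append(a.with_(score=term_scores.get(term, 0.0)))
    return ScoredAnnotationSet(scored, method)


def nearest_rank_percentile(values: list[float], p: int) -> float:
    """Nearest-rank p-th percentile of a non-empty multiset (p in 0..100)."""
    if not 0 <= p <= 100:
        raise ValueError("percentile must be in 0..100")
    ordered = sorted(values)
    if p == 0:
        return ordered[0]
    rank = math.ceil(p / 100 * len(ordered))
    return ordered[rank - 1]


def prune_by_score(s: ScoredAnnotationSet,
                   score_threshold: float | None = None,
                   confidence_threshold: int | None = None,
                   ) -> ScoredAnnotationSet:
    """Absolute cut first (inclusive), then the relative percentile cut."""
    anns = list(s.annotations)
    if score_threshold is not None:
        anns = [a for a in anns if a.score >= score_threshold]
    if confidence_threshold is not None and anns:
        if not 0 <= confidence_threshold <= 100:
            raise ValueError("confidence_threshold must be in 0..100")
        cut = nearest_rank_percentile([a.score for a in anns],
                                      confidence_threshold)
        anns = [a for a in anns if a.score >= cut]
    return ScoredAnnotationSet(anns, s.method)
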