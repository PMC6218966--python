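"""Evaluation: PER/NER entity scorers, coding scorer, gold pruning, and the
terminology-subset grid search.

PER (plain entity recognition) scores a prediction as a true positive only
when an unmatched gold entity has identical fragment offsets AND an
identical Semantic Group — so a correctly located entity with the wrong
group produces both a false positive and a false negative. Matching is
one-to-one, greedy in document order.

NER (normalized entity recognition) scores CUIs on top of the PER matching:
on a matched entity pair every predicted CUI in the gold set is a TP and
every extra predicted CUI an FP; CUIs of unmatched predictions are all FPs
even when a gold CUI coincides elsewhere, and unmatched gold entities
contribute their CUIs as FNs.

The coding scorer counts code-set overlap per certificate line, optionally
restricted to the external-causes chapter (V01–Y98 by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .annotations import Annotation, Span

EXTERNAL_CAUSES_RANGE = ("V01", "Y98")


@dataclass(frozen=True)
class GoldEntity:
    """A gold mention: >= 1 fragments (discontinuous entities supported)."""

    fragments: tuple[Span, ...]
    group: str
    cuis: frozenset[str] = frozenset()
    text: str = ""

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("gold entity needs at least one fragment")
        frags = sorted(self.fragments)
        for a, b in zip(frags, frags[1:]):
            if a.end > b.begin:
                raise ValueError("gold fragments overlap")
        object.__setattr__(self, "fragments", tuple(frags))


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def _pred_units(pred: list[Annotation]) -> list[tuple[tuple[Span, ...],
                                                      frozenset[str],
                                                      frozenset[str]]]:
    """Distinct (fragments, groups, cuis) units in document order."""
    units = []
    seen = set()
    for a in sorted(pred, key=lambda x: (x.span.begin, x.span.end,
                                         tuple(sorted(x.groups)))):
        key = ((a.span,), a.groups)
        if key in seen:
            continue
        seen.add(key)
        cuis = frozenset().union(
            *[b.cuis for b in pred
              if b.span == a.span and b.groups == a.groups]) \
            if pred else frozenset()
        units.append(((a.span,), a.groups, cuis))
    return units


def _match_per(gold: list[GoldEntity], pred: list[Annotation]):
    """Greedy one-to-one matching on (fragments, group) identity."""
    units = _pred_units(pred)
    unmatched_gold = list(gold)
    pairs = []
    unmatched_pred = []
    for frags, groups, cuis in units:
        hit = None
        for g in unmatched_gold:
            if g.fragments == frags and groups == frozenset({g.group}):
                hit = g
                break
        if hit is not None:
            unmatched_gold.remove(hit)
            pairs.append((hit, (frags, groups, cuis)))
        else:
            unmatched_pred.append((frags, groups, cuis))
    return pairs, unmatched_pred, unmatched_gold


def score_per(gold: list[GoldEntity], pred: list[Annotation]) -> EvalResult:
    pairs, unmatched_pred, unmatched_gold = _match_per(gold, pred)
    return EvalResult(tp=len(pairs), fp=len(unmatched_pred),
                      fn=len(unmatched_gold))


def score_ner(gold: list[GoldEntity], pred: list[Annotation]) -> EvalResult:
    pairs, unmatched_pred, unmatched_gold = _match_per(gold, pred)
    tp = fp = fn = 0
    for g, (_, _, cuis) in pairs:
        tp += len(cuis & g.cuis)
        fp += len(cuis - g.cuis)
        fn += len(g.cuis - cuis)
    for _, _, cuis in unmatched_pred:
        fp += len(cuis)
    for g in unmatched_gold:
        fn += len(g.cuis)
    return EvalResult(tp, fp, fn)


def is_external_cause(code: str,
                      code_range: tuple[str, str] = EXTERNAL_CAUSES_RANGE,
                      ) -> bool:
    root = code.replace(".", "")[:3]
    return code_range[0] <= root <= code_range[1]


def score_coding(gold_lines, pred_lines, external_only: bool = False,
                 code_range: tuple[str, str] = EXTERNAL_CAUSES_RANGE,
                 ) -> EvalResult:
    """Micro P/R/F1 over line-aligned (line_key, codes) sequences."""
    gold_lines, pred_lines = list(gold_lines), list(pred_lines)
    if len(gold_lines) != len(pred_lines):
        raise ValueError("gold and prediction line counts differ")
    tp = fp = fn = 0
    for (gkey, gcodes), (pkey, pcodes) in zip(gold_lines, pred_lines):
        if gkey != pkey:
            raise ValueError(f"misaligned line ids: {gkey} vs {pkey}")
        g, p = set(gcodes), set(pcodes)
        if external_only:
            g = {c for c in g if is_external_cause(c, code_range)}
            p = {c for c in p if is_external_cause(c, code_range)}
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    return EvalResult(tp, fp, fn)


def prune_gold_by_cui_coverage(gold: list[GoldEntity],
                               covered_cuis: set[str] | frozenset[str],
                               ) -> list[GoldEntity]:
    """Intersect each entity's CUIs with the covered set; drop entities whose
    intersection is empty (emulating removal of annotations that no loaded
    terminology could ever produce)."""
    out = []
    for g in gold:
        kept = g.cuis & frozenset(covered_cuis)
        if kept:
            out.append(GoldEntity(fragments=g.fragments, group=g.group,
                                  cuis=kept, text=g.text))
    return out


def grid_search(terminologies: list[str], dev_gold: list[GoldEntity],
                annotate_fn, metric: str = "per_f1", max_n: int = 20,
                ) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate every non-empty subset of terminology acronyms.

    ``annotate_fn(subset)`` must return the predictions for the development
    gold under that terminology subset. Returns the argmax subset (ties:
    smaller subset, then lexicographic) and the full 2^n - 1 row table.
    """
    if not 1 <= len(terminologies) <= max_n:
        raise ValueError(f"grid search supports 1..{max_n} terminologies")
    if metric not in ("per_f1", "ner_f1"):
        raise ValueError(f"unknown metric {metric!r}")
    scorer = score_per if metric == "per_f1" else score_ner
    rows = []
    for k in range(1, len(terminologies) + 1):
        for subset in itertools.combinations(sorted(terminologies), k):
            result = scorer(dev_gold, annotate_fn(subset))
            rows.append({
                "subset": ",".join(subset), "k": k,
                "precision": result.precision, "recall": result.recall,
                metric: result.f1,
            })
    table = pd.DataFrame(rows)
    best_idx = min(
        range(len(rows)),
        key=lambda i: (-rows[i][metric], rows[i]["k"], rows[i]["subset"]))
    best_subset = tuple(rows[best_idx]["subset"].split(","))
    return best_subset, table
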