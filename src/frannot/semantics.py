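"""Semantic filtering and semantic expansion of direct annotations.

Filtering keeps annotations whose TUIs intersect the requested Semantic
Types, with Semantic Groups first expanded to their TUIs through the
semantic table (so filtering by group DISO equals filtering by its TUI
list). Expansion adds annotations for ancestor concepts (is-a transitive
closure up to a level bound) and for concepts reachable through one
cross-terminology mapping hop; expanded annotations inherit the span and
matched text of their source. Deduplication precedence on identical
(span, concept) pairs is direct > hierarchy > mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations import Annotation
from .terminology import SemanticTable, Terminology

_PRECEDENCE = {"direct_pref": 0, "direct_syn": 0, "hierarchy": 1, "mapping": 2}


@dataclass(frozen=True)
class ExpansionOptions:
    expand_mappings: bool = False
    expand_class_hierarchy: bool = False
    class_hierarchy_max_level: int = 0
    target_terminologies: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.class_hierarchy_max_level < 0:
            raise ValueError("class_hierarchy_max_level must be >= 0")


def filter_by_semantics(anns: list[Annotation], groups: set[str],
                        types: set[str],
                        table: SemanticTable) -> list[Annotation]:
    """Keep annotations whose TUIs intersect types ∪ expansion(groups).

    Empty groups and types mean no filtering. With a filter active,
    annotations carrying no TUI are dropped.
    """
    if not groups and not types:
        return list(anns)
    active = set(types) | set(table.expand_groups(set(groups)))
    return [a for a in anns if a.tuis & active]


def _dedupe(anns: list[Annotation]) -> list[Annotation]:
    best: dict[tuple, Annotation] = {}
    order: list[tuple] = []
    for a in anns:
        k = a.key
        if k not in best:
            best[k] = a
            order.append(k)
        elif _PRECEDENCE[a.match_type] < _PRECEDENCE[best[k].match_type]:
            best[k] = a
    return [best[k] for k in order]


def expand_hierarchy(anns: list[Annotation], terminologies,
                     max_level: int,
                     table: SemanticTable | None = None) -> list[Annotation]:
    """Add one annotation per ancestor (level <= max_level) of each match.

    Direct annotations are preserved; ancestors inherit the span and matched
    text; all ancestors of a polyhierarchy are emitted at their minimal
    level. ``max_level=0`` is the identity.
    """
    if max_level <= 0:
        return list(anns)
    by_acr: dict[str, Terminology] = {t.acronym: t for t in terminologies}
    out = list(anns)
    for ann in anns:
        acr, cid = ann.concept
        term = by_acr.get(acr)
        if term is None or cid not in term.concepts:
            continue
        for pid, level in term.ancestors(cid, max_level=max_level):
            parent = term.concepts[pid]
            out.append(ann.with_(
                concept=(acr, pid), match_type="hierarchy",
                hierarchy_level=level, cuis=parent.cuis, tuis=parent.tuis,
                groups=(table.groups_for(parent.tuis) if table
                        else frozenset())))
    return _dedupe(out)


def expand_mappings(anns: list[Annotation], terminologies,
                    targets: set[str] | frozenset[str] = frozenset(),
                    table: SemanticTable | None = None) -> list[Annotation]:
    """Add one annotation per concept mapped from each annotating concept.

    One hop only (no transitive chains). When ``targets`` is non-empty the
    returned set keeps only annotations whose terminology is a target:
    direct matches outside the targets serve as bridges and are dropped.
    """
    by_acr: dict[str, Terminology] = {t.acronym: t for t in terminologies}
    out = list(anns)
    for ann in anns:
        acr, cid = ann.concept
        term = by_acr.get(acr)
        if term is None or cid not in term.concepts:
            continue
        for tgt_acr, tgt_id in term.concepts[cid].mappings:
            tgt_term = by_acr.get(tgt_acr)
            if tgt_term is None or tgt_id not in tgt_term.concepts:
                continue  # resolvability only checked when the target is loaded
            mapped = tgt_term.concepts[tgt_id]
            out.append(ann.with_(
                concept=(tgt_acr, tgt_id), match_type="mapping",
                hierarchy_level=None, cuis=mapped.cuis, tuis=mapped.tuis,
                groups=(table.groups_for(mapped.tuis) if table
                        else frozenset())))
    out = _dedupe(out)
    if targets:
        out = [a for a in out if a.concept[0] in targets]
    return out
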