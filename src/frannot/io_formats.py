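"""Readers/writers for BRAT standoff (including the Quaero dialect with CUI
normalization lines) and the JSON annotation schema.

BRAT T lines use 0-based, end-exclusive character offsets into the raw
text: ``T<k>\\t<GROUP> <begin> <end>\\t<covered text>``. Discontinuous gold
entities carry fragmented offsets ``b1 e1;b2 e2``. The Quaero dialect adds
one normalization line per CUI: ``N<j>\\tReference T<k> UMLS:<CUI>``.

The JSON schema (version 1) is a stable-field-order document with the
request echo and one record per annotation (span, concept, match type,
semantic tags, score, context). Context fields are absent when context
detection was not run.
"""

from __future__ import annotations

import json

from .annotations import Annotation, ContextLabels, Span
from .evaluation import GoldEntity

JSON_SCHEMA_VERSION = 1


class BratFormatError(ValueError):
    pass


def _entity_units(anns: list[Annotation]):
    """One unit per distinct (span, group), in document order."""
    seen = set()
    units = []
    for a in sorted(anns, key=lambda x: (x.span.begin, x.span.end)):
        groups = sorted(a.groups) or [None]
        for group in groups:
            key = (a.span, group)
            if key in seen:
                continue
            seen.add(key)
            cuis = set()
            for b in anns:
                if b.span == a.span and (group in b.groups or group is None):
                    cuis |= b.cuis
            units.append((a.span, group, sorted(cuis), a.matched_text))
    return units


def write_brat(anns, text: str, require_group: bool = False,
               with_normalization: bool = False) -> str:
    """Serialize annotations (or gold entities) to BRAT standoff."""
    lines = []
    t_index = 0
    n_index = 0
    if anns and isinstance(anns[0], GoldEntity):
        units = [(g.fragments, g.group, sorted(g.cuis), g.text) for g in anns]
    else:
        units = [((span,), group, cuis, covered)
                 for span, group, cuis, covered in _entity_units(anns)]
    for fragments, group, cuis, covered in units:
        if group is None:
            if require_group:
                raise BratFormatError(
                    "annotation lacks a semantic group; cannot emit")
            group = "MISC"
        for frag in fragments:
            if text[frag.begin:frag.end] == "":
                raise BratFormatError(f"empty fragment {frag}")
        covered_text = " ".join(text[f.begin:f.end] for f in fragments)
        offsets = ";".join(f"{f.begin} {f.end}" for f in fragments)
        t_index += 1
        lines.append(f"T{t_index}\t{group} {offsets}\t"
                     + covered_text.replace("\n", " "))
        if with_normalization:
            for cui in cuis:
                n_index += 1
                lines.append(f"N{n_index}\tReference T{t_index} UMLS:{cui}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_quaero(anns, text: str) -> str:
    """BRAT plus one N (normalization) line per CUI; groups are required."""
    return write_brat(anns, text, require_group=True, with_normalization=True)


def read_brat(ann_string: str, text: str) -> list[GoldEntity]:
    """Parse BRAT standoff into gold entities; validates covered text."""
    entities: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(ann_string.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("T"):
            parts = raw.split("\t")
            if len(parts) < 2:
                raise BratFormatError(f"line {lineno}: malformed T line")
            tid = parts[0]
            head = parts[1]
            covered = parts[2] if len(parts) > 2 else ""
            group, _, offsets_str = head.partition(" ")
            fragments = []
            for frag in offsets_str.split(";"):
                try:
                    b, e = frag.split()
                    fragments.append(Span(int(b), int(e)))
                except ValueError:
                    raise BratFormatError(
                        f"line {lineno}: bad offsets {frag!r}")
            slice_text = " ".join(
                text[f.begin:f.end] for f in fragments).replace("\n", " ")
            if covered and slice_text != covered:
                raise BratFormatError(
                    f"line {lineno}: covered text {covered!r} does not match "
                    f"text slice {slice_text!r}")
            entities[tid] = {"fragments": tuple(fragments), "group": group,
                             "cuis": set(), "text": slice_text}
            order.append(tid)
        elif raw.startswith("N"):
            parts = raw.split("\t")
            if len(parts) < 2:
                raise BratFormatError(f"line {lineno}: malformed N line")
            fields = parts[1].split()
            if len(fields) != 3 or not fields[2].startswith("UMLS:"):
                raise BratFormatError(f"line {lineno}: malformed N reference")
            _, tid, cui_ref = fields
            if tid not in entities:
                raise BratFormatError(
                    f"line {lineno}: N line references unknown {tid}")
            entities[tid]["cuis"].add(cui_ref.removeprefix("UMLS:"))
        # comment (#) and attribute (A) lines are ignored
    return [GoldEntity(fragments=entities[t]["fragments"],
                       group=entities[t]["group"],
                       cuis=frozenset(entities[t]["cuis"]),
                       text=entities[t]["text"]) for t in order]


def _annotation_record(a: Annotation) -> dict:
    record = {
        "begin": a.span.begin,
        "end": a.span.end,
        "matched_text": a.matched_text,
        "terminology": a.concept[0],
        "concept_id": a.concept[1],
        "match_type": a.match_type,
        "hierarchy_level": a.hierarchy_level,
        "groups": sorted(a.groups),
        "tuis": sorted(a.tuis),
        "cuis": sorted(a.cuis),
        "score": a.score,
    }
    if a.context is not None:
        record["negation"] = a.context.negation
        record["experiencer"] = a.context.experiencer
        record["temporality"] = a.context.temporality
    return record


def write_json(anns: list[Annotation], request_echo: dict | None = None) -> str:
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "request": request_echo or {},
        "annotations": [_annotation_record(a) for a in anns],
    }
    return json.dumps(doc, ensure_ascii=False, indent=2)


def read_json(document: str) -> list[Annotation]:
    doc = json.loads(document)
    out = []
    for r in doc["annotations"]:
        context = None
        if "negation" in r:
            context = ContextLabels(negation=r["negation"],
                                    experiencer=r["experiencer"],
                                    temporality=r["temporality"])
        out.append(Annotation(
            span=Span(r["begin"], r["end"]), matched_text=r["matched_text"],
            concept=(r["terminology"], r["concept_id"]),
            match_type=r["match_type"], hierarchy_level=r["hierarchy_level"],
            cuis=frozenset(r["cuis"]), tuis=frozenset(r["tuis"]),
            groups=frozenset(r["groups"]), score=r["score"], context=context))
    return out
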