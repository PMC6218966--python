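"""Domain model and readers for terminologies and the semantic-group table.

A terminology is a coded vocabulary: concepts with a preferred label,
synonyms, an is-a hierarchy, optional UMLS identifiers (CUIs, TUIs) and
cross-terminology mappings. Two interchange formats are supported:

* ``tabular`` — a UTF-8 TSV with columns ``id``, ``uri``, ``code``,
  ``pref_label``, ``synonyms`` (``||``-separated), ``parents``
  (``||``-separated), ``cuis``, ``tuis``, ``mappings`` (``ACRONYM:id``
  pairs). Unknown columns are ignored with a warning.
* ``skos_min`` — a minimal SKOS reader (Turtle) honouring skos:prefLabel,
  skos:altLabel and skos:broader only.

The semantic-group table maps coarse UMLS Semantic Groups (DISO, CHEM,
ANAT, ...) to the Semantic Types (TUIs) they aggregate; each TUI belongs to
at most one group.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

CUI_RE = re.compile(r"C[0-9]{7}")
TUI_RE = re.compile(r"T[0-9]{3}")

_TABULAR_COLUMNS = (
    "id", "uri", "code", "pref_label", "synonyms", "parents",
    "cuis", "tuis", "mappings",
)


class TerminologyError(ValueError):
    """Raised on malformed terminology input (carries file/line context)."""


@dataclass
class Concept:
    concept_id: str
    pref_label: str
    uri: str = ""
    code: str = ""
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    cuis: frozenset[str] = frozenset()
    tuis: frozenset[str] = frozenset()
    mappings: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise TerminologyError("concept_id must be non-empty")
        if not self.pref_label:
            raise TerminologyError(
                f"concept {self.concept_id!r}: pref_label must be non-empty")

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.pref_label, *self.synonyms)


@dataclass
class Terminology:
    acronym: str
    concepts: dict[str, Concept] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.acronym:
            raise TerminologyError("terminology acronym must be non-empty")

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise TerminologyError(
                f"duplicate concept_id {concept.concept_id!r} in {self.acronym}")
        self.concepts[concept.concept_id] = concept

    def validate(self) -> None:
        """Check referential integrity and hierarchy acyclicity."""
        for c in self.concepts.values():
            for pid in c.parent_ids:
                if pid not in self.concepts:
                    raise TerminologyError(
                        f"{self.acronym}:{c.concept_id} has dangling parent {pid!r}")
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(cid: str, trail: tuple[str, ...]) -> None:
            if state.get(cid) == 1:
                return
            if state.get(cid) == 0:
                raise TerminologyError(
                    f"hierarchy cycle in {self.acronym}: {' -> '.join(trail + (cid,))}")
            state[cid] = 0
            for pid in self.concepts[cid].parent_ids:
                visit(pid, trail + (cid,))
            state[cid] = 1

        for cid in self.concepts:
            visit(cid, ())

    def ancestors(self, concept_id: str,
                  max_level: int | None = None) -> list[tuple[str, int]]:
        """Ancestors of a concept as (concept_id, level) with level >= 1.

        Breadth-first over the (acyclic) parent relation; each ancestor is
        reported once at its minimal level.
        """
        seen: dict[str, int] = {}
        frontier = [concept_id]
        level = 0
        while frontier and (max_level is None or level < max_level):
            level += 1
            nxt: list[str] = []
            for cid in frontier:
                for pid in self.concepts[cid].parent_ids:
                    if pid not in seen and pid != concept_id:
                        seen[pid] = level
                        nxt.append(pid)
            frontier = nxt
        return sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))

    @property
    def all_cuis(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.concepts.values():
            out |= c.cuis
        return frozenset(out)


def _split(cell: str, sep: str = "||") -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(p.strip() for p in cell.split(sep) if p.strip())


def _parse_mappings(cell: str) -> tuple[tuple[str, str], ...]:
    out = []
    for pair in _split(cell):
        if ":" not in pair:
            raise TerminologyError(f"malformed mapping {pair!r} (want ACRONYM:id)")
        acr, cid = pair.split(":", 1)
        out.append((acr.strip(), cid.strip()))
    return tuple(out)


def load_terminology(path: str | Path, format: str = "tabular",
                     acronym: str | None = None) -> Terminology:
    """Load a terminology from ``path`` and return it fully linked.

    ``acronym`` defaults to the upper-cased file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    acr = acronym or path.stem.upper()
    if format == "tabular":
        term = _load_tabular(path, acr)
    elif format == "skos_min":
        term = _load_skos_min(path, acr)
    else:
        raise ValueError(f"unknown terminology format {format!r}")
    term.validate()
    return term


def _load_tabular(path: Path, acronym: str) -> Terminology:
    term = Terminology(acronym)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TerminologyError(f"{path}: empty file (missing header)")
        unknown = [c for c in header if c not in _TABULAR_COLUMNS]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown)
        idx = {c: header.index(c) for c in _TABULAR_COLUMNS if c in header}
        if "id" not in idx or "pref_label" not in idx:
            raise TerminologyError(f"{path}: header must include id and pref_label")

        def cell(row: list[str], col: str) -> str:
            i = idx.get(col)
            return row[i].strip() if i is not None and i < len(row) else ""

        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                concept = Concept(
                    concept_id=cell(row, "id"),
                    uri=cell(row, "uri"),
                    code=cell(row, "code"),
                    pref_label=cell(row, "pref_label"),
                    synonyms=_split(cell(row, "synonyms")),
                    parent_ids=_split(cell(row, "parents")),
                    cuis=frozenset(_split(cell(row, "cuis"))),
                    tuis=frozenset(_split(cell(row, "tuis"))),
                    mappings=_parse_mappings(cell(row, "mappings")),
                )
                term.add(concept)
            except TerminologyError as err:
                raise TerminologyError(f"{path}:{lineno}: {err}") from err
    return term


def write_terminology(term: Terminology, path: str | Path) -> None:
    """Serialize a terminology to the tabular TSV dialect (round-trips)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABULAR_COLUMNS)
        for cid in sorted(term.concepts):
            c = term.concepts[cid]
            writer.writerow([
                c.concept_id, c.uri, c.code, c.pref_label,
                "||".join(c.synonyms), "||".join(c.parent_ids),
                "||".join(sorted(c.cuis)), "||".join(sorted(c.tuis)),
                "||".join(f"{a}:{i}" for a, i in c.mappings),
            ])


def _uri_local_name(uri: str) -> str:
    for sep in ("#", "/"):
        if sep in uri:
            tail = uri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return uri


def _load_skos_min(path: Path, acronym: str) -> Terminology:
    import rdflib
    from rdflib.namespace import SKOS

    g = rdflib.Graph()
    g.parse(str(path), format="turtle")
    term = Terminology(acronym)
    subjects = sorted(set(g.subjects(SKOS.prefLabel, None)), key=str)
    uri_to_id = {s: _uri_local_name(str(s)) for s in subjects}
    for s in subjects:
        prefs = sorted(str(o) for o in g.objects(s, SKOS.prefLabel))
        alts = sorted(str(o) for o in g.objects(s, SKOS.altLabel))
        notations = sorted(str(o) for o in g.objects(s, SKOS.notation))
        parents = sorted(
            uri_to_id[o] for o in g.objects(s, SKOS.broader) if o in uri_to_id)
        term.add(Concept(
            concept_id=uri_to_id[s],
            uri=str(s),
            code=notations[0] if notations else "",
            pref_label=prefs[0],
            synonyms=tuple(prefs[1:]) + tuple(alts),
            parent_ids=tuple(parents),
        ))
    return term


@dataclass(frozen=True)
class SemanticTable:
    """Map from UMLS Semantic Group to its ordered set of TUIs."""

    group_to_types: dict[str, tuple[str, ...]]

    def tuis_for(self, group: str) -> tuple[str, ...]:
        if group not in self.group_to_types:
            raise KeyError(f"unknown semantic group {group!r}")
        return self.group_to_types[group]

    def groups_for(self, tuis: frozenset[str] | set[str]) -> frozenset[str]:
        """Semantic groups covering any of the given TUIs."""
        return frozenset(
            g for g, ts in self.group_to_types.items() if set(ts) & set(tuis))

    def expand_groups(self, groups: set[str]) -> frozenset[str]:
        out: set[str] = set()
        for g in groups:
            out.update(self.tuis_for(g))
        return frozenset(out)


def load_semantic_table(path: str | Path | None = None) -> SemanticTable:
    """Load a two-column GROUP<TAB>TUI table; ``None`` loads the shipped one."""
    if path is None:
        ref = resources.files("frannot.data").joinpath("semantic_groups.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    mapping: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TerminologyError(
                f"semantic table line {lineno}: want GROUP<TAB>TUI, got {line!r}")
        group, tui = parts[0].strip(), parts[1].strip()
        if not TUI_RE.fullmatch(tui):
            raise TerminologyError(
                f"semantic table line {lineno}: invalid TUI {tui!r}")
        if tui in owner and owner[tui] != group:
            raise TerminologyError(
                f"semantic table line {lineno}: TUI {tui} assigned to both "
                f"{owner[tui]} and {group}")
        owner[tui] = group
        mapping.setdefault(group, [])
        if tui not in mapping[group]:
            mapping[group].append(tui)
    return SemanticTable({g: tuple(ts) for g, ts in mapping.items()})
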