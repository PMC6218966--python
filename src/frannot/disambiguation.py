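"""Semantic-group disambiguation heuristics.

Two post-annotation strategies for mentions tagged with several Semantic
Groups (a direct consequence of multi-CUI concepts in UMLS-derived
terminologies):

* DAA (discard ambiguous annotations) — favour precision: drop every
  annotation carrying two or more groups.
* DBP (distribution-based prioritization) — favour recall: rewrite each
  multi-group annotation to its single most likely group, where likelihood
  is a group frequency ranking learned from a development gold standard
  (the most-frequent-sense baseline).

DBP never drops annotations; DAA never rewrites them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .annotations import Annotation


@dataclass(frozen=True)
class GroupRanking:
    """Semantic groups ordered most frequent first."""

    groups: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("ranking contains duplicate groups")

    def rank_key(self, group: str):
        """Sort key: ranked groups by position, unknown last lexicographic."""
        try:
            return (0, self.groups.index(group), "")
        except ValueError:
            return (1, len(self.groups), group)

    def best(self, groups) -> str:
        return min(groups, key=self.rank_key)


# Development-corpus group ranking for drug-notice text, used as a fixture
# ranking object in tests and examples.
EMEA_RANKING = GroupRanking(
    ("CHEM", "DISO", "LIVB", "PROC", "ANAT", "PHYS", "OBJC", "GEOG",
     "DEVI", "PHEN"),
    provenance="EMEA-dev",
)


def daa_filter(anns: list[Annotation]) -> list[Annotation]:
    """Remove annotations that belong to several Semantic Groups."""
    return [a for a in anns if len(a.groups) < 2]


def learn_group_ranking(gold, provenance: str = "") -> GroupRanking:
    """Frequency ranking of groups in a gold standard (ties lexicographic)."""
    gold = list(gold)
    if not gold:
        raise ValueError("cannot learn a ranking from empty gold")
    counts = Counter(e.group for e in gold)
    ordered = sorted(counts, key=lambda g: (-counts[g], g))
    return GroupRanking(tuple(ordered), provenance=provenance)


def dbp_filter(anns: list[Annotation],
               ranking: GroupRanking) -> list[Annotation]:
    """Rewrite each multi-group annotation to its best-ranked group."""
    out = []
    for a in anns:
        if len(a.groups) >= 2:
            out.append(a.with_(groups=frozenset({ranking.best(a.groups)})))
        else:
            out.append(a)
    return out


def save_ranking(ranking: GroupRanking, path: str | Path) -> None:
    Path(path).write_text("\n".join(ranking.groups) + "\n", encoding="utf-8")


def load_ranking(path: str | Path, provenance: str = "") -> GroupRanking:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return GroupRanking(tuple(g.strip() for g in lines if g.strip()),
                        provenance=provenance or str(path))
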