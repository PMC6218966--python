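"""Annotation records shared across the recognition/expansion pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MATCH_TYPES = ("direct_pref", "direct_syn", "hierarchy", "mapping")


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character span into the original text (0-based)."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise ValueError(f"invalid span ({self.begin}, {self.end})")

    def contains(self, other: "Span") -> bool:
        return self.begin <= other.begin and other.end <= self.end

    def strictly_contains(self, other: "Span") -> bool:
        return self.contains(other) and self != other

    def intersects(self, other: "Span") -> bool:
        return self.begin < other.end and other.begin < self.end


@dataclass(frozen=True)
class ContextLabels:
    """Clinical context of a mention; defaults: affirmed / patient / recent."""

    negation: str = "affirmed"
    experiencer: str = "patient"
    temporality: str = "recent"

    def __post_init__(self) -> None:
        if self.negation not in ("affirmed", "negated"):
            raise ValueError(f"bad negation value {self.negation!r}")
        if self.experiencer not in ("patient", "other"):
            raise ValueError(f"bad experiencer value {self.experiencer!r}")
        if self.temporality not in ("recent", "historical", "hypothetical"):
            raise ValueError(f"bad temporality value {self.temporality!r}")


@dataclass(frozen=True)
class Annotation:
    """A concept match on a character span of the input text."""

    span: Span
    matched_text: str
    concept: tuple[str, str]  # (terminology acronym, concept_id)
    match_type: str = "direct_syn"
    hierarchy_level: int | None = None
    cuis: frozenset[str] = frozenset()
    tuis: frozenset[str] = frozenset()
    groups: frozenset[str] = frozenset()
    score: float | None = None
    context: ContextLabels | None = None

    def __post_init__(self) -> None:
        if self.match_type not in MATCH_TYPES:
            raise ValueError(f"unknown match type {self.match_type!r}")
        if self.match_type == "hierarchy":
            if self.hierarchy_level is None or self.hierarchy_level < 1:
                raise ValueError("hierarchy annotations need level >= 1")
        if self.score is not None and self.score < 0:
            raise ValueError("scores are non-negative")

    def with_(self, **kwargs) -> "Annotation":
        return replace(self, **kwargs)

    @property
    def key(self) -> tuple:
        """Identity used for deduplication: same span, same concept."""
        return (self.span, self.concept)


def check_spans(annotations, text: str) -> None:
    """Assert every annotation's matched_text equals its slice of ``text``."""
    for ann in annotations:
        slice_ = text[ann.span.begin:ann.span.end]
        if slice_ != ann.matched_text:
            raise ValueError(
                f"annotation at {ann.span} carries {ann.matched_text!r} "
                f"but text reads {slice_!r}")


# re-exported convenience
__all__ = ["Span", "ContextLabels", "Annotation", "check_spans", "MATCH_TYPES",
           "field"]
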