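"""End-to-end annotation workflow tying the modules together.

``Annotator`` compiles the matching dictionary from a set of terminologies
once, then runs the full request pipeline per text: concept recognition →
semantic attachment → hierarchy/mapping expansion → semantic filtering →
disambiguation → scoring/pruning → clinical context detection. Each stage
is the corresponding module's public operation; this class only sequences
them the way an annotation request does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations import Annotation
from .context import TriggerTerm, detect_context
from .dictionary import BuildOptions, build_dictionary
from .disambiguation import GroupRanking, daa_filter, dbp_filter
from .recognizer import (RecognitionOptions, attach_semantics,
                         compile_matcher, recognize)
from .scoring import prune_by_score, score_annotations
from .semantics import (ExpansionOptions, expand_hierarchy, expand_mappings,
                        filter_by_semantics)
from .terminology import SemanticTable, Terminology, load_semantic_table


@dataclass
class AnnotationRequest:
    """Mirror of the request parameters of the annotation service."""

    longest_only: bool = False
    partial_words: bool = False
    semantic_groups: frozenset[str] = field(default_factory=frozenset)
    semantic_types: frozenset[str] = field(default_factory=frozenset)
    expansion: ExpansionOptions = field(default_factory=ExpansionOptions)
    daa: bool = False
    dbp_ranking: GroupRanking | None = None
    score: str | None = None
    score_threshold: float | None = None
    confidence_threshold: int | None = None
    negation: bool = False
    experiencer: bool = False
    temporality: bool = False


class Annotator:
    def __init__(self, terminologies: list[Terminology],
                 table: SemanticTable | None = None,
                 build_opts: BuildOptions | None = None,
                 lexicon: list[TriggerTerm] | None = None,
                 recognition: RecognitionOptions | None = None) -> None:
        if not terminologies:
            raise ValueError("at least one terminology is required")
        self.terminologies = list(terminologies)
        self.table = table or load_semantic_table()
        self.build_opts = build_opts or BuildOptions()
        self.dictionary = build_dictionary(self.terminologies, self.build_opts)
        self.matcher = compile_matcher(
            self.dictionary, fold_diacritics=self.build_opts.fold_diacritics)
        self.lexicon = lexicon

    def annotate(self, text: str,
                 request: AnnotationRequest | None = None,
                 ) -> list[Annotation]:
        req = request or AnnotationRequest()
        ro = RecognitionOptions(longest_only=req.longest_only,
                                partial_words=req.partial_words)
        anns = recognize(self.matcher, text, ro)
        anns = attach_semantics(anns, self.terminologies, self.table)
        exp = req.expansion
        if exp.expand_class_hierarchy and exp.class_hierarchy_max_level > 0:
            anns = expand_hierarchy(anns, self.terminologies,
                                    exp.class_hierarchy_max_level, self.table)
        if exp.expand_mappings or exp.target_terminologies:
            anns = expand_mappings(anns, self.terminologies,
                                   exp.target_terminologies, self.table)
        anns = filter_by_semantics(anns, set(req.semantic_groups),
                                   set(req.semantic_types), self.table)
        if req.daa:
            anns = daa_filter(anns)
        if req.dbp_ranking is not None:
            anns = dbp_filter(anns, req.dbp_ranking)
        if req.score:
            scored = score_annotations(anns, req.score)
            scored = prune_by_score(scored, req.score_threshold,
                                    req.confidence_threshold)
            anns = scored.annotations
        if req.negation or req.experiencer or req.temporality:
            anns = detect_context(anns, text, self.lexicon,
                                  negation=req.negation,
                                  experiencer=req.experiencer,
                                  temporality=req.temporality)
        return anns
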