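"""Deterministic synthetic test substrate.

Licensed gold corpora and UMLS-derived terminologies cannot ship with the
package, so every evaluation-facing test runs on synthetic material built
here: terminologies with controllable hierarchy depth, synonym and
label-ambiguity rates; document corpora with embedded, exactly-located gold
mentions; context-bearing sentences built from the seed trigger lexicon;
and CépiDC-style death-certificate files with gold ICD-10 codes.

Design guarantees (what makes recall/precision targets exact):

* filler vocabulary is French-letter-frequency sampled pseudo-words,
  checked disjoint from every label token, trigger token and stopword, so
  no dictionary surface can match across or inside filler;
* each concept's label tokens are private to that concept (except planted
  ambiguous duplicates), so the only possible matches are the planted
  mentions;
* generation is fully deterministic per seed.

The generator emulates the *structure* of clinical/biomedical gold corpora
(multi-word terms, nested constituents, ambiguous labels, context
templates), not the statistics of real French clinical language.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .annotations import ContextLabels, Span
from .context import TriggerTerm, load_trigger_lexicon
from .evaluation import GoldEntity
from .icd_coding import CertificateLine, IdentRecord
from .normalize import normalize, tokenize
from .terminology import Concept, SemanticTable, Terminology, load_semantic_table

_LETTERS = "eeeeeeeeaaaaaaiiiiiissssnnnnttttrrrruuullloooddccmmppvqfbghjx"


def _pseudo_word(rng: random.Random, min_len: int = 4, max_len: int = 9) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(_LETTERS) for _ in range(n))


def _word_pool(rng: random.Random, count: int,
               forbidden: set[str]) -> list[str]:
    pool: list[str] = []
    seen = set(forbidden)
    while len(pool) < count:
        w = _pseudo_word(rng)
        if w not in seen:
            seen.add(w)
            pool.append(w)
    return pool


def generate_terminology(seed: int, n_concepts: int, depth: int = 2,
                         synonym_rate: float = 0.3,
                         ambiguity_rate: float = 0.0,
                         cui_pool: int = 10_000,
                         table: SemanticTable | None = None,
                         acronym: str = "SYN") -> Terminology:
    """A deterministic synthetic terminology.

    ``depth`` bounds the maximal ancestor-chain length; ``ambiguity_rate``
    is the fraction of concepts whose preferred label duplicates another
    concept's label under a different Semantic Group (those concepts also
    carry TUIs of several groups).
    """
    if n_concepts < 1 or depth < 0 or not 0 <= ambiguity_rate <= 1:
        raise ValueError("impossible generator parameters")
    table = table or load_semantic_table()
    rng = random.Random(seed)
    groups = sorted(table.group_to_types)
    pool = _word_pool(rng, 4 * n_concepts, forbidden=set())
    term = Terminology(acronym)
    cui_numbers = rng.sample(range(1, cui_pool + 1),
                             min(n_concepts, cui_pool))
    labels_by_index: list[str] = []
    group_by_index: list[str] = []
    n_ambiguous = int(round(ambiguity_rate * n_concepts))
    for i in range(n_concepts):
        cid = f"S{i + 1:04d}"
        level = i % (depth + 1) if depth else 0
        parents: tuple[str, ...] = ()
        if level > 0:
            candidates = [f"S{j + 1:04d}" for j in range(i)
                          if j % (depth + 1) == level - 1]
            if candidates:
                parents = (rng.choice(candidates),)
        duplicate_of = None
        if i >= n_concepts - n_ambiguous and labels_by_index:
            duplicate_of = rng.randrange(len(labels_by_index))
        if duplicate_of is not None:
            label = labels_by_index[duplicate_of]
            other_groups = [g for g in groups
                            if g != group_by_index[duplicate_of]]
            group = rng.choice(other_groups)
            tuis = {rng.choice(table.group_to_types[group]),
                    rng.choice(table.group_to_types[
                        group_by_index[duplicate_of]])}
        else:
            n_tokens = rng.randint(1, 3)
            label = " ".join(pool.pop() for _ in range(n_tokens))
            group = rng.choice(groups)
            tuis = {rng.choice(table.group_to_types[group])}
        synonyms: list[str] = []
        if duplicate_of is None and rng.random() < synonym_rate:
            synonyms.append(" ".join(
                pool.pop() for _ in range(rng.randint(1, 2))))
        labels_by_index.append(label)
        group_by_index.append(group)
        term.add(Concept(
            concept_id=cid, pref_label=label, synonyms=tuple(synonyms),
            parent_ids=parents, cuis=frozenset({f"C{cui_numbers[i]:07d}"}),
            tuis=frozenset(tuis),
            uri=f"http://purl.org/frannot/syn#{cid}"))
    term.validate()
    return term


@dataclass(frozen=True)
class GoldMention:
    entity: GoldEntity
    context: ContextLabels
    concept_id: str


@dataclass
class CorpusDoc:
    text: str
    mentions: list[GoldMention] = field(default_factory=list)


_CONTEXT_TEMPLATES = (
    # (raw prefix placed right before the label, planted context)
    ("pas de ", ContextLabels(negation="negated")),
    ("antécédents de ", ContextLabels(temporality="historical")),
    ("son père a ", ContextLabels(experiencer="other")),
    ("en cas de ", ContextLabels(temporality="hypothetical")),
)


def _trigger_tokens(lexicon: list[TriggerTerm]) -> set[str]:
    out: set[str] = set()
    for t in lexicon:
        out.update(tokenize(t.phrase))
    return out


def generate_corpus(terminology: Terminology, seed: int, n_docs: int = 5,
                    mentions_per_doc: int = 6, context_rate: float = 0.0,
                    table: SemanticTable | None = None,
                    ) -> list[CorpusDoc]:
    """Documents with embedded verbatim concept labels and exact gold.

    One sentence per mention; a fraction ``context_rate`` of mentions is
    wrapped in a context template built from the seed trigger lexicon, and
    the planted context is recorded in the gold.
    """
    if not terminology.concepts:
        raise ValueError("terminology is empty")
    table = table or load_semantic_table()
    rng = random.Random(seed)
    lexicon = load_trigger_lexicon()
    label_tokens: set[str] = set()
    for c in terminology.concepts.values():
        for lab in c.labels:
            label_tokens.update(tokenize(normalize(lab)))
    forbidden = label_tokens | _trigger_tokens(lexicon)
    filler = _word_pool(rng, 80, forbidden=forbidden)
    concept_ids = sorted(terminology.concepts)
    docs: list[CorpusDoc] = []
    for _ in range(n_docs):
        pieces: list[str] = []
        mentions: list[GoldMention] = []
        offset = 0

        def emit(piece: str) -> None:
            nonlocal offset
            pieces.append(piece)
            offset += len(piece)

        for m in range(mentions_per_doc):
            cid = rng.choice(concept_ids)
            concept = terminology.concepts[cid]
            label = concept.pref_label
            with_context = rng.random() < context_rate
            if pieces:
                emit(" ")
            emit(" ".join(rng.sample(filler, rng.randint(1, 3))) + " ")
            if with_context:
                prefix, context = _CONTEXT_TEMPLATES[m % len(_CONTEXT_TEMPLATES)]
                emit(prefix)
            else:
                context = ContextLabels()
            begin = offset
            emit(label)
            end = offset
            emit(" " + " ".join(rng.sample(filler, rng.randint(1, 2))) + ".")
            groups = table.groups_for(concept.tuis)
            mentions.append(GoldMention(
                entity=GoldEntity(fragments=(Span(begin, end),),
                                  group=sorted(groups)[0],
                                  cuis=concept.cuis, text=label),
                context=context, concept_id=cid))
        docs.append(CorpusDoc(text="".join(pieces), mentions=mentions))
    return docs


def generate_noise_terminology(seed: int, corpus_docs: list[CorpusDoc],
                               n_concepts: int = 10,
                               acronym: str = "NOISE",
                               table: SemanticTable | None = None,
                               ) -> Terminology:
    """A terminology whose labels are filler words present in the corpus but
    absent from the gold — including it can only add false positives."""
    table = table or load_semantic_table()
    rng = random.Random(seed)
    gold_spans = {(i, m.entity.fragments)
                  for i, d in enumerate(corpus_docs) for m in d.mentions}
    gold_texts = {normalize(m.entity.text)
                  for d in corpus_docs for m in d.mentions}
    tokens: list[str] = []
    for d in corpus_docs:
        for tok in tokenize(normalize(d.text)):
            if len(tok) >= 4 and tok not in gold_texts and tok not in tokens:
                tokens.append(tok)
    rng.shuffle(tokens)
    groups = sorted(table.group_to_types)
    term = Terminology(acronym)
    for i, tok in enumerate(tokens[:n_concepts]):
        group = rng.choice(groups)
        term.add(Concept(
            concept_id=f"N{i + 1:04d}", pref_label=tok,
            cuis=frozenset({f"C{9_000_000 + i:07d}"}),
            tuis=frozenset({rng.choice(table.group_to_types[group])})))
    term.validate()
    if not term.concepts:
        raise ValueError("corpus too small to derive noise labels")
    _ = gold_spans  # spans only needed by callers wanting stricter checks
    return term


@dataclass
class CepidcFixture:
    lines: list[CertificateLine]
    idents: list[IdentRecord]
    dict_rows: list[tuple[str, str]]


def generate_cepidc(seed: int, n_codes: int = 12, n_lines: int = 40,
                    ambiguous_fraction: float = 0.2) -> CepidcFixture:
    """CépiDC-style aligned corpus + code dictionary with planted gold.

    Each line's RawText is (an upper-cased, possibly accent-stripped copy
    of) one code's label; a fraction of labels is shared between two codes
    to exercise the most-frequent-code resolution.
    """
    rng = random.Random(seed)
    pool = _word_pool(rng, 4 * n_codes, forbidden=set())
    codes: list[str] = []
    letters = "ABCGIJRKVXY"
    while len(codes) < n_codes:
        code = (f"{rng.choice(letters)}{rng.randint(0, 9)}{rng.randint(0, 9)}"
                f".{rng.randint(0, 9)}")
        if code not in codes:
            codes.append(code)
    labels: dict[str, str] = {}
    n_amb = int(round(ambiguous_fraction * n_codes))
    for i, code in enumerate(codes):
        if i and i <= n_amb:
            labels[code] = labels[codes[0]]  # shared, ambiguous label
        else:
            labels[code] = " ".join(
                pool.pop() for _ in range(rng.randint(1, 3)))
    lines: list[CertificateLine] = []
    idents: list[IdentRecord] = []
    for j in range(n_lines):
        code = rng.choice(codes)
        raw = labels[code].upper()
        doc_id = str(100_000 + j // 2)
        lines.append(CertificateLine(
            doc_id=doc_id, year_coded=2014, line_id=j % 2 + 1, raw_text=raw,
            int_type=rng.choice([None, 3]), int_value=rng.choice([None, 5]),
            gold_codes=[code]))
        if j % 2 == 0:
            idents.append(IdentRecord(
                doc_id=doc_id, year_coded=2014, gender=rng.choice([1, 2]),
                age=rng.randint(40, 99), location_of_death=rng.randint(1, 4),
                primary_cause=code))
    dict_rows = [(code, labels[code]) for code in codes]
    return CepidcFixture(lines=lines, idents=idents, dict_rows=dict_rows)
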