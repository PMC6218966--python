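# frannot

Ontology-based semantic annotation of French biomedical text and clinical
notes: a library and CLI for dictionary-based concept recognition over
coded terminologies, with semantic filtering and expansion, annotation
scoring, clinical context detection, disambiguation heuristics, an ICD-10
death-certificate coding pipeline, and the matching evaluation harnesses.

## Who this is for

Researchers and engineers who need to tag free French medical text (drug
notices, MEDLINE titles, clinical notes, death certificates) with concepts
from terminologies such as the French MeSH, ICD-10 (CIM-10) or MedDRA, and
to evaluate that tagging against BRAT-style gold standards — without a
web-service deployment. Licensed resources (UMLS content, Quaero, CépiDC)
are not required: a deterministic synthetic generator produces
structure-equivalent terminologies and corpora with exact embedded gold,
so the whole workflow is testable offline.

## What it computes

**Dictionary compilation.** Each concept's preferred label and synonyms
become rows of a flat Mgrep-dialect dictionary (`entry_id TAB surface`),
normalized by casefolding, diacritic folding, punctuation→space. Optional
recall heuristics add label variants (trailing-qualifier removal such as
"sans précision", conjunction splitting "A de X et de Y" → "A de X" /
"A de Y", parenthetical removal); they are off by default because they
trade precision for recall.

**Concept recognition.** A pure-Python Aho-Corasick automaton finds every
dictionary surface in the normalized text and maps spans back to the raw
string. Options mirror the annotation-service parameters:
`longest_only` (drop annotations strictly contained in a longer one),
`partial_words` (allow in-token matches, e.g. *vasculaire* inside
*cardiovasculaire*), stopword and minimum-token-length suppression.

**Semantics.** Annotations carry UMLS CUIs and Semantic Types (TUIs); a
shipped group table maps Semantic Groups to TUIs (`DISO` ↦ T020, T190,
T049, T019, T047, T050, T033, T037, T048, T191, T046, T184). Filtering by
group is exactly filtering by the expanded TUI list. Hierarchy expansion
adds ancestor-concept annotations up to a level bound; mapping expansion
adds one-hop cross-terminology annotations and can restrict output to
target terminologies while using other ones as bridges.

**Scoring.** Three methods: the legacy weighted-frequency score (`old`),
and a C-value adaptation (`cvalue`, `cvalueh`) that rewards multi-word
terms: for a matched term *a* with token count |a| and document frequency
f(a), `cvalue(a) = log2(|a|+1)·f(a)` when *a* is not nested, and
`log2(|a|+1)·(f(a) − mean_{b∈Ta} f(b))` when longer matched terms Ta
contain it. Pruning supports absolute (`score_threshold`, inclusive) and
relative (`confidence_threshold`, nearest-rank percentile) cuts.

**Clinical context.** A ConText/NegEx-style detector assigns negation,
experiencer and temporality from trigger terms with directional scopes
closed by sentence end, colon, or termination terms ("mais"); pseudo
triggers mask real ones. Defaults are affirmed / patient / recent.

**Disambiguation.** DAA discards annotations carrying several Semantic
Groups (precision); DBP rewrites them to the best group of a frequency
ranking learned from a development gold (recall, the most-frequent-sense
baseline).

**ICD-10 coding.** CépiDC-style certificate files are coded by
longest-match annotation against a code index built from the code
dictionary plus gold-coded corpus text, with ambiguous labels assigned to
their most frequent code (MFC), SKOS emission of the resolved vocabulary,
and optional MFC / cumulative-probability-cutoff post-filters.

**Evaluation.** PER (span+group, exact, one-to-one) and NER (CUIs on top
of PER matches) scorers, a per-line code-set scorer with an
external-causes restriction (V01–Y98), gold pruning by CUI coverage, and a
grid search over all 2^n − 1 terminology subsets.

## Worked example

With a one-concept French MeSH extract in `mshfre.tsv` (concept D001943,
preferred label "Tumeurs du sein", synonyms "carcinome mammaire humain",
"cancer du sein", "tumeurs mammaires humaines"):

```bash
frannot annotate \
  --text "La patiente n'a pas de cancer du sein" \
  --terminology mshfre.tsv --longest-only --negation \
  --semantic-groups DISO
```

prints

```json
{
  "schema_version": 1,
  "request": {
    "longest_only": true,
    "partial_words": false,
    "semantic_groups": ["DISO"],
    "semantic_types": []
  },
  "annotations": [
    {
      "begin": 23,
      "end": 37,
      "matched_text": "cancer du sein",
      "terminology": "MSHFRE",
      "concept_id": "D001943",
      "match_type": "direct_syn",
      "hierarchy_level": null,
      "groups": ["DISO"],
      "tuis": ["T191"],
      "cuis": ["C0006142"],
      "score": null,
      "negation": "negated",
      "experiencer": "patient",
      "temporality": "recent"
    }
  ]
}
```

The synonym "cancer du sein" matched at characters 23–37 of the raw text
(the nested "cancer" and "sein" candidates were discarded by
`--longest-only`); the T191 type places it in the DISO group, so it
survives the group filter; and the negation trigger "pas de" puts the
mention in a negated context while experiencer and temporality stay at
their defaults. `frannot evaluate` scores BRAT prediction directories
against gold (`--task per|ner|coding`) and `--grid-search` evaluates every
terminology subset.

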