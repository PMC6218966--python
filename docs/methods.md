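# Methods

This note documents the models and procedures implemented in `frannot`,
the parameters that matter, the numerical and design choices made where
the design was open, what the synthetic generator does and does not
emulate, and known limitations.

## Normalization and offsets

All matching happens on a normalized view of the text: Unicode casefold,
NFKD decomposition with combining marks removed (diacritic folding),
punctuation replaced by single spaces, whitespace collapsed. A
per-character offset map ties every normalized character to its source
span, so reported annotations always index the raw input — the convention
of BRAT gold standards. Folding is applied until stable (compatibility
decomposition can surface cased characters, e.g. 𝕊 → S → s), which makes
normalization idempotent, a property the test suite checks on arbitrary
Unicode input.

Token boundary rule: a token is a maximal run of alphanumeric characters;
apostrophes and hyphens separate tokens, so *l'urètre* exposes *urètre*
and *centro-nucléaire* exposes both halves. French elision makes this the
practical choice; the upstream recognizer this module replaces never
documented its tokenization, so equivalence is defined against these
stated rules.

Both dictionary surfaces and input text run through the same
normalization (fold on by default), which yields the diacritic/case
robustness the coding task needs ("ARRET RESPIRATOIRE" matches the label
"arrêt respiratoire") and the self-recognition property: every label of a
built dictionary is found in its own text.

## Dictionary

One entry id per concept, repeated across that concept's distinct
normalized surfaces; identical surfaces from different concepts keep
distinct ids (ambiguity is a downstream concern). Ids are sequential in
(acronym, concept_id) sort order, so identical inputs and options give
byte-identical TSV output; the opaque ids of the original service were
portal-internal and carry no information.

Recall heuristics (default **off**): trailing-qualifier removal
("SAI", "sans précision(s)", "sans autre précision(s)",
"sans explication(s)", "non classé(e)s ailleurs"), parenthetical/bracket
removal, and conjunction splitting on *et*/*ou*. Splitting reconstructs a
shared head only for the pattern "A de X et de Y" → "A de X" and
"A de Y"; other coordinations split plainly — a full French NP grammar is
out of scope and one-sided splits already capture most of the recall
gain. With heuristics on, the entry multiset is a strict superset of the
default dictionary (tested): recall extension never removes entries.

Lemmatization is a pluggable hook; the default is a rule-based French
plural stripper (final *s*/*x* dropped from tokens of ≥ 4 characters),
adequate for the plural/singular label variation it targets and
deliberately conservative elsewhere.

## Recognizer

A pure-Python Aho-Corasick automaton (goto/fail/output) over the distinct
normalized surfaces. Correctness is established against an independent
brute-force oracle — every surface tried at every position with
`str.find` — on hundreds of randomized (dictionary, text) instances under
both `longest_only` settings and with `partial_words`; the oracle shares
only the normalization layer, not the matching algorithm.

Option semantics, fixed here because the original recognizer is
closed-source:

* `partial_words=False` requires both match boundaries to fall on token
  boundaries of the normalized text;
* suppression removes matches whose **every** token is a stopword or
  shorter than `min_token_length` (default 3; shipped stopword list is a
  small normalized French function-word list) — a multi-word term with
  one contentful token survives;
* `longest_only` removes annotations strictly contained in another
  annotation's span; identical spans all survive, and equal-length
  overlaps from different concepts are all kept for downstream
  disambiguation.

## Semantic table, filtering, expansion

The shipped group table follows the standard UMLS Semantic Groups
grouping; load-time validation enforces that each TUI belongs to exactly
one group. Filtering by groups expands them to TUIs first, so group
filtering and explicit TUI-list filtering are the same operation (tested
as a set equality). With any filter active, untyped annotations drop —
they cannot witness membership.

Hierarchy expansion emits every ancestor at its minimal level up to
`class_hierarchy_max_level`; polyhierarchies emit all parents. Mapping
expansion is one hop — transitive chains through multilingual pivots are
a documented noise source and are not followed. Expanded annotations
inherit the source span and matched text. When the same (span, concept)
is reachable several ways the precedence is direct > hierarchy > mapping.
With non-empty target terminologies, out-of-target direct matches serve
as bridges and are dropped from the final set.

## Scoring

`old`: per-concept sum of per-match weights (preferred 10, synonym 8,
hierarchy level L → max(1, 8 − 2·(L−1)), mapping 7; configurable). The
legacy method's exact table was never published; these defaults are this
package's own and are flagged as such.

`cvalue`: a C-value adaptation per distinct matched term, with
`log2(|a|+1)` rather than `log2|a|` so unigrams score non-zero (all
annotations are scored, not only multi-word candidates). Nesting is
defined as token-boundary substring containment between normalized
surfaces of terms matched in the document; frequency counts distinct
occurrence spans, so several concepts sharing one span count once.
Scores are clamped at 0 (the nested discount can exceed f(a)).
`cvalueh` computes term scores on direct matches only; hierarchy/mapping
annotations inherit their source term's score through the shared span and
matched text.

Pruning: the absolute threshold is inclusive (discarding only *lower*
scores keeps equality); the relative threshold is the nearest-rank
percentile of the score multiset — deterministic where a "density
function" cut would need an estimator. `confidence_threshold=0` keeps
everything, 100 keeps only the maximal score(s). Both thresholds compose
absolute-then-relative.

## Context detection

Trigger terms (normalized like the dictionary) have a category
(negation, experiencer_other, temporality_historical,
temporality_hypothetical), a direction, and a kind (trigger / pseudo /
termination). Scopes run from a trigger to the sentence end, a colon, or
the nearest termination term — exactly those three terminators, with no
fixed token window (a window is a variant not adopted here; a
configurable maximum could be added without changing the contract).
Sentences split on `.`, `!`, `?` and newline; scopes never cross them.
The longest trigger wins at a shared position; pseudo-trigger occurrences
mask the triggers they contain ("sans doute" neutralizes "sans"). When
two scopes of one dimension cover an annotation the nearest trigger wins,
the standard tie-break. Defaults are affirmed / patient / recent;
disabled dimensions stay at default.

The shipped French lexicon is a **seed** — one or a few cues per
category, enough for the templates the generator plants and for the
canonical request sentence ("Le patient n'a pas le cancer, mais son père
a des antécédents de mélanome" → cancer negated/patient/recent, mélanome
affirmed/other/historical). It makes no completeness claim about any
production inventory.

## Disambiguation

DAA drops annotations with ≥ 2 Semantic Groups (precision strategy); DBP
rewrites each multi-group annotation to the best group of a frequency
ranking learned from development gold (recall strategy — counts are not
contextualized, it is exactly the most-frequent-sense baseline). Unknown
groups rank after all ranked ones, lexicographically, for determinism. A
fixture ranking for drug-notice text (CHEM, DISO, LIVB, PROC, ANAT, PHYS,
OBJC, GEOG, DEVI, PHEN) ships as a ready-made object for tests and
examples; `learn_group_ranking` recomputes rankings from any gold.

## ICD-10 coding

The code index maps each code (validated against
`[A-Z][0-9][0-9]\.?[0-9]?`) to dictionary labels first, then corpus
labels from gold-coded lines (RawText, and StandardText when the aligned
file carries it — the reader accepts both layouts). Ambiguous labels
(e.g. a "choc septique" listed under many codes) go to the most frequent
code, frequencies estimated from training gold; ties go to the
lexicographically smallest code. The resolved index serializes to SKOS
(prefLabel = shortest label without a run of ≥ 3 consecutive capitals,
i.e. avoiding acronyms; the rest altLabel; URI = base + code) and reloads
through the minimal SKOS terminology reader.

Coding annotates each line with `longest_only` matching and returns the
matched code set. Post-filters only remove codes: `mfc` keeps the single
most frequent matched code; `cutoff` keeps the minimal prefix of matched
codes (by descending training probability) whose cumulative normalized
probability reaches the threshold, and always keeps at least the top
code — returning nothing for a matched line would be strictly worse under
F1. Demographics (age, gender) are read but unused in coding. The
external-causes subset for evaluation is the V01–Y98 chapter range,
configurable, compared on 3-character code roots; full code strings are
compared everywhere else.

## Evaluation

PER: a prediction is a true positive iff an unmatched gold entity has
identical fragment offsets **and** identical group; matching is
one-to-one and greedy in document order (duplicate identical prediction
units collapse first). A correct span with the wrong group therefore
produces an FP and an FN simultaneously. NER scores CUIs on PER-matched
pairs (intersection TP, extras FP, missing FN); all CUIs of unmatched
predictions are FPs even when one coincides with gold elsewhere. The
recognizer never produces discontinuous spans, so a fragmented gold
entity can never be a TP — a documented limitation mirrored in the
scorer. Exact matching only; approximate-overlap scoring is out of scope.

The grid search enumerates all 2^n − 1 non-empty terminology subsets
(guarded at n ≤ 20), scores each with the chosen metric, and breaks ties
toward smaller subsets then lexicographic order.

## Synthetic generator

The generator plants exact structure: concepts with private label tokens
(so only planted mentions can match), a hierarchy of bounded depth,
controlled synonym and ambiguity rates (ambiguous labels duplicate across
concepts of different groups), filler text sampled from French letter
frequencies and checked disjoint from every label token, trigger token
and stopword, and one sentence per mention with optional context
templates built from the seed lexicon. Consequences, asserted in tests:
annotating a generated corpus with its own terminology at
`longest_only=true` gives PER precision = recall = 1.0; planted context
labels are recovered with accuracy 1.0; adding a noise terminology built
from corpus filler strictly lowers precision and the grid search excludes
it.

What the generator does **not** emulate: the lexical and distributional
statistics of real French clinical language, misspellings,
morphosyntactic variation, incomplete terminology coverage, and
subjective gold-annotation choices. Passing these tests shows the
machinery is correct under its own contracts, not that real-corpus scores
would reach any particular level — on real benchmarks those effects
(missing synonyms, variation, ambiguity) dominate the error budget.

Problem sizes used by the acceptance script — 30-concept terminologies,
4 documents × 8 mentions, 200 randomized recognizer instances, 15 codes ×
60 certificate lines — are small by design: every property they check is
scale-free (exactness, equivalence, monotonicity), and the runs complete
in seconds.

## Known limitations

* Exact string matching only: no fuzzy, stem or embedding matching; no
  morphosyntactic robustness beyond the plural-stripping lemmatizer hook.
* One-hop mappings; no interportal/multilingual mapping retrieval.
* The C-value variant is this package's adaptation (the originating
  method's exact published form differs in its treatment of candidate
  term extraction); comparisons across scoring methods are not meaningful,
  only within one method.
* The trigger lexicon is a seed; production use needs a curated
  inventory.
* BRAT support covers T and N lines (entities and normalizations);
  attributes, relations and events are ignored on read and never emitted.
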