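# Methods

## Pattern model

A sentence is a sequence of tokens with one **basic** Universal Dependencies
tree: 1-based indices, a single root (`head = 0`), acyclic head links, plain
relation labels. A **syntactic pattern** is the linearization of the
shortest undirected tree path between two spans' syntactic heads:

```
[symptom placeholder] : <nsubjpass : lemm=cause : >nmod_by : [disease placeholder]
```

* Endpoints become capture placeholders; interior nodes become
  case-insensitive lemma anchors; each traversed edge keeps its label and a
  direction — `<label` walks dependent→head, `>label` head→dependent. The
  orientation of the notation is fixed by the canonical example above, where
  the symptom is the passive subject of *caused*.
* **Case decoration.** When an `nmod` edge's dependent carries a
  case-marking child, the case lemma is appended to the label (`nmod_by`).
  Decorated labels are matched structurally (base relation + case child with
  that lemma); the basic tree itself is never mutated or collapsed.
* **Directly connected endpoints.** When the two heads are adjacent in the
  tree, the lowest mutual ancestor of the pair is one of the endpoints
  itself, so no interior lexical anchor exists. We emit the single-edge
  pattern, flag it `anchor_free`, and leave the decision to the reviewer:
  such patterns express no causal cue and are the archetypal trap
  ("symptom with ____"). This is a deliberate resolution of an
  under-specified corner; an alternative (searching for a shared governor
  outside the path) would add anchors the path does not license.
* **Phrase expansion.** A captured head token grows to the maximal
  contiguous span of recursively attached dependents whose relation is in
  {`compound`, `amod`, `nummod`, `flat`} ∪ {`nmod` without a case child};
  determiners and punctuation never attach, and expansion stops at a
  contiguity break. This set reproduces expansions like "herniation" →
  "disc herniation" / "lumbar disc herniation" and is a config knob of
  `expand_phrase` / `match`.
* Placeholders must bind nominal tokens (`NOUN`/`PROPN`/`PRON`) when POS is
  available, else they are unrestricted. Pattern identity for deduplication
  is the text form.

Matching enumerates token assignments along the path (no repeated tokens),
phrase-expands the endpoints, drops overlapping expansions, and collapses
duplicate span pairs. It is sentence-local and side-effect free.

## Bootstrapping protocol

Each iteration: (1) every sentence containing a seed pair — matched on
surface first, then lemma, case-insensitively, punctuation never matching —
contributes a derived pattern; (2) candidates are deduplicated and ranked
by yield, where yield counts distinct *seed-matching* sentences (that is
what a reviewer inspects; counting whole-corpus matches at proposal time is
the plausible alternative and would only raise yields); (3) a reviewer
accepts/rejects each candidate at or above `min_yield` (default 2, the
review threshold used in the original sessions); (4) accepted patterns are
applied corpus-wide and new seeds are harvested as co-extracted pairs whose
symptom is in the top 10 symptoms and etiology in the top 50 etiologies by
extraction frequency (fingerprint-collapsed so spelling variants pool).
The loop stops when no new reviewable pattern emerges or at the iteration
cap (default 10, a safety valve; converged sessions need 2–3). A pattern
decided once is never re-proposed, and (corpus, seeds, decision log) fully
determine the final state, so recorded sessions replay bit-identically.

Reviewer implementations: interactive CLI, scripted replay, and a gold-set
oracle for tests that accepts a pattern iff its sample-sentence precision
against the planted relations is ≥ 0.8.

## Mention unification

Fingerprint steps, in order: lowercase; strip punctuation; drop leading
articles; collapse whitespace; split, deduplicate and sort tokens; if the
joined string exceeds 6 characters, replace each token by its American
Soundex code. Two ambiguities were resolved as package design choices: the
6-character test applies to the whole joined string while Soundex is applied
per token (Soundex is defined for single words), and Soundex codes are
lowercased so the fingerprint is idempotent on its own output. Abbreviations
are detected with the Schwartz–Hearst parenthetical algorithm (right-to-left
character matching; only the "long form (SF)" order is a candidate;
conflicting definitions resolved by frequency then first occurrence) and
expanded **before** fingerprinting, so a short-form mention joins its
spelled-out concept. Concepts are ranked by mention count, ties by display
name; the display name is the modal raw surface (ties: shortest, then
lexicographic). Ontology linking is a pluggable `Linker` contract; the
default linker is the fingerprint itself, so unlinked mentions remain as
singletons under their own names.

## Verification pipeline

All four prompt templates are stored verbatim with named slots. Default
decoding parameters are temperature 1, `max_tokens` 4096, top-p 1
(overridable); the model itself is a backend contract, so tests run against
a deterministic scripted mock. Generation parses one name per line,
stripping bullets and the terminal "done" sentinel, deduplicating
case-insensitively; `n_generation_runs` (default 1) takes the best run by
name count — merging runs is not attempted because near-duplicate naming
across runs has no clean solution. Retrieval scores each corpus sentence
against "an etiology for ⟨symptom⟩" with a pluggable embedder — the default
is TF-IDF cosine similarity, a term-weighting baseline; dense abstract
embeddings can be plugged in — and, with hard constraints on (default),
keeps only sentences containing both exact phrases case-insensitively,
returning the top 50 by score (ties by sentence id). Ranking accepts at
most 3 items, parses the model's array tolerantly (code fences stripped,
Python or JSON literals), and drops any sentence that is not an exact
member of the candidate list. Vetting normalizes the reply; anything that
is not a clean yes/no counts as no, with a warning. An etiology survives
iff ≥ 1 vetted sentence remains; per-stage funnel counts
(generated ≥ with-candidates ≥ verified) are reported, and a backend
failure on one etiology never aborts the rest.

## Pooled evaluation

Names from all sources are collapsed by an injectable normalizer (default:
the fingerprint; a manual mapping can be supplied to reproduce hand
normalization). Reference-source items are auto-labelled supported; other
items take labels from the annotation mapping, defaulting to unsupported.
Gold = all supported pooled items; recall = supported items from a source /
gold; precision = supported items from the source / all its items — an
unsupported item never enters gold but does count in its source's precision
denominator. Combined sources ("patterns + LLM") are scored on the union,
counting a name found by both systems once in the denominator. Macro
averaging is the unweighted per-component mean — F is averaged directly,
not recomputed from averaged R and P; this convention is validated in the
tests against the published per-symptom pattern rows (mean of 73.51, 77.41,
54.55 = 68.49). Overlap counts partition supported items into the regions
of the ≤ 3-set diagram. Cohen's κ is computed from the contingency table,
returning 1.0 in the degenerate both-constant-and-equal case.

## Synthetic corpus

The generator emits hand-built dependency skeletons — no parser is invoked,
so tests are hermetic and byte-deterministic given (config, seed). It
emulates the constructions the extraction targets: six causal templates
("X is caused by Y", "Y induced X", "X is secondary to Y", "Y can cause X",
"X is associated with Y", "X results from Y"), a distractor ("symptoms
included X with Y and numbness") whose bare `nmod_with` edge is the known
precision trap, irrelevant filler (rate 0.1), and parenthetical
abbreviation definitions appended to etiology phrases (rate 0.15). Noun
phrases are compound chains with the last word as head; vocabulary sampling
is Zipf-skewed so frequent pairs recur across templates, as in real
abstracts. Every causal sentence contributes exactly one gold relation;
distractors and filler contribute none. Short forms are validated
initialisms: a candidate is only planted if the abbreviation detector
provably expands it back to the full name (a bare initialism can
legitimately resolve to a shorter suffix of the phrase, in which case
letters of the last word are appended).

What the generator does **not** emulate: parse errors, discontinuous or
coordinated arguments, anaphora, negation and hedging, tabular data, and
the long tail of causal phrasings. Passing tests therefore show that the
algorithms are implemented correctly under clean parses, not that
real-corpus precision/recall would match: on real text, pattern errors come
mainly from parser mistakes, wrong phrase boundaries and relatedness-only
patterns.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen as
representative rather than exhaustive: 500-sentence corpora for bootstrap
recovery, 1,500 sentences (≈ 1,000 span matches) for generation/matching
round trips, 100 random patterns for parse/linearize identity, a
100-concept × 6-mention unification benchmark, and a 50-sentence corpus for
the mocked verification funnel. All randomness flows from explicit integer
seeds. Ties are broken deterministically everywhere (yield ranking by text
form, retrieval by sentence id, concept ranking by display name), and
degenerate inputs have defined behavior: empty corpora and empty candidate
lists yield empty results, all-punctuation mentions are quarantined rather
than dropped, malformed trees are rejected into an error report, and
sentences failing tree invariants never abort a corpus load.

## Known limitations

* Only linearized path patterns are matched — no sequential operators,
  arbitrary exact-word tokens, or enhanced-dependency graphs.
* The co-occurrence search treats multi-word terms as contiguous token
  sequences; discontinuous mentions are missed.
* The default retrieval embedder is lexical; semantically paraphrased
  evidence is only reachable through a plugged-in dense embedder.
* Soundex is the American variant; other variants would change concept
  grouping and are isolated behind one function.
* Abbreviation detection recognizes only the "long form (SF)" order.
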