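# etiominer

Mining **symptom etiologies** — the diseases, conditions and exposures that
cause a given symptom — from dependency-parsed biomedical text, for
clinicians, medical librarians and text-mining researchers who need
differential-diagnosis candidates with sentence-level provenance.

Curated resources (textbooks, summarization services) lag behind the
literature and miss rare causes. `etiominer` implements two complementary
extraction routes over a parsed sentence corpus, plus the evaluation
machinery to compare them:

1. **Syntactic patterns with human-guided bootstrapping.** Starting from a
   seed pair such as ⟨sciatica, herniation⟩, every sentence containing both
   terms is found, and for each match the shortest undirected path between
   the two spans in the basic Universal Dependencies tree is linearized into
   a pattern of capture placeholders, lemma anchors and directed edge
   constraints. A reviewer accepts or rejects candidates ranked by yield;
   accepted patterns extract new pairs, which seed the next round. Extracted
   mentions are unified into ranked concepts via a string fingerprint
   (lowercase → strip punctuation → drop leading articles → deduplicate and
   sort tokens → per-token Soundex when the joined form exceeds 6
   characters), with parenthetical abbreviations expanded by the
   Schwartz–Hearst character-matching algorithm.
2. **Generative model with a fact-verification pipeline.** An LLM (behind a
   pluggable, mockable backend) is prompted for an exhaustive etiology list;
   each candidate must then survive evidence **retrieval** (similarity
   search with hard constraints requiring both exact phrases), **ranking**
   (the model selects ≤ 3 sentences from the retrieved list only) and
   **vetting** (a final yes/no judgment per sentence). Etiologies without
   vetted evidence are dropped, removing hallucinations at the cost of some
   recall.

Sources are compared IR-style: candidates from all systems plus a reference
are pooled under a shared name normalizer, labelled supported/unsupported,
and the full supported set is the recall denominator for every source
(per-symptom rows are macro-averaged; annotator agreement is Cohen's κ).

## Worked example

The canonical walk-through sentence is packaged with its gold parse:

```python
from etiominer import generate_pattern, match
from etiominer.examples import sciatica_example_sentence

sent = sciatica_example_sentence()   # "sciatica in low back pain is usually
                                     #  caused by disc herniation"
pattern = generate_pattern(sent, symptom_span=(1, 1), etiology_span=(10, 11))
print(pattern.text_form)
(cap,) = match(pattern, sent)
print(f"{cap.symptom_text!r} <- {cap.etiology_text!r}")
```

prints

```
[symptom placeholder] : <nsubjpass : lemm=cause : >nmod_by : [disease placeholder]
'sciatica' <- 'disc herniation'
```

Reading the pattern: the symptom capture is the passive subject
(`<nsubjpass` walks dependent→head) of a token with lemma *cause*, which
governs (`>nmod_by`, head→dependent, with a *by* case marker) the disease
capture. Off-path material ("in low back pain", "is usually") never enters
the pattern, and the matched etiology head "herniation" is expanded to its
phrase boundary "disc herniation".

A full bootstrap session on a synthetic corpus with six planted causal
constructions and one distractor:

```python
from etiominer import GeneratorConfig, SeedTuple, GoldOracleReviewer, BootstrapConfig
from etiominer.synthetic import generate
from etiominer.bootstrap import run

corpus, gold = generate(GeneratorConfig(n_sentences=500, rng_seed=13))
state = run(corpus, {SeedTuple("sciatica", "disc herniation")},
            GoldOracleReviewer(gold.relations), BootstrapConfig())
print(f"iterations={state.iteration} accepted={len(state.accepted)} "
      f"rejected={len(state.rejected)} extractions={len(state.extractions)}")
```

prints

```
iterations=2 accepted=6 rejected=1 extractions=323
```

— all six causal patterns are recovered in two rounds; the rejected pattern
is the anchor-free trap `[symptom placeholder] : >nmod_with : [disease
placeholder]`, which carries no causal cue (it would extract "pain and
numbness" from "symptoms included sciatica with pain and numbness").

The same operations are available from the shell: `etiominer simulate`,
`etiominer corpus search`, `etiominer pattern derive|match`, `etiominer
bootstrap`, `etiominer unify`, `etiominer verify`, `etiominer evaluate`
(see `etiominer --help`).

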