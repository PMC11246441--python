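"""Human-in-the-loop iterative pattern bootstrapping.

Starting from one or more (symptom, etiology) seed tuples, each round:

1. finds all sentences containing a seed pair and derives a candidate
   pattern from each match;
2. ranks candidates by yield (number of distinct seed-matching sentences)
   and shows those at or above ``min_yield`` to a reviewer, who accepts or
   rejects each;
3. applies the accepted pattern pool over the whole corpus;
4. harvests new seeds from the most frequent extracted symptoms and
   etiologies (fingerprint-collapsed, so spelling variants pool).

The loop stops when no new reviewable pattern emerges — newly discovered
patterns have become too specific, as indicated by their low yield — or at
the iteration cap.  The reviewer is a plain callback contract; interactive,
scripted-replay, and gold-oracle implementations are provided so a recorded
session replays to a bit-identical state.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .corpus import Corpus, ParsedSentence, Span, search_cooccurrence
from .errors import AmbiguousSpanHeadError
from .patterns import Capture, SyntacticPattern, generate_pattern, match
from .unify import fingerprint

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SeedTuple:
    symptom: str
    etiology: str

    def __post_init__(self) -> None:
        if not self.symptom or not self.etiology:
            raise ValueError("seed symptom and etiology must be non-empty")


@dataclass
class RankedPattern:
    """A candidate pattern with its yield and provenance samples."""

    pattern: SyntacticPattern
    n_matched: int
    sample_sentences: list[ParsedSentence]

    def __post_init__(self) -> None:
        if self.n_matched < 1:
            raise ValueError("yield must be >= 1")


@dataclass(frozen=True)
class Extraction:
    """One extracted symptom–etiology pair with full provenance."""

    sent_id: str
    symptom_text: str
    symptom_span: Span
    etiology_text: str
    etiology_span: Span
    pattern_text: str


#: Reviewer contract: verdict for one ranked pattern (True = accept).
Reviewer = Callable[[RankedPattern], bool]


@dataclass
class BootstrapConfig:
    min_yield: int = 2
    max_iterations: int = 10
    k_symptoms: int = 10
    k_etiologies: int = 50
    sample_size: int = 5


@dataclass
class BootstrapState:
    """Evolving pools plus a full audit trail of the session."""

    iteration: int = 0
    seed_pool: set[SeedTuple] = field(default_factory=set)
    accepted: dict[str, SyntacticPattern] = field(default_factory=dict)
    rejected: dict[str, SyntacticPattern] = field(default_factory=dict)
    extractions: list[Extraction] = field(default_factory=list)
    decision_log: list[tuple[int, str, bool]] = field(default_factory=list)

    def decided(self) -> set[str]:
        return set(self.accepted) | set(self.rejected)


# ---------------------------------------------------------------------------
# Reviewers
# ---------------------------------------------------------------------------

class ScriptedReviewer:
    """Replays recorded accept/reject decisions keyed by pattern text form."""

    def __init__(self, decisions: Mapping[str, bool], default: bool = False):
        self.decisions = dict(decisions)
        self.default = default

    def __call__(self, ranked: RankedPattern) -> bool:
        return self.decisions.get(ranked.pattern.text_form, self.default)


class GoldOracleReviewer:
    """Accepts a pattern iff its sample-sentence precision against a gold
    relation set is at least ``min_precision``.

    ``gold_relations`` holds (sent_id, symptom span, etiology span) triples;
    template ids, if present as a fourth element, are ignored.
    """

    def __init__(self, gold_relations: Iterable[tuple], min_precision: float = 0.8):
        self.gold = {(r[0], r[1], r[2]) for r in gold_relations}
        self.min_precision = min_precision

    def __call__(self, ranked: RankedPattern) -> bool:
        captures: list[Capture] = []
        for sentence in ranked.sample_sentences:
            captures.extend(match(ranked.pattern, sentence))
        if not captures:
            return False
        hits = sum(
            (c.sentence.sent_id, c.symptom_span, c.etiology_span) in self.gold
            for c in captures
        )
        return hits / len(captures) >= self.min_precision


# ---------------------------------------------------------------------------
# Protocol steps
# ---------------------------------------------------------------------------

def propose_patterns(
    corpus: Corpus,
    seeds: Iterable[SeedTuple],
    min_yield: int = 2,
    exclude: Iterable[str] = (),
    sample_size: int = 5,
) -> list[RankedPattern]:
    """Derive candidate patterns from every seed co-occurrence match.

    Patterns are deduplicated by text form; yield counts distinct
    seed-matching sentences; the list is sorted by yield descending, ties by
    text form.  Candidates below ``min_yield`` or already decided
    (``exclude``) are omitted.  Matches with ambiguous span heads are
    logged and skipped.
    """
    excluded = set(exclude)
    by_text: dict[str, SyntacticPattern] = {}
    supporting: dict[str, dict[str, ParsedSentence]] = {}
    for seed in sorted(set(seeds)):
        for span_match in search_cooccurrence(corpus, seed.symptom, seed.etiology):
            try:
                pattern = generate_pattern(
                    span_match.sentence, span_match.span_a, span_match.span_b
                )
            except AmbiguousSpanHeadError as exc:
                logger.warning("skipping match in %s: %s", span_match.sentence.sent_id, exc)
                continue
            text = pattern.text_form
            if text in excluded:
                continue
            by_text.setdefault(text, pattern)
            supporting.setdefault(text, {})[span_match.sentence.sent_id] = (
                span_match.sentence
            )
    ranked = [
        RankedPattern(
            pattern=by_text[text],
            n_matched=len(sents),
            sample_sentences=[sents[sid] for sid in sorted(sents)][:sample_size],
        )
        for text, sents in supporting.items()
        if len(sents) >= min_yield
    ]
    ranked.sort(key=lambda rp: (-rp.n_matched, rp.pattern.text_form))
    return ranked


def apply_patterns(
    corpus: Corpus, patterns: Iterable[SyntacticPattern]
) -> list[Extraction]:
    """Apply a pattern pool over the corpus and deduplicate extractions.

    The pattern is part of the identity key: two patterns extracting the
    same pair from the same sentence yield two extractions.
    """
    seen: set[tuple] = set()
    extractions: list[Extraction] = []
    for sentence in corpus:
        for pattern in patterns:
            for capture in match(pattern, sentence):
                key = (
                    sentence.sent_id,
                    capture.symptom_span,
                    capture.etiology_span,
                    pattern.text_form,
                )
                if key in seen:
                    continue
                seen.add(key)
                extractions.append(
                    Extraction(
                        sent_id=sentence.sent_id,
                        symptom_text=capture.symptom_text,
                        symptom_span=capture.symptom_span,
                        etiology_text=capture.etiology_text,
                        etiology_span=capture.etiology_span,
                        pattern_text=pattern.text_form,
                    )
                )
    extractions.sort(
        key=lambda e: (e.sent_id, e.symptom_span, e.etiology_span, e.pattern_text)
    )
    return extractions


def _top_surfaces(texts: list[str], k: int) -> tuple[set[str], dict[str, str]]:
    """Top-k fingerprint groups by frequency; returns (fingerprints, modal surface)."""
    fp_counts: Counter[str] = Counter()
    surface_counts: dict[str, Counter[str]] = {}
    for text in texts:
        fp = fingerprint(text)
        fp_counts[fp] += 1
        surface_counts.setdefault(fp, Counter())[text] += 1
    representative = {
        fp: min(counts, key=lambda s: (-counts[s], len(s), s))
        for fp, counts in surface_counts.items()
    }
    ranked = sorted(fp_counts, key=lambda fp: (-fp_counts[fp], representative[fp]))
    return set(ranked[:k]), representative


def select_seeds(
    extractions: list[Extraction],
    k_symptoms: int = 10,
    k_etiologies: int = 50,
) -> set[SeedTuple]:
    """Harvest new seeds: co-extracted pairs whose symptom is among the top-k
    symptoms and whose etiology is among the top-k etiologies by
    fingerprint-collapsed extraction frequency."""
    if not extractions or k_symptoms <= 0 or k_etiologies <= 0:
        return set()
    top_sym, sym_repr = _top_surfaces([e.symptom_text for e in extractions], k_symptoms)
    top_eti, eti_repr = _top_surfaces([e.etiology_text for e in extractions], k_etiologies)
    seeds: set[SeedTuple] = set()
    for extraction in extractions:
        sym_fp = fingerprint(extraction.symptom_text)
        eti_fp = fingerprint(extraction.etiology_text)
        if sym_fp in top_sym and eti_fp in top_eti:
            seeds.add(SeedTuple(sym_repr[sym_fp], eti_repr[eti_fp]))
    return seeds


def run(
    corpus: Corpus,
    seeds: Iterable[SeedTuple],
    reviewer: Reviewer,
    config: BootstrapConfig | None = None,
) -> BootstrapState:
    """Run the full bootstrap loop: propose → review → apply → harvest.

    A pattern rejected once is never re-proposed.  If the reviewer raises,
    the state built so far is attached to the exception (``state`` attribute)
    and the exception re-raised.
    """
    config = config or BootstrapConfig()
    state = BootstrapState(seed_pool=set(seeds))
    while state.iteration < config.max_iterations:
        state.iteration += 1
        ranked = propose_patterns(
            corpus,
            state.seed_pool,
            min_yield=config.min_yield,
            exclude=state.decided(),
            sample_size=config.sample_size,
        )
        if not ranked:
            break
        for candidate in ranked:
            try:
                verdict = reviewer(candidate)
            except Exception as exc:
                exc.state = state  # type: ignore[attr-defined]
                raise
            state.decision_log.append(
                (state.iteration, candidate.pattern.text_form, verdict)
            )
            pool = state.accepted if verdict else state.rejected
            pool[candidate.pattern.text_form] = candidate.pattern
        state.extractions = apply_patterns(corpus, state.accepted.values())
        state.seed_pool |= select_seeds(
            state.extractions, config.k_symptoms, config.k_etiologies
        )
    return state
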