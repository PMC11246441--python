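"""Deterministic generator of parsed sentences with planted relations.

The generator emulates PubMed-abstract-style sentences expressing symptom
etiologies ("X is caused by Y", "Y induced X", "X secondary to Y", ...),
distractor constructions that trap over-general patterns ("symptoms included
sciatica with pain and numbness"), irrelevant filler, and parenthetical
abbreviation definitions.  Every sentence is emitted from a hand-built
per-template dependency skeleton — no parser is ever invoked — together with
a gold set of planted relations and a concept map for evaluating mention
unification.  Identical config and seed produce bit-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Corpus, ParsedSentence, Span, Token
from .errors import ConfigError

DEFAULT_SYMPTOMS: tuple[str, ...] = (
    "sciatica",
    "jaundice",
    "hiccups",
    "chest pain",
    "photophobia",
    "polyuria",
)

DEFAULT_ETIOLOGIES: tuple[str, ...] = (
    "disc herniation",
    "endometriosis",
    "meningitis",
    "lymphoma",
    "viral hepatitis",
    "pancreatitis",
    "tuberculosis",
    "gastric distention",
    "multiple sclerosis",
    "renal cyst",
    "amyloidosis",
    "sarcoidosis",
)

#: Non-etiology terms that occupy the distractor's "with ___" slot: the trap
#: pattern extracts these as spurious etiologies if a reviewer accepts it.
FILLER_TERMS: tuple[str, ...] = ("pain", "numbness", "tingling", "weakness")

CAUSAL_TEMPLATES: tuple[str, ...] = (
    "caused_by",
    "induce",
    "secondary_to",
    "cause_verb",
    "associated_with",
    "result_from",
)

DISTRACTOR_TEMPLATE = "with_distractor"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    n_sentences: int = 500
    symptom_vocab: tuple[str, ...] = DEFAULT_SYMPTOMS
    etiology_vocab: tuple[str, ...] = DEFAULT_ETIOLOGIES
    template_mix: dict[str, float] = field(
        default_factory=lambda: {
            **{tid: 1.0 for tid in CAUSAL_TEMPLATES},
            DISTRACTOR_TEMPLATE: 2.0,
        }
    )
    abbrev_rate: float = 0.15
    noise_rate: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.symptom_vocab or not self.etiology_vocab:
            raise ConfigError("vocabularies must be non-empty")
        known = set(CAUSAL_TEMPLATES) | {DISTRACTOR_TEMPLATE}
        unknown = set(self.template_mix) - known
        if unknown:
            raise ConfigError(f"unknown template ids: {sorted(unknown)}")
        if any(w < 0 for w in self.template_mix.values()):
            raise ConfigError("template weights must be non-negative")
        if sum(self.template_mix.values()) <= 0:
            raise ConfigError("template weights must sum to > 0")
        for name in ("abbrev_rate", "noise_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class GoldSet:
    """Planted relations plus the variant→canonical concept map."""

    relations: set[tuple[str, Span, Span, str]] = field(default_factory=set)
    concept_map: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sentence builder
# ---------------------------------------------------------------------------

class _Builder:
    """Assembles a dependency skeleton from keyed rows in surface order."""

    def __init__(self) -> None:
        self._rows: list[tuple[str, str, str, str, str | None, str]] = []
        self._spans: dict[str, tuple[int, int]] = {}  # key -> row positions

    def tok(
        self,
        key: str,
        surface: str,
        upos: str,
        head_key: str | None,
        deprel: str,
        lemma: str | None = None,
    ) -> None:
        self._rows.append(
            (key, surface, lemma if lemma is not None else surface.lower(), upos, head_key, deprel)
        )

    def chunk(
        self,
        key: str,
        words: list[str],
        head_key: str | None,
        deprel: str,
        upos: str = "NOUN",
    ) -> None:
        """A noun-phrase slot: last word is the head, the rest compound to it."""
        start = len(self._rows)
        for pos, word in enumerate(words[:-1]):
            self.tok(f"{key}#{pos}", word, "NOUN", key, "compound")
        self.tok(key, words[-1], upos, head_key, deprel)
        self._spans[key] = (start, len(self._rows) - 1)

    def build(self, sent_id: str, doc_id: str = "synthetic") -> tuple[ParsedSentence, dict[str, Span]]:
        index_of = {row[0]: pos + 1 for pos, row in enumerate(self._rows)}
        tokens = tuple(
            Token(
                index=pos + 1,
                surface=surface,
                lemma=lemma,
                upos=upos,
                head=0 if head_key is None else index_of[head_key],
                deprel=deprel,
            )
            for pos, (key, surface, lemma, upos, head_key, deprel) in enumerate(self._rows)
        )
        spans = {k: (lo + 1, hi + 1) for k, (lo, hi) in self._spans.items()}
        return ParsedSentence(sent_id, doc_id, tokens), spans


def _build_causal(template: str, sym: list[str], eti: list[str]) -> _Builder:
    b = _Builder()
    if template == "caused_by":
        b.chunk("S", sym, "caused", "nsubjpass")
        b.tok("is", "is", "AUX", "caused", "auxpass", lemma="be")
        b.tok("caused", "caused", "VERB", None, "root", lemma="cause")
        b.tok("by", "by", "ADP", "E", "case")
        b.chunk("E", eti, "caused", "nmod")
        b.tok(".", ".", "PUNCT", "caused", "punct")
    elif template == "induce":
        b.chunk("E", eti, "induced", "nsubj")
        b.tok("induced", "induced", "VERB", None, "root", lemma="induce")
        b.chunk("S", sym, "induced", "dobj")
        b.tok(".", ".", "PUNCT", "induced", "punct")
    elif template == "secondary_to":
        b.chunk("S", sym, "secondary", "nsubj")
        b.tok("is", "is", "AUX", "secondary", "cop", lemma="be")
        b.tok("secondary", "secondary", "ADJ", None, "root")
        b.tok("to", "to", "ADP", "E", "case")
        b.chunk("E", eti, "secondary", "nmod")
        b.tok(".", ".", "PUNCT", "secondary", "punct")
    elif template == "cause_verb":
        b.chunk("E", eti, "cause", "nsubj")
        b.tok("can", "can", "AUX", "cause", "aux")
        b.tok("cause", "cause", "VERB", None, "root", lemma="cause")
        b.chunk("S", sym, "cause", "dobj")
        b.tok(".", ".", "PUNCT", "cause", "punct")
    elif template == "associated_with":
        b.chunk("S", sym, "associated", "nsubjpass")
        b.tok("is", "is", "AUX", "associated", "auxpass", lemma="be")
        b.tok("associated", "associated", "VERB", None, "root", lemma="associate")
        b.tok("with", "with", "ADP", "E", "case")
        b.chunk("E", eti, "associated", "nmod")
        b.tok(".", ".", "PUNCT", "associated", "punct")
    elif template == "result_from":
        b.chunk("S", sym, "results", "nsubj")
        b.tok("results", "results", "VERB", None, "root", lemma="result")
        b.tok("from", "from", "ADP", "E", "case")
        b.chunk("E", eti, "results", "nmod")
        b.tok(".", ".", "PUNCT", "results", "punct")
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown causal template {template!r}")
    return b


def _build_distractor(sym: list[str], filler: list[str]) -> _Builder:
    # "symptoms included <S> with <X> and numbness ." — the trap construction:
    # <X> is attached to the symptom by a bare nmod_with edge with no causal cue
    b = _Builder()
    b.tok("symptoms", "symptoms", "NOUN", "included", "nsubj", lemma="symptom")
    b.tok("included", "included", "VERB", None, "root", lemma="include")
    b.chunk("S", sym, "included", "dobj")
    b.tok("with", "with", "ADP", "X", "case")
    b.chunk("X", filler, "S", "nmod")
    b.tok("and", "and", "CCONJ", "numb", "cc")
    b.tok("numb", "numbness", "NOUN", "X", "conj", lemma="numbness")
    b.tok(".", ".", "PUNCT", "included", "punct")
    return b


_FILLERS: tuple[tuple[tuple[str, str, str, str | None, str, str], ...], ...] = (
    (
        ("the", "the", "DET", "study", "det", "the"),
        ("study", "study", "NOUN", "enrolled", "nsubj", "study"),
        ("enrolled", "enrolled", "VERB", None, "root", "enroll"),
        ("adult", "adult", "ADJ", "patients", "amod", "adult"),
        ("patients", "patients", "NOUN", "enrolled", "dobj", "patient"),
        (".", ".", "PUNCT", "enrolled", "punct", "."),
    ),
    (
        ("data", "data", "NOUN", "collected", "nsubjpass", "data"),
        ("were", "were", "AUX", "collected", "auxpass", "be"),
        ("collected", "collected", "VERB", None, "root", "collect"),
        ("across", "across", "ADP", "centers", "case", "across"),
        ("multiple", "multiple", "ADJ", "centers", "amod", "multiple"),
        ("centers", "centers", "NOUN", "collected", "nmod", "center"),
        (".", ".", "PUNCT", "collected", "punct", "."),
    ),
    (
        ("the", "the", "DET", "cohort", "det", "the"),
        ("cohort", "cohort", "NOUN", "completed", "nsubj", "cohort"),
        ("completed", "completed", "VERB", None, "root", "complete"),
        ("the2", "the", "DET", "survey", "det", "the"),
        ("survey", "survey", "NOUN", "completed", "dobj", "survey"),
        (".", ".", "PUNCT", "completed", "punct", "."),
    ),
)


def _build_filler(which: int) -> _Builder:
    b = _Builder()
    for key, surface, upos, head_key, deprel, lemma in _FILLERS[which]:
        b.tok(key, surface, upos, head_key, deprel, lemma=lemma)
    return b


def _insert_parenthetical(
    sentence: ParsedSentence, after: int, appos_head: int, short_form: str
) -> ParsedSentence:
    """Insert "( SF )" after token ``after``, apposed to ``appos_head``."""
    p = after + 1  # 1-based position of "("

    def shift(i: int) -> int:
        return i + 3 if i >= p else i

    tokens: list[Token] = []
    for tok in sentence.tokens:
        tokens.append(
            Token(
                index=shift(tok.index),
                surface=tok.surface,
                lemma=tok.lemma,
                upos=tok.upos,
                head=shift(tok.head) if tok.head else 0,
                deprel=tok.deprel,
            )
        )
    tokens[p - 1 : p - 1] = [
        Token(p, "(", "(", "PUNCT", p + 1, "punct"),
        Token(p + 1, short_form, short_form, "NOUN", shift(appos_head), "appos"),
        Token(p + 2, ")", ")", "PUNCT", p + 1, "punct"),
    ]
    tokens.sort(key=lambda t: t.index)
    return ParsedSentence(sentence.sent_id, sentence.doc_id, tuple(tokens))


def _pick_short_form(name: str, used: set[str]) -> str | None:
    """An unused short form that the abbreviation detector provably expands
    back to the full ``name``.

    Starts from the uppercased word initials and appends successive letters
    of the last word until the right-to-left character matching recovers the
    whole name (a bare initialism can legitimately resolve to a shorter
    suffix of the phrase, e.g. when the final initial also occurs late in
    the last word).
    """
    from .unify import _best_long_form, _valid_short_form

    words = name.split()
    if len(words) < 2:
        return None
    base = "".join(w[0] for w in words).upper()
    for extra in range(len(words[-1])):
        sf = base + words[-1][1 : 1 + extra].upper()
        if sf in used or not _valid_short_form(sf):
            continue
        if _best_long_form(sf, name) == name:
            return sf
    return None


def make_short_forms(names: tuple[str, ...] | list[str]) -> dict[str, str]:
    """Deterministic unique short forms for multi-word names."""
    table: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        sf = _pick_short_form(name, used)
        if sf is not None:
            used.add(sf)
            table[name] = sf
    return table


def _weighted_choice(rng: random.Random, items: tuple[str, ...]) -> str:
    # Zipf-like skew concentrates mass on early vocabulary entries so that
    # seed tuples recur across templates, as frequent pairs do in abstracts.
    weights = [1.0 / (k + 1) for k in range(len(items))]
    return rng.choices(items, weights=weights, k=1)[0]


def generate(config: GeneratorConfig) -> tuple[Corpus, GoldSet]:
    """Generate a corpus and its gold set from the configured conditions.

    Each causal sentence contributes exactly one gold relation; distractor
    and filler sentences contribute none.
    """
    rng = random.Random(config.rng_seed)
    short_forms = make_short_forms(config.etiology_vocab)
    template_ids = sorted(config.template_mix)
    template_weights = [config.template_mix[t] for t in template_ids]
    gold = GoldSet()
    for term in (*config.symptom_vocab, *config.etiology_vocab):
        gold.concept_map[term] = term
    for name, sf in short_forms.items():
        gold.concept_map[sf] = name

    sentences: list[ParsedSentence] = []
    for i in range(config.n_sentences):
        sent_id = f"synth{i:04d}"
        if rng.random() < config.noise_rate:
            sentence, _ = _build_filler(rng.randrange(len(_FILLERS))).build(sent_id)
            sentences.append(sentence)
            continue
        template = rng.choices(template_ids, weights=template_weights, k=1)[0]
        sym = _weighted_choice(rng, config.symptom_vocab).split()
        if template == DISTRACTOR_TEMPLATE:
            if rng.random() < 0.5:
                filler = _weighted_choice(rng, config.etiology_vocab).split()
            else:
                filler = [rng.choice(FILLER_TERMS)]
            sentence, _ = _build_distractor(sym, filler).build(sent_id)
            sentences.append(sentence)
            continue
        eti_name = _weighted_choice(rng, config.etiology_vocab)
        eti = eti_name.split()
        sentence, spans = _build_causal(template, sym, eti).build(sent_id)
        s_span, e_span = spans["S"], spans["E"]
        if rng.random() < config.abbrev_rate and eti_name in short_forms:
            sentence = _insert_parenthetical(
                sentence, e_span[1], e_span[1], short_forms[eti_name]
            )
            if s_span[0] > e_span[1]:
                s_span = (s_span[0] + 3, s_span[1] + 3)
        gold.relations.add((sent_id, s_span, e_span, template))
        sentences.append(sentence)
    return Corpus(sentences, provenance="synthetic generator"), gold


# ---------------------------------------------------------------------------
# Unification benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptVariants:
    """A canonical name with its planted surface variants and short form."""

    canonical: str
    variants: tuple[str, ...]
    short_form: str


_ADJECTIVES = (
    "chronic", "acute", "renal", "hepatic", "cardiac", "cortical", "basal",
    "spinal", "gastric", "ocular", "femoral", "lumbar", "thoracic", "cranial",
    "dermal", "neural", "arterial", "venous", "biliary", "pleural",
)
_NOUNS_A = (
    "artery", "nerve", "duct", "valve", "cyst", "ulcer", "fibroma",
    "stenosis", "embolism", "fibrosis", "atrophy", "edema", "abscess",
    "lesion", "infarct",
)
_NOUNS_B = (
    "syndrome", "disease", "disorder", "deficiency", "obstruction",
    "inflammation", "degeneration", "malformation", "rupture", "infection",
)


def make_unification_benchmark(
    n_names: int = 100, rng_seed: int = 0
) -> tuple[list[ConceptVariants], Corpus]:
    """Canonical names, five surface variants each, and defining sentences.

    Variants per name: upper-cased, word-order permuted, leading-article,
    duplicated-token, and the short-form abbreviation (defined in the
    returned corpus via a "long form ( SF )" sentence).  Names whose string
    fingerprints would collide with an earlier name are skipped, so the gold
    partition has exactly ``n_names`` concepts by construction.
    """
    from .unify import fingerprint  # local import to avoid a cycle

    rng = random.Random(rng_seed)
    adjectives = list(_ADJECTIVES)
    nouns_a = list(_NOUNS_A)
    nouns_b = list(_NOUNS_B)
    rng.shuffle(adjectives)
    rng.shuffle(nouns_a)
    rng.shuffle(nouns_b)
    candidates = [
        f"{a} {n1} {n2}" for a in adjectives for n1 in nouns_a for n2 in nouns_b
    ]

    seen_fps: set[str] = set()
    used_sfs: set[str] = set()
    chosen: list[ConceptVariants] = []
    sentences: list[ParsedSentence] = []
    for name in candidates:
        if len(chosen) == n_names:
            break
        fp = fingerprint(name)
        if fp in seen_fps:
            continue
        words = name.split()
        sf = _pick_short_form(name, used_sfs)
        if sf is None:
            continue
        seen_fps.add(fp)
        used_sfs.add(sf)
        variants = (
            name.upper(),
            " ".join(reversed(words)),
            f"the {name}",
            f"{name} {words[-1]}",
            sf,
        )
        chosen.append(ConceptVariants(name, variants, sf))
        b = _Builder()
        b.chunk("LF", words, "common", "nsubj")
        b.tok("(", "(", "PUNCT", "SF", "punct")
        b.tok("SF", sf, "NOUN", "LF", "appos")
        b.tok(")", ")", "PUNCT", "SF", "punct")
        b.tok("is", "is", "AUX", "common", "cop", lemma="be")
        b.tok("common", "common", "ADJ", None, "root")
        b.tok(".", ".", "PUNCT", "common", "punct")
        sentence, _ = b.build(f"def{len(chosen) - 1:04d}", doc_id="definitions")
        sentences.append(sentence)
    if len(chosen) < n_names:
        raise ConfigError(
            f"could only build {len(chosen)} collision-free names, "
            f"requested {n_names}"
        )
    return chosen, Corpus(sentences, provenance="unification benchmark")
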