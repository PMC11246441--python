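"""Generate → retrieve → rank → vet pipeline for etiology verification.

Generative models hallucinate, so every generated etiology must earn its
place: candidate evidence sentences are retrieved from the corpus (soft
similarity plus optional hard constraints requiring both exact phrases), a
model is asked to select and rank at most three convincing sentences from
that candidate list only, and each survivor gets a final yes/no vetting
judgment.  An etiology without at least one vetted sentence is dropped.

The model sits behind a minimal backend contract so the pipeline runs fully
deterministically with a scripted mock.
"""

from __future__ import annotations

import ast
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import Corpus

logger = logging.getLogger(__name__)

GENERATION_PROMPT = (
    "Provide an exhaustive list of all possible {symptom} etiologies. "
    "Be succinct, list only names, each name in its own line. "
    "Include all known etiologies, even the most rare ones. "
    "write done when you finish listing all etiologies."
)

RETRIEVAL_QUERY = "an etiology for {symptom}"

RANKING_PROMPT = (
    "From the list of sentences below (one per line), which 3 sentences "
    "would be the most convincing ones to be used as evidence that "
    "{etiology} is an etiology for {symptom}?\n"
    "When selecting the 3 sentences, prioritize sentences which explicitly "
    "state that the item belongs to the list over ones where this is only "
    "implied.\n"
    "Only select sentences from the list below, do not add new sentences. "
    "If the list does not contain 3 sentences that could be used as "
    "supportive evidence, return fewer sentences, or 0 sentences (an empty "
    "list) if needed.\n"
    'Format the results as a Python array, where each item is a dict with '
    'two items, the first item ("sent"), is the sentence itself. The second '
    'item ("reason") is a textual explanation of the reason why the '
    "sentence was selected.\n"
    "Be succinct, reply with the Python list and nothing else.\n"
    "\n"
    "{sentences}"
)

VETTING_PROMPT = (
    'Can the following sentence be used as evidence that "{etiology}" is an '
    "etiology for {symptom}? Be succinct, and reply with yes or no only.\n"
    "The sentence is:\n"
    "{sentence}"
)


@dataclass
class DecodingParams:
    temperature: float = 1.0
    max_tokens: int = 4096
    top_p: float = 1.0


class LLMBackend(Protocol):
    def complete(
        self,
        prompt: str,
        *,
        temperature: float = 1.0,
        max_tokens: int = 4096,
        top_p: float = 1.0,
    ) -> str: ...


class MockBackend:
    """Deterministic backend: a prompt→response mapping or a callable.

    Every call is recorded in ``calls`` for replay and auditing.
    """

    def __init__(self, responses: Mapping[str, str] | Callable[[str], str]):
        self._responses = responses
        self.calls: list[str] = []

    def complete(
        self,
        prompt: str,
        *,
        temperature: float = 1.0,
        max_tokens: int = 4096,
        top_p: float = 1.0,
    ) -> str:
        self.calls.append(prompt)
        if callable(self._responses):
            return self._responses(prompt)
        try:
            return self._responses[prompt]
        except KeyError:
            raise KeyError(
                f"mock backend has no scripted response for prompt starting "
                f"{prompt[:80]!r}"
            ) from None


class OpenAIBackend:
    """Thin adapter over the OpenAI chat-completions API (optional)."""

    def __init__(self, model: str, client=None):
        if client is None:  # pragma: no cover - requires the optional package
            import openai

            client = openai.OpenAI()
        self.model = model
        self.client = client

    def complete(
        self,
        prompt: str,
        *,
        temperature: float = 1.0,
        max_tokens: int = 4096,
        top_p: float = 1.0,
    ) -> str:  # pragma: no cover - requires live credentials
        response = self.client.chat.completions.create(
            model=self.model,
            messages=[{"role": "user", "content": prompt}],
            temperature=temperature,
            max_tokens=max_tokens,
            top_p=top_p,
        )
        return response.choices[0].message.content or ""


# ---------------------------------------------------------------------------
# Retrieval
# ---------------------------------------------------------------------------

class Embedder(Protocol):
    """Scores each sentence against a query; higher is more similar."""

    def score(self, query: str, sentences: Sequence[str]) -> list[float]: ...


class TfidfEmbedder:
    """Term-weighted lexical similarity (cosine over TF-IDF vectors)."""

    def score(self, query: str, sentences: Sequence[str]) -> list[float]:
        from sklearn.feature_extraction.text import TfidfVectorizer

        vectorizer = TfidfVectorizer()
        try:
            matrix = vectorizer.fit_transform(list(sentences))
        except ValueError:  # empty vocabulary (e.g. all-punctuation corpus)
            return [0.0] * len(sentences)
        query_vec = vectorizer.transform([query])
        scores = (matrix @ query_vec.T).toarray().ravel()
        return [float(s) for s in scores]


@dataclass
class RetrievalConfig:
    top_n: int = 50
    hard_constraints: bool = True
    embedder: Embedder = field(default_factory=TfidfEmbedder)

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class EvidenceCandidate:
    sentence_text: str
    sent_id: str
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("similarity score must be finite")


@dataclass
class VerifiedEtiology:
    """A generated etiology with at most 3 ranked, vetted evidence sentences."""

    name: str
    evidence: list[tuple[str, str, str]]  # (sentence, reason, verdict)

    def __post_init__(self) -> None:
        if len(self.evidence) > 3:
            raise ValueError("at most 3 evidence sentences")
        if any(verdict != "yes" for _, _, verdict in self.evidence):
            raise ValueError("retained evidence must have verdict 'yes'")


@dataclass
class FunnelCounts:
    """Per-stage survivor counts: generated ≥ with candidates ≥ verified."""

    generated: int = 0
    with_candidates: int = 0
    verified: int = 0


@dataclass
class VerificationReport:
    verified: list[VerifiedEtiology]
    funnel: FunnelCounts
    failures: list[tuple[str, str]]  # (etiology, error description)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

_BULLET_RE = re.compile(r"^\s*(?:[-*•]|\d+[.)])\s*")


def _parse_name_list(response: str) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    for raw in response.splitlines():
        line = _BULLET_RE.sub("", raw).strip()
        if not line:
            continue
        if line.rstrip(".!").strip().lower() == "done":
            break
        key = line.lower()
        if key not in seen:
            seen.add(key)
            names.append(line)
    return names


def generate_etiologies(
    symptom: str,
    backend: LLMBackend,
    params: DecodingParams | None = None,
    n_runs: int = 1,
) -> list[str]:
    """Prompt for an exhaustive etiology list; parse one name per line.

    Bullets, blank lines and the terminal "done" sentinel are stripped and
    names deduplicated case-insensitively, first occurrence kept.  With
    ``n_runs > 1`` the run yielding the most names wins (run counts vary;
    merging runs would require name normalization, which is not attempted).
    """
    params = params or DecodingParams()
    prompt = GENERATION_PROMPT.format(symptom=symptom)
    best: list[str] = []
    for _ in range(max(1, n_runs)):
        response = backend.complete(
            prompt,
            temperature=params.temperature,
            max_tokens=params.max_tokens,
            top_p=params.top_p,
        )
        names = _parse_name_list(response)
        if len(names) > len(best):
            best = names
    return best


def retrieve_evidence(
    symptom: str,
    etiology: str,
    corpus: Corpus,
    config: RetrievalConfig | None = None,
) -> list[EvidenceCandidate]:
    """Score corpus sentences against "an etiology for <symptom>".

    With hard constraints on, only sentences containing BOTH the etiology
    and the symptom as exact case-insensitive phrases survive.  Returns the
    top-n by score, ties broken by sentence id.
    """
    config = config or RetrievalConfig()
    sentences = list(corpus)
    texts = [s.text for s in sentences]
    scores = config.embedder.score(RETRIEVAL_QUERY.format(symptom=symptom), texts)
    candidates = []
    for sentence, text, score in zip(sentences, texts, scores):
        if config.hard_constraints:
            lowered = text.lower()
            if symptom.lower() not in lowered or etiology.lower() not in lowered:
                continue
        candidates.append(EvidenceCandidate(text, sentence.sent_id, float(score)))
    candidates.sort(key=lambda c: (-c.score, c.sent_id))
    return candidates[: config.top_n]


def _parse_ranked_array(response: str) -> list[dict] | None:
    text = response.strip()
    text = re.sub(r"^```(?:python|json)?\s*|\s*```$", "", text).strip()
    for parser in (ast.literal_eval,):
        try:
            value = parser(text)
        except (ValueError, SyntaxError):
            continue
        if isinstance(value, list):
            return [v for v in value if isinstance(v, dict)]
    return None


def rank_evidence(
    symptom: str,
    etiology: str,
    candidates: Sequence[EvidenceCandidate],
    backend: LLMBackend,
    params: DecodingParams | None = None,
) -> list[tuple[str, str]]:
    """Ask the model for the ≤3 most convincing sentences, with reasons.

    Returned items whose sentence is not an exact member of the candidate
    list are dropped (the model must not add new sentences).  An unparseable
    response yields an empty result with the payload logged, never a crash.
    """
    if not candidates:
        return []
    params = params or DecodingParams()
    prompt = RANKING_PROMPT.format(
        etiology=etiology,
        symptom=symptom,
        sentences="\n".join(c.sentence_text for c in candidates),
    )
    response = backend.complete(
        prompt,
        temperature=params.temperature,
        max_tokens=params.max_tokens,
        top_p=params.top_p,
    )
    items = _parse_ranked_array(response)
    if items is None:
        logger.warning(
            "unparseable ranking response for %r (payload preserved): %r",
            etiology,
            response,
        )
        return []
    allowed = {c.sentence_text for c in candidates}
    ranked: list[tuple[str, str]] = []
    for item in items:
        sentence = item.get("sent")
        if sentence in allowed:
            ranked.append((sentence, str(item.get("reason", ""))))
        else:
            logger.warning("dropping fabricated evidence sentence %r", sentence)
        if len(ranked) == 3:
            break
    return ranked


def vet_evidence(
    symptom: str,
    etiology: str,
    sentence: str,
    backend: LLMBackend,
    params: DecodingParams | None = None,
) -> str:
    """Final yes/no judgment; anything not normalizing to yes/no counts as no."""
    params = params or DecodingParams()
    prompt = VETTING_PROMPT.format(
        etiology=etiology, symptom=symptom, sentence=sentence
    )
    response = backend.complete(
        prompt,
        temperature=params.temperature,
        max_tokens=params.max_tokens,
        top_p=params.top_p,
    )
    normalized = response.strip().strip(".!,\"'").lower()
    if normalized in ("yes", "no"):
        return normalized
    logger.warning("non-yes/no vetting response %r treated as no", response)
    return "no"


def verify_all(
    symptom: str,
    backend: LLMBackend,
    corpus: Corpus,
    config: RetrievalConfig | None = None,
    params: DecodingParams | None = None,
    n_generation_runs: int = 1,
) -> VerificationReport:
    """Full pipeline: generate, then retrieve/rank/vet each etiology.

    An etiology survives iff at least one vetted evidence sentence remains.
    The funnel counts (generated / with candidate evidence / verified) are
    monotonically non-increasing.  A backend failure on one etiology is
    recorded and the remaining etiologies still complete.
    """
    config = config or RetrievalConfig()
    params = params or DecodingParams()
    names = generate_etiologies(symptom, backend, params, n_runs=n_generation_runs)
    funnel = FunnelCounts(generated=len(names))
    verified: list[VerifiedEtiology] = []
    failures: list[tuple[str, str]] = []
    for name in names:
        try:
            candidates = retrieve_evidence(symptom, name, corpus, config)
            if not candidates:
                continue
            funnel.with_candidates += 1
            ranked = rank_evidence(symptom, name, candidates, backend, params)
            evidence = [
                (sentence, reason, "yes")
                for sentence, reason in ranked
                if vet_evidence(symptom, name, sentence, backend, params) == "yes"
            ]
            if evidence:
                verified.append(VerifiedEtiology(name, evidence))
        except Exception as exc:  # noqa: BLE001 - partial failure is reported
            logger.warning("verification failed for %r: %s", name, exc)
            failures.append((name, str(exc)))
    funnel.verified = len(verified)
    return VerificationReport(verified, funnel, failures)
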