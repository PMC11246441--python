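"""Mention normalization and grouping into ranked concepts.

Raw etiology mentions are noisy surface strings ("The Lumbar Disc
Herniation", "disc herniation, lumbar", "ADPKD").  They are unified by:

1. expanding abbreviations detected with the Schwartz–Hearst parenthetical
   algorithm;
2. computing a string *fingerprint*: lowercase, strip punctuation, drop
   leading articles, collapse whitespace, deduplicate and sort tokens, and —
   when the joined string exceeds 6 characters — replace each token by its
   American Soundex code;
3. grouping mentions by fingerprint and ranking the groups (concepts) by
   mention count.

An ontology linker (e.g. to a disease vocabulary) is a pluggable contract;
the default linker is the fingerprint itself, so unlinked mentions remain as
singletons under their original names.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Protocol

from .corpus import Corpus, ParsedSentence, Span
from .errors import EmptyFingerprintError

logger = logging.getLogger(__name__)

_ARTICLES = frozenset({"a", "an", "the"})
_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)

_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


@dataclass(frozen=True)
class Mention:
    """An extracted span with provenance."""

    raw_text: str
    sent_id: str
    span: Span
    role: Literal["symptom", "etiology"] = "etiology"

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError("mention raw text must be non-empty")


@dataclass
class Concept:
    """A group of mentions sharing one fingerprint, ranked by count."""

    concept_id: str
    display_name: str
    mentions: list[Mention]

    @property
    def count(self) -> int:
        return len(self.mentions)


@dataclass
class AbbrevMap:
    """Short form → (long form, defining sentence id)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def long_form(self, short: str) -> str | None:
        entry = self.entries.get(short)
        return entry[0] if entry else None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, short: str) -> bool:
        return short in self.entries


class Linker(Protocol):
    """Maps a mention surface to a concept id (and a confidence score)."""

    def link(self, text: str) -> tuple[str, float]: ...


class FingerprintLinker:
    """Default linker: the concept id is the string fingerprint itself."""

    def link(self, text: str) -> tuple[str, float]:
        return fingerprint(text), 1.0


# ---------------------------------------------------------------------------
# Soundex and fingerprint
# ---------------------------------------------------------------------------

def soundex(token: str) -> str:
    """American Soundex: first letter + 3 digits, zero-padded.

    Adjacent letters with the same code collapse (including across the
    transparent letters h and w); vowels separate codes.  Non-alphabetic
    tokens are passed through unchanged with a warning.
    """
    if not token.isalpha():
        logger.warning("soundex: non-alphabetic token %r passed through", token)
        return token
    upper = token.upper()
    prev = _SOUNDEX_CODES.get(upper[0], "")
    digits: list[str] = []
    for ch in upper[1:]:
        if ch in "HW":
            continue  # transparent: previous code survives across h/w
        code = _SOUNDEX_CODES.get(ch, "")
        if code == "":
            prev = ""  # vowel: reset so a repeated code counts again
            continue
        if code != prev:
            digits.append(code)
            prev = code
        if len(digits) == 3:
            break
    return (upper[0] + "".join(digits) + "000")[:4]


def fingerprint(name: str) -> str:
    """Canonical fingerprint used to unify synonymous mentions.

    Steps, in order: lowercase; strip punctuation; drop leading articles;
    trim and collapse whitespace; split, deduplicate and sort tokens; if the
    joined normalized string exceeds 6 characters, replace each token by its
    Soundex code and rejoin (shorter strings remain as is).
    """
    if not name:
        raise EmptyFingerprintError("empty mention")
    lowered = _PUNCT_RE.sub(" ", name.lower())
    tokens = lowered.split()
    while tokens and tokens[0] in _ARTICLES:
        tokens.pop(0)
    tokens = sorted(set(tokens))
    joined = " ".join(tokens)
    if not joined:
        raise EmptyFingerprintError(f"mention {name!r} normalizes to empty")
    if len(joined) > 6:
        # lowercased codes keep the fingerprint idempotent on its own output
        joined = " ".join(soundex(tok).lower() for tok in tokens)
    return joined


# ---------------------------------------------------------------------------
# Abbreviation detection (Schwartz–Hearst)
# ---------------------------------------------------------------------------

def _valid_short_form(candidate: str) -> bool:
    if not 2 <= len(candidate) <= 10:
        return False
    if len(candidate.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in candidate):
        return False
    return candidate[0].isalnum()


def _best_long_form(short: str, long_candidate: str) -> str | None:
    """Right-to-left character matching of the short form into the long form.

    Every alphanumeric short-form character must appear, in order, in the
    long form; the first one must match at the start of a long-form word.
    """
    s_i = len(short) - 1
    l_i = len(long_candidate) - 1
    while s_i >= 0:
        ch = short[s_i].lower()
        if not ch.isalnum():
            s_i -= 1
            continue
        while l_i >= 0 and (
            long_candidate[l_i].lower() != ch
            or (s_i == 0 and l_i > 0 and long_candidate[l_i - 1].isalnum())
        ):
            l_i -= 1
        if l_i < 0:
            return None
        s_i -= 1
        l_i -= 1
    start = long_candidate.rfind(" ", 0, l_i + 1) + 1
    return long_candidate[start:]


def detect_abbreviations(corpus: Corpus) -> AbbrevMap:
    """Scan "long form ( SF )" parentheticals across the corpus.

    Conflicting definitions for a short form are resolved by frequency, then
    by first occurrence.  Only the long-form-before-parenthesis order is
    recognized, per the reference algorithm's candidate rules.
    """
    votes: dict[str, Counter[str]] = {}
    first_seen: dict[tuple[str, str], tuple[int, str]] = {}
    order = 0
    for sentence in corpus:
        tokens = sentence.tokens
        for i, tok in enumerate(tokens):
            if tok.surface != "(":
                continue
            close = next(
                (j for j in range(i + 1, len(tokens)) if tokens[j].surface == ")"),
                None,
            )
            if close is None or close == i + 1:
                continue
            short = " ".join(t.surface for t in tokens[i + 1 : close])
            if not _valid_short_form(short):
                continue
            max_words = min(len(short) + 5, len(short) * 2)
            before = [t.surface for t in tokens[max(0, i - max_words) : i]]
            if not before:
                continue
            long_form = _best_long_form(short, " ".join(before))
            if not long_form or len(long_form) <= len(short):
                continue
            votes.setdefault(short, Counter())[long_form] += 1
            key = (short, long_form)
            if key not in first_seen:
                first_seen[key] = (order, sentence.sent_id)
                order += 1
    result = AbbrevMap()
    for short, counter in votes.items():
        best = min(
            counter,
            key=lambda lf: (-counter[lf], first_seen[(short, lf)][0]),
        )
        result.entries[short] = (best, first_seen[(short, best)][1])
    return result


def expand_abbreviations(text: str, abbrevs: AbbrevMap) -> str:
    """Replace short-form words in ``text`` with their long forms."""
    if not abbrevs.entries:
        return text
    for short in sorted(abbrevs.entries, key=len, reverse=True):
        long_form = abbrevs.entries[short][0]
        text = re.sub(rf"\b{re.escape(short)}\b", long_form, text)
    return text


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def unify(
    mentions: Iterable[Mention],
    abbrevs: AbbrevMap | None = None,
    linker: Linker | None = None,
) -> tuple[list[Concept], list[Mention]]:
    """Group mentions into concepts ranked by mention count.

    Returns ``(concepts, quarantined)`` where the quarantine holds mentions
    whose text normalizes to an empty fingerprint.  Concepts are sorted by
    count descending, ties by display name; the display name is the modal raw
    surface (ties broken by shortest, then lexicographic).
    """
    abbrevs = abbrevs or AbbrevMap()
    linker = linker or FingerprintLinker()
    groups: dict[str, list[Mention]] = {}
    quarantined: list[Mention] = []
    for mention in mentions:
        expanded = expand_abbreviations(mention.raw_text, abbrevs)
        try:
            concept_id, _ = linker.link(expanded)
        except EmptyFingerprintError:
            logger.warning("unnormalizable mention %r quarantined", mention.raw_text)
            quarantined.append(mention)
            continue
        groups.setdefault(concept_id, []).append(mention)
    concepts = []
    for concept_id, members in groups.items():
        surface_counts = Counter(m.raw_text for m in members)
        display = min(
            surface_counts,
            key=lambda s: (-surface_counts[s], len(s), s),
        )
        concepts.append(Concept(concept_id, display, members))
    concepts.sort(key=lambda c: (-c.count, c.display_name))
    return concepts, quarantined
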