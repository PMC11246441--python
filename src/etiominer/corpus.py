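"""Parsed-sentence domain model, CoNLL-U I/O and keyword co-occurrence search.

A :class:`ParsedSentence` carries one *basic* Universal Dependencies tree:
1-based token indices, ``head == 0`` marking the root, and plain ``deprel``
labels.  The co-occurrence search implements the "basic" query that seeds
pattern bootstrapping: find every sentence containing two terms as contiguous
token sequences, irrespective of their syntactic configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import AmbiguousSpanHeadError, ConlluParseError, TreeInvariantError

logger = logging.getLogger(__name__)

#: Inclusive 1-based token-index range.
Span = tuple[int, int]


@dataclass(frozen=True)
class Token:
    """One token of a dependency-parsed sentence.

    ``index`` is 1-based; ``head`` is the index of the governing token, with
    0 denoting the root.  ``deprel`` is the (basic) dependency relation to
    the head.
    """

    index: int
    surface: str
    lemma: str
    upos: str
    head: int
    deprel: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise ValueError(f"token head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise TreeInvariantError(
                f"token {self.index} ({self.surface!r}) is its own head"
            )
        if not self.deprel:
            raise ValueError(f"token {self.index} has an empty deprel")


@dataclass
class ParsedSentence:
    """A sentence with exactly one basic dependency tree over its tokens."""

    sent_id: str
    doc_id: str
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        self.tokens = tuple(self.tokens)
        n = len(self.tokens)
        if n == 0:
            raise TreeInvariantError(f"sentence {self.sent_id!r} has no tokens")
        for pos, tok in enumerate(self.tokens, start=1):
            if tok.index != pos:
                raise TreeInvariantError(
                    f"sentence {self.sent_id!r}: token indices not contiguous "
                    f"(expected {pos}, found {tok.index})"
                )
            if tok.head > n:
                raise TreeInvariantError(
                    f"sentence {self.sent_id!r}: token {tok.index} heads to "
                    f"{tok.head}, beyond sentence length {n}"
                )
        roots = [t.index for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise TreeInvariantError(
                f"sentence {self.sent_id!r}: expected exactly one root, "
                f"found {len(roots)}"
            )
        # walk every head chain to the root; a revisit within one walk is a cycle
        for tok in self.tokens:
            seen: set[int] = set()
            cur = tok.index
            while cur != 0:
                if cur in seen:
                    raise TreeInvariantError(
                        f"sentence {self.sent_id!r}: cycle through token {cur}"
                    )
                seen.add(cur)
                cur = self.tokens[cur - 1].head

    def __len__(self) -> int:
        return len(self.tokens)

    def token(self, index: int) -> Token:
        """Token at 1-based ``index``."""
        return self.tokens[index - 1]

    @property
    def root_index(self) -> int:
        return next(t.index for t in self.tokens if t.head == 0)

    def children(self, index: int) -> list[Token]:
        """Direct dependents of the token at ``index``, in surface order."""
        return [t for t in self.tokens if t.head == index]

    @property
    def text(self) -> str:
        return " ".join(t.surface for t in self.tokens)

    def span_text(self, span: Span) -> str:
        lo, hi = span
        return " ".join(t.surface for t in self.tokens[lo - 1 : hi])


@dataclass
class Corpus:
    """A list of parsed sentences with unique sentence ids."""

    sentences: list[ParsedSentence] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sent_id for s in self.sentences]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sent_ids in corpus: {dupes}")
        self._by_id = {s.sent_id: s for s in self.sentences}

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[ParsedSentence]:
        return iter(self.sentences)

    def sentence(self, sent_id: str) -> ParsedSentence:
        return self._by_id[sent_id]


@dataclass(frozen=True)
class SpanMatch:
    """Two non-overlapping contiguous spans located in one sentence."""

    sentence: ParsedSentence
    span_a: Span
    span_b: Span

    def __post_init__(self) -> None:
        n = len(self.sentence)
        for name, (lo, hi) in (("span_a", self.span_a), ("span_b", self.span_b)):
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"{name} {lo, hi} out of bounds for n={n}")
        a, b = self.span_a, self.span_b
        if not (a[1] < b[0] or b[1] < a[0]):
            raise ValueError(f"spans overlap: {a} and {b}")


# ---------------------------------------------------------------------------
# CoNLL-U I/O
# ---------------------------------------------------------------------------

@dataclass
class RejectedSentence:
    """A block that parsed column-wise but failed the tree invariants."""

    sent_id: str
    line_number: int
    reason: str


def read_conllu_with_report(
    path: str | Path,
) -> tuple[Corpus, list[RejectedSentence]]:
    """Read a CoNLL-U file; quarantine tree-invalid sentences instead of failing.

    Multi-word-token (``1-2``) and empty-node (``1.1``) lines are skipped with
    a logged warning.  Malformed lines (wrong column count, non-integer head)
    raise :class:`ConlluParseError` naming the offending line.  Sentences whose
    head links violate the single-rooted-tree invariants are collected in the
    returned report, not silently dropped.
    """
    path = Path(path)
    sentences: list[ParsedSentence] = []
    rejected: list[RejectedSentence] = []

    block: list[tuple[int, list[str]]] = []  # (line number, columns)
    meta: dict[str, str] = {}
    block_start = 0
    auto_id = 0
    doc_id = ""

    def flush() -> None:
        nonlocal auto_id
        if not block:
            meta.clear()
            return
        auto_id += 1
        sent_id = meta.get("sent_id", f"s{auto_id}")
        sdoc = meta.get("doc_id", meta.get("newdoc id", doc_id))
        tokens = []
        try:
            for ln, cols in block:
                try:
                    tokens.append(
                        Token(
                            index=int(cols[0]),
                            surface=cols[1],
                            lemma=cols[2],
                            upos=cols[3],
                            head=int(cols[6]),
                            deprel=cols[7],
                        )
                    )
                except (ValueError, TreeInvariantError) as exc:
                    raise TreeInvariantError(str(exc)) from exc
            sentences.append(ParsedSentence(sent_id, sdoc, tuple(tokens)))
        except TreeInvariantError as exc:
            rejected.append(RejectedSentence(sent_id, block_start, str(exc)))
        block.clear()
        meta.clear()

    with path.open(encoding="utf-8") as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                if not block:
                    block_start = line_number + 1
                if "=" in line:
                    key, _, value = line.lstrip("#").partition("=")
                    meta[key.strip()] = value.strip()
                    if key.strip() == "newdoc id":
                        doc_id = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ConlluParseError(
                    f"expected 10 tab-separated columns, found {len(cols)}",
                    line_number,
                )
            if "-" in cols[0] or "." in cols[0]:
                logger.warning(
                    "%s line %d: skipping %s line %r",
                    path.name,
                    line_number,
                    "multi-word-token" if "-" in cols[0] else "empty-node",
                    cols[0],
                )
                continue
            if not cols[0].lstrip("-").isdigit():
                raise ConlluParseError(f"bad token id {cols[0]!r}", line_number)
            if not block:
                block_start = line_number
            block.append((line_number, cols))
    flush()
    return Corpus(sentences, provenance=str(path)), rejected


def read_conllu(path: str | Path) -> Corpus:
    """Read a CoNLL-U file, logging (but keeping out) invalid sentences."""
    corpus, rejected = read_conllu_with_report(path)
    for rej in rejected:
        logger.warning(
            "rejected sentence %s (line %d): %s",
            rej.sent_id,
            rej.line_number,
            rej.reason,
        )
    return corpus


def write_conllu(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to 10-column CoNLL-U (unused columns as ``_``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for sent in corpus:
            if sent.doc_id:
                handle.write(f"# doc_id = {sent.doc_id}\n")
            handle.write(f"# sent_id = {sent.sent_id}\n")
            handle.write(f"# text = {sent.text}\n")
            for tok in sent.tokens:
                handle.write(
                    "\t".join(
                        [
                            str(tok.index),
                            tok.surface,
                            tok.lemma,
                            tok.upos,
                            "_",
                            "_",
                            str(tok.head),
                            tok.deprel,
                            "_",
                            "_",
                        ]
                    )
                    + "\n"
                )
            handle.write("\n")


# ---------------------------------------------------------------------------
# Basic co-occurrence search
# ---------------------------------------------------------------------------

def _term_occurrences(sentence: ParsedSentence, term: str) -> list[Span]:
    """Contiguous spans where ``term`` matches on surface, else lemma.

    Matching is case-insensitive; punctuation tokens never match.  Surface
    matching is tried for the whole term first, then lemma matching, so a
    surface hit shadows lemma hits at the same position.
    """
    words = term.lower().split()
    if not words:
        return []
    spans: list[Span] = []
    n = len(sentence)
    for start in range(1, n - len(words) + 2):
        window = [sentence.token(start + k) for k in range(len(words))]
        if any(t.upos == "PUNCT" for t in window):
            continue
        if all(t.surface.lower() == w for t, w in zip(window, words)):
            spans.append((start, start + len(words) - 1))
        elif all(t.lemma.lower() == w for t, w in zip(window, words)):
            logger.debug(
                "lemma-level match for %r in sentence %s", term, sentence.sent_id
            )
            spans.append((start, start + len(words) - 1))
    return spans


def search_cooccurrence(
    corpus: Corpus, term_a: str, term_b: str
) -> list[SpanMatch]:
    """Every sentence containing both terms as contiguous token sequences.

    Each (occurrence of ``term_a``, occurrence of ``term_b``) pair yields one
    :class:`SpanMatch`; pairs whose spans overlap are excluded.
    """
    if not term_a.strip() or not term_b.strip():
        raise ValueError("search terms must be non-empty")
    matches: list[SpanMatch] = []
    for sent in corpus:
        spans_a = _term_occurrences(sent, term_a)
        if not spans_a:
            continue
        spans_b = _term_occurrences(sent, term_b)
        for sa in spans_a:
            for sb in spans_b:
                if sa[1] < sb[0] or sb[1] < sa[0]:
                    matches.append(SpanMatch(sent, sa, sb))
    return matches


def head_of_span(sentence: ParsedSentence, span: Span) -> int:
    """Index of the unique span token whose head lies outside the span.

    This token is the syntactic head of the span and serves as the endpoint
    for dependency-path pattern generation.  Raises
    :class:`AmbiguousSpanHeadError` when the span covers zero or several
    sibling subtrees.
    """
    lo, hi = span
    if not (1 <= lo <= hi <= len(sentence)):
        raise ValueError(f"span {span} out of bounds")
    heads = [
        t.index
        for t in sentence.tokens[lo - 1 : hi]
        if t.head == 0 or not (lo <= t.head <= hi)
    ]
    if len(heads) != 1:
        raise AmbiguousSpanHeadError(
            f"span {span} in sentence {sentence.sent_id!r} has "
            f"{len(heads)} external-head tokens (expected 1)"
        )
    return heads[0]
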