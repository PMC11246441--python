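"""Linearized dependency-path patterns: derivation, parsing, matching.

A pattern is the shortest undirected path between two tokens in a basic UD
tree, written out as capture placeholders at the ends, ``lemm=`` anchors at
interior nodes, and directed edge constraints in between::

    [symptom placeholder] : <nsubjpass : lemm=cause : >nmod_by : [disease placeholder]

``<label`` walks dependent→head (the previous node is the dependent);
``>label`` walks head→dependent.  An ``nmod`` edge whose dependent carries a
case-marking child is written with the case lemma appended (``nmod_by``) and
matched structurally — the tree itself is never mutated.  Matched placeholder
tokens are expanded to their linguistic phrase boundaries before extraction
(e.g. "herniation" → "disc herniation").
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .corpus import ParsedSentence, Span, head_of_span
from .errors import PatternParseError

logger = logging.getLogger(__name__)

Role = Literal["symptom", "etiology"]
Direction = Literal["up", "down"]

#: Dependent relations pulled into a capture's phrase boundary.  ``nmod`` is
#: also pulled in, but only when the dependent has no case-marking child
#: (case-marked nominal modifiers are prepositional phrases, not name parts).
DEFAULT_EXPANSION_RELATIONS = frozenset({"compound", "amod", "nummod", "flat"})

#: Placeholders must bind nominal tokens when POS information is present.
NOMINAL_POS = frozenset({"NOUN", "PROPN", "PRON"})

_ROLE_TEXT: dict[Role, str] = {
    "symptom": "[symptom placeholder]",
    "etiology": "[disease placeholder]",
}
_TEXT_ROLE = {v: k for k, v in _ROLE_TEXT.items()}


@dataclass(frozen=True)
class PatternElement:
    """One element of a linearized pattern: placeholder, anchor or edge."""

    kind: Literal["placeholder", "anchor", "edge"]
    role: Role | None = None        # placeholder only
    lemma: str | None = None        # anchor only
    label: str | None = None        # edge only
    direction: Direction | None = None  # edge only

    def __post_init__(self) -> None:
        expected = {
            "placeholder": ("role",),
            "anchor": ("lemma",),
            "edge": ("label", "direction"),
        }[self.kind]
        for name in ("role", "lemma", "label", "direction"):
            value = getattr(self, name)
            if name in expected and value is None:
                raise ValueError(f"{self.kind} element requires {name}")
            if name not in expected and value is not None:
                raise ValueError(f"{self.kind} element must not set {name}")

    @property
    def text(self) -> str:
        if self.kind == "placeholder":
            return _ROLE_TEXT[self.role]  # type: ignore[index]
        if self.kind == "anchor":
            return f"lemm={self.lemma}"
        prefix = "<" if self.direction == "up" else ">"
        return f"{prefix}{self.label}"


@dataclass(frozen=True)
class SyntacticPattern:
    """An ordered, alternating node/edge sequence with placeholder ends.

    ``anchor_free`` marks degenerate single-edge patterns (directly connected
    endpoints); such patterns carry no lexical evidence of causation and are
    surfaced to the reviewer as low-confidence.
    """

    elements: tuple[PatternElement, ...]
    source_sent_id: str = ""

    def __post_init__(self) -> None:
        elems = self.elements
        if len(elems) < 3 or len(elems) % 2 == 0:
            raise ValueError(
                "pattern must alternate node/edge with node ends "
                f"(got {len(elems)} elements)"
            )
        for pos, el in enumerate(elems):
            want_node = pos % 2 == 0
            if want_node and el.kind == "edge":
                raise ValueError(f"element {pos} must be a node, got edge")
            if not want_node and el.kind != "edge":
                raise ValueError(f"element {pos} must be an edge, got {el.kind}")
        ends = (elems[0], elems[-1])
        if not all(e.kind == "placeholder" for e in ends):
            raise ValueError("pattern ends must be placeholders")
        if elems[0].role == elems[-1].role:
            raise ValueError("end placeholders must have distinct roles")
        for el in elems[1:-1]:
            if el.kind == "placeholder":
                raise ValueError("placeholders only allowed at pattern ends")

    @property
    def text_form(self) -> str:
        return " : ".join(el.text for el in self.elements)

    @property
    def anchor_free(self) -> bool:
        return not any(el.kind == "anchor" for el in self.elements)

    def __str__(self) -> str:
        return self.text_form


@dataclass(frozen=True)
class DependencyPath:
    """Token-index path through a tree with per-step (label, direction)."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[str, Direction], ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edges) + 1:
            raise ValueError("path must have one more node than edges")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path revisits a node")


@dataclass(frozen=True)
class Capture:
    """A pattern match: phrase-expanded spans plus the raw path endpoints."""

    sentence: ParsedSentence
    symptom_span: Span
    etiology_span: Span
    symptom_head: int
    etiology_head: int
    pattern: SyntacticPattern

    @property
    def symptom_text(self) -> str:
        return self.sentence.span_text(self.symptom_span)

    @property
    def etiology_text(self) -> str:
        return self.sentence.span_text(self.etiology_span)


# ---------------------------------------------------------------------------
# Path finding and pattern generation
# ---------------------------------------------------------------------------

def shortest_dependency_path(
    sentence: ParsedSentence, a: int, b: int
) -> DependencyPath:
    """The unique undirected tree path from token ``a`` to token ``b``.

    Each step records the dependency label of the traversed edge and whether
    the walk moves ``up`` (dependent→head) or ``down`` (head→dependent).
    """
    if a == b:
        raise ValueError("path endpoints must differ")
    n = len(sentence)
    if not (1 <= a <= n and 1 <= b <= n):
        raise ValueError(f"endpoints {a},{b} out of bounds for n={n}")
    adjacency: dict[int, list[int]] = {i: [] for i in range(1, n + 1)}
    for tok in sentence.tokens:
        if tok.head != 0:
            adjacency[tok.index].append(tok.head)
            adjacency[tok.head].append(tok.index)
    prev: dict[int, int] = {a: 0}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        if cur == b:
            break
        for nxt in adjacency[cur]:
            if nxt not in prev:
                prev[nxt] = cur
                queue.append(nxt)
    nodes = [b]
    while nodes[-1] != a:
        nodes.append(prev[nodes[-1]])
    nodes.reverse()
    edges: list[tuple[str, Direction]] = []
    for u, v in zip(nodes, nodes[1:]):
        if sentence.token(u).head == v:
            edges.append((sentence.token(u).deprel, "up"))
        else:
            assert sentence.token(v).head == u
            edges.append((sentence.token(v).deprel, "down"))
    return DependencyPath(tuple(nodes), tuple(edges))


def _decorated_label(sentence: ParsedSentence, u: int, v: int) -> tuple[str, Direction]:
    """Edge label between adjacent tree nodes, with nmod case decoration."""
    if sentence.token(u).head == v:
        dep, direction = u, "up"
    else:
        dep, direction = v, "down"
    label = sentence.token(dep).deprel
    if label == "nmod":
        case = next(
            (c for c in sentence.children(dep) if c.deprel == "case"), None
        )
        if case is not None:
            label = f"nmod_{case.lemma.lower()}"
    return label, direction  # type: ignore[return-value]


def generate_pattern(
    sentence: ParsedSentence,
    symptom_span: Span,
    etiology_span: Span,
) -> SyntacticPattern:
    """Derive a linearized pattern from a matched sentence.

    The span heads become capture placeholders, interior path nodes become
    lemma anchors, and each traversed edge keeps its label and direction.
    Tokens off the path never enter the pattern.  Directly connected
    endpoints yield a degenerate anchor-free single-edge pattern: the lowest
    mutual ancestor of two adjacent tree nodes is one of the nodes
    themselves, so no interior anchor exists and the pattern is left for the
    reviewer to reject (it expresses no lexical causation cue).
    """
    a = head_of_span(sentence, symptom_span)
    b = head_of_span(sentence, etiology_span)
    path = shortest_dependency_path(sentence, a, b)
    elements: list[PatternElement] = [
        PatternElement(kind="placeholder", role="symptom")
    ]
    for u, v in zip(path.nodes, path.nodes[1:]):
        label, direction = _decorated_label(sentence, u, v)
        elements.append(PatternElement(kind="edge", label=label, direction=direction))
        if v != path.nodes[-1]:
            elements.append(
                PatternElement(kind="anchor", lemma=sentence.token(v).lemma.lower())
            )
    elements.append(PatternElement(kind="placeholder", role="etiology"))
    pattern = SyntacticPattern(tuple(elements), source_sent_id=sentence.sent_id)
    if pattern.anchor_free:
        logger.debug(
            "degenerate anchor-free pattern from %s: %s",
            sentence.sent_id,
            pattern.text_form,
        )
    return pattern


# ---------------------------------------------------------------------------
# Linearization round trip
# ---------------------------------------------------------------------------

def linearize(pattern: SyntacticPattern) -> str:
    """Canonical user-facing text form (``" : "``-separated elements)."""
    return pattern.text_form


def parse_pattern(text: str, source_sent_id: str = "") -> SyntacticPattern:
    """Parse a linearized pattern string back into a pattern object."""
    if not text.strip():
        raise PatternParseError("empty pattern string")
    parts = [p.strip() for p in text.split(":")]
    # placeholder brackets contain no ':', so a plain split is unambiguous
    elements: list[PatternElement] = []
    for pos, part in enumerate(parts):
        if not part:
            raise PatternParseError("empty element", pos)
        if part.startswith("[") and part.endswith("]"):
            role = _TEXT_ROLE.get(part)
            if role is None:
                raise PatternParseError(f"unknown placeholder {part!r}", pos)
            elements.append(PatternElement(kind="placeholder", role=role))
        elif part.startswith("lemm="):
            lemma = part[len("lemm=") :].strip()
            if not lemma:
                raise PatternParseError("empty anchor lemma", pos)
            elements.append(PatternElement(kind="anchor", lemma=lemma))
        elif part[0] in "<>":
            label = part[1:].strip()
            if not label:
                raise PatternParseError("empty edge label", pos)
            direction: Direction = "up" if part[0] == "<" else "down"
            elements.append(
                PatternElement(kind="edge", label=label, direction=direction)
            )
        else:
            raise PatternParseError(f"unrecognized element {part!r}", pos)
    try:
        return SyntacticPattern(tuple(elements), source_sent_id=source_sent_id)
    except ValueError as exc:
        raise PatternParseError(str(exc)) from exc


def load_patterns(path: str | Path) -> list[SyntacticPattern]:
    """Load a pattern file: one linearized pattern per line, ``#`` comments."""
    patterns = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_pattern(line))
    return patterns


def save_patterns(patterns: Iterable[SyntacticPattern], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{p.text_form}\n" for p in patterns), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def expand_phrase(
    sentence: ParsedSentence,
    idx: int,
    relations: frozenset[str] = DEFAULT_EXPANSION_RELATIONS,
) -> Span:
    """Maximal contiguous phrase span around ``idx``.

    Dependents whose relation is in the expansion set (plus case-less
    ``nmod``) are attached recursively; determiners and punctuation are never
    attached.  The returned span is then clipped to the contiguous run of
    attached tokens containing ``idx`` — expansion stops at a contiguity
    break.
    """
    if not (1 <= idx <= len(sentence)):
        raise ValueError(f"token index {idx} out of bounds")
    members = {idx}
    frontier = [idx]
    while frontier:
        cur = frontier.pop()
        for child in sentence.children(cur):
            if child.index in members:
                continue
            rel = child.deprel
            ok = rel in relations or (
                rel == "nmod"
                and not any(
                    c.deprel == "case" for c in sentence.children(child.index)
                )
            )
            if ok:
                members.add(child.index)
                frontier.append(child.index)
    lo = idx
    while lo - 1 in members:
        lo -= 1
    hi = idx
    while hi + 1 in members:
        hi += 1
    return (lo, hi)


def _edge_constraint(label: str) -> tuple[str, str | None]:
    """Split a possibly case-decorated label into (base relation, case lemma)."""
    if label.startswith("nmod_"):
        return "nmod", label[len("nmod_") :]
    return label, None


def _placeholder_ok(sentence: ParsedSentence, idx: int) -> bool:
    upos = sentence.token(idx).upos
    return upos in NOMINAL_POS or upos in ("", "_")


def _step(
    sentence: ParsedSentence, idx: int, edge: PatternElement
) -> list[int]:
    """Candidate next tokens reachable from ``idx`` under an edge constraint."""
    base, case_lemma = _edge_constraint(edge.label or "")

    def case_ok(dep_idx: int) -> bool:
        if case_lemma is None:
            return True
        return any(
            c.deprel == "case" and c.lemma.lower() == case_lemma
            for c in sentence.children(dep_idx)
        )

    if edge.direction == "up":
        tok = sentence.token(idx)
        if tok.head != 0 and tok.deprel == base and case_ok(idx):
            return [tok.head]
        return []
    return [
        c.index
        for c in sentence.children(idx)
        if c.deprel == base and case_ok(c.index)
    ]


def match(
    pattern: SyntacticPattern,
    sentence: ParsedSentence,
    expansion_relations: frozenset[str] = DEFAULT_EXPANSION_RELATIONS,
) -> list[Capture]:
    """All captures of ``pattern`` in ``sentence``.

    A capture exists per assignment of distinct sentence tokens to pattern
    nodes satisfying every edge constraint and anchor lemma
    (case-insensitive).  Placeholder tokens must be nominal when POS is
    available.  Matched endpoints are phrase-expanded; overlapping expansions
    and duplicate (symptom span, etiology span) pairs are dropped.
    """
    nodes = pattern.elements[0::2]
    edges = pattern.elements[1::2]

    def node_ok(el: PatternElement, idx: int) -> bool:
        if el.kind == "placeholder":
            return _placeholder_ok(sentence, idx)
        return sentence.token(idx).lemma.lower() == (el.lemma or "").lower()

    assignments: list[tuple[int, ...]] = []

    def extend(partial: tuple[int, ...]) -> None:
        depth = len(partial)
        if depth == len(nodes):
            assignments.append(partial)
            return
        if depth == 0:
            candidates: Iterable[int] = range(1, len(sentence) + 1)
        else:
            candidates = _step(sentence, partial[-1], edges[depth - 1])
        for idx in candidates:
            if idx in partial:
                continue
            if node_ok(nodes[depth], idx):
                extend(partial + (idx,))

    extend(())

    captures: list[Capture] = []
    seen: set[tuple[Span, Span]] = set()
    for assignment in assignments:
        s_head, e_head = assignment[0], assignment[-1]
        if pattern.elements[0].role == "etiology":
            s_head, e_head = e_head, s_head
        s_span = expand_phrase(sentence, s_head, expansion_relations)
        e_span = expand_phrase(sentence, e_head, expansion_relations)
        if not (s_span[1] < e_span[0] or e_span[1] < s_span[0]):
            continue
        key = (s_span, e_span)
        if key in seen:
            continue
        seen.add(key)
        captures.append(
            Capture(sentence, s_span, e_span, s_head, e_head, pattern)
        )
    captures.sort(key=lambda c: (c.symptom_span, c.etiology_span))
    return captures
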