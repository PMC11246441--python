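"""Pooled evaluation of etiology sources.

Reference sources for symptom etiologies are themselves incomplete, so
recall is measured IR-style: candidate etiologies from every source (plus a
reference assumed correct) are pooled under a shared name normalizer,
labelled supported/unsupported, and the full set of supported items becomes
the recall denominator for every source.  Per-symptom rows are combined by
unweighted macro averaging (F is averaged directly, not recomputed from
averaged R and P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .unify import fingerprint


@dataclass
class LabeledEtiology:
    """A pooled, normalized etiology with its label and contributing sources."""

    name: str
    label: str  # "supported" | "unsupported"
    sources: set[str]

    def __post_init__(self) -> None:
        if self.label not in ("supported", "unsupported"):
            raise ValueError(f"label must be supported/unsupported, got {self.label!r}")
        if not self.sources:
            raise ValueError("sources must be non-empty")


@dataclass
class MetricsRow:
    """Recall, precision and F-score as percentages in [0, 100].

    ``undefined_precision`` flags a source with zero items, whose precision
    is reported as 0 by convention.
    """

    recall: float
    precision: float
    f_score: float
    undefined_precision: bool = False

    @classmethod
    def from_rp(cls, recall: float, precision: float, **kwargs) -> "MetricsRow":
        if recall > 0 and precision > 0:
            f = 2 * recall * precision / (recall + precision)
        else:
            f = 0.0
        return cls(recall, precision, f, **kwargs)


def pool(
    per_source: Mapping[str, Sequence[str]],
    labels: Mapping[str, str] | None = None,
    normalizer: Callable[[str], str] = fingerprint,
    reference_source: str = "reference",
) -> list[LabeledEtiology]:
    """Pool names from all sources under a shared normalizer.

    Names collapsing to the same normalized form become one item recording
    every contributing source.  Items contributed by the reference source
    are auto-labelled supported; other items take their label from
    ``labels`` (keyed by any surface form), defaulting to unsupported.
    A label entry matching no pooled item is an error listing the unmatched
    names.
    """
    by_key: dict[str, LabeledEtiology] = {}
    order: list[str] = []
    for source, names in per_source.items():
        for name in names:
            key = normalizer(name)
            if key not in by_key:
                by_key[key] = LabeledEtiology(name, "unsupported", {source})
                order.append(key)
            else:
                by_key[key].sources.add(source)
    if labels:
        unmatched = [name for name in labels if normalizer(name) not in by_key]
        if unmatched:
            raise KeyError(
                f"label file references unknown names: {sorted(unmatched)}"
            )
        for name, label in labels.items():
            by_key[normalizer(name)].label = label
    for item in by_key.values():
        if reference_source in item.sources:
            item.label = "supported"
    return [by_key[key] for key in order]


def prf(
    source: str | Iterable[str], pooled: Sequence[LabeledEtiology]
) -> MetricsRow:
    """Recall/precision/F for one source (or the union of several).

    Gold = all supported pooled items.  Recall = supported items from this
    source / gold; precision = supported items from this source / all items
    from this source.  A source with zero pooled items gets precision 0 with
    the ``undefined_precision`` flag set.
    """
    if not pooled:
        raise ValueError("pooled list must be non-empty")
    sources = {source} if isinstance(source, str) else set(source)
    gold = [it for it in pooled if it.label == "supported"]
    mine = [it for it in pooled if it.sources & sources]
    mine_supported = [it for it in mine if it.label == "supported"]
    recall = 100.0 * len(mine_supported) / len(gold) if gold else 0.0
    if not mine:
        return MetricsRow.from_rp(recall, 0.0, undefined_precision=True)
    precision = 100.0 * len(mine_supported) / len(mine)
    return MetricsRow.from_rp(recall, precision)


def macro_average(rows: Sequence[MetricsRow]) -> MetricsRow:
    """Unweighted per-component mean; F is averaged, not recomputed."""
    if not rows:
        raise ValueError("cannot macro-average zero rows")
    n = len(rows)
    return MetricsRow(
        recall=sum(r.recall for r in rows) / n,
        precision=sum(r.precision for r in rows) / n,
        f_score=sum(r.f_score for r in rows) / n,
    )


def overlap_counts(
    pooled: Sequence[LabeledEtiology],
) -> dict[frozenset[str], int]:
    """Partition supported items into the regions of the ≤3-set diagram.

    Keys are frozensets of source names (every non-empty subset of the
    observed sources); values sum to the number of supported items.
    """
    supported = [it for it in pooled if it.label == "supported"]
    all_sources = sorted({s for it in supported for s in it.sources})
    if len(all_sources) > 3:
        raise ValueError(
            f"overlap diagram supports at most 3 sources, got {all_sources}"
        )
    counts: dict[frozenset[str], int] = {}
    # enumerate all non-empty subsets so empty regions are reported as 0
    for mask in range(1, 2 ** len(all_sources)):
        subset = frozenset(
            s for bit, s in enumerate(all_sources) if mask >> bit & 1
        )
        counts[subset] = 0
    for item in supported:
        counts[frozenset(item.sources)] += 1
    return counts


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa from the 2x2 contingency table of two binary label lists.

    Returns 1.0 when chance agreement is 1 and the annotators agree (both
    constant with the same label).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise ValueError("label lists must be non-empty")
    n = len(labels_a)
    categories = sorted(set(labels_a) | set(labels_b), key=repr)
    observed = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    expected = sum(
        (list(labels_a).count(c) / n) * (list(labels_b).count(c) / n)
        for c in categories
    )
    if expected == 1.0:
        return 1.0 if observed == 1.0 else 0.0
    return (observed - expected) / (1.0 - expected)
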