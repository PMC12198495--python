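"""Precision / recall / F1 for BIO tagging, token-level and entity-level.

Token-level micro metrics pool TP/FP/FN over every token of every sentence:
a token is a true positive when the predicted tag equals a non-O gold tag,
a false positive when a non-O tag is predicted incorrectly, and a false
negative when a non-O gold tag is missed — so substituting one entity tag
for another counts as both FP and FN, which is why a model with balanced
errors shows identical precision and recall.

Entity-level metrics use exact span matching in the CoNLL tradition: a
predicted entity counts only if its (start, end, class) triple exactly
matches a gold entity.  Span extraction is lenient toward orphan ``I-c``
tags (an ``I-c`` with no compatible predecessor opens a new span), so any
tag sequence — including raw model output — has a well-defined span set.

Both modes use the zero-denominator convention P (or R) = 0, and F1 = 0
when P + R = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import OUTSIDE_TAG, _TAG_RE

TagSeq = Sequence[str]


@dataclass
class ConfusionCounts:
    """Additive TP/FP/FN tallies."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class MetricsReport:
    """Micro P/R/F1 plus per-class breakdown for one counting mode."""

    precision: float
    recall: float
    f1: float
    mode: str  # "token" | "entity"
    counts: ConfusionCounts
    per_class: dict[str, ConfusionCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "per_class": {
                c: {
                    "precision": cc.precision,
                    "recall": cc.recall,
                    "f1": cc.f1,
                    "tp": cc.tp,
                    "fp": cc.fp,
                    "fn": cc.fn,
                }
                for c, cc in sorted(self.per_class.items())
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def format_table(self) -> str:
        lines = [
            f"{self.mode}-level micro metrics",
            f"{'':12s} {'P':>8s} {'R':>8s} {'F1':>8s} {'TP':>6s} {'FP':>6s} {'FN':>6s}",
            f"{'overall':12s} {self.precision:8.4f} {self.recall:8.4f} "
            f"{self.f1:8.4f} {self.counts.tp:6d} {self.counts.fp:6d} "
            f"{self.counts.fn:6d}",
        ]
        for c, cc in sorted(self.per_class.items()):
            lines.append(
                f"{c:12s} {cc.precision:8.4f} {cc.recall:8.4f} {cc.f1:8.4f} "
                f"{cc.tp:6d} {cc.fp:6d} {cc.fn:6d}"
            )
        return "\n".join(lines)


def _check_aligned(gold: Sequence[TagSeq], pred: Sequence[TagSeq]) -> None:
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold sentences vs {len(pred)} predicted")
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(
                f"sentence {i}: gold has {len(g)} tags but prediction has {len(p)}"
            )


def _report(
    counts: ConfusionCounts, per_class: dict[str, ConfusionCounts], mode: str
) -> MetricsReport:
    return MetricsReport(
        precision=counts.precision,
        recall=counts.recall,
        f1=counts.f1,
        mode=mode,
        counts=counts,
        per_class=per_class,
    )


def token_micro_metrics(
    gold: Sequence[TagSeq], pred: Sequence[TagSeq]
) -> MetricsReport:
    """Micro-averaged token-level P/R/F1 pooled over sentences and classes."""
    _check_aligned(gold, pred)
    total = ConfusionCounts()
    per_class: dict[str, ConfusionCounts] = {}

    def cls_counts(tag: str) -> ConfusionCounts:
        return per_class.setdefault(tag[2:], ConfusionCounts())

    for g_sent, p_sent in zip(gold, pred):
        for g, p in zip(g_sent, p_sent):
            if g != OUTSIDE_TAG and p == g:
                total.tp += 1
                cls_counts(g).tp += 1
                continue
            if p != OUTSIDE_TAG and p != g:
                total.fp += 1
                cls_counts(p).fp += 1
            if g != OUTSIDE_TAG and p != g:
                total.fn += 1
                cls_counts(g).fn += 1
    return _report(total, per_class, "token")


def entity_spans(tags: TagSeq) -> list[tuple[int, int, str]]:
    """Maximal entity runs as 0-based half-open (start, end, class) spans.

    An ``I-c`` without a preceding ``B-c``/``I-c`` of the same class starts
    a new span (lenient reading).  Unknown tag strings raise ``ValueError``.
    """
    spans: list[tuple[int, int, str]] = []
    start: int | None = None
    cur: str | None = None
    for i, tag in enumerate(tags):
        if not _TAG_RE.match(tag):
            raise ValueError(f"position {i}: {tag!r} is not a BIO tag")
        if tag == OUTSIDE_TAG:
            if cur is not None:
                spans.append((start, i, cur))  # type: ignore[arg-type]
                start = cur = None
            continue
        kind, cls = tag[0], tag[2:]
        if kind == "B" or cur != cls:
            if cur is not None:
                spans.append((start, i, cur))  # type: ignore[arg-type]
            start, cur = i, cls
    if cur is not None:
        spans.append((start, len(tags), cur))  # type: ignore[arg-type]
    return spans


def entity_level_metrics(
    gold: Sequence[TagSeq], pred: Sequence[TagSeq]
) -> MetricsReport:
    """Exact-span-match P/R/F1 pooled over sentences and classes."""
    _check_aligned(gold, pred)
    total = ConfusionCounts()
    per_class: dict[str, ConfusionCounts] = {}
    for g_sent, p_sent in zip(gold, pred):
        g_spans = set(entity_spans(g_sent))
        p_spans = set(entity_spans(p_sent))
        for span in p_spans & g_spans:
            total.tp += 1
            per_class.setdefault(span[2], ConfusionCounts()).tp += 1
        for span in p_spans - g_spans:
            total.fp += 1
            per_class.setdefault(span[2], ConfusionCounts()).fp += 1
        for span in g_spans - p_spans:
            total.fn += 1
            per_class.setdefault(span[2], ConfusionCounts()).fn += 1
    return _report(total, per_class, "entity")
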