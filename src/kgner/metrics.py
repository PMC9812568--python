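"""Precision / recall / F1, entity-level and per-label token-level.

Entity-level scoring uses exact-span matching (start, end, category all
equal), the BioCreative/NCBI convention; counts are micro-aggregated across
sentences. Token-level mode scores each BIO role (B, I, O) one-vs-rest,
which is the only reading under which an "O" F1 is defined. Percentages are
rounded half-up to two decimals at rendering only; aggregation across seeds
uses full precision with the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .corpus import Span, parse_tag, spans_from_bio, validate_bio

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "MixedModesError",
    "aggregate_runs",
    "confusion_entity",
    "entity_metrics",
    "format_percent",
    "per_label_token_metrics",
    "prf",
]


class MixedModesError(ValueError):
    """Aggregating reports computed under different modes."""


@dataclass
class ConfusionCounts:
    """Exact-match confusion counts (no TN at entity level)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricReport:
    """Precision/recall/F1 in [0, 1], plus optional breakdowns.

    ``zero_division`` flags metrics whose denominator was zero (reported as
    0). When produced by :func:`aggregate_runs`, the ``*_sd`` fields carry
    sample standard deviations across runs.
    """

    precision: float
    recall: float
    f1: float
    mode: str = "entity"
    per_label: dict = field(default_factory=dict)
    zero_division: bool = False
    precision_sd: float | None = None
    recall_sd: float | None = None
    f1_sd: float | None = None

    def as_percent(self) -> dict[str, str]:
        return {
            "precision": format_percent(self.precision),
            "recall": format_percent(self.recall),
            "f1": format_percent(self.f1),
        }


def format_percent(x: float) -> str:
    """Render a [0, 1] metric as a percentage, half-up to 2 decimals."""
    return str(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_entity(gold: list[Span], pred: list[Span]) -> ConfusionCounts:
    """TP/FP/FN under exact (start, end, category) span equality."""
    g, p = set(gold), set(pred)
    tp = len(g & p)
    return ConfusionCounts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)


def prf(counts: ConfusionCounts, mode: str = "entity") -> MetricReport:
    """Precision, recall and their harmonic mean from confusion counts.

    Zero denominators yield metric 0 with the ``zero_division`` flag set
    rather than an error, so seed-level aggregation stays robust.
    """
    flag = False
    if counts.tp + counts.fp == 0:
        precision, flag = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, flag = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(precision=precision, recall=recall, f1=f1, mode=mode, zero_division=flag)


def entity_metrics(
    gold: list[list[str]], pred: list[list[str]], repair: bool = True
) -> MetricReport:
    """Micro-averaged exact-span entity metrics over aligned label sequences."""
    total = ConfusionCounts()
    for g, p in zip(gold, pred, strict=True):
        gs = spans_from_bio(validate_bio(g, repair=repair))
        ps = spans_from_bio(validate_bio(p, repair=repair))
        total = total + confusion_entity(gs, ps)
    return prf(total, mode="entity")


def per_label_token_metrics(gold: list[str], pred: list[str]) -> MetricReport:
    """One-vs-rest token metrics for each BIO role (B, I, O).

    The top-level precision/recall/f1 are unweighted (macro) means over the
    roles present in gold or pred; the per-role reports sit in
    ``per_label``.
    """
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    g_roles = [parse_tag(t)[0] for t in gold]
    p_roles = [parse_tag(t)[0] for t in pred]
    per_label: dict[str, MetricReport] = {}
    for role in ("B", "I", "O"):
        if role not in g_roles and role not in p_roles:
            continue
        tp = sum(1 for g, p in zip(g_roles, p_roles) if g == role and p == role)
        fp = sum(1 for g, p in zip(g_roles, p_roles) if g != role and p == role)
        fn = sum(1 for g, p in zip(g_roles, p_roles) if g == role and p != role)
        per_label[role] = prf(ConfusionCounts(tp, fp, fn), mode="token-per-label")
    macro = {
        m: float(np.mean([getattr(r, m) for r in per_label.values()]))
        for m in ("precision", "recall", "f1")
    }
    return MetricReport(
        precision=macro["precision"],
        recall=macro["recall"],
        f1=macro["f1"],
        mode="token-per-label",
        per_label=per_label,
        zero_division=any(r.zero_division for r in per_label.values()),
    )


def aggregate_runs(reports: list[MetricReport]) -> MetricReport:
    """Mean and sample standard deviation (n-1) across >= 2 runs."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to aggregate")
    modes = {r.mode for r in reports}
    if len(modes) != 1:
        raise MixedModesError(f"mixed report modes: {sorted(modes)}")
    vals = {m: np.array([getattr(r, m) for r in reports]) for m in ("precision", "recall", "f1")}
    return MetricReport(
        precision=float(vals["precision"].mean()),
        recall=float(vals["recall"].mean()),
        f1=float(vals["f1"].mean()),
        mode=modes.pop(),
        precision_sd=float(vals["precision"].std(ddof=1)),
        recall_sd=float(vals["recall"].std(ddof=1)),
        f1_sd=float(vals["f1"].std(ddof=1)),
    )
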