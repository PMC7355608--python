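"""Example-based multi-label metrics and per-label breakdowns.

For a dataset of truth/prediction set pairs (l_i, z_i), i = 1..N:

* accuracy  = mean_i |l_i ∩ z_i| / |l_i ∪ z_i|        (Jaccard)
* precision = mean_i |l_i ∩ z_i| / |z_i|
* recall    = mean_i |l_i ∩ z_i| / |l_i|
* F1        = 2 * precision * recall / (precision + recall)

F1 is the harmonic mean of the *aggregate* precision and recall, not a mean
of per-example F1 values. All metrics are reported as percentages in
[0, 100].

Per-label metrics count proteins: recall_L is the fraction of proteins
carrying L in truth that also carry L in the prediction; precision_L the
fraction of proteins predicted with L that truly carry it. The
average-correct-rate metric used by the domain-content baseline is the mean
of |l_i ∩ z_i| / |z_i| over the proteins whose truth contains the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .taxonomy import LABELS, Label, LabelSet

__all__ = [
    "OverallMetrics",
    "PerLabelMetrics",
    "MetricsReport",
    "f1_from_pr",
    "overall_metrics",
    "per_label_metrics",
    "evaluate",
    "avg_correct_rate",
]


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of aggregate precision and recall (same units in/out)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class OverallMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class PerLabelMetrics:
    precision: float
    recall: float
    f1: float
    support: int           # proteins carrying the label in truth
    n_predicted: int       # proteins carrying the label in the prediction
    undefined: bool = False  # a zero-denominator ratio was reported as 0

    def as_dict(self) -> dict[str, float | int | bool]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "n_predicted": self.n_predicted,
            "undefined": self.undefined,
        }


@dataclass(frozen=True)
class MetricsReport:
    overall: OverallMetrics
    per_label: dict[Label, PerLabelMetrics]

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "per_label": {l.short: m.as_dict() for l, m in self.per_label.items()},
        }


def _check_keys(truth: Mapping[str, LabelSet], pred: Mapping[str, LabelSet]) -> None:
    if set(truth) != set(pred):
        only_t = sorted(set(truth) - set(pred))[:5]
        only_p = sorted(set(pred) - set(truth))[:5]
        raise ValueError(
            f"truth and prediction must cover the same proteins "
            f"(only in truth: {only_t}, only in prediction: {only_p})"
        )
    if not truth:
        raise ValueError("cannot evaluate an empty dataset")


def overall_metrics(
    truth: Mapping[str, LabelSet], pred: Mapping[str, LabelSet]
) -> OverallMetrics:
    """Example-based accuracy/precision/recall/F1 as percentages."""
    _check_keys(truth, pred)
    n = len(truth)
    acc = prec = rec = 0.0
    for pid, l in truth.items():
        z = pred[pid]
        inter = len(l.labels & z.labels)
        acc += inter / len(l.labels | z.labels)
        prec += inter / len(z)
        rec += inter / len(l)
    acc, prec, rec = (100.0 * v / n for v in (acc, prec, rec))
    return OverallMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1_from_pr(prec, rec))


def per_label_metrics(
    truth: Mapping[str, LabelSet], pred: Mapping[str, LabelSet]
) -> dict[Label, PerLabelMetrics]:
    """Protein-count precision/recall/F1 for each of the nine labels."""
    _check_keys(truth, pred)
    out: dict[Label, PerLabelMetrics] = {}
    for label in LABELS:
        support = sum(1 for l in truth.values() if label in l)
        n_pred = sum(1 for z in pred.values() if label in z)
        tp = sum(1 for pid, l in truth.items() if label in l and label in pred[pid])
        undefined = support == 0 or n_pred == 0
        recall = 100.0 * tp / support if support else 0.0
        precision = 100.0 * tp / n_pred if n_pred else 0.0
        out[label] = PerLabelMetrics(
            precision=precision,
            recall=recall,
            f1=f1_from_pr(precision, recall),
            support=support,
            n_predicted=n_pred,
            undefined=undefined,
        )
    return out


def evaluate(truth: Mapping[str, LabelSet], pred: Mapping[str, LabelSet]) -> MetricsReport:
    """Overall plus per-label metrics in one report."""
    return MetricsReport(
        overall=overall_metrics(truth, pred),
        per_label=per_label_metrics(truth, pred),
    )


def avg_correct_rate(
    truth: Mapping[str, LabelSet], pred: Mapping[str, LabelSet], label: Label
) -> float:
    """Mean correct-prediction rate over proteins whose truth carries *label*.

    The rate for one protein is the number of correctly predicted labels
    divided by the number of all predicted labels, |l ∩ z| / |z|, reported
    as a percentage.
    """
    _check_keys(truth, pred)
    rates = [
        len(l.labels & pred[pid].labels) / len(pred[pid])
        for pid, l in truth.items()
        if label in l
    ]
    if not rates:
        raise ValueError(f"label {label.short} has zero support in the truth annotations")
    return 100.0 * sum(rates) / len(rates)
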