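"""Label-shuffling null baseline and significance-comparison protocols.

The null predictor permutes the true label sets across proteins, preserving
the dataset's label multiset and cardinality distribution. Repeating the
shuffle gives per-metric means, standard deviations and a two-sided 99.9%
interval over the repetitions; a method is judged better/worse than random
when its metric falls above/below that interval. Under a uniform
permutation the expected per-label recall and precision equal the label's
prevalence, 100 * n_L / N, which serves as the closed-form check on the
simulation.

Method-vs-method comparison repeatedly evaluates both methods on the same
random half of the proteins and applies a paired t-test across the splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .metrics import evaluate, overall_metrics, per_label_metrics
from .taxonomy import LABELS, Label, LabelSet

__all__ = [
    "Z_999",
    "MetricStats",
    "ShuffleBaselineResult",
    "shuffle_baseline",
    "analytic_random_per_label",
    "MetricComparison",
    "ComparisonResult",
    "compare_methods",
    "compare_to_random",
]

#: two-sided z quantile for a 99.9% interval
Z_999 = float(stats.norm.ppf(1 - 0.001 / 2))

OVERALL_METRIC_NAMES = ("accuracy", "precision", "recall", "f1")
PER_LABEL_METRIC_NAMES = ("precision", "recall", "f1")

Verdict = Literal["+", "-", "="]


@dataclass(frozen=True)
class MetricStats:
    """Mean, spread and 99.9% interval of one metric over repetitions.

    ``ci_low``/``ci_high`` bracket the per-repetition distribution
    (mean ± z * sd); ``se`` is the standard error of the mean, kept for
    convergence checks against closed-form expectations.
    """

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    se: float

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "MetricStats":
        mean = float(np.mean(samples))
        sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else 0.0
        half = Z_999 * sd
        return cls(
            mean=mean,
            sd=sd,
            ci_low=mean - half,
            ci_high=mean + half,
            se=sd / np.sqrt(len(samples)) if len(samples) else 0.0,
        )

    def verdict_for(self, value: float) -> Verdict:
        """Is *value* above (+), below (-) or inside (=) the interval?"""
        if value > self.ci_high:
            return "+"
        if value < self.ci_low:
            return "-"
        return "="


@dataclass(frozen=True)
class ShuffleBaselineResult:
    reps: int
    seed: int
    overall: dict[str, MetricStats]
    per_label: dict[Label, dict[str, MetricStats]]

    def as_dict(self) -> dict:
        return {
            "reps": self.reps,
            "seed": self.seed,
            "overall": {k: vars(v) for k, v in self.overall.items()},
            "per_label": {
                l.short: {k: vars(v) for k, v in m.items()} for l, m in self.per_label.items()
            },
        }


def shuffle_baseline(
    truth: Mapping[str, LabelSet],
    reps: int = 1000,
    seed: int = 0,
) -> ShuffleBaselineResult:
    """Evaluate the label-shuffling null predictor over ``reps`` permutations.

    Each repetition assigns a uniform random permutation of the truth label
    sets back to the proteins as the prediction and evaluates all metrics.
    Deterministic given ``seed``.
    """
    if len(truth) < 2:
        raise ValueError("the shuffle baseline needs at least 2 proteins")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(truth)
    sets = [truth[pid] for pid in ids]

    overall_samples = {name: np.empty(reps) for name in OVERALL_METRIC_NAMES}
    per_label_samples = {
        label: {name: np.empty(reps) for name in PER_LABEL_METRIC_NAMES} for label in LABELS
    }
    for r in range(reps):
        perm = rng.permutation(len(ids))
        pred = {ids[i]: sets[perm[i]] for i in range(len(ids))}
        ov = overall_metrics(truth, pred)
        for name in OVERALL_METRIC_NAMES:
            overall_samples[name][r] = getattr(ov, name)
        pl = per_label_metrics(truth, pred)
        for label in LABELS:
            for name in PER_LABEL_METRIC_NAMES:
                per_label_samples[label][name][r] = getattr(pl[label], name)

    return ShuffleBaselineResult(
        reps=reps,
        seed=seed,
        overall={k: MetricStats.from_samples(v) for k, v in overall_samples.items()},
        per_label={
            label: {k: MetricStats.from_samples(v) for k, v in m.items()}
            for label, m in per_label_samples.items()
        },
    )


def analytic_random_per_label(n_label: int, n_total: int) -> float:
    """Closed-form shuffle expectation of per-label recall/precision.

    Under a uniform permutation the probability that any protein receives a
    label set containing L is the prevalence n_L / N, so the expected
    per-label recall and precision are both 100 * n_L / N.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_label <= n_total:
        raise ValueError("need 0 <= n_label <= n_total")
    return 100.0 * n_label / n_total


# ---------------------------------------------------------------------------
# method-vs-method comparison on repeated random half-subsets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricComparison:
    mean_a: float
    mean_b: float
    mean_diff: float  # a - b
    t_stat: float
    p_value: float
    verdict: Verdict  # '+': a better, '-': a worse, '=': not significant
    zero_variance: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    method_a: str
    method_b: str
    n_splits: int
    frac: float
    alpha: float
    seed: int
    metrics: dict[str, MetricComparison]

    def as_dict(self) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "n_splits": self.n_splits,
            "frac": self.frac,
            "alpha": self.alpha,
            "seed": self.seed,
            "metrics": {k: vars(v) for k, v in self.metrics.items()},
        }


def compare_methods(
    truth: Mapping[str, LabelSet],
    pred_a: Mapping[str, LabelSet],
    pred_b: Mapping[str, LabelSet],
    n_splits: int = 100,
    frac: float = 0.5,
    alpha: float = 0.001,
    seed: int = 0,
    method_a: str = "A",
    method_b: str = "B",
) -> ComparisonResult:
    """Paired comparison of two predictions over random protein subsets.

    Each of ``n_splits`` tests draws ``floor(frac * N)`` proteins without
    replacement (no stratification), evaluates both methods on the same
    subset, and the per-metric differences are tested with a two-sided
    paired t-test. Verdicts: '+'/'-' for a significant difference in favour
    of method A/B, '=' otherwise; all-identical differences give p = 1 with
    a zero-variance flag.
    """
    if set(truth) != set(pred_a) or set(truth) != set(pred_b):
        raise ValueError("truth, pred_a and pred_b must cover the same proteins")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    ids = np.array(sorted(truth))
    k = int(np.floor(frac * len(ids)))
    if k < 1:
        raise ValueError("frac * |D| must select at least one protein")
    rng = np.random.default_rng(seed)

    samples = {name: (np.empty(n_splits), np.empty(n_splits)) for name in OVERALL_METRIC_NAMES}
    for s in range(n_splits):
        subset = rng.choice(ids, size=k, replace=False)
        sub_truth = {pid: truth[pid] for pid in subset}
        ov_a = overall_metrics(sub_truth, {pid: pred_a[pid] for pid in subset})
        ov_b = overall_metrics(sub_truth, {pid: pred_b[pid] for pid in subset})
        for name in OVERALL_METRIC_NAMES:
            samples[name][0][s] = getattr(ov_a, name)
            samples[name][1][s] = getattr(ov_b, name)

    metrics: dict[str, MetricComparison] = {}
    for name, (a, b) in samples.items():
        diff = a - b
        zero_var = bool(np.allclose(diff, diff[0]))
        if zero_var and np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        elif zero_var:
            # constant non-zero difference: no within-sample variance, treat
            # as non-assessable by the t-test
            t_stat, p = float("inf") if diff[0] > 0 else float("-inf"), 1.0
        else:
            t_stat, p = stats.ttest_rel(a, b)
            t_stat, p = float(t_stat), float(p)
        if p < alpha:
            verdict: Verdict = "+" if diff.mean() > 0 else "-"
        else:
            verdict = "="
        metrics[name] = MetricComparison(
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            mean_diff=float(diff.mean()),
            t_stat=t_stat,
            p_value=p,
            verdict=verdict,
            zero_variance=zero_var,
        )
    return ComparisonResult(
        method_a=method_a,
        method_b=method_b,
        n_splits=n_splits,
        frac=frac,
        alpha=alpha,
        seed=seed,
        metrics=metrics,
    )


def compare_to_random(
    truth: Mapping[str, LabelSet],
    pred: Mapping[str, LabelSet],
    reps: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """Verdicts of a method against the shuffle baseline's 99.9% interval.

    Returns ``{"overall": {metric: verdict}, "per_label": {Label: {metric:
    verdict}}, "baseline": ShuffleBaselineResult}``.
    """
    baseline = shuffle_baseline(truth, reps=reps, seed=seed)
    report = evaluate(truth, pred)
    overall_verdicts = {
        name: baseline.overall[name].verdict_for(getattr(report.overall, name))
        for name in OVERALL_METRIC_NAMES
    }
    per_label_verdicts = {
        label: {
            name: baseline.per_label[label][name].verdict_for(
                getattr(report.per_label[label], name)
            )
            for name in PER_LABEL_METRIC_NAMES
        }
        for label in LABELS
    }
    return {
        "overall": overall_verdicts,
        "per_label": per_label_verdicts,
        "baseline": baseline,
    }
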