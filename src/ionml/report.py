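"""Render metric reports as aligned text tables or JSON.

The layout follows the field's convention for benchmark tables: one row per
(label, measure) pair, one column per method, with verdict superscripts
appended to each cell — first the verdict against the shuffle-null
predictor, then the verdict against the reference method.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

from .baselines import ComparisonResult, ShuffleBaselineResult
from .metrics import MetricsReport
from .taxonomy import LABELS, Label

__all__ = ["report_payload", "render_report"]

_OVERALL_ROW = "overall"
_MEASURES = ("f1", "accuracy", "precision", "recall")
_PER_LABEL_MEASURES = ("f1", "precision", "recall")


def _annotate(value: str, verdicts: Sequence[str]) -> str:
    if not verdicts:
        return value
    return f"{value} ^{'/'.join(verdicts)}^"


def report_payload(
    reports: Mapping[str, MetricsReport],
    random_baseline: ShuffleBaselineResult | None = None,
    comparisons: Mapping[str, ComparisonResult] | None = None,
    random_verdicts: Mapping[str, Mapping[str, object]] | None = None,
) -> dict:
    """Machine-readable report: nested {row -> measure -> method -> cell}."""
    methods = list(reports)
    rows: dict[str, dict[str, dict[str, object]]] = {}

    def cell(method: str, row: str, measure: str) -> dict[str, object]:
        rep = reports[method]
        if row == _OVERALL_ROW:
            value = getattr(rep.overall, measure)
        else:
            label = _label_by_short(row)
            value = getattr(rep.per_label[label], measure)
        verdicts: list[str] = []
        if random_verdicts and method in random_verdicts:
            rv = random_verdicts[method]
            if row == _OVERALL_ROW:
                verdicts.append(str(rv["overall"][measure]))  # type: ignore[index]
            else:
                verdicts.append(str(rv["per_label"][_label_by_short(row)][measure]))  # type: ignore[index]
        if comparisons and method in comparisons and row == _OVERALL_ROW:
            verdicts.append(comparisons[method].metrics[measure].verdict)
        return {"value": value, "verdicts": verdicts}

    row_names = [_OVERALL_ROW] + [l.short for l in LABELS]
    for row in row_names:
        measures = _MEASURES if row == _OVERALL_ROW else _PER_LABEL_MEASURES
        rows[row] = {
            measure: {m: cell(m, row, measure) for m in methods} for measure in measures
        }
    payload: dict = {"methods": methods, "rows": rows}
    if random_baseline is not None:
        payload["random"] = {
            _OVERALL_ROW: {k: v.mean for k, v in random_baseline.overall.items()},
            **{
                l.short: {k: v.mean for k, v in random_baseline.per_label[l].items()}
                for l in LABELS
            },
        }
    return payload


def _label_by_short(short: str) -> Label:
    for l in LABELS:
        if l.short == short:
            return l
    raise KeyError(short)


def render_report(payload: Mapping, fmt: str = "text") -> str:
    """Render a :func:`report_payload` dict as aligned text or JSON."""
    if fmt == "json":
        return json.dumps(payload, indent=1)
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    methods: list[str] = list(payload["methods"])
    has_random = "random" in payload
    columns = ["label", "measure"] + (["random"] if has_random else []) + methods
    lines: list[list[str]] = [columns]
    for row_name, measures in payload["rows"].items():
        for measure, per_method in measures.items():
            line = [row_name, measure]
            if has_random:
                rnd = payload["random"].get(row_name, {}).get(measure)
                line.append("NA" if rnd is None else f"{rnd:.1f}")
            for method in methods:
                c = per_method.get(method)
                if c is None:
                    line.append("NA")
                else:
                    line.append(_annotate(f"{c['value']:.1f}", c.get("verdicts", [])))
            lines.append(line)
    widths = [max(len(row[i]) for row in lines) for i in range(len(columns))]
    out = []
    for i, row in enumerate(lines):
        out.append("  ".join(f"{v:<{w}}" for v, w in zip(row, widths)).rstrip())
        if i == 0:
            out.append("  ".join("-" * w for w in widths))
    return "\n".join(out) + "\n"
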