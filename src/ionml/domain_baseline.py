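"""Domain-content baseline: annotation transfer via shared Pfam accessions.

For each of the eight channel labels, the training domain set is the union
of the domain accessions of the training proteins carrying that label. A
test protein is predicted with every label whose training set intersects its
own domains; proteins with no domains, or with domains unseen in any
training set, are predicted non-ion. The rule can fire across gating types,
so its outputs use the relaxed label-set type.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .taxonomy import (
    BenchmarkDataset,
    CHANNEL_LABELS,
    LABELS,
    Label,
    LabelSet,
    ProteinRecord,
)

__all__ = [
    "DomainModel",
    "fit_domain_model",
    "domain_predict",
    "domain_predict_dataset",
    "domain_coverage",
    "coverage_average",
    "read_domains",
    "write_domains",
    "attach_domains",
]


@dataclass(frozen=True)
class DomainModel:
    """Per-channel-label training domain sets (non-ion has none)."""

    domain_sets: dict[Label, frozenset[str]]
    trained_on: str = ""

    def __post_init__(self) -> None:
        if set(self.domain_sets) != set(CHANNEL_LABELS):
            raise ValueError("domain_sets must have exactly the eight channel labels as keys")


def fit_domain_model(train: BenchmarkDataset) -> DomainModel:
    """Union the domains of the training proteins of each channel label.

    Labels with no training proteins (or only domain-free ones) get an empty
    set with a warning rather than an error.
    """
    truth = train.truth_map()
    domains = train.domains_map()
    sets: dict[Label, set[str]] = {l: set() for l in CHANNEL_LABELS}
    for pid, ls in truth.items():
        for label in ls:
            if label.is_channel:
                sets[label] |= domains[pid]
    for label, s in sets.items():
        if not s:
            warnings.warn(
                f"no training domains for label {label.short}; its set is empty",
                stacklevel=2,
            )
    return DomainModel(
        domain_sets={l: frozenset(s) for l, s in sets.items()},
        trained_on=train.provenance or f"{len(train)} training proteins",
    )


def domain_predict(model: DomainModel, record: ProteinRecord) -> LabelSet:
    """Predict a (possibly mixed-gating) label set from shared domains."""
    if record.domains is None:
        raise ValueError(f"record {record.id!r} has no domain annotation field")
    hits = frozenset(
        label for label in CHANNEL_LABELS if record.domains & model.domain_sets[label]
    )
    if not hits:
        return LabelSet.non_ion()
    return LabelSet(hits, relaxed=True)


def domain_predict_dataset(model: DomainModel, dataset: BenchmarkDataset) -> dict[str, LabelSet]:
    return {rec.id: domain_predict(model, rec) for rec in dataset}


def domain_coverage(dataset: BenchmarkDataset) -> dict[Label, float]:
    """Per-label percentage of proteins annotated with at least one domain.

    Labels with zero support are excluded (with a warning) rather than
    reported as 0.
    """
    truth = dataset.truth_map()
    domains = dataset.domains_map()
    out: dict[Label, float] = {}
    for label in LABELS:
        carriers = [pid for pid, ls in truth.items() if label in ls]
        if not carriers:
            warnings.warn(f"label {label.short} has no proteins; excluded from coverage", stacklevel=2)
            continue
        with_domain = sum(1 for pid in carriers if domains[pid])
        out[label] = 100.0 * with_domain / len(carriers)
    return out


def coverage_average(*coverages: Mapping[Label, float] | Iterable[float]) -> float:
    """Unweighted mean over label-by-dataset coverage percentages."""
    values: list[float] = []
    for cov in coverages:
        if isinstance(cov, Mapping):
            values.extend(cov.values())
        else:
            values.extend(float(v) for v in cov)
    if not values:
        raise ValueError("no coverage percentages to average")
    return sum(values) / len(values)


# ---------------------------------------------------------------------------
# domain TSV IO: id <TAB> comma-separated accessions (possibly empty)
# ---------------------------------------------------------------------------


def _strip_version(accession: str) -> str:
    # PF00520.31 -> PF00520; comparison is on the family accession
    return accession.split(".", 1)[0].strip()


def read_domains(path: str | Path) -> dict[str, frozenset[str]]:
    path = Path(path)
    out: dict[str, frozenset[str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].strip().startswith("#") or not any(f.strip() for f in row):
                continue
            pid = row[0].strip()
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            accs = row[1] if len(row) > 1 else ""
            out[pid] = frozenset(
                _strip_version(a) for a in accs.split(",") if a.strip()
            )
    if not out:
        raise ValueError(f"{path}: no domain rows found")
    return out


def write_domains(
    domains: Mapping[str, Iterable[str]],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for pid in sorted(domains):
            writer.writerow([pid, ",".join(sorted(domains[pid]))])


def attach_domains(
    dataset: BenchmarkDataset, domains: Mapping[str, frozenset[str]]
) -> BenchmarkDataset:
    """Return a copy of the dataset with domain annotations attached."""
    missing = [r.id for r in dataset if r.id not in domains]
    if missing:
        raise ValueError(f"no domain annotation for ids: {missing}")
    return BenchmarkDataset(
        records=[r.with_domains(domains[r.id]) for r in dataset],
        provenance=dataset.provenance,
    )
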