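"""Label taxonomy, per-protein records and the benchmark dataset container.

The label universe has nine members: ``non-ion`` plus the eight ion-channel
labels formed by crossing the two gating types (voltage- vs ligand-gated)
with the four transported-ion subtypes (sodium, potassium, calcium, anion).
A protein's annotation is a *label set*: either the ``non-ion`` singleton or
one-to-four subtype labels that all share one gating type — channels are
annotated with a single gating mechanism but may transport several ions.
"""

from __future__ import annotations

import csv
import enum
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from Bio import SeqIO

__all__ = [
    "Gating",
    "IonType",
    "Label",
    "LABELS",
    "CHANNEL_LABELS",
    "LabelSet",
    "ProteinRecord",
    "BenchmarkDataset",
    "DatasetSummary",
    "read_labels",
    "read_predictions",
    "write_labels",
    "read_fasta",
    "dataset_summary",
]

# residues accepted in optional sequences: the 20 standard AAs plus ambiguity
# codes B/Z/X and selenocysteine U
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


class Gating(enum.Enum):
    """Gating mechanism of an ion channel."""

    VOLTAGE = "voltage"
    LIGAND = "ligand"


class IonType(enum.Enum):
    """Transported-ion subtype of an ion channel."""

    SODIUM = "sodium"
    POTASSIUM = "potassium"
    CALCIUM = "calcium"
    ANION = "anion"


ION_ORDER = (IonType.SODIUM, IonType.POTASSIUM, IonType.CALCIUM, IonType.ANION)


class Label(enum.Enum):
    """One of the nine outcome labels, in canonical order.

    Canonical order (used for serialization and every tie-break):
    ``non-ion`` first, then the four voltage-gated subtypes, then the four
    ligand-gated subtypes, each block ordered Na, K, Ca, anion.
    """

    NON_ION = ("non-ion", None, None)
    VG_SODIUM = ("vg-Na", Gating.VOLTAGE, IonType.SODIUM)
    VG_POTASSIUM = ("vg-K", Gating.VOLTAGE, IonType.POTASSIUM)
    VG_CALCIUM = ("vg-Ca", Gating.VOLTAGE, IonType.CALCIUM)
    VG_ANION = ("vg-anion", Gating.VOLTAGE, IonType.ANION)
    LG_SODIUM = ("lg-Na", Gating.LIGAND, IonType.SODIUM)
    LG_POTASSIUM = ("lg-K", Gating.LIGAND, IonType.POTASSIUM)
    LG_CALCIUM = ("lg-Ca", Gating.LIGAND, IonType.CALCIUM)
    LG_ANION = ("lg-anion", Gating.LIGAND, IonType.ANION)

    def __init__(self, short: str, gating: Optional[Gating], ion: Optional[IonType]):
        self.short = short
        self.gating = gating
        self.ion = ion

    @property
    def is_channel(self) -> bool:
        return self is not Label.NON_ION

    @property
    def order(self) -> int:
        """Position in the canonical total order."""
        return _LABEL_ORDER[self]

    @staticmethod
    def channel(gating: Gating, ion: IonType) -> "Label":
        return _BY_PARTS[(gating, ion)]

    def __lt__(self, other: "Label") -> bool:  # canonical, not value, order
        if not isinstance(other, Label):
            return NotImplemented
        return self.order < other.order

    def __repr__(self) -> str:
        return f"<{self.short}>"


LABELS: tuple[Label, ...] = tuple(Label)
CHANNEL_LABELS: tuple[Label, ...] = tuple(l for l in Label if l.is_channel)
_LABEL_ORDER = {l: i for i, l in enumerate(LABELS)}
_BY_PARTS = {(l.gating, l.ion): l for l in CHANNEL_LABELS}


@dataclass(frozen=True)
class LabelSet:
    """A non-empty set of labels annotating or predicted for one protein.

    Invariants (checked at construction):

    * ``non-ion``, when present, is the only member;
    * all channel members share one gating type, unless ``relaxed=True``
      (used by the domain-content baseline, whose rule can legitimately
      fire across gating types);
    * cardinality is between 1 and 4 per gating type.
    """

    labels: frozenset[Label]
    relaxed: bool = False

    def __post_init__(self) -> None:
        labels = frozenset(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValueError("a LabelSet must contain at least one label")
        if not all(isinstance(l, Label) for l in labels):
            raise TypeError("LabelSet members must be Label instances")
        if Label.NON_ION in labels and len(labels) > 1:
            raise ValueError("non-ion is exclusive: it cannot be combined with channel labels")
        gatings = {l.gating for l in labels if l.is_channel}
        if not self.relaxed and len(gatings) > 1:
            raise ValueError(
                "channel labels in one annotation must share a single gating type "
                f"(got {sorted(g.value for g in gatings)}); each channel is annotated "
                "with one gating mechanism"
            )
        if len(labels) > 8 or (not self.relaxed and len(labels) > 4):
            raise ValueError("label-set cardinality exceeds the number of subtypes")

    # -- convenience set protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Label]:
        return iter(sorted(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    @property
    def is_non_ion(self) -> bool:
        return Label.NON_ION in self.labels

    @classmethod
    def non_ion(cls) -> "LabelSet":
        return cls(frozenset({Label.NON_ION}))

    @classmethod
    def of(cls, *labels: Label, relaxed: bool = False) -> "LabelSet":
        return cls(frozenset(labels), relaxed=relaxed)

    def __repr__(self) -> str:
        return "{" + ",".join(l.short for l in self) + "}"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus optional sequence, truth and domains."""

    id: str
    sequence: Optional[str] = None
    truth: Optional[LabelSet] = None
    domains: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise ValueError("protein id must be a non-empty string")
        if self.sequence is not None:
            seq = self.sequence.upper()
            bad = set(seq) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence of {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
                )
            object.__setattr__(self, "sequence", seq)
        if self.domains is not None:
            object.__setattr__(self, "domains", frozenset(self.domains))

    def with_domains(self, domains: Iterable[str]) -> "ProteinRecord":
        return replace(self, domains=frozenset(domains))


@dataclass
class BenchmarkDataset:
    """Ordered collection of protein records with free-text provenance."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate protein id {rec.id!r} in dataset")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == protein_id:
                return rec
        raise KeyError(protein_id)

    def truth_map(self) -> dict[str, LabelSet]:
        """id -> truth LabelSet; raises if any record lacks truth."""
        missing = [r.id for r in self.records if r.truth is None]
        if missing:
            raise ValueError(f"records without truth annotation: {missing}")
        return {r.id: r.truth for r in self.records}  # type: ignore[misc]

    def domains_map(self) -> dict[str, frozenset[str]]:
        missing = [r.id for r in self.records if r.domains is None]
        if missing:
            raise ValueError(f"records without domain annotation: {missing}")
        return {r.id: r.domains for r in self.records}  # type: ignore[misc]


# ---------------------------------------------------------------------------
# label-file round trip
# ---------------------------------------------------------------------------

_TYPE_TOKENS = {"non-ion": None, "voltage": Gating.VOLTAGE, "ligand": Gating.LIGAND}
_ION_TOKENS = {i.value: i for i in IonType}


def parse_label_row(type_token: str, subtype_field: str, relaxed: bool = False) -> LabelSet:
    """Build a LabelSet from the two annotation columns of a label TSV row.

    With ``relaxed=True`` the extra type token ``mixed`` is accepted, whose
    subtype field lists full label short names (e.g. ``vg-Na,lg-K``); this is
    only produced by predictors whose rule can fire across gating types.
    """
    type_token = type_token.strip().lower()
    if relaxed and type_token == "mixed":
        shorts = {l.short.lower(): l for l in LABELS}
        labels = []
        for tok in (t.strip().lower() for t in subtype_field.split(",") if t.strip()):
            if tok not in shorts:
                raise ValueError(f"unknown label {tok!r} in mixed row")
            labels.append(shorts[tok])
        if not labels:
            raise ValueError("mixed rows need at least one label")
        return LabelSet(frozenset(labels), relaxed=True)
    if type_token not in _TYPE_TOKENS:
        raise ValueError(
            f"unknown channel type {type_token!r}; expected non-ion, voltage or ligand"
        )
    gating = _TYPE_TOKENS[type_token]
    subtypes = [t.strip().lower() for t in subtype_field.split(",") if t.strip()]
    if gating is None:
        if subtypes:
            raise ValueError("non-ion rows must not carry subtypes")
        return LabelSet.non_ion()
    if not subtypes:
        raise ValueError(f"{type_token} rows need at least one subtype")
    ions = []
    for tok in subtypes:
        if tok not in _ION_TOKENS:
            raise ValueError(f"unknown subtype {tok!r}")
        ions.append(_ION_TOKENS[tok])
    if len(set(ions)) != len(ions):
        raise ValueError("repeated subtype in one row")
    return LabelSet(frozenset(Label.channel(gating, ion) for ion in ions))


def format_label_set(ls: LabelSet) -> tuple[str, str]:
    """Inverse of :func:`parse_label_row` -> (type token, subtype field).

    Mixed-gating prediction sets (domain-baseline outputs) serialize with
    the ``mixed`` type token and full label short names as the subtype
    field; they round-trip only through ``parse_label_row(relaxed=True)``.
    """
    if ls.is_non_ion:
        return "non-ion", ""
    gatings = {l.gating for l in ls}
    if len(gatings) > 1:
        return "mixed", ",".join(l.short for l in sorted(ls))
    gating = next(iter(gatings))
    ions = [l.ion.value for l in sorted(ls)]
    return gating.value, ",".join(ions)


def read_labels(path: str | Path) -> BenchmarkDataset:
    """Read a label TSV (columns: id, type, subtypes) into a dataset.

    ``#`` lines are comments; the subtype column is a comma-separated list,
    empty for non-ion rows. Duplicate ids, non-ion rows carrying subtypes and
    rows mixing gating types are hard errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].strip().startswith("#")) or not any(f.strip() for f in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: need at least id and type columns")
            pid = row[0].strip()
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            seen.add(pid)
            subtype_field = row[2] if len(row) > 2 else ""
            try:
                truth = parse_label_row(row[1], subtype_field)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(ProteinRecord(id=pid, truth=truth))
    return BenchmarkDataset(records=records, provenance=f"read_labels:{path.name}")


def write_labels(
    dataset: BenchmarkDataset | Mapping[str, LabelSet],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    """Write truth/prediction label sets as a TSV (canonical label order)."""
    if isinstance(dataset, BenchmarkDataset):
        items = [(r.id, r.truth) for r in dataset]
        if any(t is None for _, t in items):
            raise ValueError("cannot write a dataset with missing truth annotations")
    else:
        items = sorted(dataset.items())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for pid, ls in items:
            type_tok, ion_field = format_label_set(ls)  # type: ignore[arg-type]
            writer.writerow([pid, type_tok, ion_field])


def read_predictions(path: str | Path) -> dict[str, LabelSet]:
    """Read a prediction TSV (same format as labels, ``mixed`` rows allowed)."""
    path = Path(path)
    out: dict[str, LabelSet] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].strip().startswith("#") or not any(f.strip() for f in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: need at least id and type columns")
            pid = row[0].strip()
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            subtype_field = row[2] if len(row) > 2 else ""
            try:
                out[pid] = parse_label_row(row[1], subtype_field, relaxed=True)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no prediction rows found")
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, uppercased sequence) pairs.

    The id is the first whitespace-delimited header token. An empty file or a
    record with an empty sequence is a hard error.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(dataset: BenchmarkDataset, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in dataset:
            if rec.sequence is None:
                raise ValueError(f"record {rec.id!r} has no sequence to write")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSummary:
    """Per-label counts and cardinality statistics of an annotated dataset."""

    per_label: dict[Label, int]
    n_total: int
    n_channels: int
    n_multilabel: int
    total_subtype_labels: int
    mean_cardinality: float
    median_cardinality: float

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(l.short, self.per_label[l]) for l in LABELS]
        rows.append(("total proteins", self.n_total))
        rows.append(("multi-label proteins", self.n_multilabel))
        return rows


def dataset_summary(dataset: BenchmarkDataset) -> DatasetSummary:
    """Count labels and summarize label cardinality across the dataset."""
    truth = dataset.truth_map()
    if not truth:
        raise ValueError("cannot summarize an empty dataset")
    counts = {l: 0 for l in LABELS}
    cards: list[int] = []
    for ls in truth.values():
        cards.append(len(ls))
        for l in ls:
            counts[l] += 1
    n_multi = sum(1 for c in cards if c > 1)
    return DatasetSummary(
        per_label=counts,
        n_total=len(truth),
        n_channels=sum(1 for ls in truth.values() if not ls.is_non_ion),
        n_multilabel=n_multi,
        total_subtype_labels=sum(counts[l] for l in CHANNEL_LABELS),
        mean_cardinality=sum(cards) / len(cards),
        median_cardinality=float(statistics.median(cards)),
    )
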