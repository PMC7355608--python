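"""Sequential aggregation of base-model propensities into label sets.

Three base models feed the flow: a channel-vs-non-channel propensity
(``p_ion``), a voltage-vs-ligand gating propensity (``p_voltage``; the
ligand propensity is its complement), and four transported-ion subtype
propensities (``p_subtype``). The multi-label rule is:

1. If ``p_ion`` is below the decision threshold, predict ``non-ion``.
2. Otherwise form the eight combo scores ``p_gating * p_subtype[ion]``
   (gating in {voltage, ligand} x four ions), sort them descending, find the
   gating type of the highest-scoring combo with a non-zero score, and
   output every non-zero combo of that gating type as the label set.

The single-label mode stops at the top-scoring combo. Ties are broken by
the canonical label order so runs are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

from .taxonomy import (
    BenchmarkDataset,
    Gating,
    ION_ORDER,
    IonType,
    Label,
    LabelSet,
)

__all__ = [
    "PropensityProfile",
    "ScoredCombo",
    "score_combos",
    "predict_multilabel",
    "predict_singlelabel",
    "predict_dataset",
    "read_scores",
    "write_scores",
]

DEFAULT_ION_THRESHOLD = 0.5
DEFAULT_ZERO_TOL = 1e-9


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a finite propensity in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class PropensityProfile:
    """The three base-model outputs for one protein.

    ``p_ion``: propensity that the protein is an ion channel.
    ``p_voltage``: propensity that a channel is voltage-gated (ligand
    propensity = 1 - p_voltage).
    ``p_subtype``: independent [0, 1] scores for the four ion subtypes;
    no normalization across subtypes is assumed.
    """

    p_ion: float
    p_voltage: float
    p_subtype: Mapping[IonType, float]

    def __post_init__(self) -> None:
        _check_unit("p_ion", self.p_ion)
        _check_unit("p_voltage", self.p_voltage)
        if set(self.p_subtype) != set(IonType):
            raise ValueError(
                "p_subtype must have exactly the four ion-subtype keys, got "
                f"{sorted(k.value if isinstance(k, IonType) else str(k) for k in self.p_subtype)}"
            )
        frozen = {ion: _check_unit(f"p_subtype[{ion.value}]", v) for ion, v in self.p_subtype.items()}
        object.__setattr__(self, "p_subtype", frozen)

    def gating_propensity(self, gating: Gating) -> float:
        return self.p_voltage if gating is Gating.VOLTAGE else 1.0 - self.p_voltage


@dataclass(frozen=True)
class ScoredCombo:
    """One (gating, ion) combination with its product score."""

    gating: Gating
    ion: IonType
    score: float

    @property
    def label(self) -> Label:
        return Label.channel(self.gating, self.ion)


def score_combos(profile: PropensityProfile) -> list[ScoredCombo]:
    """All eight combo scores, sorted by score descending.

    Each score is the product of the gating propensity and the subtype
    propensity. The sort is stable with ties broken by the canonical label
    order (voltage block before ligand, then Na, K, Ca, anion).
    """
    combos = [
        ScoredCombo(gating, ion, profile.gating_propensity(gating) * profile.p_subtype[ion])
        for gating in (Gating.VOLTAGE, Gating.LIGAND)
        for ion in ION_ORDER
    ]
    return sorted(combos, key=lambda c: (-c.score, c.label.order))


def predict_multilabel(
    profile: PropensityProfile,
    ion_threshold: float = DEFAULT_ION_THRESHOLD,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> LabelSet:
    """Multi-label prediction for one profile.

    Returns the non-ion singleton when the channel propensity is below
    ``ion_threshold``. Otherwise returns every combo whose score exceeds
    ``zero_tol`` and whose gating type matches the top-scoring such combo.
    If every combo is (numerically) zero while the channel branch already
    fired, the tie-ordered top combo is returned as a singleton.
    """
    if profile.p_ion < ion_threshold:
        return LabelSet.non_ion()
    ranked = score_combos(profile)
    nonzero = [c for c in ranked if c.score > zero_tol]
    if not nonzero:
        # the channel branch has committed to "ion channel"; fall back to the
        # tie-ordered top combo rather than contradicting the first stage
        return LabelSet.of(ranked[0].label)
    winner = nonzero[0].gating
    return LabelSet(frozenset(c.label for c in nonzero if c.gating is winner))


def predict_singlelabel(
    profile: PropensityProfile,
    ion_threshold: float = DEFAULT_ION_THRESHOLD,
) -> LabelSet:
    """Sequential single-label prediction: non-ion or the top combo only."""
    if profile.p_ion < ion_threshold:
        return LabelSet.non_ion()
    return LabelSet.of(score_combos(profile)[0].label)


def predict_dataset(
    dataset: BenchmarkDataset,
    scores: Mapping[str, PropensityProfile],
    mode: Literal["multi", "single"] = "multi",
    ion_threshold: float = DEFAULT_ION_THRESHOLD,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> dict[str, LabelSet]:
    """Predict every record of a dataset from its propensity profile."""
    missing = [r.id for r in dataset if r.id not in scores]
    if missing:
        raise ValueError(f"no propensity profile for ids: {missing}")
    if mode == "multi":
        return {
            r.id: predict_multilabel(scores[r.id], ion_threshold, zero_tol) for r in dataset
        }
    if mode == "single":
        return {r.id: predict_singlelabel(scores[r.id], ion_threshold) for r in dataset}
    raise ValueError(f"mode must be 'multi' or 'single', got {mode!r}")


# ---------------------------------------------------------------------------
# score-file IO: JSON map, or 7-column TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("id", "p_ion", "p_voltage", "sodium", "potassium", "calcium", "anion")


def _profile_from_dict(pid: str, d: Mapping) -> PropensityProfile:
    try:
        sub = d["p_subtype"]
        return PropensityProfile(
            p_ion=float(d["p_ion"]),
            p_voltage=float(d["p_voltage"]),
            p_subtype={ion: float(sub[ion.value]) for ion in IonType},
        )
    except KeyError as exc:
        raise ValueError(f"score entry for {pid!r} is missing key {exc}") from exc


def read_scores(path: str | Path) -> dict[str, PropensityProfile]:
    """Read propensity profiles from JSON (``.json``) or 7-column TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return {
            pid: _profile_from_dict(pid, entry)
            for pid, entry in data.items()
            if not pid.startswith("_")
        }
    profiles: dict[str, PropensityProfile] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if parts == list(_TSV_COLUMNS):  # optional header row
                continue
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated columns")
            pid = parts[0].strip()
            if pid in profiles:
                raise ValueError(f"{path}:{lineno}: duplicate id {pid!r}")
            vals = [float(v) for v in parts[1:]]
            profiles[pid] = PropensityProfile(
                p_ion=vals[0],
                p_voltage=vals[1],
                p_subtype=dict(zip(ION_ORDER, vals[2:])),
            )
    if not profiles:
        raise ValueError(f"{path}: no score rows found")
    return profiles


def write_scores(
    scores: Mapping[str, PropensityProfile],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write profiles as a JSON map (ids sorted for stable diffs)."""
    payload: dict[str, object] = {}
    if provenance:
        payload["_provenance"] = dict(provenance)
    for pid in sorted(scores):
        prof = scores[pid]
        payload[pid] = {
            "p_ion": prof.p_ion,
            "p_voltage": prof.p_voltage,
            "p_subtype": {ion.value: prof.p_subtype[ion] for ion in ION_ORDER},
        }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
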