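"""The sequential aggregation rule, checked against a brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionml import (
    BenchmarkDataset,
    Gating,
    IonType,
    Label,
    LabelSet,
    PropensityProfile,
    ProteinRecord,
    predict_dataset,
    predict_multilabel,
    predict_singlelabel,
    read_scores,
    score_combos,
    write_scores,
)
from ionml.taxonomy import ION_ORDER

NA, K, CA, AN = IonType.SODIUM, IonType.POTASSIUM, IonType.CALCIUM, IonType.ANION


def profile(p_ion, p_voltage, na=0.0, k=0.0, ca=0.0, anion=0.0):
    return PropensityProfile(
        p_ion=p_ion, p_voltage=p_voltage,
        p_subtype={NA: na, K: k, CA: ca, AN: anion},
    )


# ---------------------------------------------------------------------------
# independent oracle: enumerate all 2^8 candidate subsets and apply the
# verbal rule literally — keep the top-scoring non-zero combo's gating,
# include every non-zero combo of that gating, nothing else
# ---------------------------------------------------------------------------

def oracle_multilabel(prof, ion_threshold=0.5, zero_tol=1e-9):
    if prof.p_ion < ion_threshold:
        return frozenset({Label.NON_ION})
    combos = []
    for gating in (Gating.VOLTAGE, Gating.LIGAND):
        p_g = prof.p_voltage if gating is Gating.VOLTAGE else 1 - prof.p_voltage
        for ion in ION_ORDER:
            combos.append((gating, ion, p_g * prof.p_subtype[ion]))
    nonzero = [c for c in combos if c[2] > zero_tol]
    if not nonzero:
        top = min(combos, key=lambda c: (-c[2], Label.channel(c[0], c[1]).order))
        return frozenset({Label.channel(top[0], top[1])})
    top = min(nonzero, key=lambda c: (-c[2], Label.channel(c[0], c[1]).order))
    candidates = []
    for size in range(1, 9):
        for subset in itertools.combinations(combos, size):
            if any(c[2] <= zero_tol for c in subset):
                continue
            if len({c[0] for c in subset}) != 1:
                continue
            if top not in subset:
                continue
            # maximal: contains every non-zero combo of the chosen gating
            gating = subset[0][0]
            if any(c[0] is gating and c not in subset for c in nonzero):
                continue
            candidates.append(frozenset(Label.channel(c[0], c[1]) for c in subset))
    assert len(candidates) == 1
    return candidates[0]


def random_profile(rng):
    return PropensityProfile(
        p_ion=rng.uniform(), p_voltage=rng.uniform(),
        p_subtype={ion: (0.0 if rng.uniform() < 0.3 else rng.uniform()) for ion in ION_ORDER},
    )


class TestScoreCombos:
    def test_identity_case(self):
        combos = score_combos(profile(1, 1, na=1))
        assert (combos[0].gating, combos[0].ion, combos[0].score) == (Gating.VOLTAGE, NA, 1.0)
        assert all(c.score == 0 for c in combos if c.gating is Gating.LIGAND)

    def test_hand_multiplied_scores(self):
        combos = score_combos(profile(0.9, 0.8, na=0.6, k=0.4))
        top4 = [(c.label.short, round(c.score, 2)) for c in combos[:4]]
        assert top4 == [("vg-Na", 0.48), ("vg-K", 0.32), ("lg-Na", 0.12), ("lg-K", 0.08)]
        assert all(c.score == 0 for c in combos[4:])

    def test_ties_follow_canonical_order(self):
        combos = score_combos(profile(1, 0.5, na=0.5, k=0.5, ca=0.5, anion=0.5))
        assert all(abs(c.score - 0.25) < 1e-12 for c in combos)
        assert [c.label.short for c in combos] == [
            "vg-Na", "vg-K", "vg-Ca", "vg-anion", "lg-Na", "lg-K", "lg-Ca", "lg-anion",
        ]

    @pytest.mark.parametrize("bad", [dict(p_ion=1.5), dict(p_voltage=-0.1), dict(na=float("nan"))])
    def test_out_of_range_propensities_rejected(self, bad):
        kwargs = dict(p_ion=0.5, p_voltage=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            profile(**kwargs)


class TestPredictMultilabel:
    def test_non_ion_branch(self):
        assert predict_multilabel(profile(0.2, 1, na=1)).is_non_ion

    def test_same_gating_nonzero_subset(self):
        pred = predict_multilabel(profile(0.9, 0.8, na=0.6, k=0.4))
        assert pred == LabelSet.of(Label.VG_SODIUM, Label.VG_POTASSIUM)

    def test_ligand_side_wins(self):
        pred = predict_multilabel(profile(0.9, 0.3, ca=0.9, anion=0.2))
        assert pred == LabelSet.of(Label.LG_CALCIUM, Label.LG_ANION)

    def test_all_zero_fallback_is_tie_ordered_singleton(self):
        pred = predict_multilabel(profile(0.9, 0.5))
        assert pred == LabelSet.of(Label.VG_SODIUM)

    def test_matches_bruteforce_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            prof = random_profile(rng)
            assert predict_multilabel(prof).labels == oracle_multilabel(prof)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(0.5, 1), st.floats(0, 1),
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        st.sampled_from(ION_ORDER), st.floats(0.01, 0.5),
    )
    def test_raising_a_winning_subtype_never_drops_it(self, p_ion, p_v, subs, ion, bump):
        """Monotonicity: raising p_subtype[s] keeps (T, s) when T wins."""
        prof = PropensityProfile(p_ion=p_ion, p_voltage=p_v,
                                 p_subtype=dict(zip(ION_ORDER, subs)))
        pred = predict_multilabel(prof)
        if pred.is_non_ion:
            return
        winner = next(iter(pred)).gating
        target = Label.channel(winner, ion)
        if target not in pred:
            return
        raised = PropensityProfile(
            p_ion=p_ion, p_voltage=p_v,
            p_subtype={i: (min(1.0, v + bump) if i is ion else v)
                       for i, v in prof.p_subtype.items()},
        )
        assert target in predict_multilabel(raised)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_output_never_mixes_gating_or_non_ion(self, p_ion, p_v, subs):
        pred = predict_multilabel(PropensityProfile(
            p_ion=p_ion, p_voltage=p_v, p_subtype=dict(zip(ION_ORDER, subs))))
        gatings = {l.gating for l in pred if l.is_channel}
        assert len(gatings) <= 1
        if Label.NON_ION in pred:
            assert len(pred) == 1


class TestPredictSinglelabel:
    def test_non_ion_and_argmax(self):
        assert predict_singlelabel(profile(0.2, 1, na=1)).is_non_ion
        assert predict_singlelabel(profile(0.9, 0.8, na=0.6, k=0.4)) == LabelSet.of(Label.VG_SODIUM)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.5, 1), st.floats(0, 1), st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_singleton_subset_of_multilabel(self, p_ion, p_v, subs):
        prof = PropensityProfile(p_ion=p_ion, p_voltage=p_v,
                                 p_subtype=dict(zip(ION_ORDER, subs)))
        single = predict_singlelabel(prof)
        multi = predict_multilabel(prof)
        assert single.labels <= multi.labels


class TestPredictDataset:
    def test_empty_and_missing_profile(self):
        assert predict_dataset(BenchmarkDataset(), {}) == {}
        d = BenchmarkDataset(records=[ProteinRecord(id="P1")])
        with pytest.raises(ValueError, match="P1"):
            predict_dataset(d, {})

    def test_order_independent(self):
        recs = [ProteinRecord(id=f"P{i}") for i in range(5)]
        rng = np.random.default_rng(0)
        scores = {r.id: random_profile(rng) for r in recs}
        fwd = predict_dataset(BenchmarkDataset(records=recs), scores)
        rev = predict_dataset(BenchmarkDataset(records=recs[::-1]), scores)
        assert fwd == rev


class TestScoreIO:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        scores = {f"P{i}": random_profile(rng) for i in range(4)}
        path = tmp_path / "scores.json"
        write_scores(scores, path, provenance={"seed": 1})
        assert read_scores(path) == scores

    def test_tsv_seven_columns(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "id\tp_ion\tp_voltage\tsodium\tpotassium\tcalcium\tanion\n"
            "P1\t0.9\t0.8\t0.6\t0.4\t0\t0\n"
        )
        scores = read_scores(path)
        assert scores["P1"] == profile(0.9, 0.8, na=0.6, k=0.4)

    def test_malformed_tsv_rejected(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("P1\t0.9\t0.8\n")
        with pytest.raises(ValueError, match="7"):
            read_scores(path)
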