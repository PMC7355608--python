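"""Label taxonomy, label-set invariants, file round-trips and summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from ionml import (
    BenchmarkDataset,
    Label,
    LabelSet,
    ProteinRecord,
    dataset_summary,
    read_fasta,
    read_labels,
    read_predictions,
    write_labels,
)
from ionml.taxonomy import CHANNEL_LABELS, LABELS, parse_label_row, write_fasta


class TestLabelUniverse:
    def test_nine_distinct_labels(self):
        assert len(LABELS) == 9
        assert len(CHANNEL_LABELS) == 8
        assert Label.NON_ION not in CHANNEL_LABELS

    def test_canonical_order_non_ion_then_voltage_then_ligand(self):
        shorts = [l.short for l in sorted(LABELS, key=lambda l: l.order)]
        assert shorts == [
            "non-ion", "vg-Na", "vg-K", "vg-Ca", "vg-anion",
            "lg-Na", "lg-K", "lg-Ca", "lg-anion",
        ]


class TestLabelSetInvariants:
    def test_non_ion_is_exclusive(self):
        with pytest.raises(ValueError, match="exclusive"):
            LabelSet.of(Label.NON_ION, Label.VG_SODIUM)

    def test_mixed_gating_rejected_unless_relaxed(self):
        with pytest.raises(ValueError, match="gating"):
            LabelSet.of(Label.VG_SODIUM, Label.LG_CALCIUM)
        relaxed = LabelSet.of(Label.VG_SODIUM, Label.LG_CALCIUM, relaxed=True)
        assert len(relaxed) == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            LabelSet(frozenset())

    @settings(max_examples=300, derandomize=True)
    @given(st.sets(st.sampled_from(LABELS), min_size=0, max_size=9))
    def test_construction_enforces_invariants(self, labels):
        """Any constructed LabelSet satisfies exclusivity and single gating."""
        valid = (
            len(labels) >= 1
            and (Label.NON_ION not in labels or len(labels) == 1)
            and len({l.gating for l in labels if l.is_channel}) <= 1
        )
        if valid:
            ls = LabelSet(frozenset(labels))
            assert 1 <= len(ls) <= 4
            if ls.is_non_ion:
                assert len(ls) == 1
        else:
            with pytest.raises(ValueError):
                LabelSet(frozenset(labels))


class TestLabelFiles:
    def test_row_parsing(self):
        assert parse_label_row("non-ion", "") == LabelSet.non_ion()
        assert parse_label_row("voltage", "sodium,potassium") == LabelSet.of(
            Label.VG_SODIUM, Label.VG_POTASSIUM
        )

    @pytest.mark.parametrize(
        "rows,message",
        [
            ("P3\tvoltage\tsodium\nP3\tligand\tcalcium\n", "duplicate"),
            ("P1\tnon-ion\tsodium\n", "subtypes"),
            ("P1\tvoltage\t\n", "subtype"),
            ("P1\tchannel\tsodium\n", "unknown channel type"),
        ],
    )
    def test_bad_rows_are_hard_errors(self, tmp_path, rows, message):
        path = tmp_path / "labels.tsv"
        path.write_text(rows)
        with pytest.raises(ValueError, match=message):
            read_labels(path)

    def test_round_trip_canonical(self, tmp_path, bench221):
        path = tmp_path / "labels.tsv"
        write_labels(bench221, path, header_lines=["synthetic"])
        back = read_labels(path)
        assert back.ids == bench221.ids
        assert [r.truth for r in back] == [r.truth for r in bench221]

    def test_predictions_allow_mixed_rows(self, tmp_path):
        path = tmp_path / "pred.tsv"
        path.write_text("P1\tmixed\tvg-Na,lg-K\nP2\tnon-ion\t\n")
        preds = read_predictions(path)
        assert preds["P1"] == LabelSet.of(Label.VG_SODIUM, Label.LG_POTASSIUM, relaxed=True)
        assert preds["P2"].is_non_ion


class TestFasta:
    def test_basic_and_case_folding(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">P1 some description\nMKV\n>A\nmkv\nlli\n")
        assert read_fasta(path) == [("P1", "MKV"), ("A", "MKVLLI")]

    def test_empty_record_and_empty_file_error(self, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text(">A\n\n>B\nMK\n")
        with pytest.raises(ValueError, match="A"):
            read_fasta(bad)
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            read_fasta(empty)

    def test_write_read_round_trip(self, tmp_path, bench221):
        path = tmp_path / "seqs.fasta"
        write_fasta(bench221, path)
        pairs = read_fasta(path)
        assert [p[0] for p in pairs] == bench221.ids
        assert pairs[0][1] == bench221.records[0].sequence


class TestRecordsAndDataset:
    def test_bad_sequence_letters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            ProteinRecord(id="P1", sequence="MKO1")

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord(id="P1"), ProteinRecord(id="P1")]
        with pytest.raises(ValueError, match="duplicate"):
            BenchmarkDataset(records=recs)


class TestSummary:
    def test_benchmark_shape(self, bench221):
        s = dataset_summary(bench221)
        assert s.n_total == 221
        assert s.n_channels == 110
        assert s.n_multilabel == 29
        assert s.total_subtype_labels == 180
        assert round(s.mean_cardinality, 2) == 1.32
        assert s.median_cardinality == 1

    def test_singletons(self):
        d = BenchmarkDataset(records=[
            ProteinRecord(id=f"P{i}", truth=LabelSet.non_ion()) for i in range(3)
        ])
        s = dataset_summary(d)
        assert (s.mean_cardinality, s.median_cardinality, s.n_multilabel) == (1.0, 1, 0)

    def test_mixed_cardinalities(self):
        d = BenchmarkDataset(records=[
            ProteinRecord(id="A", truth=LabelSet.of(Label.VG_SODIUM)),
            ProteinRecord(id="B", truth=LabelSet.of(
                Label.LG_SODIUM, Label.LG_POTASSIUM, Label.LG_CALCIUM)),
        ])
        s = dataset_summary(d)
        assert (s.mean_cardinality, s.median_cardinality) == (2.0, 2)

    def test_missing_truth_is_hard_error(self):
        d = BenchmarkDataset(records=[ProteinRecord(id="A")])
        with pytest.raises(ValueError, match="A"):
            dataset_summary(d)
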