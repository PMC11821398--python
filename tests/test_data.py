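"""Composition-table I/O, validation and replicate preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oilauth import (
    FeatureSchema,
    average_replicates,
    read_composition_table,
    validate_table,
    write_composition_table,
)
from oilauth.data import SchemaMismatchError, TableParseError

from conftest import make_table


class TestRoundTrip:
    def test_write_read_identity(self, tiny_schema, tmp_path):
        table = make_table(
            tiny_schema, [[60.0, 40.0, 100.0, 100.0], [59.5, 40.5, 100.0, 100.0]]
        )
        path = tmp_path / "t.csv"
        write_composition_table(table, path)
        back = read_composition_table(path, tiny_schema)
        assert len(back) == 2
        np.testing.assert_array_equal(back.matrix(), table.matrix())
        assert [s.sample_id for s in back.samples] == ["S1", "S2"]

    def test_flags_survive_round_trip(self, tiny_schema, tmp_path):
        table = make_table(tiny_schema, [[8.0, "ND", 100.0, 100.0]])
        path = tmp_path / "t.csv"
        write_composition_table(table, path)
        back = read_composition_table(path, tiny_schema)
        assert back.samples[0].flags[1] == "ND"
        assert np.isnan(back.samples[0].values[1])

    def test_empty_table_writes_header_only(self, tiny_schema, tmp_path):
        table = make_table(tiny_schema, [])
        path = tmp_path / "t.csv"
        write_composition_table(table, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert "fa1" in lines[0]
        assert len(read_composition_table(path, tiny_schema)) == 0

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.floats(0, 100, allow_nan=False, width=32), min_size=4, max_size=4
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, rows):
        from oilauth import FeatureSchema

        schema = FeatureSchema(
            ["fa1", "fa2", "tag1", "toco1"],
            {"fa1": "FA", "fa2": "FA", "tag1": "TAG", "toco1": "TOCO"},
        )
        table = make_table(schema, rows)
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        write_composition_table(table, path)
        back = read_composition_table(path, schema)
        np.testing.assert_array_equal(back.matrix(), table.matrix())


class TestReadErrors:
    def test_missing_feature_column(self, tiny_schema, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,class_label,fa1,fa2,tag1\nS1,CO,1,2,3\n")
        with pytest.raises(SchemaMismatchError, match="toco1"):
            read_composition_table(path, tiny_schema)

    def test_unknown_column(self, tiny_schema, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,class_label,fa1,fa2,tag1,toco1,bogus\nS1,CO,1,2,3,4,5\n"
        )
        with pytest.raises(SchemaMismatchError, match="bogus"):
            read_composition_table(path, tiny_schema)

    def test_unparseable_cell(self, tiny_schema, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,class_label,fa1,fa2,tag1,toco1\nS1,CO,1,oops,3,4\n")
        with pytest.raises(TableParseError, match="fa2"):
            read_composition_table(path, tiny_schema)


class TestValidate:
    def test_exact_block_sums_pass(self, tiny_schema):
        table = make_table(tiny_schema, [[60.0, 40.0, 100.0, 100.0]])
        assert validate_table(table).passed

    def test_negative_value_flagged(self, tiny_schema):
        table = make_table(tiny_schema, [[100.1, -0.1, 100.0, 100.0]])
        report = validate_table(table)
        assert any(i.rule == "negative-value" and "fa2" in i.detail
                   for i in report.issues)

    def test_open_block_sum_flagged(self, tiny_schema):
        # FA block sums to 92: deviation 8 > default tolerance 5
        table = make_table(tiny_schema, [[60.0, 32.0, 100.0, 100.0]])
        report = validate_table(table)
        assert any(i.rule == "block-sum" and "FA" in i.detail for i in report.issues)
        assert validate_table(table, block_sum_tolerance=10.0).passed


class TestAverageReplicates:
    def test_arithmetic_mean(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [[10.0, 90.0, 100.0, 100.0], [12.0, 88.0, 100.0, 100.0]],
            replicate_ids=["a", "b"],
            sample_ids=["S1", "S1"],
        )
        out = average_replicates(table)
        assert len(out) == 1
        assert out.samples[0].values[0] == pytest.approx(11.0)
        assert out.samples[0].replicate_id is None

    def test_flagged_entry_counts_as_zero(self, tiny_schema):
        table = make_table(
            tiny_schema,
            [[8.0, 92.0, 100.0, 100.0], ["ND", 100.0, 100.0, 100.0]],
            replicate_ids=["a", "b"],
            sample_ids=["S1", "S1"],
        )
        out = average_replicates(table)
        assert out.samples[0].values[0] == pytest.approx(4.0)

    def test_single_replicate_unchanged_and_idempotent(self, tiny_schema):
        table = make_table(tiny_schema, [[10.0, 90.0, 100.0, 100.0]])
        once = average_replicates(table)
        twice = average_replicates(once)
        np.testing.assert_array_equal(once.matrix(), table.matrix())
        np.testing.assert_array_equal(twice.matrix(), once.matrix())

    def test_one_output_row_per_sample_id_nonnegative(self, tiny_schema):
        rng = np.random.default_rng(5)
        rows = rng.uniform(0, 50, size=(6, 4)).tolist()
        table = make_table(
            tiny_schema, rows,
            replicate_ids=["r1", "r2"] * 3,
            sample_ids=["A", "A", "B", "B", "C", "C"],
        )
        out = average_replicates(table)
        assert [s.sample_id for s in out.samples] == ["A", "B", "C"]
        assert (out.matrix() >= 0).all()

    def test_conflicting_labels_error(self, tiny_schema):
        from oilauth import CompositionSample, CompositionTable

        table = CompositionTable(
            tiny_schema,
            [
                CompositionSample.from_values("S1", "CO", [1, 2, 3, 4], "a"),
                CompositionSample.from_values("S1", "SO", [1, 2, 3, 4], "b"),
            ],
        )
        with pytest.raises(ValueError, match="conflicting"):
            average_replicates(table)


class TestSchema:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureSchema(["a", "a"], {"a": "FA"})

    def test_unassigned_feature_rejected(self):
        with pytest.raises(ValueError, match="block"):
            FeatureSchema(["a", "b"], {"a": "FA"})

    def test_canonical_schema_shape(self, schema):
        assert schema.n_features == 37
        slices = schema.block_slices()
        assert len(slices["FA"]) == 12
        assert len(slices["TAG"]) == 21
        assert len(slices["TOCO"]) == 4

    def test_schema_serialization_round_trip(self, schema, tmp_path):
        for name in ("s.json", "s.yaml"):
            schema.save(tmp_path / name)
            back = FeatureSchema.load(tmp_path / name)
            assert back.feature_names == schema.feature_names
            assert back.block_of == schema.block_of
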