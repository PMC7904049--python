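import dataclasses
from pathlib import Path

import pytest
from hypothesis import given, strategies as st

import mi2cast as m
from mi2cast.errors import ExportError, MitabParseError
from mi2cast.mitab import (
    COLUMNS,
    EMPTY,
    N_COLUMNS,
    _quote,
    _split_quoted,
    _unquote,
    record_from_line,
)
from mi2cast.template import ModificationSpec

GOLDEN = Path(__file__).parent / "data" / "golden.causaltab"


def golden_statements(registry):
    return list(m.gen_corpus(seed=11, n=3, registry=registry))


class TestRecord:
    def test_column_count_is_frozen(self):
        assert N_COLUMNS == 46
        assert len(set(COLUMNS)) == 46

    def test_relation_couple_in_causal_statement_column(self, registry):
        statement = m.gen_statement(1, registry=registry)
        record = m.statement_to_mitab(statement)
        cell = record.columns[45]
        assert statement.relation.id in cell
        assert statement.relation.label in cell

    def test_every_record_has_fixed_width(self, corpus):
        for statement in corpus:
            assert len(m.statement_to_mitab(statement).columns) == N_COLUMNS

    def test_lossiness_log_names_dropped_subfeatures(self, registry):
        profile = m.FeatureSelection(
            source_modifications=(ModificationSpec(residue=True,
                                                   position=True),),
            relation_context=frozenset({m.FieldRole.COMPARTMENT,
                                        m.FieldRole.CELL_LINE}),
        )
        statement = m.gen_statement(2, profile, registry)
        record = m.statement_to_mitab(statement)
        assert set(record.dropped) == {
            "source.modifications[0]",
            "source.modifications[0].residue",
            "source.modifications[0].position",
            "compartment",
            "cell_line",
        }

    def test_mapped_fields_are_not_logged_as_dropped(self, registry):
        profile = m.FeatureSelection(
            source_biological_type=True,
            relation_context=frozenset({m.FieldRole.MECHANISM,
                                        m.FieldRole.TAXON}),
        )
        record = m.statement_to_mitab(m.gen_statement(3, profile, registry))
        assert record.dropped == ()
        assert record.columns[44] != EMPTY  # mechanism
        assert record.columns[9] != EMPTY   # taxon

    def test_lossiness_complement_matches_projection(self, corpus):
        """dropped ∪ mapped-subset = whole statement, for every statement."""
        for statement in corpus:
            record = m.statement_to_mitab(statement)
            projected = m.mitab_projection(statement)
            if record.dropped:
                assert projected != statement
            else:
                assert projected == statement


class TestWriteRead:
    def test_empty_list_with_header(self):
        text = m.write_causaltab([], include_header=True)
        assert text.startswith("#" + COLUMNS[0])
        assert len(text.splitlines()) == 1
        assert m.read_causaltab(text) == []

    def test_no_header_mode(self, registry):
        statement = m.gen_statement(1, registry=registry)
        text = m.write_causaltab([statement], include_header=False)
        assert not text.startswith("#")
        assert len(text.splitlines()) == 1

    def test_row_count_and_width_over_corpus(self, registry):
        statements = list(m.gen_corpus(seed=900, n=200, registry=registry))
        text = m.write_causaltab(statements)
        rows = [ln for ln in text.splitlines() if not ln.startswith("#")]
        assert len(rows) == 200
        for ln in rows:
            assert len(_split_quoted(ln, "\t")) == N_COLUMNS

    def test_subset_round_trip(self, registry):
        statements = list(m.gen_corpus(seed=900, n=200, registry=registry))
        back = m.read_causaltab(m.write_causaltab(statements))
        assert back == [m.mitab_projection(s) for s in statements]

    def test_pipe_in_label_survives_round_trip(self, registry):
        statement = m.gen_statement(1, registry=registry)
        weird = dataclasses.replace(
            statement,
            source=dataclasses.replace(statement.source,
                                       label='A|K(T)1\t"x"'))
        text = m.write_causaltab([weird])
        back = m.read_causaltab(text)
        assert back[0].source.label == 'A|K(T)1\t"x"'

    def test_wrong_column_count_rejected_with_line_number(self, registry):
        text = m.write_causaltab([m.gen_statement(1, registry=registry)])
        truncated = text.splitlines()[1].rsplit("\t", 1)[0]
        with pytest.raises(MitabParseError, match="line 1"):
            m.read_causaltab(truncated + "\n")

    def test_dash_cells_read_as_absent_context(self, registry):
        statement = m.gen_statement(1, registry=registry)
        back = m.read_causaltab(m.write_causaltab([statement]))[0]
        assert back.mechanism is None
        assert back.taxon is None
        assert back.source.biological_type is None

    def test_invalid_statement_rejected(self, registry):
        with pytest.raises(ExportError, match="MISSING_RELATION"):
            m.write_causaltab([m.gen_invalid(1, "MISSING_RELATION",
                                             registry)])


class TestQuoting:
    @given(st.text(min_size=0, max_size=30))
    def test_quote_unquote_inverse(self, text):
        assert _unquote(_quote(text)) == text

    @given(st.lists(st.text(alphabet=st.characters(
        blacklist_categories=("Cs",)), max_size=15), min_size=1, max_size=4))
    def test_cell_join_split_inverse(self, values):
        joined = "|".join(_quote(v) for v in values)
        assert [_unquote(p) for p in _split_quoted(joined, "|")] == values


class TestGoldenFile:
    def test_output_byte_stable_against_golden(self, registry):
        text = m.write_causaltab(golden_statements(registry))
        assert text == GOLDEN.read_text(encoding="utf-8")

    def test_golden_rows_parse_at_fixed_width(self):
        for line in GOLDEN.read_text(encoding="utf-8").splitlines():
            if line.startswith("#"):
                continue
            assert len(record_from_line(line).columns) == N_COLUMNS
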