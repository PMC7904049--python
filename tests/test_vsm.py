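import itertools
import json

import pytest

import mi2cast as m
from mi2cast import FieldRole as R
from mi2cast.errors import (
    FillError,
    IncompleteSentenceError,
    InvalidStatementError,
    ResolutionError,
    UnknownFieldError,
    VsmJsonError,
)
from mi2cast.template import ModificationSpec
from mi2cast.vsm import VsmSentence, VsmTerm


def field_id_of(sentence, role, index=0):
    return [f.field_id for f in sentence.fields if f.role is role][index]


def fill_minimal(template, registry):
    """Fill every field of a template with fixture terms, in order."""
    fillers = {
        R.SOURCE_ENTITY: "uniprot:P31750",
        R.TARGET_ENTITY: "uniprot:Q60823",
        R.CAUSAL_RELATION: "MI:2235",
        R.REFERENCE: "pubmed:123456",
        R.EVIDENCE: "ECO:0000269",
        R.BIOLOGICAL_TYPE: "MI:0326",
        R.BIOLOGICAL_MODIFICATION: "MOD:00696",
        R.RESIDUE: "MOD:00046",
        R.POSITION: "position:42",
        R.COMPARTMENT: "GO:0005737",
        R.MECHANISM: "MI:0217",
        R.CELL_LINE: "BTO:0000567",
        R.CELL_TYPE: "CL:0000057",
        R.TISSUE: "BTO:0000759",
        R.TAXON: "NCBITaxon:10090",
    }
    sentence = template
    for f in template.fields:
        sentence = m.fill_field(sentence, f.field_id,
                                registry.resolve(fillers[f.role]), registry)
    return sentence


class TestFillField:
    def test_fill_relation_with_up_regulates(self, minimal_template, registry):
        rel = field_id_of(minimal_template, R.CAUSAL_RELATION)
        filled = m.fill_field(minimal_template, rel,
                              registry.resolve("MI:2235"), registry)
        term = filled.field_term(rel)
        assert (term.id, term.label) == ("MI:2235", "up-regulates")

    def test_fill_source_with_entity_record(self, minimal_template, registry):
        src = field_id_of(minimal_template, R.SOURCE_ENTITY)
        filled = m.fill_field(minimal_template, src,
                              registry.resolve("uniprot:P31750"), registry)
        assert filled.field_term(src).label == "AKT1_MOUSE"

    def test_vocabulary_violation_rejected_with_role_named(
            self, minimal_template, registry):
        rel = field_id_of(minimal_template, R.CAUSAL_RELATION)
        with pytest.raises(FillError, match="causal_relation.*PSI-MI"):
            m.fill_field(minimal_template, rel,
                         registry.resolve("GO:0005634"), registry)

    def test_unknown_field_rejected(self, minimal_template, registry):
        with pytest.raises(UnknownFieldError):
            m.fill_field(minimal_template, "f99",
                         registry.resolve("MI:2235"), registry)

    def test_unresolvable_term_rejected(self, minimal_template, registry):
        bad = m.OntologyTerm("MI:0000000", "made up")
        rel = field_id_of(minimal_template, R.CAUSAL_RELATION)
        with pytest.raises(ResolutionError):
            m.fill_field(minimal_template, rel, bad, registry)

    def test_bare_integer_fills_position_field_only(self, registry):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(position=True),))
        template = m.generate_template(selection)
        pos = field_id_of(template, R.POSITION)
        filled = m.fill_field(template, pos, 42, registry)
        assert filled.field_term(pos).id == "position:42"
        with pytest.raises(FillError):
            m.fill_field(template, field_id_of(template, R.EVIDENCE), 42,
                         registry)


class TestIsComplete:
    def test_fresh_template_incomplete(self, minimal_template):
        assert not m.is_complete(minimal_template)

    def test_fully_filled_complete(self, minimal_template, registry):
        assert m.is_complete(fill_minimal(minimal_template, registry))

    def test_partially_filled_evidence_incomplete(self, registry):
        template = m.generate_template(m.FeatureSelection(evidence_count=2))
        one = m.fill_field(template, field_id_of(template, R.EVIDENCE),
                           registry.resolve("ECO:0000269"), registry)
        assert not m.is_complete(one)


class TestVsmJson:
    def test_empty_template_serializes_all_parts(self, minimal_template):
        doc = json.loads(m.to_vsm_json(minimal_template))
        fields = [t for t in doc["terms"] if t["type"] == "field"]
        relations = [t for t in doc["terms"] if t["type"] == "relation"]
        assert len(fields) == 5
        assert len(relations) == 2  # reported in, has evidence
        assert len(doc["connectors"]) == 3
        assert all("placeholder" in f and "lookup_roles" in f for f in fields)

    def test_round_trip_identity(self, corpus, registry, minimal_template):
        sentences = [m.statement_to_sentence(s) for s in corpus[:20]]
        sentences.append(minimal_template)
        sentences.append(fill_minimal(minimal_template, registry))
        for sentence in sentences:
            assert m.from_vsm_json(m.to_vsm_json(sentence)) == sentence

    def test_degenerate_single_term_sentence(self):
        sentence = VsmSentence((VsmTerm(kind="relation", label="note"),), ())
        assert m.from_vsm_json(m.to_vsm_json(sentence)) == sentence

    def test_out_of_range_connector_rejected(self, minimal_template):
        doc = json.loads(m.to_vsm_json(minimal_template))
        doc["connectors"][0] = [0, 1, 99]
        with pytest.raises(VsmJsonError, match="outside the term list"):
            m.from_vsm_json(json.dumps(doc))

    def test_duplicate_positions_rejected(self, minimal_template):
        doc = json.loads(m.to_vsm_json(minimal_template))
        doc["terms"][1]["position"] = 0
        with pytest.raises(VsmJsonError, match="duplicate"):
            m.from_vsm_json(json.dumps(doc))

    def test_malformed_json_rejected(self):
        with pytest.raises(VsmJsonError, match="malformed"):
            m.from_vsm_json("{not json")


class TestVsmJsonLight:
    def test_projection_of_full_form(self, corpus):
        for statement in corpus[:10]:
            sentence = m.statement_to_sentence(statement)
            full = json.loads(m.to_vsm_json(sentence))
            light = json.loads(m.to_vsm_json_light(sentence))
            full_pairs = [(t.get("id"), t.get("label")) for t in full["terms"]]
            light_pairs = [(t.get("id"), t.get("label"))
                           for t in light["terms"]]
            assert light_pairs == full_pairs
            assert light["connectors"] == full["connectors"]

    def test_no_autocomplete_or_template_data(self, minimal_template):
        light = json.loads(m.to_vsm_json_light(minimal_template))
        for term in light["terms"]:
            assert "lookup_roles" not in term
            assert "placeholder" not in term
            assert "field_id" not in term

    def test_empty_fields_keep_their_role(self, minimal_template):
        light = json.loads(m.to_vsm_json_light(minimal_template))
        roles = [t["role"] for t in light["terms"] if "role" in t]
        assert roles.count("source_entity") == 1
        assert len(roles) == 5


class TestConnectorLegality:
    def test_tridents_over_enumerated_templates(self):
        """Every connector in every template: 3 distinct in-range endpoints,
        and the sentence graph is a spanning tree."""
        for selection in itertools.islice(m.enumerate_selections(2, 1),
                                          0, None, 17):
            template = m.generate_template(selection)
            n = len(template.terms)
            for c in template.connectors:
                ends = c.endpoints()
                assert len(ends) == 3
                assert len(set(ends)) == 3
                assert all(0 <= e < n for e in ends)
            m.check_well_formed(template)


class TestStatementConversion:
    def test_filled_modification_template_interpretation(self, registry):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(),),
            relation_context=frozenset({R.COMPARTMENT}),
        )
        sentence = fill_minimal(m.generate_template(selection), registry)
        statement = m.sentence_to_statement(sentence)
        assert len(statement.source.modifications) == 1
        assert statement.source.modifications[0].term.id == "MOD:00696"
        assert statement.compartment is not None
        assert statement.target.modifications == ()
        assert m.is_valid(statement, registry)

    def test_minimal_template_yields_empty_context(self, registry,
                                                   minimal_template):
        statement = m.sentence_to_statement(
            fill_minimal(minimal_template, registry))
        assert statement.context_items() == ()

    def test_incomplete_sentence_rejected(self, minimal_template):
        with pytest.raises(IncompleteSentenceError):
            m.sentence_to_statement(minimal_template)

    def test_statement_sentence_bijection(self, corpus):
        for statement in corpus:
            sentence = m.statement_to_sentence(statement)
            assert m.sentence_to_statement(sentence) == statement

    def test_each_position_links_to_its_own_modification(self, registry):
        profile = m.FeatureSelection(source_modifications=(
            ModificationSpec(position=True), ModificationSpec(position=True)))
        statement = m.gen_statement(4, profile, registry)
        sentence = m.statement_to_sentence(statement)
        back = m.sentence_to_statement(sentence)
        positions = [mod.position for mod in back.source.modifications]
        assert positions == [mod.position
                             for mod in statement.source.modifications]

    def test_invalid_statement_rejected(self):
        with pytest.raises(InvalidStatementError):
            m.statement_to_sentence(m.CausalStatement())

    def test_sentence_round_trip_is_isomorphic(self, registry):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(residue=True),),
            target_biological_type=True,
            relation_context=frozenset({R.TAXON}),
        )
        sentence = fill_minimal(m.generate_template(selection), registry)
        back = m.statement_to_sentence(m.sentence_to_statement(sentence))
        assert m.canonical_form(back) == m.canonical_form(sentence)
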