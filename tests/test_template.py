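import itertools

import pytest

import mi2cast as m
from mi2cast import FieldRole as R
from mi2cast.errors import (
    IncompatibleAnchorError,
    MandatoryFieldError,
    SelectionError,
    UnknownFieldError,
)
from mi2cast.template import ModificationSpec

MANDATORY_ROLES = {R.SOURCE_ENTITY, R.TARGET_ENTITY, R.CAUSAL_RELATION,
                   R.REFERENCE, R.EVIDENCE}


def field_id_of(template, role):
    return next(f.field_id for f in template.fields if f.role is role)


class TestGenerate:
    def test_minimal_selection_gives_exactly_the_mandatory_five(self):
        template = m.generate_template(m.FeatureSelection())
        roles = [f.role for f in template.fields]
        assert len(roles) == 5
        assert set(roles) == MANDATORY_ROLES

    def test_source_modification_plus_compartment_gives_seven_fields(self):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(),),
            relation_context=frozenset({R.COMPARTMENT}),
        )
        template = m.generate_template(selection)
        assert [f.placeholder for f in template.fields] == [
            "source entity", "modification", "causal relation",
            "target entity", "compartment", "reference", "evidence",
        ]

    def test_evidence_counter_multiplies_evidence_fields(self):
        template = m.generate_template(m.FeatureSelection(evidence_count=3))
        roles = [f.role for f in template.fields]
        assert roles.count(R.EVIDENCE) == 3
        assert len(roles) == 7

    def test_modification_trident_through_has_modif_term(self):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(),))
        template = m.generate_template(selection)
        src = template.field_position(field_id_of(template, R.SOURCE_ENTITY))
        mod = template.field_position(
            field_id_of(template, R.BIOLOGICAL_MODIFICATION))
        tridents = [c for c in template.connectors
                    if c.bearer == src and c.argument == mod]
        assert len(tridents) == 1
        assert template.terms[tridents[0].relation].label == "has modif."

    def test_deterministic_output(self):
        selection = m.FeatureSelection(
            source_biological_type=True, reference_count=2,
            relation_context=frozenset({R.TAXON, R.MECHANISM}))
        assert m.generate_template(selection) == m.generate_template(selection)

    def test_counters_below_one_rejected(self):
        with pytest.raises(SelectionError):
            m.FeatureSelection(evidence_count=0)
        with pytest.raises(SelectionError):
            m.FeatureSelection(reference_count=0)

    def test_selection_dict_round_trip(self):
        selection = m.FeatureSelection(
            source_modifications=(ModificationSpec(residue=True),),
            target_compartment=True,
            relation_context=frozenset({R.CELL_LINE}),
            evidence_count=2,
        )
        assert m.FeatureSelection.from_dict(selection.to_dict()) == selection


class TestSubfeatures:
    def test_modification_has_residue_and_position(self):
        assert m.subfeatures_for(R.BIOLOGICAL_MODIFICATION) == \
            frozenset({R.RESIDUE, R.POSITION})

    @pytest.mark.parametrize("role", [r for r in R
                                      if r is not R.BIOLOGICAL_MODIFICATION])
    def test_other_roles_have_none(self, role):
        assert m.subfeatures_for(role) == frozenset()


class TestAddFeature:
    def test_add_modification_to_source(self, minimal_template):
        grown = m.add_feature(minimal_template, R.BIOLOGICAL_MODIFICATION,
                              field_id_of(minimal_template, R.SOURCE_ENTITY))
        assert R.BIOLOGICAL_MODIFICATION in {f.role for f in grown.fields}
        assert "has modif." in {t.label for t in grown.terms
                                if t.kind == "relation"}

    def test_add_position_links_to_its_own_modification(self, minimal_template):
        src = field_id_of(minimal_template, R.SOURCE_ENTITY)
        t = m.add_feature(minimal_template, R.BIOLOGICAL_MODIFICATION, src)
        t = m.add_feature(t, R.BIOLOGICAL_MODIFICATION, src)
        first_mod = [f.field_id for f in t.fields
                     if f.role is R.BIOLOGICAL_MODIFICATION][0]
        t = m.add_feature(t, R.POSITION, first_mod)
        mod_pos = t.field_position(first_mod)
        pos_pos = t.field_position(field_id_of(t, R.POSITION))
        assert any(c.bearer == mod_pos and c.argument == pos_pos
                   for c in t.connectors)

    def test_add_residue_to_evidence_rejected(self, minimal_template):
        with pytest.raises(IncompatibleAnchorError):
            m.add_feature(minimal_template, R.RESIDUE,
                          field_id_of(minimal_template, R.EVIDENCE))

    def test_add_to_unknown_anchor_rejected(self, minimal_template):
        with pytest.raises(UnknownFieldError):
            m.add_feature(minimal_template, R.COMPARTMENT, "f999")

    def test_filled_values_preserved(self, registry, minimal_template):
        rel = field_id_of(minimal_template, R.CAUSAL_RELATION)
        filled = m.fill_field(minimal_template, rel,
                              registry.resolve("MI:2235"), registry)
        grown = m.add_feature(filled, R.TAXON, rel)
        assert grown.field_term(rel).id == "MI:2235"
        shrunk = m.remove_feature(grown, field_id_of(grown, R.TAXON))
        assert shrunk.field_term(rel).id == "MI:2235"


class TestRemoveFeature:
    def test_remove_modification_cascades_to_subfeatures(self):
        selection = m.FeatureSelection(source_modifications=(
            ModificationSpec(residue=True, position=True),))
        template = m.generate_template(selection)
        mod = field_id_of(template, R.BIOLOGICAL_MODIFICATION)
        shrunk = m.remove_feature(template, mod)
        # modification + residue + position fields and their relation terms
        assert len(template.terms) - len(shrunk.terms) == 6
        assert len(template.connectors) - len(shrunk.connectors) == 3
        assert m.canonical_form(shrunk) == \
            m.canonical_form(m.generate_template(m.FeatureSelection()))

    def test_remove_sole_evidence_rejected(self, minimal_template):
        with pytest.raises(MandatoryFieldError):
            m.remove_feature(minimal_template,
                             field_id_of(minimal_template, R.EVIDENCE))

    def test_remove_sole_reference_rejected(self, minimal_template):
        with pytest.raises(MandatoryFieldError):
            m.remove_feature(minimal_template,
                             field_id_of(minimal_template, R.REFERENCE))

    def test_remove_one_of_two_references_allowed(self):
        template = m.generate_template(m.FeatureSelection(reference_count=2))
        shrunk = m.remove_feature(template,
                                  field_id_of(template, R.REFERENCE))
        assert [f.role for f in shrunk.fields].count(R.REFERENCE) == 1

    def test_remove_mandatory_core_rejected(self, minimal_template):
        for role in (R.SOURCE_ENTITY, R.TARGET_ENTITY, R.CAUSAL_RELATION):
            with pytest.raises(MandatoryFieldError):
                m.remove_feature(minimal_template,
                                 field_id_of(minimal_template, role))

    def test_remove_then_readd_is_isomorphic(self, minimal_template):
        rel = field_id_of(minimal_template, R.CAUSAL_RELATION)
        grown = m.add_feature(minimal_template, R.CELL_LINE, rel)
        again = m.add_feature(
            m.remove_feature(grown, field_id_of(grown, R.CELL_LINE)),
            R.CELL_LINE, rel)
        assert m.canonical_form(again) == m.canonical_form(grown)


class TestSelectionTemplateCorrespondence:
    """Properties over the exhaustive selection enumeration."""

    def enumeration(self):
        return itertools.islice(m.enumerate_selections(2, 1), 0, None, 41)

    def test_mandatory_core_always_present(self):
        for selection in self.enumeration():
            roles = {f.role for f in m.generate_template(selection).fields}
            assert MANDATORY_ROLES <= roles

    def test_field_count_matches_selection(self):
        for selection in self.enumeration():
            template = m.generate_template(selection)
            assert len(template.fields) == selection.annotatable_field_count

    def test_selection_recoverable_from_template(self):
        for selection in self.enumeration():
            assert m.selection_of(m.generate_template(selection)) == selection

    def test_generation_equals_base_plus_additions(self):
        """generate(selection) is isomorphic to generate(minimal) followed by
        the corresponding add_feature calls."""
        for selection in itertools.islice(m.enumerate_selections(2, 1),
                                          0, None, 97):
            base_sel = m.FeatureSelection(
                reference_count=selection.reference_count,
                evidence_count=selection.evidence_count)
            built = m.generate_template(base_sel)
            for side_role, flags, mods in (
                (R.SOURCE_ENTITY,
                 (selection.source_biological_type,
                  selection.source_compartment),
                 selection.source_modifications),
                (R.TARGET_ENTITY,
                 (selection.target_biological_type,
                  selection.target_compartment),
                 selection.target_modifications),
            ):
                anchor = field_id_of(built, side_role)
                if flags[0]:
                    built = m.add_feature(built, R.BIOLOGICAL_TYPE, anchor)
                if flags[1]:
                    built = m.add_feature(built, R.COMPARTMENT, anchor)
                for spec in mods:
                    built = m.add_feature(built, R.BIOLOGICAL_MODIFICATION,
                                          anchor)
                    mod_id = [f.field_id for f in built.fields
                              if f.role is R.BIOLOGICAL_MODIFICATION][-1]
                    if spec.residue:
                        built = m.add_feature(built, R.RESIDUE, mod_id)
                    if spec.position:
                        built = m.add_feature(built, R.POSITION, mod_id)
            rel = field_id_of(built, R.CAUSAL_RELATION)
            for role in sorted(selection.relation_context,
                               key=lambda r: r.value):
                built = m.add_feature(built, role, rel)
            target = m.generate_template(selection)
            assert m.canonical_form(built) == m.canonical_form(target)
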