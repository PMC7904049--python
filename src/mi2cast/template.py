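"""Template generation: turn a feature selection into a VSM template graph
and mutate it as optional features and subfeatures are added or removed.

The selection mirrors an interactive configuration panel: checkboxes for
single-valued optional context, counters for multi-valued mandatory slots
(references, evidence) and per-modification subfeature flags.  The five
mandatory fields — source entity, target entity, causal relation, reference
and evidence — are always present; optional features add one annotatable
field each, wired into the sentence graph with a prefilled relation term and
a trident connector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Tuple

from .errors import (
    IncompatibleAnchorError,
    MandatoryFieldError,
    SelectionError,
    UnknownFieldError,
)
from .vocab import FieldRole
from .vsm import (
    CONTEXT_ORDER,
    EntityBlock,
    Field,
    ModSlot,
    Structure,
    VsmSentence,
    linearize,
    parse_structure,
)

#: Roles that may annotate the causal relation (the statement itself).
RELATION_CONTEXT_ROLES: FrozenSet[FieldRole] = frozenset(CONTEXT_ORDER)

#: Roles that may annotate an entity.
ENTITY_CONTEXT_ROLES: FrozenSet[FieldRole] = frozenset(
    {FieldRole.BIOLOGICAL_TYPE, FieldRole.COMPARTMENT}
)

#: Subfeatures per parent role.
_SUBFEATURES: Dict[FieldRole, FrozenSet[FieldRole]] = {
    FieldRole.BIOLOGICAL_MODIFICATION: frozenset(
        {FieldRole.RESIDUE, FieldRole.POSITION}
    ),
}


def subfeatures_for(feature: FieldRole | str) -> FrozenSet[FieldRole]:
    """Subfeatures that become selectable once *feature* is selected."""
    feature = FieldRole.coerce(feature)
    return _SUBFEATURES.get(feature, frozenset())


@dataclass(frozen=True)
class ModificationSpec:
    """Subfeature flags for one selected modification."""

    residue: bool = False
    position: bool = False


@dataclass(frozen=True)
class FeatureSelection:
    """The configuration-panel state that drives template generation."""

    source_modifications: Tuple[ModificationSpec, ...] = ()
    target_modifications: Tuple[ModificationSpec, ...] = ()
    source_biological_type: bool = False
    source_compartment: bool = False
    target_biological_type: bool = False
    target_compartment: bool = False
    relation_context: FrozenSet[FieldRole] = frozenset()
    reference_count: int = 1
    evidence_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_modifications",
                           tuple(self.source_modifications))
        object.__setattr__(self, "target_modifications",
                           tuple(self.target_modifications))
        ctx = frozenset(FieldRole.coerce(r) for r in self.relation_context)
        if not ctx <= RELATION_CONTEXT_ROLES:
            bad = sorted(r.value for r in ctx - RELATION_CONTEXT_ROLES)
            raise SelectionError(f"not statement-context roles: {bad}")
        object.__setattr__(self, "relation_context", ctx)
        if self.reference_count < 1 or self.evidence_count < 1:
            raise SelectionError(
                "reference_count and evidence_count must be >= 1 (mandatory)"
            )

    @property
    def annotatable_field_count(self) -> int:
        """Number of annotatable fields in the generated template."""
        n = 3 + self.reference_count + self.evidence_count
        n += sum((self.source_biological_type, self.source_compartment,
                  self.target_biological_type, self.target_compartment))
        n += len(self.relation_context)
        for spec in self.source_modifications + self.target_modifications:
            n += 1 + spec.residue + spec.position
        return n

    # --- configuration-document support (JSON / YAML) -------------------

    def to_dict(self) -> dict:
        return {
            "source": {
                "biological_type": self.source_biological_type,
                "compartment": self.source_compartment,
                "modifications": [
                    {"residue": m.residue, "position": m.position}
                    for m in self.source_modifications
                ],
            },
            "target": {
                "biological_type": self.target_biological_type,
                "compartment": self.target_compartment,
                "modifications": [
                    {"residue": m.residue, "position": m.position}
                    for m in self.target_modifications
                ],
            },
            "relation_context": sorted(r.value for r in self.relation_context),
            "reference_count": self.reference_count,
            "evidence_count": self.evidence_count,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureSelection":
        if not isinstance(doc, dict):
            raise SelectionError("selection document must be a mapping")

        def side(name: str) -> dict:
            block = doc.get(name, {})
            if not isinstance(block, dict):
                raise SelectionError(f"{name!r} must be a mapping")
            return block

        def mods(block: dict, name: str) -> Tuple[ModificationSpec, ...]:
            raw = block.get("modifications", [])
            if isinstance(raw, int):  # counter shorthand: n plain modifications
                raw = [{}] * raw
            if not isinstance(raw, list):
                raise SelectionError(f"{name}.modifications must be a list")
            return tuple(
                ModificationSpec(bool(m.get("residue", False)),
                                 bool(m.get("position", False)))
                for m in raw
            )

        src, tgt = side("source"), side("target")
        known = {"source", "target", "relation_context",
                 "reference_count", "evidence_count"}
        unknown = set(doc) - known
        if unknown:
            raise SelectionError(f"unknown selection keys: {sorted(unknown)}")
        return cls(
            source_modifications=mods(src, "source"),
            target_modifications=mods(tgt, "target"),
            source_biological_type=bool(src.get("biological_type", False)),
            source_compartment=bool(src.get("compartment", False)),
            target_biological_type=bool(tgt.get("biological_type", False)),
            target_compartment=bool(tgt.get("compartment", False)),
            relation_context=frozenset(doc.get("relation_context", ())),
            reference_count=int(doc.get("reference_count", 1)),
            evidence_count=int(doc.get("evidence_count", 1)),
        )


def generate_template(selection: FeatureSelection) -> VsmSentence:
    """Generate the VSM template for a feature selection.

    Deterministic: field identifiers are opaque tokens (``f1``, ``f2``, ...)
    assigned in reading order; the output contains the five mandatory roles
    plus exactly one field per selected feature/subfeature.
    """
    if not isinstance(selection, FeatureSelection):
        raise SelectionError("selection must be a FeatureSelection")
    counter = [0]

    def new_field(role: FieldRole) -> Field:
        counter[0] += 1
        return Field(f"f{counter[0]}", role)

    def entity_block(role: FieldRole, biological_type: bool, compartment: bool,
                     mods: Tuple[ModificationSpec, ...]) -> EntityBlock:
        block = EntityBlock(new_field(role))
        if biological_type:
            block.biological_type = new_field(FieldRole.BIOLOGICAL_TYPE)
        if compartment:
            block.compartment = new_field(FieldRole.COMPARTMENT)
        for spec in mods:
            slot = ModSlot(new_field(FieldRole.BIOLOGICAL_MODIFICATION))
            if spec.residue:
                slot.residue = new_field(FieldRole.RESIDUE)
            if spec.position:
                slot.position = new_field(FieldRole.POSITION)
            block.modifications.append(slot)
        return block

    source = entity_block(FieldRole.SOURCE_ENTITY,
                          selection.source_biological_type,
                          selection.source_compartment,
                          selection.source_modifications)
    relation = new_field(FieldRole.CAUSAL_RELATION)
    target = entity_block(FieldRole.TARGET_ENTITY,
                          selection.target_biological_type,
                          selection.target_compartment,
                          selection.target_modifications)
    structure = Structure(source, relation, target)
    for role in CONTEXT_ORDER:
        if role in selection.relation_context:
            structure.context[role] = new_field(role)
    for _ in range(selection.reference_count):
        structure.references.append(new_field(FieldRole.REFERENCE))
    for _ in range(selection.evidence_count):
        structure.evidences.append(new_field(FieldRole.EVIDENCE))
    return linearize(structure)


def selection_of(template: VsmSentence) -> FeatureSelection:
    """Recover the feature selection a template realises."""
    s = parse_structure(template)
    return FeatureSelection(
        source_modifications=tuple(
            ModificationSpec(m.residue is not None, m.position is not None)
            for m in s.source.modifications),
        target_modifications=tuple(
            ModificationSpec(m.residue is not None, m.position is not None)
            for m in s.target.modifications),
        source_biological_type=s.source.biological_type is not None,
        source_compartment=s.source.compartment is not None,
        target_biological_type=s.target.biological_type is not None,
        target_compartment=s.target.compartment is not None,
        relation_context=frozenset(s.context),
        reference_count=len(s.references),
        evidence_count=len(s.evidences),
    )


def add_feature(
    template: VsmSentence,
    feature: FieldRole | str,
    anchor: str,
) -> VsmSentence:
    """Insert a new empty field (plus its prefilled relation term and
    connector) at its canonical place, anchored on an existing field.

    Anchor compatibility: entity features anchor on an entity field,
    subfeatures on a modification field, statement context and extra
    reference/evidence fields on the causal-relation field.  Previously
    filled values are preserved.
    """
    feature = FieldRole.coerce(feature)
    structure = parse_structure(template)
    anchor_field = _find_field(structure, anchor)
    new = Field(structure.next_field_id(), feature)

    if anchor_field.role in (FieldRole.SOURCE_ENTITY, FieldRole.TARGET_ENTITY):
        block = (structure.source
                 if anchor_field.role is FieldRole.SOURCE_ENTITY
                 else structure.target)
        if feature is FieldRole.BIOLOGICAL_MODIFICATION:
            block.modifications.append(ModSlot(new))
        elif feature is FieldRole.BIOLOGICAL_TYPE:
            _set_once(block, "biological_type", new, feature)
        elif feature is FieldRole.COMPARTMENT:
            _set_once(block, "compartment", new, feature)
        else:
            raise IncompatibleAnchorError(
                f"{feature.value} cannot be added to an entity field"
            )
    elif anchor_field.role is FieldRole.BIOLOGICAL_MODIFICATION:
        slot = _find_mod_slot(structure, anchor)
        if feature is FieldRole.RESIDUE:
            if slot.residue is not None:
                raise IncompatibleAnchorError("modification already has a residue")
            slot.residue = new
        elif feature is FieldRole.POSITION:
            if slot.position is not None:
                raise IncompatibleAnchorError("modification already has a position")
            slot.position = new
        else:
            raise IncompatibleAnchorError(
                f"{feature.value} cannot be added to a modification field"
            )
    elif anchor_field.role is FieldRole.CAUSAL_RELATION:
        if feature is FieldRole.REFERENCE:
            structure.references.append(new)
        elif feature is FieldRole.EVIDENCE:
            structure.evidences.append(new)
        elif feature in RELATION_CONTEXT_ROLES:
            if feature in structure.context:
                raise IncompatibleAnchorError(
                    f"statement already has a {feature.value} field"
                )
            structure.context[feature] = new
            structure.context = {r: structure.context[r]
                                 for r in CONTEXT_ORDER
                                 if r in structure.context}
        else:
            raise IncompatibleAnchorError(
                f"{feature.value} cannot be added to the causal relation"
            )
    else:
        raise IncompatibleAnchorError(
            f"{feature.value} cannot be anchored on a "
            f"{anchor_field.role.value} field"
        )
    return linearize(structure)


def remove_feature(template: VsmSentence, field_id: str) -> VsmSentence:
    """Remove an optional field together with its relation term, connectors
    and dependent subfeature fields; everything else is unchanged.

    Removing source, target or causal relation — or the last reference or
    evidence field — is rejected, keeping the mandatory core intact.
    """
    structure = parse_structure(template)
    f = _find_field(structure, field_id)
    role = f.role
    if role in (FieldRole.SOURCE_ENTITY, FieldRole.TARGET_ENTITY,
                FieldRole.CAUSAL_RELATION):
        raise MandatoryFieldError(f"cannot remove mandatory {role.value} field")
    if role is FieldRole.REFERENCE:
        if len(structure.references) <= 1:
            raise MandatoryFieldError(
                "at least one reference field is mandatory"
            )
        structure.references = [x for x in structure.references
                                if x.field_id != field_id]
    elif role is FieldRole.EVIDENCE:
        if len(structure.evidences) <= 1:
            raise MandatoryFieldError(
                "at least one evidence field is mandatory"
            )
        structure.evidences = [x for x in structure.evidences
                               if x.field_id != field_id]
    elif role in RELATION_CONTEXT_ROLES or role in ENTITY_CONTEXT_ROLES:
        removed = False
        for ctx_role, ctx_field in list(structure.context.items()):
            if ctx_field.field_id == field_id:
                del structure.context[ctx_role]
                removed = True
        for block in (structure.source, structure.target):
            if (block.biological_type is not None
                    and block.biological_type.field_id == field_id):
                block.biological_type = None
                removed = True
            if (block.compartment is not None
                    and block.compartment.field_id == field_id):
                block.compartment = None
                removed = True
        assert removed
    elif role is FieldRole.BIOLOGICAL_MODIFICATION:
        for block in (structure.source, structure.target):
            block.modifications = [
                slot for slot in block.modifications
                if slot.modification.field_id != field_id
            ]
    elif role in (FieldRole.RESIDUE, FieldRole.POSITION):
        for block in (structure.source, structure.target):
            for slot in block.modifications:
                if (slot.residue is not None
                        and slot.residue.field_id == field_id):
                    slot.residue = None
                if (slot.position is not None
                        and slot.position.field_id == field_id):
                    slot.position = None
    else:  # pragma: no cover - all roles handled above
        raise MandatoryFieldError(f"cannot remove {role.value} field")
    return linearize(structure)


def _set_once(block: EntityBlock, slot: str, new: Field,
              feature: FieldRole) -> None:
    if getattr(block, slot) is not None:
        raise IncompatibleAnchorError(
            f"entity already has a {feature.value} field"
        )
    setattr(block, slot, new)


def _find_field(structure: Structure, field_id: str) -> Field:
    for f in structure.all_fields():
        if f.field_id == field_id:
            return f
    raise UnknownFieldError(f"no field with id {field_id!r}")


def _find_mod_slot(structure: Structure, field_id: str) -> ModSlot:
    for block in (structure.source, structure.target):
        for slot in block.modifications:
            if slot.modification.field_id == field_id:
                return slot
    raise UnknownFieldError(f"no modification field with id {field_id!r}")
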