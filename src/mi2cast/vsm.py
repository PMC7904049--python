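"""VSM sentence/template graphs: terms, trident connectors, fill-in,
serialization and interpretation into causal statements.

A VSM sentence is an ordered list of terms joined by *trident* connectors.
Each term is either a *field* (an annotatable slot, empty until filled with a
term+identifier couple) or a *prefilled relation* term (a fixed label such as
``"has modif."`` that names the semantic relation inside one triple).  A
connector assigns three terms — bearer, relation, argument — to one semantic
subunit; connectors attach only to terms, and the three endpoints are
pairwise distinct.  A *template* is simply a sentence that still contains
empty fields.

Graph shape.  Every trident contributes the undirected edges
bearer–relation and relation–argument; a well-formed sentence's edge union
is a single tree spanning all terms (connected, acyclic).  The core triple
is the one whose relation endpoint is the causal-relation field itself
(source —relation→ target); statement-level context, references and evidence
hang off that causal-relation term, entity context hangs off the entity
terms, and modification subfeatures hang off their own modification term, so
each subfeature is linked to the correct modification explicitly.

The VSM-JSON dialect used here is this package's own documented format (see
``to_vsm_json``); the light form is a lossy projection keeping identifiers
and labels but no autocomplete configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, field as dc_field
from typing import Dict, List, Optional, Tuple

from .errors import (
    FillError,
    IncompleteSentenceError,
    InvalidStatementError,
    StructureError,
    UnknownFieldError,
    VsmError,
    VsmJsonError,
)
from .model import BioEntity, CausalStatement, Modification
from .vocab import (
    FieldRole,
    OntologyTerm,
    VocabRegistry,
    ROLE_VOCABULARIES,
    VOCAB_NAMESPACES,
    position_term,
)

# Frozen prefilled relation-term labels.
REL_IS_A = "is a"
REL_HAS_MODIF = "has modif."
REL_HAS_RESIDUE = "has residue"
REL_AT_POSITION = "at position"
REL_HAS_COMPARTMENT = "has compartment"
REL_HAS_MECHANISM = "has mechanism"
REL_IN_CELL_LINE = "in cell line"
REL_IN_CELL_TYPE = "in cell type"
REL_IN_TISSUE = "in tissue"
REL_IN_TAXON = "in taxon"
REL_REPORTED_IN = "reported in"
REL_HAS_EVIDENCE = "has evidence"

#: Statement-level context roles in canonical (reading) order.
CONTEXT_ORDER: Tuple[FieldRole, ...] = (
    FieldRole.MECHANISM,
    FieldRole.COMPARTMENT,
    FieldRole.CELL_LINE,
    FieldRole.CELL_TYPE,
    FieldRole.TISSUE,
    FieldRole.TAXON,
)

_CONTEXT_LABELS: Dict[FieldRole, str] = {
    FieldRole.MECHANISM: REL_HAS_MECHANISM,
    FieldRole.COMPARTMENT: REL_HAS_COMPARTMENT,
    FieldRole.CELL_LINE: REL_IN_CELL_LINE,
    FieldRole.CELL_TYPE: REL_IN_CELL_TYPE,
    FieldRole.TISSUE: REL_IN_TISSUE,
    FieldRole.TAXON: REL_IN_TAXON,
}
_LABEL_CONTEXT = {v: k for k, v in _CONTEXT_LABELS.items()}

#: Placeholder hint shown in each empty field, per role.
PLACEHOLDERS: Dict[FieldRole, str] = {
    FieldRole.SOURCE_ENTITY: "source entity",
    FieldRole.TARGET_ENTITY: "target entity",
    FieldRole.CAUSAL_RELATION: "causal relation",
    FieldRole.REFERENCE: "reference",
    FieldRole.EVIDENCE: "evidence",
    FieldRole.BIOLOGICAL_TYPE: "biological type",
    FieldRole.BIOLOGICAL_MODIFICATION: "modification",
    FieldRole.RESIDUE: "residue",
    FieldRole.POSITION: "position",
    FieldRole.COMPARTMENT: "compartment",
    FieldRole.MECHANISM: "mechanism",
    FieldRole.CELL_LINE: "cell line",
    FieldRole.CELL_TYPE: "cell type",
    FieldRole.TISSUE: "tissue",
    FieldRole.TAXON: "taxon",
}


@dataclass(frozen=True)
class VsmTerm:
    """One term in sentence order.

    ``kind`` is ``"field"`` for annotatable slots (empty or filled) and
    ``"relation"`` for prefilled relation terms.  Filled fields carry both
    label and identifier (the term+identifier couple).
    """

    kind: str  # "field" | "relation"
    label: Optional[str] = None
    id: Optional[str] = None
    field_id: Optional[str] = None
    role: Optional[FieldRole] = None
    placeholder: Optional[str] = None

    @property
    def is_field(self) -> bool:
        return self.kind == "field"

    @property
    def is_filled(self) -> bool:
        return self.is_field and self.id is not None


@dataclass(frozen=True)
class VsmConnector:
    """Trident with three pairwise-distinct term positions."""

    bearer: int
    relation: int
    argument: int

    def endpoints(self) -> Tuple[int, int, int]:
        return (self.bearer, self.relation, self.argument)


@dataclass(frozen=True)
class VsmSentence:
    """Ordered terms plus trident connectors.  Immutable; operations return
    new sentences.  A template is a sentence with >= 1 empty field."""

    terms: Tuple[VsmTerm, ...] = ()
    connectors: Tuple[VsmConnector, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "connectors", tuple(self.connectors))

    @property
    def fields(self) -> Tuple[VsmTerm, ...]:
        return tuple(t for t in self.terms if t.is_field)

    def field_term(self, field_id: str) -> VsmTerm:
        for t in self.terms:
            if t.is_field and t.field_id == field_id:
                return t
        raise UnknownFieldError(f"no field with id {field_id!r}")

    def field_position(self, field_id: str) -> int:
        for i, t in enumerate(self.terms):
            if t.is_field and t.field_id == field_id:
                return i
        raise UnknownFieldError(f"no field with id {field_id!r}")


def check_well_formed(sentence: VsmSentence) -> None:
    """Raise :class:`VsmError` if connector legality or tree shape is broken.

    Rules: every connector has three in-range, pairwise-distinct endpoints;
    if any connectors exist, the undirected edge union (bearer–relation,
    relation–argument per trident) forms one tree spanning all terms.
    """
    n = len(sentence.terms)
    for c in sentence.connectors:
        ends = c.endpoints()
        if any(e < 0 or e >= n for e in ends):
            raise VsmError(f"connector {ends} endpoint out of range (0..{n - 1})")
        if len(set(ends)) != 3:
            raise VsmError(f"connector {ends} endpoints are not pairwise distinct")
    if not sentence.connectors:
        if n > 1:
            raise VsmError("multi-term sentence with no connectors is disconnected")
        return
    edges = []
    for c in sentence.connectors:
        edges.append((c.bearer, c.relation))
        edges.append((c.relation, c.argument))
    if len(edges) != n - 1:
        raise VsmError(
            f"connector graph is not a tree: {len(edges)} edges over {n} terms"
        )
    adjacency: Dict[int, List[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n:
        raise VsmError("connector graph does not span all terms")


# --------------------------------------------------------------------------
# Structured (tree) view of a sentence — the bridge between the flat
# term/connector representation, template mutation and statement conversion.
# --------------------------------------------------------------------------


@dataclass
class Field:
    field_id: str
    role: FieldRole
    value: Optional[OntologyTerm] = None


@dataclass
class ModSlot:
    modification: Field
    residue: Optional[Field] = None
    position: Optional[Field] = None

    def fields(self) -> List[Field]:
        out = [self.modification]
        out += [f for f in (self.residue, self.position) if f is not None]
        return out


@dataclass
class EntityBlock:
    entity: Field
    biological_type: Optional[Field] = None
    compartment: Optional[Field] = None
    modifications: List[ModSlot] = dc_field(default_factory=list)

    def fields(self) -> List[Field]:
        out = [self.entity]
        out += [f for f in (self.biological_type, self.compartment)
                if f is not None]
        for slot in self.modifications:
            out += slot.fields()
        return out


@dataclass
class Structure:
    """Canonical tree of fields behind a sentence."""

    source: EntityBlock
    relation: Field
    target: EntityBlock
    context: Dict[FieldRole, Field] = dc_field(default_factory=dict)
    references: List[Field] = dc_field(default_factory=list)
    evidences: List[Field] = dc_field(default_factory=list)

    def all_fields(self) -> List[Field]:
        out = self.source.fields() + [self.relation] + self.target.fields()
        out += [self.context[r] for r in CONTEXT_ORDER if r in self.context]
        out += self.references + self.evidences
        return out

    def next_field_id(self) -> str:
        top = 0
        for f in self.all_fields():
            if f.field_id.startswith("f"):
                try:
                    top = max(top, int(f.field_id[1:]))
                except ValueError:
                    pass
        return f"f{top + 1}"


def _field_term(f: Field) -> VsmTerm:
    return VsmTerm(
        kind="field",
        label=f.value.label if f.value else None,
        id=f.value.id if f.value else None,
        field_id=f.field_id,
        role=f.role,
        placeholder=PLACEHOLDERS[f.role],
    )


def linearize(structure: Structure) -> VsmSentence:
    """Deterministic reading-order serialization of a structure.

    Order: source block (entity, type, compartment, modifications with their
    subfeatures), causal relation, target block, statement context, then
    references and evidence.  The core trident is listed first.
    """
    terms: List[VsmTerm] = []
    connectors: List[VsmConnector] = []

    def emit_field(f: Field) -> int:
        terms.append(_field_term(f))
        return len(terms) - 1

    def emit_rel(label: str) -> int:
        terms.append(VsmTerm(kind="relation", label=label))
        return len(terms) - 1

    def emit_entity(block: EntityBlock) -> int:
        e = emit_field(block.entity)
        if block.biological_type is not None:
            r = emit_rel(REL_IS_A)
            connectors.append(VsmConnector(e, r, emit_field(block.biological_type)))
        if block.compartment is not None:
            r = emit_rel(REL_HAS_COMPARTMENT)
            connectors.append(VsmConnector(e, r, emit_field(block.compartment)))
        for slot in block.modifications:
            r = emit_rel(REL_HAS_MODIF)
            m = emit_field(slot.modification)
            connectors.append(VsmConnector(e, r, m))
            if slot.residue is not None:
                r2 = emit_rel(REL_HAS_RESIDUE)
                connectors.append(VsmConnector(m, r2, emit_field(slot.residue)))
            if slot.position is not None:
                r2 = emit_rel(REL_AT_POSITION)
                connectors.append(VsmConnector(m, r2, emit_field(slot.position)))
        return e

    src = emit_entity(structure.source)
    rel = emit_field(structure.relation)
    tgt = emit_entity(structure.target)
    connectors.insert(0, VsmConnector(src, rel, tgt))
    for role in CONTEXT_ORDER:
        if role in structure.context:
            r = emit_rel(_CONTEXT_LABELS[role])
            connectors.append(VsmConnector(rel, r, emit_field(structure.context[role])))
    for f in structure.references:
        r = emit_rel(REL_REPORTED_IN)
        connectors.append(VsmConnector(rel, r, emit_field(f)))
    for f in structure.evidences:
        r = emit_rel(REL_HAS_EVIDENCE)
        connectors.append(VsmConnector(rel, r, emit_field(f)))
    return VsmSentence(tuple(terms), tuple(connectors))


def parse_structure(sentence: VsmSentence) -> Structure:
    """Recover the structured view by interpreting prefilled relation labels.

    Works on any connector order (not only linearized output).  Raises
    :class:`StructureError` on unrecognised relation labels or ill-shaped
    graphs.
    """
    check_well_formed(sentence)
    terms = sentence.terms

    def as_field(pos: int, what: str) -> Field:
        t = terms[pos]
        if not t.is_field:
            raise StructureError(f"{what} endpoint at {pos} is not a field term")
        value = OntologyTerm(t.id, t.label) if t.id is not None else None
        return Field(t.field_id or f"p{pos}", t.role, value)

    core = None
    for c in sentence.connectors:
        t = terms[c.relation]
        if t.is_field and t.role is FieldRole.CAUSAL_RELATION:
            if core is not None:
                raise StructureError("multiple core causal triples")
            core = c
    if core is None:
        raise StructureError("no core causal triple (causal-relation field "
                             "as relation endpoint) found")

    fields_at: Dict[int, Field] = {}

    def field_at(pos: int, what: str) -> Field:
        if pos not in fields_at:
            fields_at[pos] = as_field(pos, what)
        return fields_at[pos]

    source = EntityBlock(field_at(core.bearer, "source"))
    relation = field_at(core.relation, "relation")
    target = EntityBlock(field_at(core.argument, "target"))
    blocks = {core.bearer: source, core.argument: target}
    structure = Structure(source, relation, target)
    mod_slots: Dict[int, ModSlot] = {}

    deferred: List[VsmConnector] = []
    for c in sentence.connectors:
        if c is core:
            continue
        rel_term = terms[c.relation]
        if rel_term.kind != "relation" or not rel_term.label:
            raise StructureError(
                f"connector {c.endpoints()} relation endpoint is not a "
                "prefilled relation term"
            )
        label = rel_term.label
        if label in (REL_HAS_RESIDUE, REL_AT_POSITION):
            deferred.append(c)
            continue
        if label == REL_HAS_MODIF:
            block = blocks.get(c.bearer)
            if block is None:
                raise StructureError("'has modif.' must be borne by an entity")
            slot = ModSlot(field_at(c.argument, "modification"))
            mod_slots[c.argument] = slot
            block.modifications.append((c.argument, slot))  # sorted below
        elif label == REL_IS_A:
            block = blocks.get(c.bearer)
            if block is None or block.biological_type is not None:
                raise StructureError("'is a' must annotate an entity, once")
            block.biological_type = field_at(c.argument, "biological type")
        elif label == REL_HAS_COMPARTMENT:
            if c.bearer in blocks:
                block = blocks[c.bearer]
                if block.compartment is not None:
                    raise StructureError("entity has two compartments")
                block.compartment = field_at(c.argument, "compartment")
            elif c.bearer == core.relation:
                if FieldRole.COMPARTMENT in structure.context:
                    raise StructureError("statement has two compartments")
                structure.context[FieldRole.COMPARTMENT] = field_at(
                    c.argument, "compartment")
            else:
                raise StructureError("'has compartment' must be borne by an "
                                     "entity or the causal relation")
        elif label == REL_REPORTED_IN:
            if c.bearer != core.relation:
                raise StructureError("'reported in' must be borne by the "
                                     "causal relation")
            structure.references.append((c.argument, field_at(c.argument,
                                                              "reference")))
        elif label == REL_HAS_EVIDENCE:
            if c.bearer != core.relation:
                raise StructureError("'has evidence' must be borne by the "
                                     "causal relation")
            structure.evidences.append((c.argument, field_at(c.argument,
                                                             "evidence")))
        elif label in _LABEL_CONTEXT:
            role = _LABEL_CONTEXT[label]
            if c.bearer != core.relation:
                raise StructureError(f"{label!r} must be borne by the causal "
                                     "relation")
            if role in structure.context:
                raise StructureError(f"duplicate statement context {role.value}")
            structure.context[role] = field_at(c.argument, role.value)
        else:
            raise StructureError(f"unrecognised relation label {label!r}")

    for c in deferred:
        label = terms[c.relation].label
        slot = mod_slots.get(c.bearer)
        if slot is None:
            raise StructureError(f"{label!r} must be borne by a modification")
        f = field_at(c.argument, label)
        if label == REL_HAS_RESIDUE:
            if slot.residue is not None:
                raise StructureError("modification has two residues")
            slot.residue = f
        else:
            if slot.position is not None:
                raise StructureError("modification has two positions")
            slot.position = f

    # restore sentence order within multi-valued groups
    for block in (source, target):
        block.modifications = [s for _, s in sorted(block.modifications,
                                                    key=lambda p: p[0])]
    structure.references = [f for _, f in sorted(structure.references,
                                                 key=lambda p: p[0])]
    structure.evidences = [f for _, f in sorted(structure.evidences,
                                                key=lambda p: p[0])]
    # context order is canonical by construction of the dict insertions
    structure.context = {r: structure.context[r] for r in CONTEXT_ORDER
                         if r in structure.context}
    return structure


# --------------------------------------------------------------------------
# Operations on sentences
# --------------------------------------------------------------------------


def is_complete(sentence: VsmSentence) -> bool:
    """True iff no empty fields remain."""
    return all(t.is_filled for t in sentence.fields)


def fill_field(
    sentence: VsmSentence,
    field_id: str,
    term: "OntologyTerm | int",
    registry: VocabRegistry,
) -> VsmSentence:
    """Fill (or refill) a field with a vocabulary term.

    The term must resolve in the registry and belong to a vocabulary allowed
    for the field's role; a bare positive integer is accepted for position
    fields.  Returns a new sentence.
    """
    pos = sentence.field_position(field_id)
    target = sentence.terms[pos]
    role = target.role
    if isinstance(term, int):
        if role is not FieldRole.POSITION:
            raise FillError(
                f"field {field_id} ({role.value}) cannot take a bare integer"
            )
        term = position_term(term)
    resolved = registry.resolve(term.id)  # raises ResolutionError if unknown
    allowed = registry.allowed_prefixes_for(role)
    if resolved.namespace not in allowed:
        names = ", ".join(sorted(ROLE_VOCABULARIES[role]))
        raise FillError(
            f"term {term.id} is not allowed for role {role.value}; "
            f"allowed vocabularies: {names}"
        )
    new_term = replace(target, label=resolved.label, id=resolved.id)
    terms = list(sentence.terms)
    terms[pos] = new_term
    return VsmSentence(tuple(terms), sentence.connectors)


# --------------------------------------------------------------------------
# VSM-JSON serialization
# --------------------------------------------------------------------------

VSM_JSON_FORMAT = "vsm-json/1"
VSM_JSON_LIGHT_FORMAT = "vsm-json-light/1"


def to_vsm_json(sentence: VsmSentence) -> str:
    """Full, lossless serialization (templates and partial fills included)."""
    terms = []
    for i, t in enumerate(sentence.terms):
        if t.is_field:
            entry: dict = {
                "position": i,
                "type": "field",
                "field_id": t.field_id,
                "role": t.role.value,
                "placeholder": t.placeholder,
                "lookup_roles": [t.role.value],
            }
            if t.is_filled:
                entry["id"] = t.id
                entry["label"] = t.label
        else:
            entry = {"position": i, "type": "relation", "label": t.label}
        terms.append(entry)
    doc = {
        "format": VSM_JSON_FORMAT,
        "terms": terms,
        "connectors": [list(c.endpoints()) for c in sentence.connectors],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def to_vsm_json_light(sentence: VsmSentence) -> str:
    """Lossy projection: identifiers and labels only, no autocomplete
    configuration, placeholders or field ids.  Empty fields keep their role
    so the reader can still see what was left unannotated."""
    terms = []
    for t in sentence.terms:
        if t.is_filled:
            terms.append({"id": t.id, "label": t.label})
        elif t.is_field:
            terms.append({"role": t.role.value})
        else:
            terms.append({"label": t.label})
    doc = {
        "format": VSM_JSON_LIGHT_FORMAT,
        "terms": terms,
        "connectors": [list(c.endpoints()) for c in sentence.connectors],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def from_vsm_json(text: str) -> VsmSentence:
    """Inverse of :func:`to_vsm_json` (the light form is not invertible)."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise VsmJsonError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != VSM_JSON_FORMAT:
        raise VsmJsonError(
            f"not a {VSM_JSON_FORMAT} document (format={doc.get('format')!r})"
            if isinstance(doc, dict) else "not a JSON object"
        )
    raw_terms = doc.get("terms")
    raw_connectors = doc.get("connectors", [])
    if not isinstance(raw_terms, list) or not raw_terms:
        raise VsmJsonError("document has no terms")
    seen_positions = set()
    entries = []
    for entry in raw_terms:
        if not isinstance(entry, dict) or "position" not in entry:
            raise VsmJsonError(f"bad term entry: {entry!r}")
        pos = entry["position"]
        if pos in seen_positions:
            raise VsmJsonError(f"duplicate term position {pos}")
        seen_positions.add(pos)
        entries.append((pos, entry))
    entries.sort(key=lambda p: p[0])
    if [p for p, _ in entries] != list(range(len(entries))):
        raise VsmJsonError("term positions are not consecutive 0-based")
    terms: List[VsmTerm] = []
    for _, entry in entries:
        if entry.get("type") == "relation":
            if not entry.get("label"):
                raise VsmJsonError("relation term without label")
            terms.append(VsmTerm(kind="relation", label=entry["label"]))
        elif entry.get("type") == "field":
            role = FieldRole.coerce(entry.get("role"))
            terms.append(VsmTerm(
                kind="field",
                label=entry.get("label"),
                id=entry.get("id"),
                field_id=entry.get("field_id"),
                role=role,
                placeholder=entry.get("placeholder", PLACEHOLDERS[role]),
            ))
        else:
            raise VsmJsonError(f"unknown term type {entry.get('type')!r}")
    connectors = []
    n = len(terms)
    for c in raw_connectors:
        if (not isinstance(c, list)) or len(c) != 3:
            raise VsmJsonError(f"connector {c!r} is not a trident")
        if any(not isinstance(e, int) or e < 0 or e >= n for e in c):
            raise VsmJsonError(
                f"connector {c!r} attaches outside the term list (0..{n - 1})"
            )
        if len(set(c)) != 3:
            raise VsmJsonError(f"connector {c!r} endpoints are not distinct")
        connectors.append(VsmConnector(*c))
    return VsmSentence(tuple(terms), tuple(connectors))


def canonical_form(sentence: VsmSentence) -> dict:
    """Structure-only form used for graph-isomorphism comparison: field-id
    tokens are dropped; order and connector shape are kept."""
    terms = []
    for t in sentence.terms:
        if t.is_field:
            terms.append(("field", t.role.value, t.id, t.label))
        else:
            terms.append(("relation", t.label))
    return {
        "terms": terms,
        "connectors": sorted(c.endpoints() for c in sentence.connectors),
    }


# --------------------------------------------------------------------------
# Sentence <-> statement conversion
# --------------------------------------------------------------------------


def _require(term: Optional[OntologyTerm], what: str) -> OntologyTerm:
    if term is None:
        raise IncompleteSentenceError(f"{what} field is empty")
    return term


def _entity_from_block(block: EntityBlock) -> BioEntity:
    value = _require(block.entity.value, block.entity.role.value)
    mods = []
    for slot in block.modifications:
        position = None
        if slot.position is not None:
            pos_term = _require(slot.position.value, "position")
            position = int(pos_term.id.split(":", 1)[1])
        mods.append(Modification(
            term=_require(slot.modification.value, "modification"),
            residue=(slot.residue.value if slot.residue is not None else None),
            position=position,
        ))
    return BioEntity(
        id=value.id,
        label=value.label,
        biological_type=(block.biological_type.value
                         if block.biological_type is not None else None),
        modifications=tuple(mods),
        compartment=(block.compartment.value
                     if block.compartment is not None else None),
    )


def sentence_to_statement(sentence: VsmSentence) -> CausalStatement:
    """Interpret a completely filled sentence into a causal statement.

    Triples are read through their prefilled relation labels (``has modif.``
    attaches a modification to its entity, ``reported in`` a reference to the
    statement, and so on)."""
    if not is_complete(sentence):
        empty = [t.field_id for t in sentence.fields if not t.is_filled]
        raise IncompleteSentenceError(
            f"sentence has unfilled fields: {', '.join(map(str, empty))}"
        )
    structure = parse_structure(sentence)
    ctx = {role: f.value for role, f in structure.context.items()}
    return CausalStatement(
        source=_entity_from_block(structure.source),
        target=_entity_from_block(structure.target),
        relation=_require(structure.relation.value, "causal relation"),
        references=tuple(_require(f.value, "reference").id
                         for f in structure.references),
        evidence=tuple(_require(f.value, "evidence")
                       for f in structure.evidences),
        mechanism=ctx.get(FieldRole.MECHANISM),
        compartment=ctx.get(FieldRole.COMPARTMENT),
        cell_line=ctx.get(FieldRole.CELL_LINE),
        cell_type=ctx.get(FieldRole.CELL_TYPE),
        tissue=ctx.get(FieldRole.TISSUE),
        taxon=ctx.get(FieldRole.TAXON),
    )


def _vocab_for_prefix(prefix: str) -> str:
    for name, ns in VOCAB_NAMESPACES.items():
        if ns == prefix:
            return name
    return prefix


def _as_term(term: OntologyTerm) -> OntologyTerm:
    if term.vocabulary:
        return term
    return OntologyTerm(term.id, term.label, _vocab_for_prefix(term.namespace))


def statement_to_sentence(statement: CausalStatement) -> VsmSentence:
    """Build the filled sentence whose interpretation is *statement*.

    The template shape is inferred from the statement's populated slots;
    :func:`sentence_to_statement` inverts this exactly."""
    for what, value in (("source", statement.source),
                        ("target", statement.target),
                        ("relation", statement.relation)):
        if value is None:
            raise InvalidStatementError(f"statement is missing its {what}")
    if not statement.references or not statement.evidence:
        raise InvalidStatementError(
            "statement needs at least one reference and one evidence"
        )

    counter = [0]

    def new_field(role: FieldRole, value: Optional[OntologyTerm]) -> Field:
        counter[0] += 1
        return Field(f"f{counter[0]}", role,
                     _as_term(value) if value is not None else None)

    def entity_block(entity: BioEntity, role: FieldRole) -> EntityBlock:
        block = EntityBlock(new_field(
            role, OntologyTerm(entity.id, entity.label,
                               _vocab_for_prefix(entity.namespace))))
        if entity.biological_type is not None:
            block.biological_type = new_field(FieldRole.BIOLOGICAL_TYPE,
                                              entity.biological_type)
        if entity.compartment is not None:
            block.compartment = new_field(FieldRole.COMPARTMENT,
                                          entity.compartment)
        for mod in entity.modifications:
            slot = ModSlot(new_field(FieldRole.BIOLOGICAL_MODIFICATION,
                                     mod.term))
            if mod.residue is not None:
                slot.residue = new_field(FieldRole.RESIDUE, mod.residue)
            if mod.position is not None:
                slot.position = new_field(FieldRole.POSITION,
                                          position_term(mod.position))
            block.modifications.append(slot)
        return block

    source = entity_block(statement.source, FieldRole.SOURCE_ENTITY)
    relation = new_field(FieldRole.CAUSAL_RELATION, statement.relation)
    target = entity_block(statement.target, FieldRole.TARGET_ENTITY)
    structure = Structure(source, relation, target)
    ctx_slots = {
        FieldRole.MECHANISM: statement.mechanism,
        FieldRole.COMPARTMENT: statement.compartment,
        FieldRole.CELL_LINE: statement.cell_line,
        FieldRole.CELL_TYPE: statement.cell_type,
        FieldRole.TISSUE: statement.tissue,
        FieldRole.TAXON: statement.taxon,
    }
    for role in CONTEXT_ORDER:
        if ctx_slots[role] is not None:
            structure.context[role] = new_field(role, ctx_slots[role])
    for ref in statement.references:
        label = ref.split(":", 1)[1] if ":" in ref else ref
        structure.references.append(new_field(
            FieldRole.REFERENCE,
            OntologyTerm(ref, label, _vocab_for_prefix(
                ref.split(":", 1)[0] if ":" in ref else ""))))
    for ev in statement.evidence:
        structure.evidences.append(new_field(FieldRole.EVIDENCE, ev))
    return linearize(structure)
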