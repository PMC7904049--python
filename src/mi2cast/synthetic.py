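"""Deterministic synthesis of causal statements and feature selections.

Every pipeline stage (template generation, filling, validation, all four
export formats) is testable offline: statements draw their terms only from
the bundled fixture vocabularies, per annotation role.  Generation uses
Python's seeded Mersenne Twister, which is reproducible across processes and
platforms; identical seed and profile always yield the identical statement.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterator, Optional, Tuple

from .errors import Mi2castError
from .model import BioEntity, CausalStatement, Code, Modification
from .template import FeatureSelection, ModificationSpec
from .vocab import (
    FieldRole,
    OntologyTerm,
    VocabRegistry,
    default_registry,
)

# Stable fixture anchors for each slot (ids resolved through the registry so
# a broken fixture file fails loudly).
CAUSAL_RELATION_IDS = (
    "MI:2235", "MI:2236", "MI:2237", "MI:2240", "MI:2241", "MI:2242",
    "RO:0002212", "RO:0002213", "RO:0002629", "RO:0002630",
)
MECHANISM_IDS = ("MI:0217", "MI:0220", "MI:0407")
BIOLOGICAL_TYPE_IDS = ("MI:0326", "MI:0328", "MI:0320", "MI:0319")
MODIFICATION_IDS = ("MOD:00696", "MOD:00394")
RESIDUE_IDS = ("MOD:00046", "MOD:00047", "MOD:00048")


def _choice(rng: random.Random, registry: VocabRegistry,
            ids: Tuple[str, ...]) -> OntologyTerm:
    return registry.resolve(rng.choice(ids))


def _role_terms(registry: VocabRegistry, role: FieldRole) -> Tuple[OntologyTerm, ...]:
    terms = registry.terms_for_role(role)
    if not terms:
        raise Mi2castError(
            f"no fixture vocabulary terms available for role {role.value}"
        )
    return terms


def gen_statement(
    seed: int,
    profile: Optional[FeatureSelection] = None,
    registry: Optional[VocabRegistry] = None,
) -> CausalStatement:
    """Generate a valid statement whose shape follows *profile*.

    The default profile is the minimal mandatory core (one reference, one
    evidence, no optional context).
    """
    profile = profile if profile is not None else FeatureSelection()
    registry = registry or default_registry()
    rng = random.Random(seed)

    def entity(role: FieldRole, biological_type: bool, compartment: bool,
               mods: Tuple[ModificationSpec, ...]) -> BioEntity:
        base = rng.choice(_role_terms(registry, role))
        modifications = []
        for spec in mods:
            modifications.append(Modification(
                term=_choice(rng, registry, MODIFICATION_IDS),
                residue=(_choice(rng, registry, RESIDUE_IDS)
                         if spec.residue else None),
                position=rng.randint(1, 999) if spec.position else None,
            ))
        return BioEntity(
            id=base.id,
            label=base.label,
            biological_type=(_choice(rng, registry, BIOLOGICAL_TYPE_IDS)
                             if biological_type else None),
            modifications=tuple(modifications),
            compartment=(rng.choice(_role_terms(registry,
                                                FieldRole.COMPARTMENT))
                         if compartment else None),
        )

    source = entity(FieldRole.SOURCE_ENTITY, profile.source_biological_type,
                    profile.source_compartment, profile.source_modifications)
    target = entity(FieldRole.TARGET_ENTITY, profile.target_biological_type,
                    profile.target_compartment, profile.target_modifications)
    relation = _choice(rng, registry, CAUSAL_RELATION_IDS)
    references = tuple(f"pubmed:{rng.randint(1_000_000, 9_999_999)}"
                       for _ in range(profile.reference_count))
    evidence = tuple(rng.choice(_role_terms(registry, FieldRole.EVIDENCE))
                     for _ in range(profile.evidence_count))

    def context(role: FieldRole, ids: Optional[Tuple[str, ...]] = None):
        if role not in profile.relation_context:
            return None
        if ids is not None:
            return _choice(rng, registry, ids)
        return rng.choice(_role_terms(registry, role))

    return CausalStatement(
        source=source,
        target=target,
        relation=relation,
        references=references,
        evidence=evidence,
        mechanism=context(FieldRole.MECHANISM, MECHANISM_IDS),
        compartment=context(FieldRole.COMPARTMENT),
        cell_line=context(FieldRole.CELL_LINE),
        cell_type=context(FieldRole.CELL_TYPE),
        tissue=context(FieldRole.TISSUE),
        taxon=context(FieldRole.TAXON),
    )


def gen_invalid(
    seed: int,
    violation: "Code | str",
    registry: Optional[VocabRegistry] = None,
) -> CausalStatement:
    """A statement whose validation report carries exactly the requested
    ERROR code (single-fault construction from a valid statement)."""
    try:
        violation = Code(violation)
    except ValueError:
        raise Mi2castError(f"unknown violation code {violation!r}") from None
    statement = gen_statement(seed, registry=registry)
    if violation is Code.MISSING_SOURCE:
        return CausalStatement(**{**_asdict(statement), "source": None})
    if violation is Code.MISSING_TARGET:
        return CausalStatement(**{**_asdict(statement), "target": None})
    if violation is Code.MISSING_RELATION:
        return CausalStatement(**{**_asdict(statement), "relation": None})
    if violation is Code.MISSING_REFERENCE:
        return CausalStatement(**{**_asdict(statement), "references": ()})
    if violation is Code.MISSING_EVIDENCE:
        return CausalStatement(**{**_asdict(statement), "evidence": ()})
    # VOCAB_VIOLATION: a causal relation outside the PSI-MI / RO namespaces
    bad_relation = OntologyTerm("GO:0005634", "nucleus", "GO")
    return CausalStatement(**{**_asdict(statement), "relation": bad_relation})


def _asdict(statement: CausalStatement) -> dict:
    return {
        "source": statement.source,
        "target": statement.target,
        "relation": statement.relation,
        "references": statement.references,
        "evidence": statement.evidence,
        "mechanism": statement.mechanism,
        "compartment": statement.compartment,
        "cell_line": statement.cell_line,
        "cell_type": statement.cell_type,
        "tissue": statement.tissue,
        "taxon": statement.taxon,
    }


# A rotation of statement shapes used when many varied statements are needed.
_PROFILE_CYCLE: Tuple[FeatureSelection, ...] = (
    FeatureSelection(),
    FeatureSelection(
        source_modifications=(ModificationSpec(residue=True, position=True),),
        relation_context=frozenset({FieldRole.COMPARTMENT}),
    ),
    FeatureSelection(
        source_modifications=(ModificationSpec(position=True),
                              ModificationSpec(residue=True)),
        target_modifications=(ModificationSpec(),),
        source_biological_type=True,
        target_compartment=True,
        reference_count=2,
        evidence_count=3,
    ),
    FeatureSelection(
        source_biological_type=True,
        target_biological_type=True,
        relation_context=frozenset({
            FieldRole.MECHANISM, FieldRole.CELL_LINE, FieldRole.CELL_TYPE,
            FieldRole.TISSUE, FieldRole.TAXON,
        }),
        reference_count=2,
    ),
    FeatureSelection(
        source_compartment=True,
        target_modifications=(ModificationSpec(residue=True),),
        relation_context=frozenset({FieldRole.TAXON, FieldRole.COMPARTMENT}),
        evidence_count=2,
    ),
)


def gen_corpus(
    seed: int,
    n: int,
    registry: Optional[VocabRegistry] = None,
) -> Tuple[CausalStatement, ...]:
    """*n* varied valid statements covering every optional field class."""
    return tuple(
        gen_statement(seed + i, _PROFILE_CYCLE[i % len(_PROFILE_CYCLE)],
                      registry)
        for i in range(n)
    )


def enumerate_selections(
    max_counter: int,
    max_modifications: int,
) -> Iterator[FeatureSelection]:
    """Exhaustive, duplicate-free, deterministically ordered enumeration of
    feature selections within the given bounds.

    Axes: entity flags per side (type/compartment), statement-context
    subsets, reference and evidence counters in ``1..max_counter``, and per
    side every ordered tuple of up to ``max_modifications`` modification
    specs with all subfeature subsets.  Yielded lazily: the cross product
    grows combinatorially with the bounds.
    """
    if max_counter < 1 or max_modifications < 0:
        raise Mi2castError("bounds must be >= 1 counter, >= 0 modifications")
    flag_pairs = list(itertools.product((False, True), repeat=2))
    context_subsets = [
        frozenset(c)
        for r in range(len(_ALL_CONTEXT) + 1)
        for c in itertools.combinations(_ALL_CONTEXT, r)
    ]
    mod_specs = [ModificationSpec(r, p)
                 for r, p in itertools.product((False, True), repeat=2)]
    mod_tuples = [
        combo
        for k in range(max_modifications + 1)
        for combo in itertools.product(mod_specs, repeat=k)
    ]
    counters = range(1, max_counter + 1)
    for src_flags in flag_pairs:
        for tgt_flags in flag_pairs:
            for context in context_subsets:
                for ref_count in counters:
                    for ev_count in counters:
                        for src_mods in mod_tuples:
                            for tgt_mods in mod_tuples:
                                yield FeatureSelection(
                                    source_modifications=src_mods,
                                    target_modifications=tgt_mods,
                                    source_biological_type=src_flags[0],
                                    source_compartment=src_flags[1],
                                    target_biological_type=tgt_flags[0],
                                    target_compartment=tgt_flags[1],
                                    relation_context=context,
                                    reference_count=ref_count,
                                    evidence_count=ev_count,
                                )


_ALL_CONTEXT = (
    FieldRole.MECHANISM,
    FieldRole.COMPARTMENT,
    FieldRole.CELL_LINE,
    FieldRole.CELL_TYPE,
    FieldRole.TISSUE,
    FieldRole.TAXON,
)
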