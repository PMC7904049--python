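"""MI2CAST causal-statement domain model and compliance validator.

A causal statement asserts that a *source* biological entity regulates the
activity or quantity of a *target* entity.  MI2CAST's mandatory core is:
source entity, target entity, causal relation, at least one literature
reference and at least one evidence type.  Everything else — entity types,
compartments, protein modifications (with residue/position subfeatures),
mechanism, cell line, cell type, tissue, taxon — is optional context.

Validation never raises on content problems; it produces a
:class:`ValidationReport` whose ERROR-severity entries correspond exactly to
broken mandatory rules, so that downstream platforms can map violation codes
onto their own quality control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import Mi2castError
from .vocab import (
    FieldRole,
    OntologyTerm,
    VocabRegistry,
    default_registry,
)

#: CURIE prefixes accepted for literature references.
REFERENCE_PREFIXES = frozenset({"pubmed", "doi"})


@dataclass(frozen=True)
class Modification:
    """A protein modification with optional residue and 1-based position.

    Residue and position are subfeatures: they exist only attached to a
    modification, never free-standing.
    """

    term: OntologyTerm
    residue: Optional[OntologyTerm] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position is not None and (
            not isinstance(self.position, int) or self.position < 1
        ):
            raise Mi2castError(
                f"modification position must be >= 1, got {self.position!r}"
            )


@dataclass(frozen=True)
class BioEntity:
    """A biological entity: identifier, label and optional annotations."""

    id: str
    label: str
    biological_type: Optional[OntologyTerm] = None
    modifications: Tuple[Modification, ...] = ()
    compartment: Optional[OntologyTerm] = None

    def __post_init__(self) -> None:
        if not self.id or not self.label:
            raise Mi2castError("entity id and label must be non-empty")
        object.__setattr__(self, "modifications", tuple(self.modifications))

    @property
    def namespace(self) -> str:
        return self.id.split(":", 1)[0] if ":" in self.id else ""


@dataclass(frozen=True)
class CausalStatement:
    """One annotated molecular causal interaction.

    Mandatory slots may be ``None``/empty so that non-compliant statements can
    be represented and *reported on*; use :func:`validate` / :func:`is_valid`.
    References are CURIEs in a publication namespace (``pubmed:``/``doi:``).
    """

    source: Optional[BioEntity] = None
    target: Optional[BioEntity] = None
    relation: Optional[OntologyTerm] = None
    references: Tuple[str, ...] = ()
    evidence: Tuple[OntologyTerm, ...] = ()
    mechanism: Optional[OntologyTerm] = None
    compartment: Optional[OntologyTerm] = None
    cell_line: Optional[OntologyTerm] = None
    cell_type: Optional[OntologyTerm] = None
    tissue: Optional[OntologyTerm] = None
    taxon: Optional[OntologyTerm] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "references", tuple(self.references))
        object.__setattr__(self, "evidence", tuple(self.evidence))

    def context_items(self) -> Tuple[Tuple[str, OntologyTerm], ...]:
        """Populated statement-level context as (name, term) pairs."""
        pairs = []
        for name in ("mechanism", "compartment", "cell_line", "cell_type",
                     "tissue", "taxon"):
            term = getattr(self, name)
            if term is not None:
                pairs.append((name, term))
        return tuple(pairs)


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


class Code(str, enum.Enum):
    """Frozen violation codes (part of the public interface)."""

    MISSING_SOURCE = "MISSING_SOURCE"
    MISSING_TARGET = "MISSING_TARGET"
    MISSING_RELATION = "MISSING_RELATION"
    MISSING_REFERENCE = "MISSING_REFERENCE"
    MISSING_EVIDENCE = "MISSING_EVIDENCE"
    VOCAB_VIOLATION = "VOCAB_VIOLATION"


@dataclass(frozen=True)
class Violation:
    code: Code
    severity: Severity
    message: str
    path: str


@dataclass(frozen=True)
class ValidationReport:
    violations: Tuple[Violation, ...] = ()

    @property
    def errors(self) -> Tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity is Severity.ERROR)

    @property
    def warnings(self) -> Tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity is Severity.WARNING)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        if not self.violations:
            return "OK: statement satisfies all mandatory rules"
        return "\n".join(
            f"{v.severity.value} {v.code.value} at {v.path}: {v.message}"
            for v in self.violations
        )


def _term_prefix(term: OntologyTerm) -> str:
    return term.id.split(":", 1)[0]


def validate(
    statement: CausalStatement,
    registry: Optional[VocabRegistry] = None,
) -> ValidationReport:
    """Check a statement against the mandatory and optional annotation rules.

    One ERROR per missing mandatory element; one ERROR per relation or
    evidence term whose namespace falls outside the vocabularies allowed for
    its role; WARNINGs for optional-context terms in unexpected namespaces.
    The report is deterministic and ordered by field path (source block,
    target block, relation, references, evidence, statement context).
    """
    registry = registry or default_registry()
    out: list[Violation] = []

    def err(code: Code, path: str, message: str) -> None:
        out.append(Violation(code, Severity.ERROR, message, path))

    def warn(path: str, message: str) -> None:
        out.append(Violation(Code.VOCAB_VIOLATION, Severity.WARNING, message, path))

    def check_term(term: OntologyTerm, role: FieldRole, path: str,
                   severity: Severity) -> None:
        allowed = registry.allowed_prefixes_for(role)
        prefix = _term_prefix(term)
        if prefix not in allowed:
            msg = (
                f"term {term.id} is outside the vocabularies allowed for "
                f"{role.value} (namespaces: {', '.join(sorted(allowed))})"
            )
            if severity is Severity.ERROR:
                err(Code.VOCAB_VIOLATION, path, msg)
            else:
                warn(path, msg)

    def check_entity(entity: Optional[BioEntity], path: str,
                     missing_code: Code) -> None:
        if entity is None:
            err(missing_code, path, f"{path} entity is required")
            return
        role = (FieldRole.SOURCE_ENTITY if path == "source"
                else FieldRole.TARGET_ENTITY)
        if ":" in entity.id:
            check_term(OntologyTerm(entity.id, entity.label), role, path,
                       Severity.WARNING)
        if entity.biological_type is not None:
            check_term(entity.biological_type, FieldRole.BIOLOGICAL_TYPE,
                       f"{path}.biological_type", Severity.WARNING)
        if entity.compartment is not None:
            check_term(entity.compartment, FieldRole.COMPARTMENT,
                       f"{path}.compartment", Severity.WARNING)
        for i, mod in enumerate(entity.modifications):
            check_term(mod.term, FieldRole.BIOLOGICAL_MODIFICATION,
                       f"{path}.modifications[{i}]", Severity.WARNING)
            if mod.residue is not None:
                check_term(mod.residue, FieldRole.RESIDUE,
                           f"{path}.modifications[{i}].residue",
                           Severity.WARNING)

    check_entity(statement.source, "source", Code.MISSING_SOURCE)
    check_entity(statement.target, "target", Code.MISSING_TARGET)

    if statement.relation is None:
        err(Code.MISSING_RELATION, "relation", "a causal relation is required")
    else:
        check_term(statement.relation, FieldRole.CAUSAL_RELATION, "relation",
                   Severity.ERROR)

    if not statement.references:
        err(Code.MISSING_REFERENCE, "references",
            "at least one reference is required")
    else:
        for i, ref in enumerate(statement.references):
            prefix = ref.split(":", 1)[0] if ":" in ref else ""
            if prefix not in REFERENCE_PREFIXES:
                warn(f"references[{i}]",
                     f"reference {ref!r} is not in a recognised publication "
                     f"namespace ({', '.join(sorted(REFERENCE_PREFIXES))})")

    if not statement.evidence:
        err(Code.MISSING_EVIDENCE, "evidence",
            "at least one evidence type is required")
    else:
        for i, term in enumerate(statement.evidence):
            check_term(term, FieldRole.EVIDENCE, f"evidence[{i}]",
                       Severity.ERROR)

    context_roles = {
        "mechanism": FieldRole.MECHANISM,
        "compartment": FieldRole.COMPARTMENT,
        "cell_line": FieldRole.CELL_LINE,
        "cell_type": FieldRole.CELL_TYPE,
        "tissue": FieldRole.TISSUE,
        "taxon": FieldRole.TAXON,
    }
    for name, term in statement.context_items():
        check_term(term, context_roles[name], name, Severity.WARNING)

    return ValidationReport(tuple(out))


def is_valid(
    statement: CausalStatement,
    registry: Optional[VocabRegistry] = None,
) -> bool:
    """True iff the statement has no ERROR-severity violations."""
    return validate(statement, registry).ok


def statement_summary(statement: CausalStatement) -> str:
    """One-line human-readable rendering (purely presentational)."""
    src = statement.source.label if statement.source else "?"
    tgt = statement.target.label if statement.target else "?"
    rel = statement.relation.label if statement.relation else "?"
    n_ctx = len(statement.context_items())
    for entity in (statement.source, statement.target):
        if entity is not None:
            n_ctx += len(entity.modifications)
            n_ctx += sum(
                x is not None for x in (entity.biological_type, entity.compartment)
            )
    return (
        f"{src} —{rel}→ {tgt} "
        f"[{len(statement.references)} reference(s), "
        f"{len(statement.evidence)} evidence, {n_ctx} context]"
    )
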