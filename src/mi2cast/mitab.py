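"""CausalTAB (PSI-MITAB2.8) writer and reader.

PSI-MITAB2.8 extends the 42-column MITAB2.7 layout with four causal columns
(biological effect of interactors A and B, causal regulatory mechanism,
causal statement), for a fixed width of 46 tab-separated columns.  Cells are
pipe-separated multi-values; ``-`` denotes an empty cell; tokens containing
reserved characters are double-quoted with backslash escaping.

This is a *lossy* export: only the subset of a statement with a MITAB column
is written (see ``docs/causaltab.md`` for the frozen field map), and every
dropped field is named in the record's lossiness log.  ``read_causaltab``
recovers exactly the mapped subset, so write∘read is the identity on
``mitab_projection`` of a statement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .errors import ExportError, MitabParseError
from .model import BioEntity, CausalStatement, validate
from .vocab import OntologyTerm, VocabRegistry, default_registry

#: Frozen PSI-MITAB2.8 column names, in order.
COLUMNS: Tuple[str, ...] = (
    "ID(s) interactor A",
    "ID(s) interactor B",
    "Alt. ID(s) interactor A",
    "Alt. ID(s) interactor B",
    "Alias(es) interactor A",
    "Alias(es) interactor B",
    "Interaction detection method(s)",
    "Publication 1st author(s)",
    "Publication Identifier(s)",
    "Taxid interactor A",
    "Taxid interactor B",
    "Interaction type(s)",
    "Source database(s)",
    "Interaction identifier(s)",
    "Confidence value(s)",
    "Expansion method(s)",
    "Biological role(s) interactor A",
    "Biological role(s) interactor B",
    "Experimental role(s) interactor A",
    "Experimental role(s) interactor B",
    "Type(s) interactor A",
    "Type(s) interactor B",
    "Xref(s) interactor A",
    "Xref(s) interactor B",
    "Interaction Xref(s)",
    "Annotation(s) interactor A",
    "Annotation(s) interactor B",
    "Interaction annotation(s)",
    "Host organism(s)",
    "Interaction parameter(s)",
    "Creation date",
    "Update date",
    "Checksum(s) interactor A",
    "Checksum(s) interactor B",
    "Interaction Checksum(s)",
    "Negative",
    "Feature(s) interactor A",
    "Feature(s) interactor B",
    "Stoichiometry(s) interactor A",
    "Stoichiometry(s) interactor B",
    "Identification method participant A",
    "Identification method participant B",
    "Biological effect of interactor A",
    "Biological effect of interactor B",
    "Causal regulatory mechanism",
    "Causal statement",
)

N_COLUMNS = len(COLUMNS)
EMPTY = "-"

# CURIE prefix <-> MITAB database label
_DB_FOR_PREFIX = {
    "MI": "psi-mi",
    "MOD": "psi-mod",
    "ECO": "eco",
    "GO": "go",
    "RO": "ro",
    "NCBITaxon": "taxid",
}
_PREFIX_FOR_DB = {db: prefix for prefix, db in _DB_FOR_PREFIX.items()}

_RESERVED = set('|():"\t\n\\')


class MitabWarning(UserWarning):
    pass


# --- token quoting --------------------------------------------------------


def _quote(token: str) -> str:
    if any(ch in _RESERVED for ch in token) or not token:
        escaped = token.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    return token


def _split_quoted(text: str, sep: str) -> List[str]:
    """Split on *sep* outside double quotes, keeping cell text verbatim."""
    parts: List[str] = []
    buf: List[str] = []
    in_quotes = False
    i = 0
    while i < len(text):
        ch = text[i]
        if in_quotes:
            if ch == "\\" and i + 1 < len(text):
                buf.append(ch)
                buf.append(text[i + 1])
                i += 2
                continue
            if ch == '"':
                in_quotes = False
        elif ch == '"':
            in_quotes = True
        elif ch == sep:
            parts.append("".join(buf))
            buf = []
            i += 1
            continue
        buf.append(ch)
        i += 1
    parts.append("".join(buf))
    return parts


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.i = 0

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def token(self, stop: str) -> str:
        """Read one possibly-quoted token, stopping at any char in *stop*."""
        if self.peek() == '"':
            self.i += 1
            out: List[str] = []
            while self.i < len(self.text):
                ch = self.text[self.i]
                if ch == "\\" and self.i + 1 < len(self.text):
                    out.append(self.text[self.i + 1])
                    self.i += 2
                    continue
                if ch == '"':
                    self.i += 1
                    return "".join(out)
                out.append(ch)
                self.i += 1
            raise MitabParseError("unterminated quoted token")
        out = []
        while self.i < len(self.text) and self.text[self.i] not in stop:
            out.append(self.text[self.i])
            self.i += 1
        return "".join(out)


def _format_xref(db: str, identifier: str, label: Optional[str] = None) -> str:
    text = f"{db}:{_quote(identifier)}"
    if label is not None:
        text += f"({_quote(label)})"
    return text


def _parse_xref(value: str) -> Tuple[str, str, Optional[str]]:
    scanner = _Scanner(value)
    db = scanner.token(":")
    if scanner.peek() != ":":
        raise MitabParseError(f"not a db:id cross-reference: {value!r}")
    scanner.i += 1
    identifier = scanner.token("(")
    label: Optional[str] = None
    if scanner.peek() == "(":
        scanner.i += 1
        label = scanner.token(")")
        if scanner.peek() != ")":
            raise MitabParseError(f"unterminated label in {value!r}")
        scanner.i += 1
    if not db or not identifier:
        raise MitabParseError(f"not a db:id cross-reference: {value!r}")
    return db, identifier, label


def _term_xref(term: OntologyTerm) -> str:
    prefix, local = term.id.split(":", 1)
    db = _DB_FOR_PREFIX.get(prefix)
    if db == "taxid":
        return _format_xref(db, local, term.label)
    if db is not None:
        return _format_xref(db, term.id, term.label)
    return _format_xref(prefix, local, term.label)


def _xref_term(value: str) -> OntologyTerm:
    db, identifier, label = _parse_xref(value)
    prefix = _PREFIX_FOR_DB.get(db)
    if prefix == "NCBITaxon":
        curie = f"NCBITaxon:{identifier}"
    elif prefix is not None:
        curie = identifier if ":" in identifier else f"{prefix}:{identifier}"
    else:
        curie = identifier if ":" in identifier else f"{db}:{identifier}"
    if label is None:
        try:
            return default_registry().resolve(curie)
        except Exception:
            warnings.warn(
                f"no label for {curie} and not resolvable from fixtures; "
                "using the identifier as label",
                MitabWarning,
                stacklevel=4,
            )
            label = curie
    return OntologyTerm(curie, label)


# --- record construction --------------------------------------------------


@dataclass(frozen=True)
class MitabRecord:
    """One CausalTAB data row plus its lossiness log."""

    columns: Tuple[str, ...]
    dropped: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.columns) != N_COLUMNS:
            raise ExportError(
                f"record has {len(self.columns)} columns, expected {N_COLUMNS}"
            )

    def to_line(self) -> str:
        return "\t".join(self.columns)


def _entity_dropped(entity: BioEntity, side: str) -> List[str]:
    out = []
    if entity.compartment is not None:
        out.append(f"{side}.compartment")
    for i, mod in enumerate(entity.modifications):
        out.append(f"{side}.modifications[{i}]")
        if mod.residue is not None:
            out.append(f"{side}.modifications[{i}].residue")
        if mod.position is not None:
            out.append(f"{side}.modifications[{i}].position")
    return out


def dropped_fields(statement: CausalStatement) -> Tuple[str, ...]:
    """Populated fields that have no CausalTAB column (the lossiness log)."""
    out: List[str] = []
    out += _entity_dropped(statement.source, "source")
    out += _entity_dropped(statement.target, "target")
    for name in ("compartment", "cell_line", "cell_type", "tissue"):
        if getattr(statement, name) is not None:
            out.append(name)
    return tuple(out)


def mitab_projection(statement: CausalStatement) -> CausalStatement:
    """The statement restricted to the CausalTAB-representable subset."""
    return replace(
        statement,
        source=replace(statement.source, modifications=(), compartment=None),
        target=replace(statement.target, modifications=(), compartment=None),
        compartment=None,
        cell_line=None,
        cell_type=None,
        tissue=None,
    )


def _entity_columns(entity: BioEntity) -> Tuple[str, str, str]:
    """(ids, aliases, type) cells for one interactor."""
    if ":" in entity.id:
        db, local = entity.id.split(":", 1)
    else:
        db, local = "unknown", entity.id
    ids = _format_xref(db, local)
    alias = f"{db}:{_quote(entity.label)}(display_short)"
    itype = (_term_xref(entity.biological_type)
             if entity.biological_type is not None else EMPTY)
    return ids, alias, itype


def statement_to_mitab(statement: CausalStatement) -> MitabRecord:
    """Map one valid statement onto a fixed-width CausalTAB record.

    Fields without a column are dropped and named in ``record.dropped``.
    """
    cells = [EMPTY] * N_COLUMNS
    ids_a, alias_a, type_a = _entity_columns(statement.source)
    ids_b, alias_b, type_b = _entity_columns(statement.target)
    cells[0] = ids_a
    cells[1] = ids_b
    cells[4] = alias_a
    cells[5] = alias_b
    cells[6] = "|".join(_term_xref(t) for t in statement.evidence) or EMPTY
    cells[8] = "|".join(_quote(r) if any(c in _RESERVED for c in r) else r
                        for r in statement.references) or EMPTY
    if statement.taxon is not None:
        taxid = _term_xref(statement.taxon)
        cells[9] = taxid
        cells[10] = taxid
    cells[20] = type_a
    cells[21] = type_b
    cells[35] = "false"
    if statement.mechanism is not None:
        cells[44] = _term_xref(statement.mechanism)
    cells[45] = _term_xref(statement.relation)
    return MitabRecord(tuple(cells), dropped_fields(statement))


def write_causaltab(
    statements: Sequence[CausalStatement],
    include_header: bool = True,
    registry: Optional[VocabRegistry] = None,
) -> str:
    """Serialize statements to CausalTAB text (newline-terminated rows)."""
    for i, statement in enumerate(statements):
        report = validate(statement, registry)
        if not report.ok:
            codes = ", ".join(v.code.value for v in report.errors)
            raise ExportError(
                f"statement {i} is not exportable; violations: {codes}"
            )
    lines = []
    if include_header:
        lines.append("#" + "\t".join(COLUMNS))
    lines.extend(statement_to_mitab(s).to_line() for s in statements)
    return "".join(line + "\n" for line in lines)


# --- reading --------------------------------------------------------------


def _cell_values(cell: str) -> List[str]:
    cell = cell.strip()
    if cell in (EMPTY, ""):
        return []
    return _split_quoted(cell, "|")


def _unquote(token: str) -> str:
    scanner = _Scanner(token)
    return scanner.token("")


def record_from_line(line: str, lineno: int = 0) -> MitabRecord:
    cells = _split_quoted(line.rstrip("\n"), "\t")
    if len(cells) != N_COLUMNS:
        raise MitabParseError(
            f"row has {len(cells)} columns, expected {N_COLUMNS}", lineno
        )
    return MitabRecord(tuple(cells))


def _entity_from_cells(ids: str, aliases: str, itype: str) -> BioEntity:
    id_values = _cell_values(ids)
    if not id_values:
        raise MitabParseError("interactor identifier cell is empty")
    db, identifier, _ = _parse_xref(id_values[0])
    entity_id = identifier if ":" in identifier else f"{db}:{identifier}"
    label = identifier
    for alias in _cell_values(aliases):
        a_db, a_id, a_type = _parse_xref(alias)
        if a_type in (None, "display_short", "display_long"):
            label = a_id
            break
    type_values = _cell_values(itype)
    return BioEntity(
        id=entity_id,
        label=label,
        biological_type=_xref_term(type_values[0]) if type_values else None,
    )


def record_to_statement(record: MitabRecord) -> CausalStatement:
    cells = record.columns
    source = _entity_from_cells(cells[0], cells[4], cells[20])
    target = _entity_from_cells(cells[1], cells[5], cells[21])
    evidence = tuple(_xref_term(v) for v in _cell_values(cells[6]))
    references = tuple(_unquote(v) for v in _cell_values(cells[8]))
    taxon_values = _cell_values(cells[9])
    mech_values = _cell_values(cells[44])
    relation_values = _cell_values(cells[45])
    return CausalStatement(
        source=source,
        target=target,
        relation=_xref_term(relation_values[0]) if relation_values else None,
        references=references,
        evidence=evidence,
        mechanism=_xref_term(mech_values[0]) if mech_values else None,
        taxon=_xref_term(taxon_values[0]) if taxon_values else None,
    )


def read_causaltab(text: str) -> List[CausalStatement]:
    """Parse CausalTAB text; ``#``-prefixed lines are headers/comments."""
    statements = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        record = record_from_line(line, lineno)
        try:
            statements.append(record_to_statement(record))
        except MitabParseError as exc:
            raise MitabParseError(str(exc), lineno) from exc
    return statements
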