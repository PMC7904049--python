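"""Lossless causal-JSON reader/writer.

The document is ``{"format_version": "1.0", "statements": [...]}``; every
populated field of a statement is represented, terms always as
``{"id", "label"}`` objects (never bare strings) so the term+identifier
couple survives the round trip.  Reading tolerates unknown keys (warned and
ignored) and reports schema violations with a JSON-path locator.  A
descriptive schema document ships in ``docs/causal-json.schema.json``.
"""

from __future__ import annotations

import json
import warnings
from typing import List, Optional, Sequence

from .errors import CausalJsonError, ExportError
from .model import (
    BioEntity,
    CausalStatement,
    Modification,
    validate,
)
from .vocab import OntologyTerm, VocabRegistry

FORMAT_VERSION = "1.0"

_STATEMENT_KEYS = {
    "source", "target", "relation", "references", "evidence",
    "mechanism", "compartment", "cell_line", "cell_type", "tissue", "taxon",
}
_ENTITY_KEYS = {"id", "label", "biological_type", "modifications", "compartment"}
_MODIFICATION_KEYS = {"term", "residue", "position"}
_TERM_KEYS = {"id", "label"}


class UnknownKeyWarning(UserWarning):
    """An input document carried a vendor/unknown key that was ignored."""


def _term_to_json(term: OntologyTerm) -> dict:
    return {"id": term.id, "label": term.label}


def _entity_to_json(entity: BioEntity) -> dict:
    doc: dict = {"id": entity.id, "label": entity.label}
    if entity.biological_type is not None:
        doc["biological_type"] = _term_to_json(entity.biological_type)
    if entity.modifications:
        mods = []
        for mod in entity.modifications:
            m: dict = {"term": _term_to_json(mod.term)}
            if mod.residue is not None:
                m["residue"] = _term_to_json(mod.residue)
            if mod.position is not None:
                m["position"] = mod.position
            mods.append(m)
        doc["modifications"] = mods
    if entity.compartment is not None:
        doc["compartment"] = _term_to_json(entity.compartment)
    return doc


def statement_to_json(statement: CausalStatement) -> dict:
    doc: dict = {
        "source": _entity_to_json(statement.source),
        "target": _entity_to_json(statement.target),
        "relation": _term_to_json(statement.relation),
        "references": [{"id": ref} for ref in statement.references],
        "evidence": [_term_to_json(t) for t in statement.evidence],
    }
    for name, term in statement.context_items():
        doc[name] = _term_to_json(term)
    return doc


def write_causal_json(
    statements: Sequence[CausalStatement],
    registry: Optional[VocabRegistry] = None,
) -> str:
    """Serialize valid statements to a causal-JSON document.

    Raises :class:`ExportError` listing the violation codes if any statement
    breaks a mandatory rule.
    """
    for i, statement in enumerate(statements):
        report = validate(statement, registry)
        if not report.ok:
            codes = ", ".join(v.code.value for v in report.errors)
            raise ExportError(
                f"statement {i} is not exportable; violations: {codes}"
            )
    doc = {
        "format_version": FORMAT_VERSION,
        "statements": [statement_to_json(s) for s in statements],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


# --- reading --------------------------------------------------------------


def _fail(path: str, message: str) -> "CausalJsonError":
    return CausalJsonError(f"at {path}: {message}")


def _check_unknown(doc: dict, known: set, path: str) -> None:
    unknown = set(doc) - known
    if unknown:
        warnings.warn(
            f"ignoring unknown keys at {path}: {sorted(unknown)}",
            UnknownKeyWarning,
            stacklevel=3,
        )


def _parse_term(doc, path: str) -> OntologyTerm:
    if not isinstance(doc, dict):
        raise _fail(path, "term must be an object with 'id' and 'label'")
    _check_unknown(doc, _TERM_KEYS, path)
    for key in ("id", "label"):
        if not isinstance(doc.get(key), str) or not doc[key]:
            raise _fail(f"{path}.{key}", "missing or empty")
    try:
        return OntologyTerm(doc["id"], doc["label"])
    except Exception as exc:
        raise _fail(path, str(exc)) from exc


def _parse_entity(doc, path: str) -> BioEntity:
    if not isinstance(doc, dict):
        raise _fail(path, "entity must be an object")
    _check_unknown(doc, _ENTITY_KEYS, path)
    for key in ("id", "label"):
        if not isinstance(doc.get(key), str) or not doc[key]:
            raise _fail(f"{path}.{key}", "missing or empty")
    mods: List[Modification] = []
    raw_mods = doc.get("modifications", [])
    if not isinstance(raw_mods, list):
        raise _fail(f"{path}.modifications", "must be a list")
    for i, m in enumerate(raw_mods):
        mpath = f"{path}.modifications[{i}]"
        if not isinstance(m, dict):
            raise _fail(mpath, "must be an object")
        _check_unknown(m, _MODIFICATION_KEYS, mpath)
        if "term" not in m:
            raise _fail(f"{mpath}.term", "missing")
        position = m.get("position")
        if position is not None and (
            not isinstance(position, int) or position < 1
        ):
            raise _fail(f"{mpath}.position", "must be a positive integer")
        mods.append(Modification(
            term=_parse_term(m["term"], f"{mpath}.term"),
            residue=(_parse_term(m["residue"], f"{mpath}.residue")
                     if "residue" in m else None),
            position=position,
        ))
    return BioEntity(
        id=doc["id"],
        label=doc["label"],
        biological_type=(_parse_term(doc["biological_type"],
                                     f"{path}.biological_type")
                         if "biological_type" in doc else None),
        modifications=tuple(mods),
        compartment=(_parse_term(doc["compartment"], f"{path}.compartment")
                     if "compartment" in doc else None),
    )


def statement_from_json(doc, path: str = "statement") -> CausalStatement:
    if not isinstance(doc, dict):
        raise _fail(path, "statement must be an object")
    _check_unknown(doc, _STATEMENT_KEYS, path)
    for key in ("source", "target", "relation", "references", "evidence"):
        if key not in doc:
            raise _fail(f"{path}.{key}", "missing mandatory key")
    raw_refs = doc["references"]
    if not isinstance(raw_refs, list) or not raw_refs:
        raise _fail(f"{path}.references", "must be a non-empty list")
    references = []
    for i, ref in enumerate(raw_refs):
        if not isinstance(ref, dict) or not isinstance(ref.get("id"), str):
            raise _fail(f"{path}.references[{i}]", "must be {'id': <CURIE>}")
        _check_unknown(ref, {"id"}, f"{path}.references[{i}]")
        references.append(ref["id"])
    raw_ev = doc["evidence"]
    if not isinstance(raw_ev, list) or not raw_ev:
        raise _fail(f"{path}.evidence", "must be a non-empty list")
    evidence = tuple(_parse_term(t, f"{path}.evidence[{i}]")
                     for i, t in enumerate(raw_ev))

    def context(name: str) -> Optional[OntologyTerm]:
        if name in doc:
            return _parse_term(doc[name], f"{path}.{name}")
        return None

    return CausalStatement(
        source=_parse_entity(doc["source"], f"{path}.source"),
        target=_parse_entity(doc["target"], f"{path}.target"),
        relation=_parse_term(doc["relation"], f"{path}.relation"),
        references=tuple(references),
        evidence=evidence,
        mechanism=context("mechanism"),
        compartment=context("compartment"),
        cell_line=context("cell_line"),
        cell_type=context("cell_type"),
        tissue=context("tissue"),
        taxon=context("taxon"),
    )


def read_causal_json(text: str) -> List[CausalStatement]:
    """Parse a causal-JSON document into statements.

    ``read_causal_json(write_causal_json(S)) == S`` for every valid list of
    statements (lossless round trip).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CausalJsonError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise _fail("$", "document must be an object")
    _check_unknown(doc, {"format_version", "statements"}, "$")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise _fail("$.format_version",
                    f"unsupported version {version!r} (expected "
                    f"{FORMAT_VERSION!r})")
    raw = doc.get("statements")
    if not isinstance(raw, list):
        raise _fail("$.statements", "must be a list")
    return [statement_from_json(s, f"$.statements[{i}]")
            for i, s in enumerate(raw)]
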