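"""Controlled-vocabulary registry with offline fixture dictionaries.

The atomic annotation unit is an :class:`OntologyTerm`: a CURIE identifier
coupled with a human-readable label, drawn from a named vocabulary.  A
:class:`VocabRegistry` holds several vocabularies and offers identifier
resolution plus autocomplete-style lookup restricted per annotation role,
emulating a unified query layer over biological dictionaries (ontologies and
controlled vocabularies) without any network access.

Bundled fixture vocabularies (small curated subsets shipped as TSV):

* PSI-MI (``MI:``) — causal relations (e.g. ``MI:2235`` *up-regulates*),
  mechanisms and interactor types;
* Relation Ontology (``RO:``) — regulatory relations;
* ECO (``ECO:``) — evidence types;
* GO cellular component (``GO:``) — compartments;
* PSI-MOD (``MOD:``) — protein modifications and modified residues;
* a UniProt-like entity subset (``uniprot:``), BTO, CL and NCBI Taxonomy
  subsets for biological context.

Two *open* namespaces accept any well-formed local identifier without an
enumerated term list: ``pubmed:`` for literature references and
``position:`` for 1-based sequence positions (kept as a pseudo-CURIE so that
every filled field is a term+identifier couple).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Tuple

from .errors import (
    DuplicateNamespaceError,
    NormalizationError,
    ResolutionError,
    UnknownRoleError,
    VocabError,
)


class FieldRole(str, enum.Enum):
    """Annotation roles a template field can play."""

    SOURCE_ENTITY = "source_entity"
    TARGET_ENTITY = "target_entity"
    CAUSAL_RELATION = "causal_relation"
    REFERENCE = "reference"
    EVIDENCE = "evidence"
    BIOLOGICAL_TYPE = "biological_type"
    BIOLOGICAL_MODIFICATION = "biological_modification"
    RESIDUE = "residue"
    POSITION = "position"
    COMPARTMENT = "compartment"
    MECHANISM = "mechanism"
    CELL_LINE = "cell_line"
    CELL_TYPE = "cell_type"
    TISSUE = "tissue"
    TAXON = "taxon"

    @classmethod
    def coerce(cls, value: "FieldRole | str") -> "FieldRole":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise UnknownRoleError(f"unknown field role: {value!r}") from None


@dataclass(frozen=True)
class OntologyTerm:
    """A term+identifier couple.

    Identity (equality/hashing) is the couple itself: ``id`` and ``label``.
    ``vocabulary`` and ``description`` are carried metadata.
    """

    id: str
    label: str
    vocabulary: str = field(compare=False, default="")
    description: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if ":" not in self.id:
            raise VocabError(f"term id {self.id!r} is not a CURIE")
        if not self.label:
            raise VocabError(f"term {self.id} has an empty label")

    @property
    def namespace(self) -> str:
        return self.id.split(":", 1)[0]


def normalize_id(raw: str) -> str:
    """Normalise an identifier to canonical ``PREFIX:LOCAL`` CURIE form.

    Ontology portals often print the underscore form (``MI_2235``); the
    canonical internal form uses a colon (``MI:2235``).  Idempotent.
    """
    raw = raw.strip()
    if not raw:
        raise NormalizationError("empty identifier")
    if ":" in raw:
        prefix, local = raw.split(":", 1)
    elif "_" in raw:
        prefix, local = raw.split("_", 1)
    else:
        raise NormalizationError(
            f"{raw!r} has no namespace prefix separator (':' or '_')"
        )
    if not prefix or not local:
        raise NormalizationError(f"{raw!r} is not a valid CURIE")
    return f"{prefix}:{local}"


class Vocabulary:
    """A named dictionary of terms sharing one CURIE namespace prefix.

    An *open* vocabulary has no enumerated term list; any syntactically valid
    local identifier in its namespace resolves to a synthesised term.
    """

    def __init__(
        self,
        name: str,
        namespace: str,
        terms: Iterable[OntologyTerm] = (),
        open_namespace: bool = False,
    ):
        self.name = name
        self.namespace = namespace
        self.open_namespace = open_namespace
        self._terms: Dict[str, OntologyTerm] = {}
        for term in terms:
            self.add(term)

    def add(self, term: OntologyTerm) -> None:
        if term.namespace != self.namespace:
            raise VocabError(
                f"term {term.id} does not belong to namespace {self.namespace!r}"
            )
        if term.id in self._terms:
            raise VocabError(f"duplicate term id {term.id} in {self.name}")
        self._terms[term.id] = OntologyTerm(
            term.id, term.label, self.name, term.description
        )

    @property
    def terms(self) -> Tuple[OntologyTerm, ...]:
        return tuple(self._terms[k] for k in sorted(self._terms))

    def __len__(self) -> int:
        return len(self._terms)

    def get(self, curie: str) -> OntologyTerm | None:
        hit = self._terms.get(curie)
        if hit is not None:
            return hit
        if self.open_namespace and curie.startswith(self.namespace + ":"):
            local = curie.split(":", 1)[1]
            if local:
                return OntologyTerm(curie, local, self.name)
        return None


# Role -> names of vocabularies whose terms may fill a field with that role.
ROLE_VOCABULARIES: Dict[FieldRole, Tuple[str, ...]] = {
    FieldRole.SOURCE_ENTITY: ("UniProt",),
    FieldRole.TARGET_ENTITY: ("UniProt",),
    FieldRole.CAUSAL_RELATION: ("PSI-MI", "Relation Ontology"),
    FieldRole.REFERENCE: ("PubMed",),
    FieldRole.EVIDENCE: ("ECO",),
    FieldRole.BIOLOGICAL_TYPE: ("PSI-MI",),
    FieldRole.BIOLOGICAL_MODIFICATION: ("PSI-MOD",),
    FieldRole.RESIDUE: ("PSI-MOD",),
    FieldRole.POSITION: ("Position",),
    FieldRole.COMPARTMENT: ("GO",),
    FieldRole.MECHANISM: ("PSI-MI",),
    FieldRole.CELL_LINE: ("BRENDA Tissue Ontology",),
    FieldRole.CELL_TYPE: ("Cell Ontology",),
    FieldRole.TISSUE: ("BRENDA Tissue Ontology",),
    FieldRole.TAXON: ("NCBI Taxonomy",),
}

# Canonical namespace prefix per vocabulary name (used when a vocabulary is
# not registered, e.g. when validating a statement read from a file).
VOCAB_NAMESPACES: Dict[str, str] = {
    "PSI-MI": "MI",
    "Relation Ontology": "RO",
    "ECO": "ECO",
    "GO": "GO",
    "PSI-MOD": "MOD",
    "UniProt": "uniprot",
    "PubMed": "pubmed",
    "Position": "position",
    "BRENDA Tissue Ontology": "BTO",
    "Cell Ontology": "CL",
    "NCBI Taxonomy": "NCBITaxon",
}


def allowed_vocabularies_for(role: FieldRole | str) -> frozenset:
    """Names of the vocabularies recommended for a given annotation role."""
    role = FieldRole.coerce(role)
    return frozenset(ROLE_VOCABULARIES[role])


class VocabRegistry:
    """Pluggable set of vocabularies with resolution and ranked lookup."""

    def __init__(self) -> None:
        self._by_name: Dict[str, Vocabulary] = {}
        self._by_namespace: Dict[str, Vocabulary] = {}

    def register(self, vocab: Vocabulary) -> "VocabRegistry":
        if vocab.namespace in self._by_namespace:
            raise DuplicateNamespaceError(
                f"namespace {vocab.namespace!r} is already registered"
            )
        if vocab.name in self._by_name:
            raise DuplicateNamespaceError(
                f"vocabulary {vocab.name!r} is already registered"
            )
        self._by_name[vocab.name] = vocab
        self._by_namespace[vocab.namespace] = vocab
        return self

    def vocabulary(self, name: str) -> Vocabulary | None:
        return self._by_name.get(name)

    @property
    def vocabularies(self) -> Tuple[Vocabulary, ...]:
        return tuple(self._by_name[k] for k in sorted(self._by_name))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_name.values())

    def resolve(self, curie: str) -> OntologyTerm:
        """Return the unique term with this canonical identifier."""
        prefix = curie.split(":", 1)[0] if ":" in curie else None
        vocab = self._by_namespace.get(prefix) if prefix else None
        if vocab is not None:
            hit = vocab.get(curie)
            if hit is not None:
                return hit
        raise ResolutionError(f"unknown identifier {curie!r}")

    def allowed_prefixes_for(self, role: FieldRole | str) -> frozenset:
        """CURIE prefixes acceptable for a role (registered or conventional)."""
        role = FieldRole.coerce(role)
        prefixes = set()
        for name in ROLE_VOCABULARIES[role]:
            vocab = self._by_name.get(name)
            prefixes.add(vocab.namespace if vocab else VOCAB_NAMESPACES[name])
        return frozenset(prefixes)

    def terms_for_role(self, role: FieldRole | str) -> Tuple[OntologyTerm, ...]:
        role = FieldRole.coerce(role)
        out: List[OntologyTerm] = []
        for name in ROLE_VOCABULARIES[role]:
            vocab = self._by_name.get(name)
            if vocab is not None:
                out.extend(vocab.terms)
        return tuple(out)

    def lookup(
        self,
        query: str,
        role: FieldRole | str,
        limit: int = 10,
    ) -> List[OntologyTerm]:
        """Ranked autocomplete over the vocabularies allowed for *role*.

        Ranking: case-insensitive exact label match, then label-prefix
        matches, then substring matches; each tier sorted by label then id.
        An empty query matches nothing.
        """
        role = FieldRole.coerce(role)
        if limit < 1:
            raise VocabError("limit must be >= 1")
        q = query.strip().lower()
        if not q:
            return []
        exact: List[OntologyTerm] = []
        prefix: List[OntologyTerm] = []
        substring: List[OntologyTerm] = []
        for term in self.terms_for_role(role):
            label = term.label.lower()
            if label == q:
                exact.append(term)
            elif label.startswith(q):
                prefix.append(term)
            elif q in label:
                substring.append(term)
        key = lambda t: (t.label.lower(), t.id)  # noqa: E731
        ranked = sorted(exact, key=key) + sorted(prefix, key=key) + sorted(
            substring, key=key
        )
        return ranked[:limit]


# --- fixture loading -----------------------------------------------------

# file -> (vocabulary name, namespace)
_FIXTURE_FILES: Tuple[Tuple[str, str, str], ...] = (
    ("psi_mi.tsv", "PSI-MI", "MI"),
    ("relation_ontology.tsv", "Relation Ontology", "RO"),
    ("eco.tsv", "ECO", "ECO"),
    ("go_cc.tsv", "GO", "GO"),
    ("psi_mod.tsv", "PSI-MOD", "MOD"),
    ("uniprot.tsv", "UniProt", "uniprot"),
    ("bto.tsv", "BRENDA Tissue Ontology", "BTO"),
    ("cl.tsv", "Cell Ontology", "CL"),
    ("ncbitaxon.tsv", "NCBI Taxonomy", "NCBITaxon"),
)

_TSV_HEADER = ("id", "label", "vocabulary", "description")


def read_vocabulary_tsv(text: str, name: str, namespace: str) -> Vocabulary:
    """Parse a 4-column vocabulary TSV (``id  label  vocabulary  description``)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return Vocabulary(name, namespace)
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _TSV_HEADER:
        raise VocabError(f"bad vocabulary TSV header: {header!r}")
    vocab = Vocabulary(name, namespace)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise VocabError(f"bad vocabulary TSV line: {ln!r}")
        parts = list(parts) + [""] * (4 - len(parts))
        curie, label, _src, description = parts[:4]
        vocab.add(OntologyTerm(normalize_id(curie), label, name, description))
    return vocab


def load_default_registry() -> VocabRegistry:
    """Registry over the bundled fixture vocabularies plus open namespaces."""
    registry = VocabRegistry()
    data = resources.files("mi2cast.data")
    for filename, name, namespace in _FIXTURE_FILES:
        text = (data / filename).read_text(encoding="utf-8")
        registry.register(read_vocabulary_tsv(text, name, namespace))
    registry.register(Vocabulary("PubMed", "pubmed", open_namespace=True))
    registry.register(Vocabulary("Position", "position", open_namespace=True))
    return registry


@lru_cache(maxsize=1)
def default_registry() -> VocabRegistry:
    """Cached module-wide default registry (treat as read-only)."""
    return load_default_registry()


def position_term(position: int) -> OntologyTerm:
    """Wrap a 1-based sequence position as a term+identifier couple."""
    if not isinstance(position, int) or position < 1:
        raise VocabError(f"position must be a positive integer, got {position!r}")
    return OntologyTerm(f"position:{position}", str(position), "Position")
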