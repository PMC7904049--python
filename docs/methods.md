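# Methods

## The model

A molecular causal statement asserts that a *source* biological entity
regulates the activity or quantity of a *target* entity, together with the
context in which the assertion holds.  The MI2CAST checklist splits the
annotation into a mandatory core — source entity, target entity, causal
relation, ≥ 1 literature reference, ≥ 1 evidence type — and optional context:
per-entity biological type, compartment and modifications (each modification
optionally carrying a residue term and a 1-based sequence position), and
per-statement mechanism, compartment, cell line, cell type, tissue and taxon.

Statements are curated through a *VSM sentence*: an ordered list of terms
joined by three-endpoint ("trident") connectors.  Each term is either an
annotatable **field** or a **prefilled relation term** (a fixed label such as
`has modif.`).  A connector assigns bearer, relation and argument terms to
one semantic subunit; connectors attach only to terms and their endpoints
are pairwise distinct.  A *template* is a sentence that still has empty
fields; every field carries a placeholder hint and an autocomplete
configuration restricting lookup to the vocabularies recommended for its
role.

### Graph shape

Each trident contributes the undirected edges bearer–relation and
relation–argument; a well-formed sentence's edge union is a single tree
spanning all terms.  Consequently a sentence with *T* terms always has
*(T − 1)/2* connectors.  The core triple is the one whose relation endpoint
is the causal-relation field itself (source —relation→ target).  References,
evidence and statement-level context hang off the causal-relation term;
entity context hangs off the entity terms; residue/position subfeatures hang
off their own modification term, which keeps "which subfeature belongs to
which modification" explicit even with several modifications per entity.
An alternative contraction (bearer→argument edges only) was considered and
rejected: it leaves the reference/evidence triples disconnected from the
core edge, so no template could satisfy a connectivity invariant under it.

### Template generation and mutation

A `FeatureSelection` mirrors a configuration panel: boolean flags for
single-valued context, counters (≥ 1) for references and evidence, and a
tuple of per-modification subfeature flags per side.  `generate_template`
assigns field identifiers (`f1`, `f2`, …) in a fixed reading order — source
block, causal relation, target block, statement context
(mechanism, compartment, cell line, cell type, tissue, taxon), references,
evidence — so generation is deterministic and exports are diffable.
`add_feature`/`remove_feature` parse the sentence back into its structure
tree, mutate it, and re-linearize.  Because linearization is canonical,
generating from a selection and growing the minimal template by additions
produce isomorphic graphs (equal up to field-id tokens), which the tests
check by comparing canonical serializations.  Removal cascades to dependent
subfeatures so no residue/position can outlive its modification, and the
mandatory core (including the last reference/evidence field) cannot be
removed.

## Vocabularies

All lookup is offline, over small fixture subsets shipped as 4-column TSV
(id, label, vocabulary, description): PSI-MI (causal relations such as
`MI:2235` *up-regulates*, mechanisms, interactor types), Relation Ontology,
ECO, GO cellular component, PSI-MOD, a UniProt-like entity subset, BTO, CL
and NCBI Taxonomy.  The role→vocabulary map is frozen in
`mi2cast.vocab.ROLE_VOCABULARIES`; the causal-relation role is restricted to
PSI-MI and Relation Ontology exactly.  Two namespaces are *open* (no
enumerated term list): `pubmed:` for references and `position:`, a
pseudo-namespace that wraps sequence positions so every filled field is
uniformly a term+identifier couple.  Identifiers are normalised to the
colon CURIE form (`MI_2235` → `MI:2235`) on input.

Autocomplete ranking is deliberately simple and total: case-insensitive
exact-label match, then label-prefix matches, then substring matches, each
tier sorted by label then id; the empty query returns nothing.  The registry
is a pluggable interface — a live multi-dictionary client could implement
the same lookup/resolve surface — but the fixture registry is the default
and the only implementation shipped.

## Validation

`validate` never raises on content: it returns an ordered report.  Missing
mandatory elements produce one ERROR each (codes `MISSING_SOURCE`,
`MISSING_TARGET`, `MISSING_RELATION`, `MISSING_REFERENCE`,
`MISSING_EVIDENCE`); relation or evidence terms outside their roles'
namespaces produce ERROR `VOCAB_VIOLATION`; optional context in an
unexpected namespace only warns, since the checklist's hard requirements are
the five-element core.  The code and severity enumerations are part of the
public interface so host platforms can map them onto their own QC.

## Serialization

* **VSM-JSON** (`.vsm.json`) — this package's own documented dialect: a
  `terms` array (explicit 0-based positions, field ids, placeholders,
  lookup roles, id/label when filled) plus a `connectors` array of
  `[bearer, relation, argument]` triples.  `from_vsm_json∘to_vsm_json` is
  the identity; partial templates serialize too.  Compatibility with any
  external widget's wire format is not claimed.
* **VSM-JSON-light** (`.vsml.json`) — a lossy projection with the same
  connector list, keeping only `{id, label}` per filled term, `{label}` per
  relation term and `{role}` per empty field; no placeholders, field ids or
  autocomplete configuration.  Write-only.
* **causal-JSON** (`.causal.json`) — lossless statement interchange,
  versioned (`format_version: "1.0"`); schema in
  `docs/causal-json.schema.json`.  The reader reports violations with a
  JSON-path locator and ignores unknown keys with a warning so vendor
  extensions do not break interchange.
* **CausalTAB / PSI-MITAB2.8** — fixed 46-column TSV; the field map and
  quoting rules are frozen in `docs/causaltab.md`.  Lossy by design: the
  mapped subset round-trips exactly and the lossiness log names exactly the
  complement.  Evidence terms are carried in the interaction-detection
  column; one reader fallback is worth noting — if a term cell has no label
  and the CURIE is not resolvable from the fixtures, the CURIE itself is
  used as the label (a term's label must be non-empty) and a warning is
  emitted.

## Synthetic data

`gen_statement(seed, profile)` draws terms per role from the fixture
vocabularies only, using Python's seeded Mersenne Twister (stable across
platforms and processes; no ambient randomness).  The default profile is the
minimal mandatory core; `gen_corpus` cycles through five shapes chosen to
cover every optional field class at least once, including multi-modification
entities with residue/position subfeatures and multi-reference/evidence
statements.  References are synthesized as 7-digit `pubmed:` identifiers and
positions drawn from 1–999.  `gen_invalid(seed, code)` makes a single-fault
statement whose report carries exactly the requested ERROR.

What the generator does *not* emulate: real curation corpora (term
frequencies, co-occurrence of context fields, literature identifiers that
exist), free-text entity naming, or vocabulary churn.  Passing round-trip
and validation suites therefore demonstrates structural correctness of the
pipeline, not curation quality on real literature.

`enumerate_selections(max_counter, max_modifications)` enumerates the full
cross product of selection axes lazily (the count grows combinatorially:
1024 selections with counters at 1 and no modifications; millions at
counters ≤ 3 with ≤ 2 modifications per side).  Property suites therefore
check the complete flags-only enumeration and deterministic strides through
the larger one; problem sizes are stated in each test.

## Numerical / degenerate-input choices

* Term identity is the (id, label) couple; vocabulary and description are
  carried metadata excluded from equality, so a statement read back from a
  file compares equal to its in-memory original.
* A one-term sentence with no connectors is the only legal connector-free
  sentence (degenerate but serializable).
* Tie-breaks in lookup are lexicographic by label then id; report ordering
  follows a fixed field-path order (source block, target block, relation,
  references, evidence, context).
* Statement compartment and entity compartments may coexist; both are
  supported simultaneously and kept distinct by their bearer term.

## Known limitations

* The role→vocabulary map is a frozen convention; deployments following a
  different recommendation list must register their own vocabularies.
* No live ontology lookup, OBO/OWL parsing or subsumption reasoning.
* CausalTAB biological-effect columns (43/44) are always empty: activity
  effects are not modeled.
* Nested protein complexes and non-trident connector types (lists,
  coreference) are out of scope.
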