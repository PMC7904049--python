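# mi2cast

Headless curation of **molecular causal statements** that comply with the
MI2CAST checklist (Minimum Information about a Molecular Interaction Causal
Statement), for biocurators and curation-tool developers who need the
annotation pipeline — template generation, vocabulary-constrained term
filling, compliance validation and multi-format export — without a GUI or a
database.

A causal statement asserts that a source entity regulates a target entity:

```
source entity  —[causal relation]→  target entity
```

with a mandatory core of *source, target, causal relation, ≥ 1 reference,
≥ 1 evidence type*, plus optional context (entity types, compartments,
protein modifications with residue/position subfeatures, mechanism, cell
line, cell type, tissue, taxon).  Statements are curated through **VSM
sentences**: ordered terms — each a `(identifier, label)` couple from a
controlled vocabulary — joined by trident connectors that assign bearer,
relation and argument to one semantic triple.  A template is a sentence
with empty fields; each empty field carries a placeholder and an
autocomplete configuration restricted to the vocabularies recommended for
its role (e.g. a causal-relation field only accepts PSI-MI and Relation
Ontology terms, such as `MI:2235` *up-regulates*).

Everything runs offline against bundled fixture vocabulary subsets (PSI-MI,
Relation Ontology, ECO, GO cellular component, PSI-MOD, a UniProt-like
entity set, BTO, CL, NCBI Taxonomy).

## Worked example

```python
import mi2cast as m
from mi2cast import FieldRole

registry = m.default_registry()

# ranked, role-restricted autocomplete
for t in registry.lookup("up-reg", FieldRole.CAUSAL_RELATION):
    print(t.id, t.label)

# generate the minimal template and fill it
template = m.generate_template(m.FeatureSelection())
fills = {FieldRole.SOURCE_ENTITY: "uniprot:P31750",
         FieldRole.CAUSAL_RELATION: "MI:2235",
         FieldRole.TARGET_ENTITY: "uniprot:O43524",
         FieldRole.REFERENCE: "pubmed:10358075",
         FieldRole.EVIDENCE: "ECO:0000269"}
sentence = template
for f in template.fields:
    sentence = m.fill_field(sentence, f.field_id,
                            registry.resolve(fills[f.role]), registry)

statement = m.sentence_to_statement(sentence)
print(m.statement_summary(statement))
print(m.validate(statement, registry))
```

prints

```
MI:2235 up-regulates
MI:2236 up-regulates activity
MI:2237 up-regulates quantity
AKT1_MOUSE —up-regulates→ FOXO3_HUMAN [1 reference(s), 1 evidence, 0 context]
OK: statement satisfies all mandatory rules
```

— the autocomplete ranks the exact label match first; the filled template
interprets into a statement whose five mandatory elements all check out.
Exports: `m.write_causal_json([statement])` (lossless),
`m.to_vsm_json(sentence)` / `m.to_vsm_json_light(sentence)`, and
`m.write_causaltab([statement])` for a 46-column CausalTAB (PSI-MITAB2.8)
row whose lossiness log names any field the format cannot carry.  The
`examples/` directory has one narrative script per capability.

## Command line

```sh
mi2cast template --select selection.yaml -o template.vsm.json
mi2cast validate statements.causal.json
mi2cast convert -i statements.causal.json -f causal-json -o out.mitab -t causaltab
mi2cast lookup --role causal_relation up-reg
```

Exit codes: 0 success/valid, 1 validation failure, 2 parse/usage failure.

## Layout

* `src/mi2cast/` — `vocab` (registry, CURIEs, lookup), `model` (statements
  and validator), `template`/`vsm` (sentence graphs), `causaljson`/`mitab`
  (I/O), `synthetic` (seeded generators), `cli`.
* `docs/methods.md` — model, design choices, limitations;
  `docs/causal-json.schema.json`, `docs/causaltab.md` — format freezes.
* `tests/` — unit, property and end-to-end suites.
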