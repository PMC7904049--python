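"""Fill a template with controlled-vocabulary terms and validate the result.

Term lookup is restricted per field role (a causal-relation field only sees
PSI-MI and Relation Ontology terms), so a curator picks from ranked
suggestions instead of typing identifiers.  Once every field is filled the
sentence is interpreted into a causal statement and checked against the
mandatory annotation rules.
"""

import mi2cast as m
from mi2cast import FieldRole

registry = m.default_registry()

hits = registry.lookup("up-reg", FieldRole.CAUSAL_RELATION)
print("autocomplete 'up-reg' for the causal-relation field:")
for t in hits:
    print(f"  {t.id}  {t.label}  [{t.vocabulary}]")

template = m.generate_template(m.FeatureSelection())
fills = {
    FieldRole.SOURCE_ENTITY: "uniprot:P31750",   # AKT1_MOUSE
    FieldRole.CAUSAL_RELATION: hits[0].id,       # MI:2235 up-regulates
    FieldRole.TARGET_ENTITY: "uniprot:O43524",   # FOXO3_HUMAN
    FieldRole.REFERENCE: "pubmed:10358075",
    FieldRole.EVIDENCE: "ECO:0000269",
}
sentence = template
for f in template.fields:
    sentence = m.fill_field(sentence, f.field_id,
                            registry.resolve(fills[f.role]), registry)

print("\ncomplete:", m.is_complete(sentence))
statement = m.sentence_to_statement(sentence)
print("statement:", m.statement_summary(statement))
print(m.validate(statement, registry))
# "OK" means every mandatory rule holds: source, target, causal relation,
# at least one reference and at least one evidence type.
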