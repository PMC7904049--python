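"""Generate a curation template from a feature selection.

Selecting a biological modification for the source entity plus the
compartment of the causal relationship yields a seven-field template: the
five mandatory fields (source entity, causal relation, target entity,
reference, evidence) plus one field per selected feature, each wired into
the sentence graph by a trident connector through a prefilled relation term.
"""

import mi2cast as m
from mi2cast import FieldRole
from mi2cast.template import ModificationSpec

selection = m.FeatureSelection(
    source_modifications=(ModificationSpec(),),
    relation_context=frozenset({FieldRole.COMPARTMENT}),
)
template = m.generate_template(selection)

print("annotatable fields (reading order):")
for f in template.fields:
    print(f"  {f.field_id}: <{f.placeholder}>")

print("\ntriples (bearer --relation--> argument):")
for c in template.connectors:
    def show(i):
        t = template.terms[i]
        return t.label if t.label else f"<{t.placeholder}>"
    print(f"  {show(c.bearer)} --{show(c.relation)}--> {show(c.argument)}")

# Each line above is one semantic subunit: e.g. the modification field is
# attached to the source entity through the prefilled 'has modif.' term.
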