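"""Export one annotated causal statement to every supported format.

causal-JSON is lossless (every annotation detail survives a round trip);
VSM-JSON serializes the sentence graph itself; VSM-JSON-light is a compact
projection keeping ids and labels only; CausalTAB (PSI-MITAB2.8) is a
fixed-width 46-column exchange format that carries the PSI-MI-supported
subset and logs what it drops.
"""

import mi2cast as m
from mi2cast import FieldRole
from mi2cast.template import ModificationSpec

profile = m.FeatureSelection(
    source_modifications=(ModificationSpec(residue=True, position=True),),
    relation_context=frozenset({FieldRole.COMPARTMENT, FieldRole.TAXON}),
)
statement = m.gen_statement(seed=42, profile=profile)
print("statement:", m.statement_summary(statement))

causal_json = m.write_causal_json([statement])
print(f"\ncausal-JSON: {len(causal_json)} bytes; lossless round trip:",
      m.read_causal_json(causal_json) == [statement])

sentence = m.statement_to_sentence(statement)
print(f"VSM-JSON: {len(m.to_vsm_json(sentence))} bytes, "
      f"light: {len(m.to_vsm_json_light(sentence))} bytes")

record = m.statement_to_mitab(statement)
print(f"\nCausalTAB: {len(record.columns)} columns")
print("  causal statement column:", record.columns[45])
print("  dropped (no MITAB column):", ", ".join(record.dropped))
back = m.read_causaltab(m.write_causaltab([statement]))[0]
print("  subset round trip:", back == m.mitab_projection(statement))
# The lossiness log names exactly the fields CausalTAB cannot carry
# (modification subfeatures, compartments, cell/tissue context).
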