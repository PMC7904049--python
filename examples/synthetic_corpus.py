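"""Generate seeded synthetic statements, valid and deliberately broken.

The generator draws terms only from the bundled fixture vocabularies and is
fully deterministic per seed, so compliance checking and every exporter can
be exercised offline and reproducibly.
"""

import mi2cast as m
from mi2cast import Code

corpus = m.gen_corpus(seed=7, n=50)
n_valid = sum(m.is_valid(s) for s in corpus)
print(f"{n_valid}/{len(corpus)} generated statements pass validation")
print("example:", m.statement_summary(corpus[1]))

print("\nsingle-fault statements, one per violation code:")
for code in Code:
    broken = m.gen_invalid(seed=3, violation=code)
    report = m.validate(broken)
    printed = ", ".join(f"{v.code.value}@{v.path}" for v in report.errors)
    print(f"  requested {code.value:<18} -> reported {printed}")
# Each broken statement fails with exactly the requested ERROR code, which
# is how the validator's single-fault detection is tested.
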