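# CausalTAB (PSI-MITAB2.8) export: column layout and field map

CausalTAB is the PSI-MI tab-delimited molecular-interaction format extended
with four causal columns.  The layout is frozen at **46 columns**: the 42
columns of MITAB2.7 followed by *Biological effect of interactor A*,
*Biological effect of interactor B*, *Causal regulatory mechanism* and
*Causal statement* (columns 43–46).  The full ordered name list is
`mi2cast.mitab.COLUMNS`.

## Cell syntax

* multi-valued cells are pipe-separated; `-` is the empty cell;
* cross-references are written `db:id(label)`; a token containing any of
  `| ( ) : " tab` is double-quoted with `\"` escaping (so ontology CURIEs
  appear as e.g. `psi-mi:"MI:2235"(up-regulates)`);
* rows are newline-terminated; an optional header row is prefixed with `#`.

## Statement → column map (frozen)

| statement field            | column(s) | cell form                              |
|----------------------------|-----------|----------------------------------------|
| source / target id         | 1 / 2     | `uniprot:P31750`                       |
| source / target label      | 5 / 6     | `uniprot:AKT1_MOUSE(display_short)`    |
| evidence (ECO)             | 7         | `eco:"ECO:0000269"(…)`, pipe-joined    |
| references                 | 9         | `pubmed:10358075`, pipe-joined         |
| taxon                      | 10 and 11 | `taxid:9606(Homo sapiens)`             |
| biological type (A / B)    | 21 / 22   | `psi-mi:"MI:0326"(protein)`            |
| negative flag              | 36        | always `false`                         |
| mechanism                  | 45        | `psi-mi:"MI:0217"(…)`                  |
| causal relation            | 46        | `psi-mi:"MI:2235"(up-regulates)`       |

All other columns are written as `-`.

## Dropped fields (the lossiness log)

MI2CAST fields without a CausalTAB column are dropped on export and each one
is named in the record's lossiness log (`MitabRecord.dropped`, echoed to
stderr by `mi2cast convert`):

* entity modifications, including their residue and position subfeatures,
* entity compartments and the statement compartment,
* cell line, cell type and tissue.

`mi2cast.mitab.mitab_projection(statement)` returns the statement restricted
to the mapped subset; `read_causaltab(write_causaltab([s]))` recovers exactly
that projection.  Golden-file fixtures live in `tests/data/golden.causaltab`.
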