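# templex

Reaction-template extraction from atom-mapped reaction SMILES, for
retrosynthesis and retro-biosynthesis pipelines.

A reaction template is a generic SMARTS-encoded transformation that captures
the reaction centre — the atoms whose bonds, hydrogen counts or charges
change between substrates and products — together with its local environment
up to a chosen topological radius. Radius 0 keeps the centre alone (maximal
generality, e.g. for modelling enzymatic promiscuity); radii up to 10
progressively enforce context until the whole substrate is encompassed.
templex turns a batch of atom-mapped reactions (from MetaNetX/Rhea-style
biochemical sources, USPTO-style organic sources, or your own mapper) into a
deduplicated catalog of validated templates with stable identifiers,
provenance and sequence-support scores.

The pipeline, per reaction:

1. **Parse and normalize** the mapped SMILES: heavy-atom graphs with
   implicit hydrogen counts, all stereochemistry stripped, aromaticity
   perceived once and frozen. Mass-imbalanced records (missing water,
   lumped cofactors…) are admitted whenever the mapping itself is coherent.
2. **Prune cofactors** by exact canonical-structure equality against a
   curated list; removed names stay attached to downstream records.
3. **Decompose** into mono-substrate components, both directions: each focal
   substrate is paired with every product inheriting ≥ 1 of its mapped
   atoms; atoms mapped to other substrates are re-labelled as unmapped
   context.
4. **Detect the reaction centre** by a per-atom environment diff under the
   map (bond orders, neighbor sets, H counts, charges,
   appearance/disappearance).
5. **Encode** the environment at each radius 0–10 as a canonical
   minimal-primitive SMARTS: per atom exactly element symbol,
   aromatic/aliphatic case, atomic number and hydrogen count, plus a formal
   charge only when the atom is charged on either side. Isomorphic
   environments serialize to byte-identical strings.
6. **Validate** every candidate by a round-trip check — applying the
   template back to its source substrate must regenerate the expected
   products — and drop failures into a machine-readable diagnostics stream.
7. **Merge** into a catalog keyed by canonical SMARTS, with three-layer
   identifiers `RR:AAAAAA-BBBBBB-CCCCCC` (A: substrate heavy-atom topology,
   B: product topology, C: full SMARTS; SHA-256 → 30 bits → base32 each) and
   the sequence-support score *s* = *n*^(−1/*r*), where *n* is the number of
   supporting enzyme sequence clusters and *r* > 0 a regularization
   parameter (default 2). Spontaneous reactions score exactly 1; templates
   with no evidence and no spontaneous flag carry a null score.

## Worked example

The transamination RHEA:25152 (2-oxoglutarate + L-phenylalanine →
3-phenylpyruvate + L-glutamate, EC 2.6.1.5/2.6.1.57) ships as a built-in
fixture:

```python
from rdkit import Chem
from templex import extract_all, merge, apply_template
from templex.fixtures import worked_example

rxn = worked_example()
templates, diagnostics = extract_all(rxn)
print(f"{len(templates)} templates, {len(diagnostics)} diagnostics")

phe_fwd = [t for t in templates if t.direction == "forward"
           and "N" in Chem.MolToSmiles(t.component.focal_substrate)]
t0 = next(t for t in phe_fwd if t.radius == 0)
print(t0.smarts)

catalog = merge(templates)
rec = catalog.by_smarts()[t0.smarts]
print(rec.identifier, sorted(rec.radii))

for products in apply_template(t0.smarts, Chem.MolFromSmiles("NC(Cc1ccccc1)C(O)=O")):
    print(" + ".join(products))
```

prints

```
44 templates, 0 diagnostics
[C;#6;H1:1]-[N;#7;H2:2]>>[C;#6;H0:1]=[O;#8;H0].[C;#6;H0](-[C;#6;H1](-[C;#6;H2]-[C;#6;H2]-[C;#6;H0](=[O;#8;H0])-[O;#8;H1])-[N;#7;H2:2])(=[O;#8;H0])-[O;#8;H1]
RR:4YMN6J-MX77TV-X47W55 [0]
NC(CCC(=O)O)C(=O)O + O=C(O)C(=O)Cc1ccccc1
```

44 = 2 substrates × 2 directions × 11 radii, every one passing its round
trip. The radius-0 phenylalanine-focal template keeps only the changing
Cα–N pair on the substrate side (mapped atoms `:1`/`:2`); the amine leaves
into the appearing glutamate skeleton and the keto oxygen arrives as `=O`.
Applying it back to L-phenylalanine regenerates L-glutamate plus
3-phenylpyruvate.

## Command line

```
templex extract corpus.tsv --cofactors biochem --radii 0:10 \
        --direction both --out catalog.tsv --diagnostics diag.tsv
templex query catalog.tsv --ec 2.6.1 --radius 0
templex apply --catalog catalog.tsv --template-id RR:... --target "CCO"
```

`extract` reads the batch TSV format (`reaction_id`, `dataset`,
`mapped_rxn_smiles`, `ec_numbers`, `spontaneous`,
`sequence_cluster_count`), writes a catalog in TSV/CSV/JSON (lossless
round trip, JSON validated against the shipped schema) and a run manifest
with tool versions, options and input digests. `query` filters by dataset,
radius (0–10), EC number (exact or prefix, e.g. `2.7.1`), reaction ID or
template ID. A ≥ 50-reaction synthetic corpus for experimentation is
available via `templex.fixtures.write_corpus("some_dir")`.

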