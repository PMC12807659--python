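# Methods

## Scope and model

templex extracts directed, mono-substrate reaction templates from
atom-mapped reaction SMILES. The unit of extraction is the *mono-substrate
component*: one focal substrate plus every product that inherits at least
one of its mapped atoms. The inheritance threshold is deliberately ≥ 1
shared mapped atom — a majority rule would silently drop products such as
the amine acceptor in a transamination, whose only link to the focal
substrate is the transferred nitrogen. Product atoms mapped to *other*
substrates are re-labelled as unmapped context rather than kept, so every
emitted template is strictly mono-substrate; reverse templates come from
the same procedure with the two sides swapped.

Templates are emitted only in the direction they were extracted, only at
radii 0–10, and only if they pass the round-trip check (below). Bimolecular
(multi-substrate) template emission, stereochemistry-aware patterns and
atom-atom mapping itself are out of scope: mappings are consumed as input,
and an optional mapper plugin is just a callable from unmapped to mapped
reaction SMILES.

## Normalization and the frozen aromaticity model

Parsing produces heavy-atom graphs with per-atom implicit hydrogen counts;
explicit hydrogen vertices are folded away. All stereochemistry
(tetrahedral tags, double-bond geometry, enhanced stereo groups) is removed
and nothing else is altered; normalization is idempotent. Aromaticity is
perceived once at parse time under RDKit's default model and frozen; the
same model is applied to target molecules at application time, so patterns
and probes always agree. We make no claim that this choice reproduces any
particular hosted rule database bit-for-bit — uniformity within the
pipeline is the requirement.

Map index 0 and an absent map attribute both mean "unmapped", and the
serializer never emits `:0`. Indices occurring on only one side stay on
their atoms but are excluded from the substrate/product bijection: such
atoms count as unmapped in the mapping report and behave as
disappearing/appearing atoms downstream. This is how mass-imbalanced
records flow through without artificial rebalancing, which would manufacture
atoms the source never asserted.

## Reaction centre

An atom belongs to the centre iff, comparing its substrate- and
product-side environments under the map, any of the following differ:
incident bond orders to shared mapped neighbors; the set of mapped
neighbors; the multiset of (element, bond order) over *unmapped* neighbors;
total hydrogen count; formal charge. Atoms present on one side only are
centre members of kind appears/disappears. The unmapped-neighbor profile is
compared by element and bond order, not by count alone: an OH → Cl swap
written without mapping the leaving group must mark the carbon, while an
O-for-O exchange (imbalanced esterification) genuinely leaves the carbon's
comparable environment unchanged. A component with an entirely empty centre
is an identity transformation and is rejected with a no-change diagnostic.

## Radius expansion

Radius is topological bond distance (shortest path) from the nearest centre
atom; radius 0 is the centre itself. The substrate subgraph at radius ρ is
induced by all atoms within ρ bonds of a centre atom; the product side is
its image under the map. Appearing product atoms and disappearing substrate
atoms are included at every radius with full primitives: they are centre
members by definition, and their inclusion is precisely what makes
templates from imbalanced reactions regenerate complete products in the
round-trip check. Bonds crossing the radius boundary are cut; boundary
atoms keep their primitives unchanged (no attachment-point wildcards).
Consequences, asserted as properties: atom sets grow monotonically with
radius, substrate-pattern match sets shrink monotonically, and once the
environment saturates the emitted strings become byte-identical.

## Encoding and canonicalization

Each atom is rendered with exactly four primitives — element symbol
(lower-case when aromatic), atomic number, total hydrogen count, and a
formal charge emitted only when the mapped atom pair is charged on either
side (including an explicit `+0` on the neutral partner, which is what
resets the charge on application). Bonds are always explicit (`-`, `=`,
`#`, `:`). Atom ranks come from Morgan-style iterative refinement over
(atomic number, aromaticity, H count, charge, product-partner signature),
with remaining ties broken by exhaustively selecting the order that
minimizes the serialized string; atom maps are excluded from substrate-side
ranking and then renumbered 1..k in canonical output order. The
partner signature (a one-neighborhood fingerprint of the mapped atom's
product image) replaces centre-membership in the rank invariants: centre
membership is not recoverable from a template string, and using it would
make re-encoding a parsed template unstable, whereas the partner signature
is intrinsic to the pattern pair. The net contract: isomorphic environment
pairs produce byte-identical template strings, and encode ∘ decode ∘ encode
= encode.

Product-side fragments are grouped with SMARTS component parentheses per
parent product molecule (likewise the substrate side when its
radius-limited subgraph is disconnected). Grouping is part of the canonical
string; it keeps generated product molecules aligned one-to-one with the
expected inherited products.

Hydrogen-count primitives are matched *exactly* at application time — the
aggressive-specificity reading, which we flag as a divergence risk against
tools that treat H counts as lower bounds. `apply_template(...,
relax_h=True)` (CLI `--relax-h`) drops H primitives from the substrate
pattern and from mapped product atoms for deliberately looser matching; the
default everywhere, including the round-trip check, is exact.

## Round-trip validation

A template is valid iff applying it to its source substrate yields at least
one outcome whose canonical product structures equal the inherited
products' canonical structures exactly. Failures are excluded from output
and recorded in a TSV diagnostics stream with reaction, direction, focal
index, radius and reason. By construction 100% of *emitted* templates pass;
the typical honest failure is the radius-0 template of an imbalanced
esterification, whose mapped centre is empty and whose pattern is therefore
unanchored until radius 1 brings in mapped context.

## Identifiers and scoring

Identifier segments hash, respectively: the substrate pattern's heavy-atom
connectivity (atoms as bare atomic numbers, explicit bond orders, no H/charge/map),
the product pattern's connectivity, and the full canonical SMARTS. Each
segment is SHA-256 truncated to 30 bits, rendered as 6 characters of
RFC 4648 base32 — the hash function is unnamed upstream of this package, so
the choice is frozen here and versioned in output metadata. Excluding H
counts and charges from A/B is what makes A-segment grouping coincide with
substrate-motif isomorphism classes, the retrieval use-case the layering
exists for. At fixture-catalog scale (hundreds to thousands of templates)
the 30-bit segments give a vanishing birthday-collision probability; the
catalog additionally enforces that no two records share a SMARTS or a full
identifier.

The sequence-support score is s = n^(−1/r): s ∈ (0, 1], s = 1 at n = 1,
strictly decreasing in n and increasing in r. Default r = 2, configurable
(`--score-r`); no canonical value is claimed. When identical templates
merge across reactions, the record's score uses the *maximum* n across
supporting reactions — the most conservative ambiguity estimate — and any
spontaneous source forces s = 1. Unannotated, non-spontaneous templates
carry a null score exported as an empty field (serialized with 6
significant digits otherwise); we prefer null over a worst score because
absence of evidence is not evidence of ambiguity.

## Catalog semantics

The dedup key is the canonical SMARTS string. Radii form a set (the same
SMARTS arises at several radii once environments saturate), directions a
subset of {forward, reverse}, datasets a label → reaction-ID map with
domains derived from labels (mnx/rhea → biochemical, uspto → organic
chemistry). EC filtering is string-prefix on dot boundaries; no hierarchy
file is needed. Exports (TSV/CSV/JSON) share one frozen column layout and
round-trip losslessly; scores are stored at their serialized precision so
re-export is byte-identical. The JSON export validates against the shipped
schema via a small structural validator covering the subset of JSON Schema
the schema uses.

## Synthetic corpus: what it emulates and what it does not

The fixture corpus (51 reactions by default) is built from seven
parametrized families — transamination, (di)esterification and its
water-free imbalanced variant, nucleophilic substitution (aliphatic and
aryl), alcohol oxidation, and spontaneous epoxide ring opening — spanning
1–3 substrates, stoichiometric duplicates, aromatic and aliphatic centres,
charged species, spontaneous flags and seeded sequence-cluster
annotations. Mappings and ground truths (centre atom sets, expected
inherited products) are constructed with the chemistry, so they are
independent oracles for the detector and the round-trip machinery.
Generation is a pure function of the specs and seeds.

What passing on this corpus does not show: real mapper noise (wrong or
shifted mappings), exotic valences and organometallics, tautomer and
protonation-state inconsistencies between databases, or template behaviour
on molecules far larger than the fixtures. The corpus validates the
extraction algebra, not the curation quality of any upstream resource.

## Numerical and degenerate-input choices

Tie-break search in canonicalization is capped (8 orders per fragment, 64
order combinations, 2048 refinement leaves) — generous for template-sized
graphs and never reached on the corpus; fragment permutations are explored
only within runs of equal fragment strings. Duplicate mono-substrate
components are collapsed on map-stripped structure (focal + sorted
inherited products), since map labels are erased by canonical encoding
anyway. Spectator substrates are dropped with a logged notice; pruning that
empties a side, decompositions with no surviving component, and identity
components raise typed errors that batch drivers convert to diagnostics.
Bond orders outside {single, double, triple, aromatic} are rejected.

## Known limitations

- Templates are mono-substrate; multi-substrate chemistry is represented
  through decomposition, not bimolecular patterns.
- Exact hydrogen-count matching makes high-radius templates very specific;
  the relaxed mode is a blunt instrument, not a calibrated alternative.
- Appearing atoms are included at every radius, so radius-0 templates of
  atom-transferring reactions carry the full appearing fragment; this is
  required for round trips but means radius 0 is not always "small".
- The 30-bit identifier segments are collision-safe at catalog scales of
  ~10^4, not at the scale of hundreds of millions of templates.
- No kekulization policy beyond the frozen RDKit aromaticity model, no
  InChI handling, no automatic cofactor inference, no EC hierarchy
  validation beyond syntax.
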