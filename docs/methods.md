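# Methods

## The chemical graph model

Molecules are hydrogen-suppressed graphs ("skeleton graphs"): nodes are
heavy atoms (element, formal charge, aromatic flag), edges are bonds with
order single/double/triple/aromatic. Hydrogens are never stored as nodes;
they are inferred per atom as

    implicit_h = allowed_valence(element, charge) − bond_order_sum

with default valences B 3, C 4, N 3, O 2, P 3, S 2, halogens 1. Aromatic
bonds contribute 1 to the bond-order sum, and an aromatic atom carrying
two or more aromatic bonds loses one further hydrogen. This reproduces
the SMILES organic-subset convention: a benzene carbon gets exactly one
hydrogen, a substituted ring carbon none. Charge adjustment is the
minimal rule set the supported chemistry needs: +1 on nitrogen raises the
allowed valence by one, −1 on oxygen lowers it by one, everything else
uses the default. Sulfur (4, 6) and phosphorus (5) may exceed their
default valence when explicit bond orders force it, but a hypervalent
atom never receives inferred hydrogens; a bond-order sum beyond every
allowed state is a valence error. Inference is idempotent and bracket
SMILES atoms carry an explicit hydrogen count that overrides it.

Ring count is the cyclomatic number E − V + C, not SSSR — it is
unambiguous, order-invariant and cheap, which is what a constitutional
descriptor registry needs; it equals SSSR size for the fused-ring systems
the generator produces. The Wiener index is the sum of shortest-path bond
distances over unordered heavy-atom pairs and is defined only on
connected graphs (a per-component convention would be a silent choice, so
disconnection is an error instead).

Average molecular mass uses a bundled, versioned table of standard atomic
weights rounded to three decimals, so results are reproducible offline
and to a fixed precision (aspirin: 9·12.011 + 8·1.008 + 4·15.999 =
180.159 Da).

## Formats

The SMILES dialect is the Daylight organic subset: B C N O P S F Cl Br I,
aromatic b c n o p s, bracket atoms with hydrogen count and charge,
branches, bond symbols `- = # :`, ring-closure digits 0–9, and `.`.
Stereochemistry, isotopes, wildcards and `%nn` closures are out of scope.
All whitespace is removed before lexing, because SMILES strings copied
out of typeset documents routinely acquire spurious spaces. The writer is
deterministic for a fixed atom ordering but not canonical; the guaranteed
property is that `parse(write(g))` is isomorphic to `g`.

Molfiles are V2000 only, written with zero coordinates and 3-character
counts-line fields; charges travel as `M  CHG` lines. SD-file properties
are returned verbatim as strings — SD property blocks are free text, and
typing them is the descriptor layer's job. That is also how precomputed
InChI/InChIKey values enter the system: they are pass-through
annotations, stored and queried byte-exact, never computed or validated
(the worked aspirin example deliberately uses a pre-standard InChI with
an `/f` layer and a 25-character InChIKey).

## Descriptors

Descriptor types form a subclass hierarchy rooted at the generic
chemical-descriptor class; published identifiers
(`…/CHEMINF_000123`, `_000400`, `_000113`, `_000186`, `_000251`) are used
for the terms that have them, and every other type is minted under
`http://example.org/cheminfkb/vocab/` — the published namespace is never
extended locally. Each type carries a format specification
(numeric-real, numeric-integer, textual, structured); instance values are
validated against it at construction, so nothing malformed ever reaches
the triple store.

Hydrogen-bond counts use Lipinski's operational definitions: donors are
N/O atoms bearing at least one hydrogen, acceptors are all N plus O
atoms. By construction `hbd ≤ hba` under these definitions (this is not
true of donor/acceptor counts in general).

logP is an additive per-atom estimate over ~15 atom types keyed on
element, aromaticity and heteroatom neighbourhood (aliphatic carbon
+0.5, aromatic carbon +0.31, hydroxyl oxygen −0.4, chlorine +0.7, …; the
full table ships as `data/logp_contributions.json`). The scheme is
deliberately crude: the toolkit's subject matter is typed, provenance-
annotated descriptor values, not state-of-the-art lipophilicity
prediction, so determinism and exact additivity (used by the tests) are
the design targets, not accuracy. Atoms without a table entry fall back
to an element-level default and are logged.

## Knowledge-base modelling

Molecules become chemical-entity nodes with an `rdfs:label`. A descriptor
instance hangs off its molecule as exactly

    entity  —has attribute (CHEMINF_000200)→  instance
    instance —rdf:type→                      descriptor type URI
    instance —has value (SIO_000300)→        typed literal

plus, when provenance exists, `instance —is output of (CHEMINF_000606)→
execution` and `execution —ro:has_agent→ agent`. Literals always carry an
explicit datatype: integers as `xsd:integer`, reals as `xsd:double`,
everything else as `xsd:string` — which is what lets numeric threshold
queries mix integer and double restrictions safely.

Choices worth flagging:

* **No blank nodes.** Instances, executions and parameters get minted
  URIs (md5 of run id, node kind, label and a counter, truncated). This
  makes Turtle round trips exact set equalities and files diffable.
* **Value-predicate alias.** `CHEMINF_000012` is accepted as a synonym of
  `SIO_000300` on read and normalized; only `SIO_000300` is written.
  Whether the two are truly synonymous upstream is unknown; this is a
  repo convention.
* **`ro:has_agent`** is minted under a declared, overridable RO prefix
  (`http://www.obofoundry.org/ro/ro.owl#`), since the relation is used
  with an unexpanded prefix in its source context.
* **Timestamps** on executions are optional and omitted by default so
  identical builds are triple-identical.

## Query semantics

`subclass_closure` is the reflexive-transitive set of subclasses.
The Rule-of-Five filter is a conjunction of (type, comparison, threshold)
constraints, default mass ≤ 500 ∧ logP < 5 ∧ HBA ≤ 10 ∧ HBD ≤ 5,
evaluated **closed-world**: an entity lacking a required descriptor is
excluded and reported in the diagnostics, where an open-world reasoner
would return unknown. Multiple descriptors of one type use
"some"-semantics — any satisfying value qualifies — and comparisons are
by numeric value, never lexical form. Conjunctive triple patterns are
joined left-to-right with binding propagation; a disconnected join graph
or projection of an unbound variable is rejected up front. Relaxing any
threshold can only grow the result set (tested as a monotonicity
property).

## The synthetic generator

`generate_molecules` emulates a small drug-like screening panel: 90
molecules by default, random carbon skeletons of 6–14 heavy atoms
(optional six-ring, aromatic half the time, ring probability 0.6)
decorated with hydroxyl/amine/halogen/carboxyl substituents
(heteroatom probability 0.35). A 2% violation rate injects molecules
built to break a Rule-of-Five bound — an oversized alkane or a
six-donor polyol — giving the familiar "almost all drug-like" shape of a
known-drug panel. Compliant molecules are rejection-sampled against all
four bounds so the violator fraction is governed solely by the violation
draw. All randomness flows through one `random.Random(seed)`; output is
byte-deterministic.

What it does **not** emulate: real pharmacophores, stereochemistry,
fused/heteroaromatic ring systems, realistic property correlations, or
the actual structures of any marketed drug class. Passing tests on this
set therefore demonstrate the correctness of the descriptor/KB/query
machinery under realistic value ranges, not chemical realism.

## Numerical and scale choices

Masses and logP values are rounded to 3 decimals; all other descriptors
are exact integers or strings. Test problem sizes: the full 90-molecule
set for end-to-end checks, exhaustive random sweeps at ≤ 8 atoms for the
Wiener oracle (Floyd–Warshall), hierarchies ≤ 50 types for the closure
oracle (boolean matrix powers), and full graph isomorphism for round
trips at ≤ 10 atoms with invariant-based comparison above that. These
sizes exercise every code path while keeping the whole suite around a
second.

## Known limitations

No stereochemistry, isotopes, tautomers or coordinates; no kekulization
of aromatic systems beyond single benzenoid rings; no canonical SMILES;
no SSSR; no OWL reasoning beyond subclass closure plus datatype
comparison (full DL classification is explicitly out of scope); InChI is
never computed. The 999-atom molfile limit is inherited from V2000.
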