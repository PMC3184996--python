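# cheminfkb

Computed molecular properties only become reusable scientific data when
two questions have answers: *what kind of value is this* (which
descriptor, under which definition, in which syntax) and *where did it
come from* (which software, which version, which parameters). `cheminfkb`
is a small cheminformatics toolkit built around exactly those two
questions. It parses molecules as hydrogen-suppressed chemical graphs,
computes constitutional and topological descriptors, attaches every
value to its molecule in an RDF knowledge base together with the
*parameterized software execution* that produced it, and answers the
query shapes such a knowledge base exists for: drug-likeness filtering,
provenance scoping, and subclass-aware tabulation.

It is aimed at people building semantic-web pipelines for chemical data
— the kind of setting where a "logP" from one toolkit must not be
silently pooled with a "logP" from another.

## The model in brief

A molecule is a skeleton graph: heavy atoms and bonds only, with
hydrogens inferred per atom from element, connectivity and charge
(`implicit_h = allowed_valence − bond_order_sum`, with SMILES aromatic
conventions). On top of the graph the toolkit computes molecular formula
(Hill order), average molecular mass, ring count (cyclomatic number
E − V + C), the Wiener index W = Σ_{i<j} d(i,j), Lipinski hydrogen-bond
donor/acceptor counts, and an additive per-atom logP estimate.

Descriptor *types* form a subclass hierarchy (toolkit-specific types sit
under generic ones via `rdfs:subClassOf`); each type carries a format
specification that values are validated against. In the knowledge base a
value hangs off its molecule as

    entity —has attribute→ instance —rdf:type→ type
                           instance —has value→ typed literal
                           instance —is output of→ execution —has_agent→ software

and queries exploit the hierarchy through reflexive-transitive subclass
closure. The Rule-of-Five filter (mass ≤ 500, logP < 5, HBA ≤ 10,
HBD ≤ 5) is evaluated closed-world with per-entity diagnostics.

## Worked example

The classic worked example is acetylsalicylic acid, whose annotated
SMILES — even with the spaces it picks up in typeset text — parses to
the C9H8O4 composition of its InChI:

```python
from cheminfkb import (parse_smiles, molecular_formula, average_molecular_mass,
                       hbd_count, hba_count, logp_estimate)

g = parse_smiles("CC( = O)Oc1ccccc1C(O) = O")
print(molecular_formula(g))    # C9H8O4
print(average_molecular_mass(g))  # 180.159
print(hbd_count(g), hba_count(g))  # 1 4   (carboxylic OH; four oxygens)
print(logp_estimate(g))        # 1.45
```

The donor count is 1, not 2: the phenolic oxygen is esterified and
carries no hydrogen — a detail the valence inference gets right for
free.

From the shell, the same machinery end to end:

```sh
cheminfkb generate -n 90 --seed 42 -o mols.smi
cheminfkb build-kb mols.smi --agent toolkit-A --agent-version 1.0 -o kb.ttl
cheminfkb query lipinski kb.ttl | wc -l    # prints 88
cheminfkb query provenance kb.ttl --agent <agent-uri> | wc -l   # prints 360
```

The seeded 90-molecule synthetic set is built with a 2% Rule-of-Five
violation rate, so 88 of 90 molecules pass the Lipinski filter and each
of the four descriptors computed per molecule (mass, HBD, HBA, logP)
appears among the agent's 360 provenance-scoped data items. InChI and
InChIKey values are never computed: they enter as pass-through SD-file
properties and are stored and queried byte-exact.

See `docs/methods.md` for the valence rules, the logP contribution
table, the KB modelling conventions and known limitations.

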