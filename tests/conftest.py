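import networkx as nx
import pytest

from cheminfkb import GeneratorConfig, generate_molecules, parse_smiles
from cheminfkb.chemgraph import ChemicalGraph, cyclomatic_ring_count, molecular_formula

# The aspirin annotation strings as they appear typeset (with spurious
# spaces); values are stored byte-exact, the SMILES is parsed after
# whitespace stripping.
ASPIRIN_SMILES = "CC( = O)Oc1ccccc1C(O) = O"
ASPIRIN_INCHI = (
    "InChI = 1/C9H8O4/c1-6(10)13-8-5-3-2-4-7(8)9(11)12/h2-5H,1H3,(H,11,12)/f/h11H"
)
ASPIRIN_INCHIKEY = "InChIKey = BSYNRYMUTXBXSQ-WXRBYKJCCW"


@pytest.fixture
def aspirin() -> ChemicalGraph:
    return parse_smiles(ASPIRIN_SMILES)


@pytest.fixture
def cyclohexane() -> ChemicalGraph:
    return parse_smiles("C1CCCCC1")


@pytest.fixture(scope="session")
def molecules90() -> list[tuple[str, str]]:
    """The default seeded 90-molecule synthetic set."""
    return generate_molecules(GeneratorConfig())


def graphs_isomorphic(g1: ChemicalGraph, g2: ChemicalGraph) -> bool:
    """Isomorphism check used by round-trip tests.

    Canonical invariants (formula, ring count, sorted per-atom signatures)
    for all sizes; full networkx isomorphism with atom matching for small
    graphs.
    """

    def signature(g: ChemicalGraph):
        return sorted(
            (a.element, a.formal_charge, a.aromatic, g.degree(i),
             g.implicit_h[i] if g.implicit_h else 0)
            for i, a in enumerate(g.atoms)
        )

    if str(molecular_formula(g1)) != str(molecular_formula(g2)):
        return False
    if cyclomatic_ring_count(g1) != cyclomatic_ring_count(g2):
        return False
    if signature(g1) != signature(g2):
        return False
    if len(g1.atoms) <= 10:
        n1, n2 = g1.to_networkx(), g2.to_networkx()
        for g, n in ((g1, n1), (g2, n2)):
            for i, a in enumerate(g.atoms):
                n.nodes[i]["el"] = (a.element, a.formal_charge, a.aromatic)
            for b in g.bonds:
                n.edges[b.i, b.j]["order"] = b.order
        return nx.is_isomorphic(
            n1, n2,
            node_match=lambda x, y: x["el"] == y["el"],
            edge_match=lambda x, y: x["order"] == y["order"],
        )
    return True
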