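import random

import numpy as np
import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS

from cheminfkb.descriptors import (
    SPEC_REAL,
    DescriptorInstance,
    compute_descriptors,
    default_registry,
)
from cheminfkb.errors import QueryError
from cheminfkb.kb_model import (
    CHEMINF,
    HAS_ATTRIBUTE,
    HAS_VALUE,
    INCHI_DESCRIPTOR,
    IS_OUTPUT_OF,
    XLOGP_DESCRIPTOR,
    KnowledgeBase,
)
from cheminfkb.query_engine import (
    ClassExpressionFilter,
    TriplePattern,
    count_molecules_with_inchi,
    filter_entities,
    lipinski_filter,
    pattern_query,
    provenance_query,
    subclass_closure,
)
from cheminfkb.structure_io import parse_smiles


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def kb(registry):
    kb = KnowledgeBase(run_id="qtest")
    kb.register_types(registry)
    return kb


def build_descriptor_kb(kb, registry, molecules, agent_name="toolkit-A"):
    """Attach the four Lipinski descriptors to every molecule under one agent."""
    agent = kb.add_agent(agent_name, "1.0")
    execution = kb.record_execution(agent)
    for smiles, label in molecules:
        g = parse_smiles(smiles)
        entity = kb.add_molecule(g, label)
        for inst in compute_descriptors(
            g, ["mass", "hbd", "hba", "logp"], execution, registry, subject=label
        ):
            kb.attach_descriptor(entity, inst)
    return agent, execution


class TestSubclassClosure:
    def test_leaf_is_reflexive(self, kb):
        leaf = URIRef("http://example.org/cheminfkb/vocab/molecular-mass")
        assert subclass_closure(kb, leaf) == {leaf}

    def test_chain(self, kb):
        a, b, c = (URIRef(f"http://x/{x}") for x in "abc")
        kb.graph.add((a, RDFS.subClassOf, b))
        kb.graph.add((b, RDFS.subClassOf, c))
        assert subclass_closure(kb, c) == {a, b, c}

    def test_toolkit_subtype_reachable_from_xlogp(self, kb, registry):
        sub = registry.register_descriptor_type("toolkit XLogP", "XLogP descriptor", SPEC_REAL)
        kb.register_types(registry)
        assert URIRef(sub.identifier) in subclass_closure(kb, XLOGP_DESCRIPTOR)

    def test_unknown_type_warns_and_is_empty(self, kb, caplog):
        with caplog.at_level("WARNING"):
            assert subclass_closure(kb, URIRef("http://x/none")) == set()
        assert "unknown" in caplog.text

    def test_matches_matrix_transitive_closure(self, kb):
        """Random DAG hierarchies up to 50 types vs a boolean-matrix oracle."""
        rnd = random.Random(99)
        for _ in range(10):
            n = rnd.randint(2, 50)
            nodes = [URIRef(f"http://t/{i}") for i in range(n)]
            adj = np.eye(n, dtype=bool)
            g = KnowledgeBase(run_id="h")
            for i in range(1, n):
                for p in rnd.sample(range(i), min(i, rnd.randint(1, 2))):
                    g.graph.add((nodes[i], RDFS.subClassOf, nodes[p]))
                    adj[i, p] = True
            reach = adj.copy()
            for _ in range(n):  # power iteration to fixpoint
                reach = reach | (reach @ adj)
            for t in range(n):
                expected = {nodes[i] for i in range(n) if reach[i, t]}
                assert subclass_closure(g, nodes[t]) == expected


def brute_force_filter(kb, conjuncts):
    """Independent per-entity evaluation reading raw triples only."""
    ops = {"<=": lambda a, b: a <= b, "<": lambda a, b: a < b,
           ">=": lambda a, b: a >= b, ">": lambda a, b: a > b,
           "=": lambda a, b: a == b}
    out = set()
    for entity in kb.entities():
        good = True
        for ctype, op, threshold in conjuncts:
            closure = subclass_closure(kb, ctype)
            witnessed = False
            for attr in kb.graph.objects(entity, HAS_ATTRIBUTE):
                types = set(kb.graph.objects(attr, RDF.type))
                if not (types & closure):
                    continue
                for val in kb.graph.objects(attr, HAS_VALUE):
                    try:
                        if ops[op](float(val.toPython()), float(threshold)):
                            witnessed = True
                    except (ValueError, TypeError):
                        pass
            if not witnessed:
                good = False
                break
        if good:
            out.add(entity)
    return out


class TestFilterEntities:
    def test_aspirin_is_drug_like(self, kb, registry):
        build_descriptor_kb(kb, registry, [("CC(=O)Oc1ccccc1C(O)=O", "aspirin")])
        result = filter_entities(kb, lipinski_filter(registry=registry))
        assert len(result) == 1

    def test_oversized_mass_excluded(self, kb, registry):
        entity = kb.add_molecule(None, "heavy")
        inst = DescriptorInstance(registry.get("molecular mass"), 600.0)
        kb.attach_descriptor(entity, inst)
        flt = ClassExpressionFilter(
            ((URIRef(registry.get("molecular mass").identifier), "<=", 500.0),)
        )
        assert len(filter_entities(kb, flt)) == 0

    def test_missing_descriptor_is_closed_world(self, kb, registry):
        entity = kb.add_molecule(None, "bare")
        result = filter_entities(kb, lipinski_filter(registry=registry))
        assert entity not in result
        assert entity in result.missing

    def test_ninety_molecule_set_matches_oracle(self, kb, registry, molecules90):
        build_descriptor_kb(kb, registry, molecules90)
        flt = lipinski_filter(registry=registry)
        result = filter_entities(kb, flt)
        assert result.matched == frozenset(brute_force_filter(kb, flt.conjuncts))

    def test_relaxing_thresholds_is_monotone(self, kb, registry, molecules90):
        build_descriptor_kb(kb, registry, molecules90[:40])
        base = filter_entities(kb, lipinski_filter(registry=registry)).matched
        for kwargs in ({"max_mass": 700}, {"max_logp": 9}, {"max_hba": 14},
                       {"max_hbd": 8}):
            relaxed = filter_entities(
                kb, lipinski_filter(registry=registry, **kwargs)
            ).matched
            assert base <= relaxed


class TestProvenanceQuery:
    def test_counts_constructed_batch(self, kb, registry):
        agent, _ = build_descriptor_kb(kb, registry, [("CCO", "a"), ("CC", "b")])
        assert len(provenance_query(kb, agent.identifier)) == 8  # 2 mols x 4 descriptors

    def test_no_executions(self, kb):
        assert provenance_query(kb, URIRef("http://x/agent")) == set()

    def test_two_agents_partition(self, kb, registry, molecules90):
        agent1, exec1 = build_descriptor_kb(kb, registry, molecules90[:5], "toolkit-A")
        agent2 = kb.add_agent("toolkit-B", "2.0")
        exec2 = kb.record_execution(agent2)
        for smiles, label in molecules90[5:8]:
            g = parse_smiles(smiles)
            entity = kb.add_molecule(g, label + "-b")
            for inst in compute_descriptors(g, ["logp"], exec2, registry):
                kb.attach_descriptor(entity, inst)
        r1 = provenance_query(kb, agent1.identifier)
        r2 = provenance_query(kb, agent2.identifier)
        assert len(r1) == 20 and len(r2) == 3
        assert not r1 & r2

    def test_invariant_under_triple_permutation(self, kb, registry):
        agent, _ = build_descriptor_kb(kb, registry, [("CCO", "a")])
        expected = provenance_query(kb, agent.identifier)
        shuffled = KnowledgeBase(run_id="perm")
        triples = sorted(kb.graph, key=lambda t: hash(t))
        for t in triples:
            shuffled.graph.add(t)
        assert provenance_query(shuffled, agent.identifier) == expected


class TestPatternQuery:
    def make_openeye_kb(self, kb, registry):
        agent = kb.add_agent("OpenEye", "1.7", identifier=CHEMINF.CHEMINF_000267)
        execution = kb.record_execution(agent)
        for smiles, label in [("CCO", "ethanol"), ("CCCC", "butane")]:
            g = parse_smiles(smiles)
            entity = kb.add_molecule(g, label)
            for inst in compute_descriptors(g, ["logp"], execution, registry):
                kb.attach_descriptor(entity, inst,
                                     instance_label=f"{label} XLogP")
        return agent

    def tabulation_patterns(self, kb, agent_uri):
        return [
            TriplePattern("?compound", HAS_ATTRIBUTE, "?x"),
            TriplePattern("?compound", RDFS.label, "?compname"),
            TriplePattern("?x", RDF.type, "?y"),
            TriplePattern("?x", HAS_VALUE, "?descvalue"),
            TriplePattern("?x", RDFS.label, "?descname"),
            TriplePattern("?x", IS_OUTPUT_OF, "?z"),
            TriplePattern("?y", RDFS.subClassOf, XLOGP_DESCRIPTOR, subclass=True),
            TriplePattern("?y", RDFS.label, "?desctype"),
            TriplePattern("?z", kb.has_agent, agent_uri),
        ]

    def test_tabulates_openeye_descriptors(self, kb, registry):
        agent = self.make_openeye_kb(kb, registry)
        rows = pattern_query(
            kb, self.tabulation_patterns(kb, agent.identifier),
            ["?compname", "?desctype", "?descname", "?descvalue"],
        )
        assert len(rows) == 2
        names = {str(r[0]) for r in rows}
        assert names == {"ethanol", "butane"}
        for _, desctype, _, value in rows:
            assert str(desctype) == "XLogP descriptor"
            assert isinstance(value, Literal) and isinstance(value.toPython(), float)

    def test_absent_agent_yields_no_rows(self, kb, registry):
        self.make_openeye_kb(kb, registry)
        rows = pattern_query(
            kb, self.tabulation_patterns(kb, URIRef("http://x/ghost")),
            ["?compname"],
        )
        assert rows == []

    def test_unbound_projection_rejected(self, kb):
        with pytest.raises(QueryError, match="not bound"):
            pattern_query(kb, [TriplePattern("?s", RDF.type, "?o")], ["?missing"])

    def test_disconnected_join_rejected(self, kb):
        with pytest.raises(QueryError, match="connected"):
            pattern_query(
                kb,
                [TriplePattern("?a", RDF.type, "?b"),
                 TriplePattern("?c", RDFS.label, "?d")],
                ["?a"],
            )


class TestInChICount:
    def add_inchi(self, kb, registry, label, value="InChI = 1/..."):
        entity = kb.add_molecule(None, label)
        inst = DescriptorInstance(registry.get("InChI descriptor"), value)
        kb.attach_descriptor(entity, inst)
        return entity

    def test_three_molecules(self, kb, registry):
        for i in range(3):
            self.add_inchi(kb, registry, f"m{i}")
        assert count_molecules_with_inchi(kb) == 3

    def test_empty_kb(self, kb):
        assert count_molecules_with_inchi(kb) == 0

    def test_distinctness(self, kb, registry):
        entity = self.add_inchi(kb, registry, "m")
        inst = DescriptorInstance(registry.get("InChI descriptor"), "InChI = 1/other")
        kb.attach_descriptor(entity, inst)
        assert count_molecules_with_inchi(kb) == 1

    def test_subtype_counts_through_closure(self, kb, registry):
        from cheminfkb.descriptors import SPEC_INCHI

        sub = registry.register_descriptor_type(
            "toolkit InChI", "InChI descriptor", SPEC_INCHI
        )
        kb.register_types(registry)
        entity = kb.add_molecule(None, "m")
        kb.graph.add((entity, HAS_ATTRIBUTE, URIRef("http://x/i")))
        kb.graph.add((URIRef("http://x/i"), RDF.type, URIRef(sub.identifier)))
        assert count_molecules_with_inchi(kb) == 1
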