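"""The RDF knowledge base: molecules, descriptors, agents and executions.

Molecules are typed as chemical entities and labelled; descriptor
instances hang off them via *has attribute* (CHEMINF_000200) and carry
their value via *has value* (SIO_000300) as an explicitly datatyped
literal. Computed values additionally point at the parameterized software
execution (CHEMINF_000147) that produced them via *is output of*
(CHEMINF_000606), and the execution names its software agent. Everything
serializes as Turtle through rdflib.

Design notes:

* No blank nodes — descriptor instances, executions and parameters get
  minted URIs (a short hash of run id, kind and label), so triple-set
  round trips are exact and files diff cleanly.
* ``CHEMINF_000012`` is accepted as a synonym of ``SIO_000300`` on read
  and normalized to the latter; only ``SIO_000300`` is ever written.
  Whether the two are synonymous in the released ontology is a repo
  convention, not an upstream fact.
* ``has_agent`` is minted under a declared RO prefix because the source
  queries never expand it; the prefix is overridable per knowledge base.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, XSD
from rdflib.plugins.parsers.notation3 import BadSyntax

from .chemgraph import ChemicalGraph
from .descriptors import LOCAL_NS, DescriptorInstance, DescriptorRegistry
from .errors import CheminfError, ParseError

log = logging.getLogger(__name__)

CHEMINF = Namespace("http://semanticscience.org/resource/")
HAS_ATTRIBUTE = CHEMINF.CHEMINF_000200
HAS_VALUE = CHEMINF.SIO_000300
HAS_VALUE_ALIAS = CHEMINF.CHEMINF_000012
IS_OUTPUT_OF = CHEMINF.CHEMINF_000606
PARAMETERIZED_EXECUTION = CHEMINF.CHEMINF_000147
SOFTWARE_MODULE = CHEMINF.CHEMINF_000340
INCHI_DESCRIPTOR = CHEMINF.CHEMINF_000113
XLOGP_DESCRIPTOR = CHEMINF.CHEMINF_000186
OPENEYE_AGENT = CHEMINF.CHEMINF_000267

DEFAULT_RO_NS = "http://www.obofoundry.org/ro/ro.owl#"
DEFAULT_BASE = "http://example.org/cheminfkb/kb/"

LOCALV = Namespace(LOCAL_NS)
CHEMICAL_ENTITY = LOCALV["chemical-entity"]
HAS_PARAMETER = LOCALV["has-parameter"]
VERSION = LOCALV["version"]
TIMESTAMP = LOCALV["timestamp"]


def typed_literal(value) -> Literal:
    """Integers as xsd:integer, reals as xsd:double, everything else string."""
    if isinstance(value, bool):
        return Literal(str(value), datatype=XSD.string)
    if isinstance(value, int):
        return Literal(value, datatype=XSD.integer)
    if isinstance(value, float):
        return Literal(value, datatype=XSD.double)
    return Literal(str(value), datatype=XSD.string)


@dataclass(frozen=True)
class SoftwareAgent:
    identifier: URIRef
    name: str
    version: str = ""


@dataclass(frozen=True)
class ExecutionRecord:
    identifier: URIRef
    agent: SoftwareAgent
    parameters: tuple[tuple[str, object], ...] = ()
    timestamp: str | None = None


class KnowledgeBase:
    """A triple set plus class-hierarchy assertions and a namespace table."""

    def __init__(self, base: str = DEFAULT_BASE, ro_ns: str = DEFAULT_RO_NS,
                 run_id: str = "run"):
        if base.startswith(str(CHEMINF)):
            raise CheminfError("instance base URI must not live inside the CHEMINF namespace")
        self.base = base
        self.run_id = run_id
        self.ro = Namespace(ro_ns)
        self.has_agent = self.ro.has_agent
        self.graph = Graph()
        self._bind()
        self.agents: dict[URIRef, SoftwareAgent] = {}
        self._minted: dict[str, int] = {}

    def _bind(self) -> None:
        self.graph.bind("cheminf", CHEMINF)
        self.graph.bind("ro", self.ro)
        self.graph.bind("kb", Namespace(self.base))
        self.graph.bind("local", LOCALV)

    def _mint(self, kind: str, label: str) -> URIRef:
        n = self._minted.get(kind, 0)
        self._minted[kind] = n + 1
        digest = hashlib.md5(
            f"{self.run_id}|{kind}|{label}|{n}".encode()
        ).hexdigest()[:12]
        return URIRef(f"{self.base}{kind}-{digest}")

    # -- content ------------------------------------------------------------

    def load_core_vocabulary(self) -> None:
        """Merge the bundled CHEMINF/SIO term labels and subclass spine."""
        ttl = resources.files("cheminfkb.data").joinpath("core_vocabulary.ttl").read_text()
        self.graph.parse(data=ttl, format="turtle")

    def register_types(self, registry: DescriptorRegistry) -> None:
        """Write the registry's labels and subclass edges into the KB."""
        for t in registry.types.values():
            self.graph.add((URIRef(t.identifier), RDFS.label, Literal(t.label)))
            for p in sorted(t.parents):
                self.graph.add((URIRef(t.identifier), RDFS.subClassOf, URIRef(p)))

    def add_molecule(self, g: ChemicalGraph | None, label: str) -> URIRef:
        """Add a chemical-entity node with the given label; returns its URI.

        A duplicate label logs a warning but still mints a fresh URI — two
        records may legitimately share a name.
        """
        if not label:
            raise CheminfError("molecule label must be nonempty")
        if (None, RDFS.label, Literal(label)) in self.graph:
            log.warning("duplicate molecule label %r; minting a new URI", label)
        uri = self._mint("molecule", label)
        self.graph.add((uri, RDF.type, CHEMICAL_ENTITY))
        self.graph.add((uri, RDFS.label, Literal(label)))
        return uri

    def add_agent(self, name: str, version: str = "",
                  identifier: URIRef | None = None) -> SoftwareAgent:
        uri = identifier if identifier is not None else self._mint("agent", name)
        agent = SoftwareAgent(uri, name, version)
        self.agents[uri] = agent
        self.graph.add((uri, RDF.type, SOFTWARE_MODULE))
        self.graph.add((uri, RDFS.label, Literal(name)))
        if version:
            self.graph.add((uri, VERSION, Literal(version, datatype=XSD.string)))
        return agent

    def record_execution(self, agent: SoftwareAgent,
                         parameters: dict[str, object] | None = None,
                         timestamp: str | None = None) -> ExecutionRecord:
        """Record a parameterized software execution with one node per binding.

        Timestamps are optional and excluded when absent so that repeated
        builds of the same inputs are triple-identical.
        """
        if agent.identifier not in self.agents:
            raise CheminfError(f"agent {agent.name!r} is not registered in this KB")
        parameters = parameters or {}
        uri = self._mint("execution", agent.name)
        self.graph.add((uri, RDF.type, PARAMETERIZED_EXECUTION))
        self.graph.add((uri, self.has_agent, agent.identifier))
        for pname in sorted(parameters):
            pnode = self._mint("parameter", f"{agent.name}|{pname}")
            self.graph.add((uri, HAS_PARAMETER, pnode))
            self.graph.add((pnode, RDFS.label, Literal(pname)))
            self.graph.add((pnode, HAS_VALUE, typed_literal(parameters[pname])))
        if timestamp is not None:
            self.graph.add((uri, TIMESTAMP, Literal(timestamp, datatype=XSD.string)))
        return ExecutionRecord(uri, agent, tuple(sorted(parameters.items())), timestamp)

    def attach_descriptor(
        self,
        entity: URIRef,
        inst: DescriptorInstance,
        instance_label: str | None = None,
    ) -> set[tuple]:
        """Attach a descriptor instance to an entity; returns the emitted triples.

        Exactly three triples without provenance (has-attribute, rdf:type,
        has-value), five with (plus is-output-of and the execution's
        has-agent edge). An optional instance label adds an rdfs:label.
        """
        if (entity, None, None) not in self.graph:
            raise CheminfError(f"entity {entity} is not in this knowledge base")
        inst_uri = self._mint("descriptor", f"{entity}|{inst.dtype.identifier}")
        emitted = {
            (entity, HAS_ATTRIBUTE, inst_uri),
            (inst_uri, RDF.type, URIRef(inst.dtype.identifier)),
            (inst_uri, HAS_VALUE, typed_literal(inst.value)),
        }
        if inst.execution is not None:
            exec_uri = getattr(inst.execution, "identifier", inst.execution)
            agent = getattr(inst.execution, "agent", None)
            emitted.add((inst_uri, IS_OUTPUT_OF, exec_uri))
            if agent is not None:
                emitted.add((exec_uri, self.has_agent, agent.identifier))
        if instance_label:
            emitted.add((inst_uri, RDFS.label, Literal(instance_label)))
        for t in emitted:
            self.graph.add(t)
        return emitted

    # -- access -------------------------------------------------------------

    def entities(self) -> list[URIRef]:
        return sorted(self.graph.subjects(RDF.type, CHEMICAL_ENTITY))

    def label_of(self, uri: URIRef) -> str | None:
        val = self.graph.value(uri, RDFS.label)
        return str(val) if val is not None else None

    def triples(self) -> set[tuple]:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)


def add_molecule(kb: KnowledgeBase, g: ChemicalGraph | None, label: str) -> URIRef:
    return kb.add_molecule(g, label)


def attach_descriptor(kb: KnowledgeBase, entity: URIRef,
                      inst: DescriptorInstance, **kw) -> set[tuple]:
    return kb.attach_descriptor(entity, inst, **kw)


def record_execution(kb: KnowledgeBase, agent: SoftwareAgent,
                     parameters: dict | None = None, **kw) -> ExecutionRecord:
    return kb.record_execution(agent, parameters, **kw)


def serialize_turtle(kb: KnowledgeBase, path: str | Path) -> None:
    kb.graph.serialize(destination=str(path), format="turtle")


def load_turtle(path: str | Path, base: str = DEFAULT_BASE) -> KnowledgeBase:
    """Load a Turtle file; ``CHEMINF_000012`` values are normalized on read.

    Malformed Turtle raises :class:`ParseError` carrying the line number.
    """
    kb = KnowledgeBase(base=base)
    try:
        kb.graph.parse(str(path), format="turtle")
    except BadSyntax as exc:
        line = getattr(exc, "lines", None)
        line = line + 1 if line is not None else None
        raise ParseError(f"malformed Turtle in {path}: {exc.message}", line) from exc
    for s, _, o in list(kb.graph.triples((None, HAS_VALUE_ALIAS, None))):
        kb.graph.remove((s, HAS_VALUE_ALIAS, o))
        kb.graph.add((s, HAS_VALUE, o))
    kb._bind()
    return kb
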