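"""Query answering over a knowledge base.

Four query shapes are supported, matching how a descriptor KB is actually
interrogated: subclass-aware conjunctive triple patterns, datatype-
threshold class expressions (the Lipinski Rule-of-Five filter), scoping
data items by the software agent that produced them, and counting
molecules that carry an InChI annotation.

The class-expression filter is evaluated closed-world: an entity that
lacks a descriptor required by some conjunct is excluded (and reported in
the diagnostics), where a DL reasoner would merely fail to prove
membership. Multiple descriptors of one type on an entity use
"some"-semantics — any satisfying value qualifies. Numeric comparisons
are by value, never by lexical form, so an xsd:integer 4 satisfies a
double threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .descriptors import DescriptorRegistry, default_registry
from .errors import QueryError
from .kb_model import (
    HAS_ATTRIBUTE,
    HAS_VALUE,
    HAS_VALUE_ALIAS,
    INCHI_DESCRIPTOR,
    IS_OUTPUT_OF,
    XLOGP_DESCRIPTOR,
    KnowledgeBase,
)

log = logging.getLogger(__name__)

_COMPARATORS = {
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "=": lambda a, b: a == b,
}


# ---------------------------------------------------------------------------
# Subclass closure
# ---------------------------------------------------------------------------

def subclass_closure(kb: KnowledgeBase, type_uri: URIRef | str) -> set[URIRef]:
    """Reflexive-transitive set of subclasses of ``type_uri`` (itself included).

    A type the KB has never heard of yields an empty set with a warning.
    """
    t = URIRef(type_uri)
    if (t, None, None) not in kb.graph and (None, None, t) not in kb.graph:
        log.warning("type %s is unknown in this knowledge base", t)
        return set()
    closure = {t}
    frontier = [t]
    while frontier:
        cur = frontier.pop()
        for child in kb.graph.subjects(RDFS.subClassOf, cur):
            if child not in closure:
                closure.add(child)
                frontier.append(child)
    return closure


# ---------------------------------------------------------------------------
# Class-expression (Lipinski-shaped) filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassExpressionFilter:
    """A conjunction of descriptor-threshold constraints.

    Each conjunct is (descriptor type URI, comparison, threshold); an
    entity qualifies iff every conjunct is witnessed by at least one
    attached descriptor whose type lies in the conjunct's subclass
    closure and whose numeric value satisfies the comparison.
    """

    conjuncts: tuple[tuple[URIRef, str, float], ...]

    def __post_init__(self):
        for _, op, _ in self.conjuncts:
            if op not in _COMPARATORS:
                raise QueryError(f"unknown comparison operator {op!r}")


@dataclass(frozen=True)
class FilterResult:
    """Matched entities plus closed-world diagnostics.

    ``missing`` maps each excluded entity to the conjunct types for which
    it carried no descriptor at all (as opposed to a violating value).
    """

    matched: frozenset[URIRef]
    missing: dict[URIRef, tuple[URIRef, ...]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.matched)

    def __contains__(self, item):
        return item in self.matched

    def __len__(self):
        return len(self.matched)


def _numeric(lit) -> float | None:
    if not isinstance(lit, Literal):
        return None
    try:
        v = lit.toPython()
        return float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else float(str(v))
    except (ValueError, TypeError):
        return None


def lipinski_filter(
    max_mass: float = 500.0,
    max_logp: float = 5.0,
    max_hba: int = 10,
    max_hbd: int = 5,
    registry: DescriptorRegistry | None = None,
) -> ClassExpressionFilter:
    """The Rule-of-Five class expression: mass <= 500, logP < 5, HBA <= 10, HBD <= 5."""
    r = registry or default_registry()
    return ClassExpressionFilter((
        (URIRef(r.get("molecular mass").identifier), "<=", float(max_mass)),
        (XLOGP_DESCRIPTOR, "<", float(max_logp)),
        (URIRef(r.get("hydrogen bond acceptor count").identifier), "<=", float(max_hba)),
        (URIRef(r.get("hydrogen bond donor count").identifier), "<=", float(max_hbd)),
    ))


def filter_entities(kb: KnowledgeBase, f: ClassExpressionFilter) -> FilterResult:
    """Evaluate a class-expression filter over every chemical entity."""
    closures = [
        (subclass_closure(kb, ctype), op, float(threshold))
        for ctype, op, threshold in f.conjuncts
    ]
    matched: set[URIRef] = set()
    missing: dict[URIRef, tuple[URIRef, ...]] = {}
    for entity in kb.entities():
        attrs = list(kb.graph.objects(entity, HAS_ATTRIBUTE))
        lacking: list[URIRef] = []
        ok = True
        for (closure, op, threshold), (ctype, _, _) in zip(closures, f.conjuncts):
            found_any = False
            satisfied = False
            for a in attrs:
                if any((a, RDF.type, t) in kb.graph for t in closure):
                    found_any = True
                    for val in kb.graph.objects(a, HAS_VALUE):
                        num = _numeric(val)
                        if num is not None and _COMPARATORS[op](num, threshold):
                            satisfied = True
                            break
                if satisfied:
                    break
            if not found_any:
                lacking.append(URIRef(ctype))
            if not satisfied:
                ok = False
        if ok:
            matched.add(entity)
        elif lacking:
            missing[entity] = tuple(lacking)
    return FilterResult(frozenset(matched), missing)


# ---------------------------------------------------------------------------
# Provenance scoping
# ---------------------------------------------------------------------------

def provenance_query(kb: KnowledgeBase, agent_uri: URIRef | str) -> set[URIRef]:
    """All data items output by some execution whose agent is ``agent_uri``."""
    agent = URIRef(agent_uri)
    executions = set(kb.graph.subjects(kb.has_agent, agent))
    return {
        s
        for s, _, e in kb.graph.triples((None, IS_OUTPUT_OF, None))
        if e in executions
    }


# ---------------------------------------------------------------------------
# Conjunctive triple patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriplePattern:
    """One pattern of a conjunctive query.

    Positions are either rdflib terms or variable names starting with
    ``?``. With ``subclass=True`` an ``rdfs:subClassOf`` pattern matches
    the reflexive-transitive closure and an ``rdf:type`` pattern matches
    instances of any subclass of its object.
    """

    s: object
    p: object
    o: object
    subclass: bool = False

    def variables(self) -> set[str]:
        return {x for x in (self.s, self.p, self.o)
                if isinstance(x, str) and x.startswith("?")}


def _check_connected(patterns: list[TriplePattern]) -> None:
    if not patterns:
        raise QueryError("empty pattern list")
    groups = list(range(len(patterns)))

    def find(i):
        while groups[i] != i:
            groups[i] = groups[groups[i]]
            i = groups[i]
        return i

    for i in range(len(patterns)):
        for j in range(i + 1, len(patterns)):
            if patterns[i].variables() & patterns[j].variables():
                groups[find(i)] = find(j)
    if len({find(i) for i in range(len(patterns))}) > 1:
        raise QueryError("patterns do not form a connected join graph")
    if not set().union(*(p.variables() for p in patterns)):
        raise QueryError("a pattern set needs at least one variable")


def _pattern_matches(kb: KnowledgeBase, pat: TriplePattern, binding: dict):
    def resolve(x):
        if isinstance(x, str) and x.startswith("?"):
            return binding.get(x)
        return x

    s, p, o = resolve(pat.s), resolve(pat.p), resolve(pat.o)
    if p == HAS_VALUE_ALIAS:
        p = HAS_VALUE
    if pat.subclass and p == RDFS.subClassOf and o is not None:
        for t in subclass_closure(kb, o):
            yield (t, p, o)
        return
    if pat.subclass and p == RDF.type and o is not None:
        for t in subclass_closure(kb, o):
            for s2 in kb.graph.subjects(RDF.type, t):
                if s is None or s2 == s:
                    yield (s2, p, o)
        return
    yield from kb.graph.triples((s, p, o))


def pattern_query(
    kb: KnowledgeBase,
    patterns: list[TriplePattern],
    projection: list[str],
) -> list[tuple]:
    """Conjunctive join over triple patterns; returns sorted projected rows.

    Raises :class:`QueryError` for a disconnected join graph or the
    projection of a variable bound by no pattern.
    """
    _check_connected(patterns)
    all_vars = set().union(*(p.variables() for p in patterns))
    for v in projection:
        if v not in all_vars:
            raise QueryError(f"projected variable {v} is not bound by any pattern")

    # order patterns so each (after the first) shares a variable with the prefix
    ordered = [patterns[0]]
    remaining = list(patterns[1:])
    bound_vars = set(patterns[0].variables())
    while remaining:
        nxt = next(p for p in remaining if p.variables() & bound_vars)
        ordered.append(nxt)
        bound_vars |= nxt.variables()
        remaining.remove(nxt)

    bindings: list[dict] = [{}]
    for pat in ordered:
        new_bindings: list[dict] = []
        for binding in bindings:
            for s, p, o in _pattern_matches(kb, pat, binding):
                b = dict(binding)
                consistent = True
                for var, val in zip((pat.s, pat.p, pat.o), (s, p, o)):
                    if isinstance(var, str) and var.startswith("?"):
                        if var in b and b[var] != val:
                            consistent = False
                            break
                        b[var] = val
                if consistent:
                    new_bindings.append(b)
        bindings = new_bindings
        if not bindings:
            break
    rows = [tuple(b[v] for v in projection) for b in bindings]
    return sorted(rows, key=lambda r: tuple(str(x) for x in r))


def count_molecules_with_inchi(kb: KnowledgeBase) -> int:
    """Distinct entities bearing at least one InChI-typed attribute."""
    closure = subclass_closure(kb, INCHI_DESCRIPTOR)
    found: set[URIRef] = set()
    for s, _, a in kb.graph.triples((None, HAS_ATTRIBUTE, None)):
        if any((a, RDF.type, t) in kb.graph for t in closure):
            found.add(s)
    return len(found)


def rows_to_tsv(rows: list[tuple]) -> str:
    """Render query rows as TSV text (one line per row, no header)."""
    return "\n".join("\t".join(str(x) for x in row) for row in rows)
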