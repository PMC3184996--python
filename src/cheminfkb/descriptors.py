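"""Descriptor types, format specifications, and the bundled calculators.

A *chemical descriptor* here is a data item about a molecule whose syntax
conforms to a format specification (numeric-real, numeric-integer,
textual or structured). Descriptor *types* form a subclass hierarchy
rooted at the generic chemical-descriptor class, mirroring how toolkit-
specific descriptors (e.g. a particular library's logP) are mapped under
the vocabulary's generic terms; query answering later exploits that
hierarchy through subclass closure. Descriptor *instances* carry a typed
value, the molecule they are about, and optionally the parameterized
software execution that produced them.

Identifiers for terms taken from the published vocabulary live in the
``http://semanticscience.org/resource/`` namespace (CHEMINF_000123
chemical descriptor, CHEMINF_000400 chemical graph, CHEMINF_000113 InChI
descriptor, CHEMINF_000186 XLogP descriptor, CHEMINF_000251 LogP
descriptor). Every other type is minted in a local namespace — nothing is
ever invented inside the published one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

from .chemgraph import (
    ChemicalGraph,
    average_molecular_mass,
    cyclomatic_ring_count,
    wiener_index,
)
from .errors import ConformanceError, HierarchyError, StateError
from .structure_io import write_smiles

log = logging.getLogger(__name__)

CHEMINF_NS = "http://semanticscience.org/resource/"
LOCAL_NS = "http://example.org/cheminfkb/vocab/"

CHEMICAL_DESCRIPTOR = CHEMINF_NS + "CHEMINF_000123"
CHEMICAL_GRAPH = CHEMINF_NS + "CHEMINF_000400"
INCHI_DESCRIPTOR = CHEMINF_NS + "CHEMINF_000113"
XLOGP_DESCRIPTOR = CHEMINF_NS + "CHEMINF_000186"
LOGP_DESCRIPTOR = CHEMINF_NS + "CHEMINF_000251"

VALUE_SYNTAXES = ("numeric-real", "numeric-integer", "textual", "structured")


@dataclass(frozen=True)
class FormatSpecification:
    """A directive constraining the syntax of descriptor values."""

    identifier: str
    name: str
    value_syntax: str
    citation: str = ""

    def __post_init__(self):
        if self.value_syntax not in VALUE_SYNTAXES:
            raise ValueError(f"unknown value syntax {self.value_syntax!r}")


@dataclass(frozen=True)
class Quality:
    """A molecular quality a descriptor describes (mass, lipophilicity, ...)."""

    identifier: str
    label: str


@dataclass(frozen=True)
class DescriptorType:
    identifier: str
    label: str
    parents: frozenset[str]
    format_spec: FormatSpecification
    about_quality: Quality | None = None


def validate_value(spec: FormatSpecification, value) -> bool:
    """Verdict on whether ``value`` conforms to the spec's value syntax."""
    if spec.value_syntax == "numeric-integer":
        if isinstance(value, bool):
            return False
        if isinstance(value, int):
            return True
        try:
            int(str(value))
            return True
        except ValueError:
            return False
    if spec.value_syntax == "numeric-real":
        if isinstance(value, bool):
            return False
        if isinstance(value, (int, float)):
            return True
        try:
            float(str(value))
            return True
        except ValueError:
            return False
    # textual and structured accept any string-convertible value
    return True


@dataclass(frozen=True)
class DescriptorInstance:
    """A typed descriptor value attached to a molecule entity.

    ``execution`` is the URI (or record) of the parameterized software
    execution that produced the value; pass-through annotations such as an
    InChI read from an SD file have none.
    """

    dtype: DescriptorType
    value: object
    subject: str = ""
    execution: object = None

    def __post_init__(self):
        if not validate_value(self.dtype.format_spec, self.value):
            raise ConformanceError(
                f"value {self.value!r} violates the "
                f"{self.dtype.format_spec.value_syntax} specification of "
                f"{self.dtype.label!r}"
            )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

SPEC_REAL = FormatSpecification(LOCAL_NS + "fs-real", "real number", "numeric-real")
SPEC_INT = FormatSpecification(LOCAL_NS + "fs-int", "integer", "numeric-integer")
SPEC_TEXT = FormatSpecification(LOCAL_NS + "fs-text", "free text", "textual")
SPEC_SMILES = FormatSpecification(
    LOCAL_NS + "fs-smiles", "SMILES line notation", "structured",
    citation="Weininger 1988, SMILES specification",
)
SPEC_INCHI = FormatSpecification(
    LOCAL_NS + "fs-inchi", "IUPAC InChI", "structured",
    citation="IUPAC International Chemical Identifier",
)


class DescriptorRegistry:
    """The descriptor-type hierarchy plus calculator bindings."""

    def __init__(self):
        self.types: dict[str, DescriptorType] = {}
        self.by_label: dict[str, DescriptorType] = {}
        self._root = DescriptorType(
            CHEMICAL_DESCRIPTOR, "chemical descriptor", frozenset(), SPEC_TEXT
        )
        self.types[CHEMICAL_DESCRIPTOR] = self._root
        self.by_label["chemical descriptor"] = self._root

    @property
    def root(self) -> DescriptorType:
        return self._root

    def get(self, key: str) -> DescriptorType:
        """Look a type up by identifier or label."""
        if key in self.types:
            return self.types[key]
        if key in self.by_label:
            return self.by_label[key]
        raise KeyError(f"unknown descriptor type {key!r}")

    def register_descriptor_type(
        self,
        label: str,
        parent: str,
        format_spec: FormatSpecification,
        about_quality: Quality | None = None,
        identifier: str | None = None,
    ) -> DescriptorType:
        """Add a type under ``parent`` (identifier or label).

        New identifiers are minted in the local namespace unless given.
        Raises :class:`HierarchyError` on an unknown parent or a subclass
        cycle.
        """
        parent_type = self._resolve_parent(parent)
        if identifier is None:
            slug = label.lower().replace(" ", "-")
            identifier = LOCAL_NS + slug
        if identifier in self.types:
            self._check_cycle(identifier, parent_type.identifier)
            old = self.types[identifier]
            updated = DescriptorType(
                identifier, label, old.parents | {parent_type.identifier},
                format_spec, about_quality,
            )
        else:
            updated = DescriptorType(
                identifier, label, frozenset({parent_type.identifier}),
                format_spec, about_quality,
            )
        self.types[identifier] = updated
        self.by_label[label] = updated
        return updated

    def _resolve_parent(self, parent: str) -> DescriptorType:
        try:
            return self.get(parent)
        except KeyError:
            raise HierarchyError(f"unknown parent descriptor type {parent!r}") from None

    def _check_cycle(self, child_id: str, new_parent_id: str) -> None:
        # would child become its own ancestor?
        seen, frontier = set(), {new_parent_id}
        while frontier:
            t = frontier.pop()
            if t == child_id:
                raise HierarchyError(
                    f"registering {child_id} under {new_parent_id} creates a cycle"
                )
            if t in seen or t not in self.types:
                continue
            seen.add(t)
            frontier |= set(self.types[t].parents)

    def subclass_edges(self) -> list[tuple[str, str]]:
        """(child, parent) pairs for serialization into a knowledge base."""
        return [
            (t.identifier, p) for t in self.types.values() for p in sorted(t.parents)
        ]


def default_registry() -> DescriptorRegistry:
    """The bundled core vocabulary plus one type per built-in calculator."""
    r = DescriptorRegistry()
    root = "chemical descriptor"
    r.register_descriptor_type("chemical graph", root, SPEC_TEXT,
                               identifier=CHEMICAL_GRAPH)
    r.register_descriptor_type("InChI descriptor", root, SPEC_INCHI,
                               identifier=INCHI_DESCRIPTOR)
    r.register_descriptor_type("LogP descriptor", root, SPEC_REAL,
                               about_quality=Quality(LOCAL_NS + "q-lipophilicity", "lipophilicity"),
                               identifier=LOGP_DESCRIPTOR)
    r.register_descriptor_type("XLogP descriptor", "LogP descriptor", SPEC_REAL,
                               identifier=XLOGP_DESCRIPTOR)
    r.register_descriptor_type("InChIKey descriptor", root, SPEC_TEXT)
    r.register_descriptor_type("SMILES descriptor", root, SPEC_SMILES)
    mass_q = Quality(LOCAL_NS + "q-mass", "molecular mass")
    r.register_descriptor_type("molecular mass", root, SPEC_REAL, about_quality=mass_q)
    r.register_descriptor_type("hydrogen bond donor count", root, SPEC_INT)
    r.register_descriptor_type("hydrogen bond acceptor count", root, SPEC_INT)
    r.register_descriptor_type("ring count", root, SPEC_INT)
    r.register_descriptor_type("heavy atom count", root, SPEC_INT)
    r.register_descriptor_type("carbon count", root, SPEC_INT)
    r.register_descriptor_type("nitrogen count", root, SPEC_INT)
    r.register_descriptor_type("oxygen count", root, SPEC_INT)
    r.register_descriptor_type("Wiener index", root, SPEC_INT)
    return r


# ---------------------------------------------------------------------------
# Calculators
# ---------------------------------------------------------------------------

def hbd_count(g: ChemicalGraph) -> int:
    """Lipinski hydrogen-bond donors: N or O atoms bearing >= 1 hydrogen."""
    if g.implicit_h is None:
        raise StateError("hbd_count requires implicit hydrogens")
    return sum(
        1
        for i, a in enumerate(g.atoms)
        if a.element in ("N", "O") and g.implicit_h[i] > 0
    )


def hba_count(g: ChemicalGraph) -> int:
    """Lipinski hydrogen-bond acceptors: the count of N plus O atoms."""
    return sum(1 for a in g.atoms if a.element in ("N", "O"))


_LOGP_TABLE: dict | None = None


def _logp_table() -> dict:
    global _LOGP_TABLE
    if _LOGP_TABLE is None:
        path = resources.files("cheminfkb.data").joinpath("logp_contributions.json")
        _LOGP_TABLE = json.loads(path.read_text())
    return _LOGP_TABLE


def logp_atom_type(g: ChemicalGraph, i: int) -> str:
    """Atom-type key into the logP contribution table."""
    a = g.atoms[i]
    het = {"N", "O", "S", "P", "F", "Cl", "Br", "I"}
    if a.element == "C":
        has_het = any(g.atoms[j].element in het for j in g.neighbors(i))
        base = "C.aromatic" if a.aromatic else "C.aliphatic"
        return base + (".het" if has_het else "")
    if a.element == "N":
        return "N.aromatic" if a.aromatic else "N.aliphatic"
    if a.element == "O":
        if any(b.order == "double" for b in g.incident_bonds(i)):
            return "O.carbonyl"
        if a.aromatic:
            return "O.aromatic"
        h = g.implicit_h[i] if g.implicit_h is not None else 0
        return "O.hydroxyl" if h > 0 else "O.ether"
    if a.element in ("S", "P"):
        return a.element + ".any"
    return a.element


def logp_estimate(g: ChemicalGraph, table: dict | None = None) -> float:
    """Additive logP estimate: sum of per-atom contributions.

    A crude group-contribution scheme over ~15 atom types keyed on
    element, aromaticity and heteroatom neighbourhood; deliberately simple
    — provenance of the value, not chemical accuracy, is what the toolkit
    is built around. Atoms without an entry fall back to an element-level
    default (logged).
    """
    if g.implicit_h is None:
        raise StateError("logp_estimate requires implicit hydrogens")
    if table is None:
        table = _logp_table()
    contribs = table["contributions"]
    defaults = table.get("element_defaults", {})
    total = 0.0
    for i, a in enumerate(g.atoms):
        key = logp_atom_type(g, i)
        if key in contribs:
            total += contribs[key]
        else:
            log.warning("no logP contribution for atom type %s; using element default", key)
            total += defaults.get(a.element, 0.0)
    return round(total, 3)


#: label -> (descriptor-type label, calculator). Labels are what the CLI's
#: --descriptors flag and compute_descriptors accept.
CALCULATORS: dict[str, tuple[str, callable]] = {
    "mass": ("molecular mass", average_molecular_mass),
    "hbd": ("hydrogen bond donor count", hbd_count),
    "hba": ("hydrogen bond acceptor count", hba_count),
    "logp": ("XLogP descriptor", logp_estimate),
    "rings": ("ring count", cyclomatic_ring_count),
    "heavy-atoms": ("heavy atom count", lambda g: len(g.atoms)),
    "carbons": ("carbon count", lambda g: g.element_count("C")),
    "nitrogens": ("nitrogen count", lambda g: g.element_count("N")),
    "oxygens": ("oxygen count", lambda g: g.element_count("O")),
    "wiener": ("Wiener index", wiener_index),
    "smiles": ("SMILES descriptor", write_smiles),
}


def compute_descriptors(
    g: ChemicalGraph,
    requested: list[str],
    execution=None,
    registry: DescriptorRegistry | None = None,
    subject: str = "",
) -> list[DescriptorInstance]:
    """Run the requested calculators and return provenance-linked instances.

    ``requested`` holds calculator labels (keys of :data:`CALCULATORS`).
    An unknown label raises ``KeyError`` listing the available ones; a
    calculator failure propagates with the molecule label attached.
    """
    if registry is None:
        registry = default_registry()
    out: list[DescriptorInstance] = []
    for label in requested:
        if label not in CALCULATORS:
            raise KeyError(
                f"unknown descriptor {label!r}; available: "
                + ", ".join(sorted(CALCULATORS))
            )
        type_label, fn = CALCULATORS[label]
        try:
            value = fn(g)
        except Exception as exc:
            raise type(exc)(f"{subject or 'molecule'}: {exc}") from exc
        out.append(
            DescriptorInstance(registry.get(type_label), value, subject, execution)
        )
    return out
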