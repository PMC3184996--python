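"""Hydrogen-suppressed chemical graphs (skeleton graphs).

A molecule is modelled as a graph whose nodes are heavy atoms and whose
edges are covalent bonds. Hydrogens are not stored as nodes; they are
inferred from each atom's element, connectivity and formal charge, which
is the standard skeleton-graph convention for compact chemical exchange
formats. On top of the graph this module provides the constitutional
descriptors that need nothing but the graph itself: molecular formula,
average molecular mass, the cyclomatic ring count and the Wiener index.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources

import networkx as nx

from .errors import (
    ConfigurationError,
    GraphValidationError,
    StateError,
    ValenceError,
)

#: Elements accepted as heavy atoms (H only on explicitly flagged graphs).
SUPPORTED_ELEMENTS = frozenset({"B", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H"})

#: Default valences used for implicit-hydrogen inference.
DEFAULT_VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1,
}

#: Higher valence states accepted only when explicit bond orders force them.
#: No hydrogens are ever inferred onto a hypervalent atom.
EXTRA_VALENCES = {"S": (4, 6), "P": (5,)}

BOND_ORDERS = ("single", "double", "triple", "aromatic")

#: Contribution of each bond order to an atom's bond-order sum. Aromatic
#: bonds count 1; the aromatic correction happens separately in inference.
ORDER_VALUE = {"single": 1, "double": 2, "triple": 3, "aromatic": 1}

_HILL_FIRST = ("C", "H")


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, formal charge and aromaticity flag.

    ``hcount`` is an optional explicit hydrogen count (e.g. from a SMILES
    bracket atom); when set it overrides valence-based inference.
    """

    element: str
    formal_charge: int = 0
    aromatic: bool = False
    hcount: int | None = None

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise GraphValidationError(f"unsupported element {self.element!r}")
        if not -3 <= self.formal_charge <= 3:
            raise GraphValidationError(
                f"formal charge {self.formal_charge} outside [-3, +3]"
            )


@dataclass(frozen=True)
class Bond:
    """An undirected bond between two atom ordinals."""

    i: int
    j: int
    order: str = "single"

    def __post_init__(self):
        if self.order not in BOND_ORDERS:
            raise GraphValidationError(f"unknown bond order {self.order!r}")

    @property
    def endpoints(self) -> frozenset[int]:
        return frozenset((self.i, self.j))


@dataclass
class ChemicalGraph:
    """A validated hydrogen-suppressed molecular graph.

    ``implicit_h`` is ``None`` until :func:`infer_implicit_hydrogens` has
    run; descriptor operations that need hydrogen counts raise
    :class:`~cheminfkb.errors.StateError` before that.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    implicit_h: list[int] | None = None
    allow_explicit_h: bool = False
    _adj: dict[int, list[Bond]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._adj = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            self._adj[b.i].append(b)
            self._adj[b.j].append(b)

    # -- structural accessors -------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        return [b.j if b.i == i else b.i for b in self._adj[i]]

    def incident_bonds(self, i: int) -> list[Bond]:
        return list(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def bond_order_sum(self, i: int) -> int:
        return sum(ORDER_VALUE[b.order] for b in self._adj[i])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def element_count(self, element: str) -> int:
        return sum(1 for a in self.atoms if a.element == element)

    def total_hydrogens(self) -> int:
        """Implicit hydrogens plus any explicitly flagged H nodes."""
        if self.implicit_h is None:
            raise StateError("implicit hydrogens not yet inferred")
        return sum(self.implicit_h) + self.element_count("H")


def build_graph(
    atoms: list[Atom], bonds: list[Bond], *, allow_explicit_h: bool = False
) -> ChemicalGraph:
    """Validate atoms and bonds and assemble a :class:`ChemicalGraph`.

    Raises :class:`GraphValidationError` naming the offending ordinal for
    dangling endpoints, self-loops, duplicate bonds, or H nodes on a graph
    not flagged to allow them. ``implicit_h`` is left unset.
    """
    n = len(atoms)
    for i, a in enumerate(atoms):
        if a.element == "H" and not allow_explicit_h:
            raise GraphValidationError(
                f"explicit hydrogen at ordinal {i} on a hydrogen-suppressed graph"
            )
    seen: set[frozenset[int]] = set()
    for b in bonds:
        for end in (b.i, b.j):
            if not 0 <= end < n:
                raise GraphValidationError(f"bond endpoint {end} is not a valid ordinal")
        if b.i == b.j:
            raise GraphValidationError(f"self-loop on ordinal {b.i}")
        key = b.endpoints
        if key in seen:
            raise GraphValidationError(f"duplicate bond between ordinals {b.i} and {b.j}")
        seen.add(key)
    return ChemicalGraph(list(atoms), list(bonds), allow_explicit_h=allow_explicit_h)


def _allowed_valence(atom: Atom) -> int:
    """Default valence after the minimal charge adjustment."""
    v = DEFAULT_VALENCE[atom.element]
    if atom.element == "N" and atom.formal_charge == 1:
        v += 1
    elif atom.element == "O" and atom.formal_charge == -1:
        v -= 1
    return v


def infer_implicit_hydrogens(g: ChemicalGraph) -> ChemicalGraph:
    """Fill ``implicit_h`` for every atom from element, connectivity and charge.

    Rules: each atom's hydrogen count is its (charge-adjusted) default
    valence minus its bond-order sum. Aromatic bonds contribute 1 to the
    sum, and an aromatic atom carrying two or more aromatic bonds loses one
    further hydrogen, matching SMILES organic-subset conventions (a benzene
    carbon ends up with exactly one H). Sulfur and phosphorus may exceed
    their default valence when explicit bond orders force it, in which case
    no hydrogens are added. A bond-order sum beyond every allowed valence
    raises :class:`ValenceError`. Idempotent; returns ``g``.
    """
    counts: list[int] = []
    for i, atom in enumerate(g.atoms):
        bsum = g.bond_order_sum(i)
        if atom.hcount is not None:
            counts.append(atom.hcount)
            continue
        v = _allowed_valence(atom)
        if bsum <= v:
            h = v - bsum
            n_arom = sum(1 for b in g.incident_bonds(i) if b.order == "aromatic")
            if atom.aromatic and n_arom >= 2:
                h = max(0, h - 1)
        else:
            extra = EXTRA_VALENCES.get(atom.element, ())
            if any(bsum <= ev for ev in extra):
                h = 0  # hypervalent state accepted, but never H-filled
            else:
                raise ValenceError(
                    f"atom {i} ({atom.element}, charge {atom.formal_charge:+d}): "
                    f"bond-order sum {bsum} exceeds allowed valence"
                )
        counts.append(h)
    g.implicit_h = counts
    return g


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count mapping, rendered in Hill order (C, H, alphabetical)."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counter(cls, counter: Counter) -> "MolecularFormula":
        rest = sorted(e for e in counter if e not in _HILL_FIRST)
        order = [e for e in _HILL_FIRST if counter.get(e, 0) > 0] + [
            e for e in rest if counter[e] > 0
        ]
        return cls(tuple((e, counter[e]) for e in order))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(
            e if c == 1 else f"{e}{c}" for e, c in self.counts
        )


def molecular_formula(g: ChemicalGraph) -> MolecularFormula:
    """Hill-ordered molecular formula including inferred hydrogens."""
    if g.implicit_h is None:
        raise StateError("molecular_formula requires implicit hydrogens; run inference first")
    counter: Counter = Counter(a.element for a in g.atoms)
    counter["H"] += sum(g.implicit_h)
    return MolecularFormula.from_counter(counter)


def _load_weights() -> dict[str, float]:
    path = resources.files("cheminfkb.data").joinpath("atomic_weights.json")
    table = json.loads(path.read_text())
    return table["weights"]


_WEIGHTS: dict[str, float] | None = None


def average_molecular_mass(g: ChemicalGraph) -> float:
    """Average molecular mass in daltons from the bundled weight table.

    Deterministic to three decimals; hydrogens come from ``implicit_h``.
    """
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = _load_weights()
    formula = molecular_formula(g)
    mass = 0.0
    for element, count in formula.counts:
        try:
            mass += count * _WEIGHTS[element]
        except KeyError:
            raise ConfigurationError(
                f"element {element!r} missing from the atomic weight table"
            ) from None
    return round(mass, 3)


def cyclomatic_ring_count(g: ChemicalGraph) -> int:
    """Cyclomatic number E - V + C: the number of independent rings."""
    nxg = g.to_networkx()
    c = nx.number_connected_components(nxg) if len(g.atoms) else 0
    return len(g.bonds) - len(g.atoms) + c


def wiener_index(g: ChemicalGraph) -> int:
    """Sum of shortest-path bond distances over all unordered heavy-atom pairs.

    Defined only for connected graphs; every bond counts as distance 1
    regardless of order.
    """
    if len(g.atoms) <= 1:
        return 0
    nxg = g.to_networkx()
    if not nx.is_connected(nxg):
        raise GraphValidationError("Wiener index is undefined for disconnected graphs")
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(nxg):
        total += sum(dists.values())
    return total // 2


def relabeled(g: ChemicalGraph, perm: list[int]) -> ChemicalGraph:
    """Return a copy with atom ordinals permuted (``perm[i]`` = new ordinal of i)."""
    n = len(g.atoms)
    new_atoms: list[Atom | None] = [None] * n
    for i, a in enumerate(g.atoms):
        new_atoms[perm[i]] = a
    new_bonds = [replace(b, i=perm[b.i], j=perm[b.j]) for b in g.bonds]
    out = build_graph([a for a in new_atoms if a is not None], new_bonds,
                      allow_explicit_h=g.allow_explicit_h)
    if g.implicit_h is not None:
        hh = [0] * n
        for i, h in enumerate(g.implicit_h):
            hh[perm[i]] = h
        out.implicit_h = hh
    return out
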