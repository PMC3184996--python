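"""Molecule exchange formats: a SMILES subset, MDL molfile V2000 and SD files.

The SMILES dialect is the Daylight organic subset: atoms B C N O P S F Cl
Br I (lowercase for aromatic b c n o p s), bracket atoms with an optional
explicit hydrogen count and formal charge, branches, bond symbols
``- = # :``, ring-closure digits 0-9 and ``.`` for disconnected parts. No
stereo marks, isotopes, wildcard atoms or ``%nn`` ring closures. All
whitespace is stripped before lexing, so strings copied out of typeset
documents (which often acquire spurious spaces) parse unchanged.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

from .chemgraph import (
    Atom,
    Bond,
    ChemicalGraph,
    build_graph,
    infer_implicit_hydrogens,
)
from .errors import (
    CapacityError,
    FormatError,
    ParseError,
    UnsupportedFeatureError,
)

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
AROMATIC_SYMBOLS = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}
_BOND_SYMBOLS = {"-": "single", "=": "double", "#": "triple", ":": "aromatic"}
_ORDER_TO_MDL = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}
_MDL_TO_ORDER = {v: k for k, v in _ORDER_TO_MDL.items()}


# ---------------------------------------------------------------------------
# SMILES reading
# ---------------------------------------------------------------------------

def _parse_bracket(s: str, pos: int) -> tuple[Atom, int]:
    """Parse a bracket atom starting at the ``[`` at ``pos``; return (atom, end)."""
    i = pos + 1
    if i < len(s) and s[i].isdigit():
        raise ParseError("isotope specifications are unsupported", i)
    element = None
    aromatic = False
    if s[i : i + 2] in ("Cl", "Br"):
        element, i = s[i : i + 2], i + 2
    elif i < len(s) and s[i] in AROMATIC_SYMBOLS:
        element, aromatic, i = AROMATIC_SYMBOLS[s[i]], True, i + 1
    elif i < len(s) and s[i].isupper() and s[i] in ORGANIC_SUBSET | {"H"}:
        element, i = s[i], i + 1
    else:
        raise ParseError(f"unknown element in bracket atom: {s[i:i+2]!r}", i)
    hcount = None
    if i < len(s) and s[i] == "H" and element != "H":
        i += 1
        m = re.match(r"\d+", s[i:])
        if m:
            hcount, i = int(m.group()), i + m.end()
        else:
            hcount = 1
    charge = 0
    if i < len(s) and s[i] in "+-":
        sign = 1 if s[i] == "+" else -1
        ch = s[i]
        i += 1
        m = re.match(r"\d+", s[i:])
        if m:
            charge, i = sign * int(m.group()), i + m.end()
        else:
            charge = sign
            while i < len(s) and s[i] == ch:  # ++ / -- forms
                charge += sign
                i += 1
    if i >= len(s) or s[i] != "]":
        raise ParseError("unterminated bracket atom", pos)
    if hcount is None:
        hcount = 0  # bracket atoms state their hydrogens explicitly
    return Atom(element, charge, aromatic, hcount=hcount), i + 1


def parse_smiles(s: str) -> ChemicalGraph:
    """Parse a SMILES string into a graph with implicit hydrogens inferred.

    Raises :class:`ParseError` with a character offset for unmatched ring
    closures or parentheses and unknown symbols.
    """
    s = "".join(s.split())
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    branch_stack: list[int | None] = []
    prev: int | None = None
    pending_bond: str | None = None
    ring_open: dict[str, tuple[int, str | None, int]] = {}
    pos = 0

    def add_atom(atom: Atom) -> None:
        nonlocal prev, pending_bond
        idx = len(atoms)
        atoms.append(atom)
        if prev is not None:
            order = pending_bond
            if order is None:
                order = (
                    "aromatic"
                    if atoms[prev].aromatic and atom.aromatic
                    else "single"
                )
            bonds.append(Bond(prev, idx, order))
        prev = idx
        pending_bond = None

    while pos < len(s):
        ch = s[pos]
        if s[pos : pos + 2] in ("Cl", "Br"):
            add_atom(Atom(s[pos : pos + 2]))
            pos += 2
        elif ch in ORGANIC_SUBSET:
            add_atom(Atom(ch))
            pos += 1
        elif ch in AROMATIC_SYMBOLS:
            add_atom(Atom(AROMATIC_SYMBOLS[ch], aromatic=True))
            pos += 1
        elif ch == "[":
            atom, pos = _parse_bracket(s, pos)
            add_atom(atom)
        elif ch in _BOND_SYMBOLS:
            pending_bond = _BOND_SYMBOLS[ch]
            pos += 1
        elif ch == "(":
            if prev is None:
                raise ParseError("branch opened before any atom", pos)
            branch_stack.append(prev)
            pos += 1
        elif ch == ")":
            if not branch_stack:
                raise ParseError("unmatched closing parenthesis", pos)
            prev = branch_stack.pop()
            pos += 1
        elif ch.isdigit():
            if prev is None:
                raise ParseError("ring closure before any atom", pos)
            if ch in ring_open:
                other, other_bond, _ = ring_open.pop(ch)
                order = pending_bond or other_bond
                if pending_bond and other_bond and pending_bond != other_bond:
                    raise ParseError(f"conflicting bond orders on ring closure {ch}", pos)
                if order is None:
                    order = (
                        "aromatic"
                        if atoms[other].aromatic and atoms[prev].aromatic
                        else "single"
                    )
                if other == prev:
                    raise ParseError(f"ring closure {ch} bonds an atom to itself", pos)
                bonds.append(Bond(other, prev, order))
            else:
                ring_open[ch] = (prev, pending_bond, pos)
            pending_bond = None
            pos += 1
        elif ch == ".":
            prev = None
            pending_bond = None
            pos += 1
        else:
            raise ParseError(f"unknown symbol {ch!r}", pos)

    if branch_stack:
        raise ParseError("unmatched opening parenthesis", len(s))
    if ring_open:
        digit, (_, _, where) = next(iter(ring_open.items()))
        raise ParseError(f"unmatched ring closure {digit}", where)
    g = build_graph(atoms, bonds, allow_explicit_h=any(a.element == "H" for a in atoms))
    return infer_implicit_hydrogens(g)


# ---------------------------------------------------------------------------
# SMILES writing
# ---------------------------------------------------------------------------

def _atom_token(atom: Atom, implicit_h: int) -> str:
    if atom.aromatic and atom.element not in AROMATIC_SYMBOLS.values():
        raise UnsupportedFeatureError(f"aromatic {atom.element} is outside the grammar")
    sym = atom.element.lower() if atom.aromatic else atom.element
    if atom.formal_charge == 0 and atom.hcount is None and atom.element in ORGANIC_SUBSET:
        return sym
    h = atom.hcount if atom.hcount is not None else implicit_h
    out = "[" + sym
    if h == 1:
        out += "H"
    elif h > 1:
        out += f"H{h}"
    if atom.formal_charge:
        sign = "+" if atom.formal_charge > 0 else "-"
        mag = abs(atom.formal_charge)
        out += sign if mag == 1 else f"{sign}{mag}"
    return out + "]"


def _bond_prefix(order: str, a: Atom, b: Atom) -> str:
    if order == "single":
        return "-" if (a.aromatic and b.aromatic) else ""
    if order == "double":
        return "="
    if order == "triple":
        return "#"
    return "" if (a.aromatic and b.aromatic) else ":"


def write_smiles(g: ChemicalGraph) -> str:
    """Serialize a graph to SMILES; deterministic for a fixed atom ordering.

    Not canonical across orderings: ``parse_smiles(write_smiles(g))`` is
    guaranteed isomorphic to ``g``, nothing stronger.
    """
    if any(a.element == "H" for a in g.atoms):
        raise UnsupportedFeatureError("explicit hydrogen nodes are outside the grammar")
    n = len(g.atoms)
    hs = g.implicit_h if g.implicit_h is not None else [0] * n
    visited = [False] * n
    tree_children: dict[int, list[tuple[int, Bond]]] = defaultdict(list)
    opens: dict[int, list[int]] = defaultdict(list)   # atom -> ring bond ids
    closes: dict[int, list[int]] = defaultdict(list)
    ring_bonds: list[Bond] = []
    processed: set[frozenset[int]] = set()

    # classify must walk in the same order as emit so that every ring bond
    # opens at the endpoint that is emitted first (its DFS ancestor)
    def classify(u: int) -> None:
        visited[u] = True
        for b in sorted(g.incident_bonds(u), key=lambda b: b.j if b.i == u else b.i):
            v = b.j if b.i == u else b.i
            if b.endpoints in processed:
                continue
            processed.add(b.endpoints)
            if visited[v]:
                rb = len(ring_bonds)
                ring_bonds.append(b)
                opens[v].append(rb)
                closes[u].append(rb)
            else:
                tree_children[u].append((v, b))
                classify(v)

    digit_of: dict[int, str] = {}
    free_digits: list[str]

    def emit(u: int, out: list[str]) -> None:
        out.append(_atom_token(g.atoms[u], hs[u]))
        for rb in opens[u]:
            if not free_digits:
                raise UnsupportedFeatureError("more than 10 simultaneously open rings")
            digit_of[rb] = free_digits.pop(0)
            b = ring_bonds[rb]
            other = b.j if b.i == u else b.i
            out.append(_bond_prefix(b.order, g.atoms[u], g.atoms[other]) + digit_of[rb])
        for rb in closes[u]:
            d = digit_of.pop(rb)
            free_digits.append(d)
            out.append(d)
        children = tree_children[u]
        for k, (v, b) in enumerate(children):
            prefix = _bond_prefix(b.order, g.atoms[u], g.atoms[v])
            if k < len(children) - 1:
                out.append("(" + prefix)
                emit(v, out)
                out.append(")")
            else:
                out.append(prefix)
                emit(v, out)

    pieces = []
    for start in range(n):
        if visited[start]:
            continue
        classify(start)
        free_digits = list("1234567890")
        part: list[str] = []
        emit(start, part)
        pieces.append("".join(part))
    return ".".join(pieces)


# ---------------------------------------------------------------------------
# MDL molfile V2000
# ---------------------------------------------------------------------------

def write_molfile(g: ChemicalGraph, name: str = "") -> str:
    """Render as MDL molfile V2000 with zero coordinates.

    The counts line uses the fixed 3-character field widths of the V2000
    layout. Formal charges are written as ``M  CHG`` property lines.
    """
    na, nb = len(g.atoms), len(g.bonds)
    if na > 999:
        raise CapacityError(f"{na} atoms exceed the 999-atom V2000 limit")
    lines = [name, "  cheminfkb", ""]
    lines.append(f"{na:>3}{nb:>3}  0  0  0  0  0  0  0  0999 V2000")
    for a in g.atoms:
        lines.append(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for b in g.bonds:
        lines.append(f"{b.i + 1:>3}{b.j + 1:>3}{_ORDER_TO_MDL[b.order]:>3}  0  0  0  0")
    charged = [(i + 1, a.formal_charge) for i, a in enumerate(g.atoms) if a.formal_charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k : k + 8]
        lines.append(
            f"M  CHG{len(chunk):>3}" + "".join(f"{i:>4}{c:>4}" for i, c in chunk)
        )
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_molfile(text: str) -> ChemicalGraph:
    """Parse an MDL molfile V2000; coordinates are discarded.

    Raises :class:`FormatError` when the counts line disagrees with the
    block lengths.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError("molfile truncated before the counts line")
    counts = lines[3]
    try:
        na, nb = int(counts[0:3]), int(counts[3:6])
    except ValueError:
        raise FormatError(f"unreadable counts line: {counts!r}") from None
    if len(lines) < 4 + na + nb:
        raise FormatError(
            f"counts line declares {na} atoms and {nb} bonds but the file is shorter"
        )
    elements: list[str] = []
    for k in range(na):
        line = lines[4 + k]
        el = line[31:34].strip()
        if not el:
            raise FormatError(f"atom line {k + 1} has no element symbol (counts mismatch?)")
        elements.append(el)
    bonds: list[Bond] = []
    for k in range(nb):
        line = lines[4 + na + k]
        try:
            i, j, t = int(line[0:3]) - 1, int(line[3:6]) - 1, int(line[6:9])
        except ValueError:
            raise FormatError(f"unreadable bond line {k + 1}: {line!r}") from None
        order = _MDL_TO_ORDER.get(t)
        if order is None:
            raise FormatError(f"bond line {k + 1}: unsupported bond type {t}")
        bonds.append(Bond(i, j, order))
    charges: dict[int, int] = {}
    for line in lines[4 + na + nb :]:
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            toks = line.split()[3:]
            for idx, chg in zip(toks[0::2], toks[1::2]):
                charges[int(idx) - 1] = int(chg)
    aromatic_atoms = {e for b in bonds if b.order == "aromatic" for e in (b.i, b.j)}
    atoms = [
        Atom(el, charges.get(i, 0), aromatic=i in aromatic_atoms)
        for i, el in enumerate(elements)
    ]
    g = build_graph(atoms, bonds, allow_explicit_h=any(e == "H" for e in elements))
    return infer_implicit_hydrogens(g)


# ---------------------------------------------------------------------------
# Multi-molecule files
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[tuple[ChemicalGraph, str]]:
    """Read a .smi file: one ``SMILES [label]`` per line, blank lines skipped."""
    out: list[tuple[ChemicalGraph, str]] = []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        label = parts[1].strip() if len(parts) > 1 else f"mol{k + 1}"
        out.append((parse_smiles(smiles), label))
    return out


def read_sdf(path: str | Path) -> list[tuple[ChemicalGraph, dict[str, str]]]:
    """Read an SD file: V2000 records with ``> <TAG>`` property blocks.

    Property values are returned verbatim as strings — SD properties are
    free text and typing them is the job of the descriptor layer. A record
    without a ``$$$$`` terminator raises :class:`FormatError` naming the
    record index.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    records: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append([])
        else:
            records[-1].append(line)
    trailing = records.pop()
    if any(l.strip() for l in trailing):
        raise FormatError(f"record {len(records) + 1} lacks a $$$$ terminator")
    out: list[tuple[ChemicalGraph, dict[str, str]]] = []
    for ridx, rec in enumerate(records):
        try:
            end = next(i for i, l in enumerate(rec) if l.startswith("M  END"))
        except StopIteration:
            raise FormatError(f"record {ridx + 1} has no M  END line") from None
        graph = read_molfile("\n".join(rec[: end + 1]))
        props: dict[str, str] = {}
        i = end + 1
        while i < len(rec):
            line = rec[i]
            m = re.match(r">\s*<(.+?)>", line)
            if m:
                tag = m.group(1)
                vals = []
                i += 1
                while i < len(rec) and rec[i].strip():
                    vals.append(rec[i])
                    i += 1
                props[tag] = "\n".join(vals)
            else:
                i += 1
        out.append((graph, props))
    return out
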