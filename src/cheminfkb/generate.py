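"""Seeded synthetic-molecule generator.

Emulates the shape of a small drug-like screening set (by default 90
molecules, the size of a typical antidepressant panel): random carbon skeletons —
trees plus an optional six-ring, aromatic or saturated — decorated with
hydroxyl, amine, halogen and carboxyl substituents so that mass, logP and
hydrogen-bond counts span the Rule-of-Five boundaries. A configurable
fraction of molecules is constructed to violate at least one Lipinski
bound (an oversized alkane or an over-donored polyol), so a 90-molecule
set at the default 2% rate has the familiar "almost all drug-like" shape.

All randomness flows through one ``random.Random(seed)``; output is
byte-deterministic for a fixed config.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .chemgraph import Atom, Bond, ChemicalGraph, build_graph, infer_implicit_hydrogens
from .descriptors import average_molecular_mass, hba_count, hbd_count, logp_estimate
from .errors import ConfigurationError


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 90
    seed: int = 42
    ring_probability: float = 0.6
    heteroatom_probability: float = 0.35
    size_range: tuple[int, int] = (6, 14)
    lipinski_violation_rate: float = 0.02

    def __post_init__(self):
        for name in ("ring_probability", "heteroatom_probability", "lipinski_violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"unsatisfiable size_range {self.size_range}")
        if self.n < 0:
            raise ConfigurationError(f"negative molecule count {self.n}")


class _Builder:
    """Mutable scaffold with per-atom remaining substituent capacity."""

    def __init__(self):
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self.capacity: list[int] = []

    def add(self, element: str, aromatic: bool = False, capacity: int | None = None) -> int:
        self.atoms.append(Atom(element, aromatic=aromatic))
        if capacity is None:
            capacity = {"C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1}[element]
        self.capacity.append(capacity)
        return len(self.atoms) - 1

    def bond(self, i: int, j: int, order: str = "single") -> None:
        cost = {"single": 1, "double": 2, "triple": 3, "aromatic": 1}[order]
        self.bonds.append(Bond(i, j, order))
        self.capacity[i] -= cost
        self.capacity[j] -= cost

    def open_sites(self, element: str | None = None) -> list[int]:
        return [
            i
            for i, c in enumerate(self.capacity)
            if c > 0 and (element is None or self.atoms[i].element == element)
        ]

    def finish(self) -> ChemicalGraph:
        return infer_implicit_hydrogens(build_graph(self.atoms, self.bonds))


def _carbon_chain(k: int) -> _Builder:
    b = _Builder()
    prev = b.add("C")
    for _ in range(k - 1):
        nxt = b.add("C")
        b.bond(prev, nxt)
        prev = nxt
    return b


def _decorate(b: _Builder, rng: random.Random, p_het: float) -> None:
    for i in list(b.open_sites("C")):
        if b.capacity[i] <= 0 or rng.random() >= p_het:
            continue
        roll = rng.random()
        if roll < 0.35:  # hydroxyl
            o = b.add("O")
            b.bond(i, o)
        elif roll < 0.55:  # amine
            n = b.add("N")
            b.bond(i, n)
        elif roll < 0.75:  # halogen
            x = b.add(rng.choice(["F", "Cl"]))
            b.bond(i, x)
        else:  # carboxyl
            c = b.add("C")
            b.bond(i, c)
            o1 = b.add("O")
            b.bond(c, o1, "double")
            o2 = b.add("O")
            b.bond(c, o2)


def _random_skeleton(rng: random.Random, cfg: GeneratorConfig) -> _Builder:
    k = rng.randint(*cfg.size_range)
    b = _Builder()
    if k >= 6 and rng.random() < cfg.ring_probability:
        aromatic = rng.random() < 0.5
        ring = [b.add("C", aromatic=aromatic) for _ in range(6)]
        for idx in range(6):
            b.bond(ring[idx], ring[(idx + 1) % 6],
                   "aromatic" if aromatic else "single")
        if aromatic:
            # one inferred H is consumed by aromaticity; one substituent slot each
            for idx in ring:
                b.capacity[idx] = 1
        grown = 6
    else:
        b.add("C")
        grown = 1
    while grown < k:
        sites = b.open_sites("C")
        if not sites:
            break
        at = rng.choice(sites)
        c = b.add("C")
        b.bond(at, c)
        grown += 1
    _decorate(b, rng, cfg.heteroatom_probability)
    return b


def _is_rule_of_five_compliant(g: ChemicalGraph) -> bool:
    return (
        average_molecular_mass(g) <= 500.0
        and logp_estimate(g) < 5.0
        and hba_count(g) <= 10
        and hbd_count(g) <= 5
    )


def _violator(rng: random.Random) -> ChemicalGraph:
    if rng.random() < 0.5:
        # oversized alkane: mass well above 500
        b = _carbon_chain(44)
    else:
        # polyol with six donors
        b = _carbon_chain(8)
        for i in rng.sample(range(8), 6):
            o = b.add("O")
            b.bond(i, o)
    return b.finish()


def generate_molecule(rng: random.Random, cfg: GeneratorConfig,
                      violator: bool) -> ChemicalGraph:
    """One molecule; compliant ones are rejection-sampled against all four bounds."""
    if violator:
        return _violator(rng)
    for _ in range(100):
        g = _random_skeleton(rng, cfg).finish()
        if _is_rule_of_five_compliant(g):
            return g
    # tiny fallback skeleton is always compliant
    return _carbon_chain(4).finish()


def generate_molecules(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    """Deterministic (SMILES, label) pairs for the configured set."""
    from .structure_io import write_smiles

    rng = random.Random(cfg.seed)
    out: list[tuple[str, str]] = []
    for i in range(cfg.n):
        violator = rng.random() < cfg.lipinski_violation_rate
        g = generate_molecule(rng, cfg, violator)
        out.append((write_smiles(g), f"SYN-{i + 1:04d}"))
    return out
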