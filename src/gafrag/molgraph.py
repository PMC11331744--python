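"""Attributed molecular graph: bond perception, node attributes, and
perception of conjugated systems and hyperconjugated donor/acceptor pairs.

A molecular system is modelled as a graph whose nodes are atoms (attributes:
atomic number, formal charge, π-electron count, hybridisation, coordinates)
and whose edges are covalent bonds (sole attribute: integer bond order).
Bonds are perceived geometrically against a bundled reference-length table.

Conjugated systems are maximal connected components of the sp²/sp-induced
subgraph with at least three members; each carries a conjugation score

    cs = (1/N_A) Σ_i N_e^i / N_A

over its per-atom π contributions.  Hyperconjugated pairs couple a σ group
(C–H or C–halogen bond) with a π group (multiple bond, lone pair, charged
sp² carbon, or a whole conjugated system) at a graph separation of at most
three bonds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from . import tables
from .geom import Structure


class Hybridisation(str, Enum):
    SP3 = "sp3"
    SP2 = "sp2"
    SP = "sp"
    OTHER = "other"


@dataclass
class Atom:
    index: int
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    n_pi_electrons: int = 0
    hybridisation: Hybridisation = Hybridisation.OTHER

    @property
    def atomic_number(self) -> int:
        return tables.ATOMIC_NUMBERS[self.element]

    @property
    def covalent_radius(self) -> float:
        return tables.COVALENT_RADII[self.element]

    @property
    def vdw_radius(self) -> float:
        return tables.VDW_RADII[self.element]


@dataclass
class Bond:
    i: int
    j: int
    order: int
    length: float

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.i, self.j)

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class ConjugatedSystem:
    atom_indices: frozenset[int]
    pi_contribution: dict[int, int]
    member_bonds: frozenset[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.atom_indices)

    @property
    def conjugation_score(self) -> float:
        n = self.size
        return sum(self.pi_contribution.values()) / (n * n)

    @property
    def delta_max(self) -> float:
        """Largest possible conjugation disruption: every internal bond cut."""
        return self.size - 1

    @property
    def total_pi_electrons(self) -> int:
        return sum(self.pi_contribution.values())


class GroupType(str, Enum):
    SIGMA = "sigma"
    PI = "pi"


@dataclass(frozen=True)
class HyperGroup:
    """A donor/acceptor candidate: an atom set with a σ/π character."""

    atoms: frozenset[int]
    gtype: GroupType
    label: str
    #: electrons the group donates when acting as a donor
    n_electrons: int = 2


@dataclass
class HyperconjugatedPair:
    donor: HyperGroup
    acceptor: HyperGroup
    separation_bonds: int
    #: shortest donor→acceptor bond path (atom indices, donor end first)
    path: tuple[int, ...]

    @property
    def donated_electrons(self) -> int:
        return self.donor.n_electrons

    @property
    def donor_atom_count(self) -> int:
        return len(self.donor.atoms)

    @property
    def delta_max(self) -> float:
        return self.donated_electrons / self.donor_atom_count


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[Bond]
    conjugated_systems: list[ConjugatedSystem] = field(default_factory=list)
    hyper_pairs: list[HyperconjugatedPair] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def total_atom_count(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def bond_lookup(self) -> dict[tuple[int, int], Bond]:
        return {b.key(): b for b in self.bonds}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.atoms)
        g.add_edges_from((b.i, b.j, {"order": b.order}) for b in self.bonds)
        return g

    def neighbours(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return sorted(out)

    def subgraph(self, atom_indices: set[int]) -> "MolecularGraph":
        """Induced subgraph with atoms re-indexed 0..n-1 (perception is
        re-run by the caller via :func:`annotate` if needed).  The mapping
        old->new is stored on each Atom as the original global index being
        preserved in ``Atom.index``? No: new indices are local; use the
        returned ``mapping`` attribute."""
        order = sorted(atom_indices)
        remap = {old: new for new, old in enumerate(order)}
        atoms = []
        for old in order:
            a = self.atoms[old]
            atoms.append(Atom(remap[old], a.element, a.coords.copy(),
                              a.formal_charge))
        bonds = [Bond(remap[b.i], remap[b.j], b.order, b.length)
                 for b in self.bonds
                 if b.i in atom_indices and b.j in atom_indices]
        sub = MolecularGraph(atoms, bonds, name=self.name)
        sub.local_to_global = order  # type: ignore[attr-defined]
        return sub


def perceive_bonds(structure: Structure) -> list[Bond]:
    """Geometric bond perception against the bundled reference-length table.

    A bond exists between two atoms when their distance does not exceed the
    longest reference length for the element pair plus a 0.25 Å tolerance;
    its order is the reference order with the smallest absolute deviation.
    """
    n = len(structure)
    if n < 1:
        raise ValueError("structure has no atoms")
    xyz = structure.coords
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    bonds: list[Bond] = []
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.sqrt(d2[i, j]))
            if dist < tables.OVERLAP_DISTANCE:
                raise ValueError(
                    f"overlapping atoms {i} ({structure.elements[i]}) and "
                    f"{j} ({structure.elements[j]}): d = {dist:.3f} Å")
            refs = tables.reference_lengths(structure.elements[i],
                                            structure.elements[j])
            if not refs:
                continue
            if dist <= max(refs.values()) + tables.BOND_TOLERANCE:
                order = min(refs, key=lambda o: abs(dist - refs[o]))
                bonds.append(Bond(i, j, order, dist))
    return bonds


def build_graph(structure: Structure) -> MolecularGraph:
    """Perceive bonds and return a bare (unannotated) molecular graph."""
    for el in structure.elements:
        if el not in tables.COVALENT_RADII or el not in tables.VDW_RADII:
            raise ValueError(f"element {el!r} outside the bundled radius tables")
    atoms = [Atom(i, el, structure.coords[i].copy(),
                  structure.formal_charges[i])
             for i, el in enumerate(structure.elements)]
    return MolecularGraph(atoms, perceive_bonds(structure),
                          name=structure.name)


# lone-pair π donors eligible for promotion into an adjacent π path
_PROMOTABLE = {"N", "O", "S"}


def assign_node_attributes(graph: MolecularGraph) -> MolecularGraph:
    """Assign hybridisation and formal-charge-aware π-electron counts.

    Rules: a triple bond or two double bonds → sp; exactly one double bond →
    sp²; otherwise sp³ for polyvalent main-group atoms, ``other`` for
    monovalent atoms.  N/O/S atoms (and anionic carbons) without multiple
    bonds that sit adjacent to a multiply-bonded sp²/sp atom are promoted to
    sp² (lone pair entering the π path).  π-electron counts are finalised in
    :func:`find_conjugated_systems`, since only members of a conjugated
    system may carry a non-zero count.
    """
    n_double = {a.index: 0 for a in graph.atoms}
    n_triple = {a.index: 0 for a in graph.atoms}
    degree = {a.index: 0 for a in graph.atoms}
    for b in graph.bonds:
        degree[b.i] += 1
        degree[b.j] += 1
        if b.order == 2:
            n_double[b.i] += 1
            n_double[b.j] += 1
        elif b.order == 3:
            n_triple[b.i] += 1
            n_triple[b.j] += 1

    for a in graph.atoms:
        i = a.index
        if n_triple[i] >= 1 or n_double[i] >= 2:
            a.hybridisation = Hybridisation.SP
        elif n_double[i] == 1:
            a.hybridisation = Hybridisation.SP2
        elif degree[i] >= 2 or (degree[i] == 1 and a.element
                                in {"C", "N", "O", "S", "P"}):
            a.hybridisation = Hybridisation.SP3
        else:
            a.hybridisation = Hybridisation.OTHER
        a.n_pi_electrons = 0

    # promotion pass: lone-pair donors adjacent to a genuine π bond
    multiple = {i for i in n_double
                if n_double[i] >= 1 or n_triple[i] >= 1}
    adjacency: dict[int, list[int]] = {a.index: [] for a in graph.atoms}
    for b in graph.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)
    for a in graph.atoms:
        if a.hybridisation is not Hybridisation.SP3:
            continue
        lone_pair_donor = (a.element in _PROMOTABLE
                           or (a.element == "C" and a.formal_charge == -1))
        if lone_pair_donor and any(nb in multiple for nb in adjacency[a.index]):
            a.hybridisation = Hybridisation.SP2
    graph._n_double = n_double  # type: ignore[attr-defined]
    graph._n_triple = n_triple  # type: ignore[attr-defined]
    return graph


def _pi_contribution(atom: Atom, n_double: int, n_triple: int) -> int:
    if atom.element == "C" and atom.formal_charge == 1:
        return 0
    if n_double == 0 and n_triple == 0:
        # promoted lone-pair donor (e.g. pyrrole nitrogen): two electrons
        return 2
    return n_double + 2 * n_triple


def find_conjugated_systems(graph: MolecularGraph) -> list[ConjugatedSystem]:
    """Maximal connected sp²/sp components with ≥ 3 atoms."""
    n_double = getattr(graph, "_n_double")
    n_triple = getattr(graph, "_n_triple")
    pi_nodes = {a.index for a in graph.atoms
                if a.hybridisation in (Hybridisation.SP2, Hybridisation.SP)}
    g = graph.to_networkx().subgraph(pi_nodes)
    systems: list[ConjugatedSystem] = []
    for comp in nx.connected_components(g):
        if len(comp) < 3:
            continue
        contrib = {}
        for i in sorted(comp):
            a = graph.atoms[i]
            contrib[i] = _pi_contribution(a, n_double[i], n_triple[i])
            a.n_pi_electrons = contrib[i]
        member_bonds = frozenset(
            b.key() for b in graph.bonds
            if b.i in comp and b.j in comp)
        systems.append(ConjugatedSystem(frozenset(comp), contrib, member_bonds))
    systems.sort(key=lambda s: min(s.atom_indices))
    graph.conjugated_systems = systems
    return systems


def _sigma_groups(graph: MolecularGraph) -> list[HyperGroup]:
    """C–H and C–halogen σ bonds.  C–H bonds on a halogen-bearing carbon are
    suppressed: the polarised C–X bond dominates that centre."""
    halogenated_carbons = set()
    for b in graph.bonds:
        ei, ej = graph.atoms[b.i].element, graph.atoms[b.j].element
        if {ei, ej} & tables.HALOGENS and "C" in (ei, ej):
            halogenated_carbons.add(b.i if ei == "C" else b.j)
    groups = []
    for b in graph.bonds:
        if b.order != 1:
            continue
        ei, ej = graph.atoms[b.i].element, graph.atoms[b.j].element
        pair = {ei, ej}
        if pair == {"C", "H"} or (len(pair) == 2 and "C" in pair
                                  and pair & tables.HALOGENS):
            carbon = b.i if ei == "C" else b.j
            other = b.j if carbon == b.i else b.i
            other_el = graph.atoms[other].element
            if other_el == "H" and carbon in halogenated_carbons:
                continue
            label = f"C-{other_el}"
            groups.append(HyperGroup(frozenset((carbon, other)),
                                     GroupType.SIGMA, label))
    return groups


# acceptor-only / donor-only σ and π classes
_SIGMA_DONORS = {"C-H"}
_SIGMA_ACCEPTORS = {"C-H", "C-F", "C-Cl", "C-Br", "C-I"}


def _pi_groups(graph: MolecularGraph) -> list[tuple[HyperGroup, bool, bool]]:
    """π groups as (group, can_donate, can_accept)."""
    in_conj: dict[int, ConjugatedSystem] = {}
    for sys_ in graph.conjugated_systems:
        for i in sys_.atom_indices:
            in_conj[i] = sys_

    out: list[tuple[HyperGroup, bool, bool]] = []
    seen_systems = set()
    for sys_ in graph.conjugated_systems:
        key = sys_.atom_indices
        if key in seen_systems:
            continue
        seen_systems.add(key)
        out.append((HyperGroup(key, GroupType.PI, "conjugated",
                               sys_.total_pi_electrons), True, True))

    for b in graph.bonds:
        if b.order < 2:
            continue
        if b.i in in_conj and b.j in in_conj:
            continue  # represented by its conjugated system
        ei, ej = graph.atoms[b.i].element, graph.atoms[b.j].element
        pair = frozenset((b.i, b.j))
        if {ei, ej} == {"C"}:
            label = "C=C" if b.order == 2 else "C#C"
            out.append((HyperGroup(pair, GroupType.PI, label, 2), True, True))
        elif {ei, ej} == {"C", "O"} and b.order == 2:
            out.append((HyperGroup(pair, GroupType.PI, "C=O", 2), False, True))

    for a in graph.atoms:
        if a.index in in_conj:
            continue
        if a.element == "C" and a.hybridisation is Hybridisation.SP2:
            if a.formal_charge == 1:
                out.append((HyperGroup(frozenset((a.index,)), GroupType.PI,
                                       "C+(sp2)", 0), False, True))
            elif a.formal_charge == -1:
                out.append((HyperGroup(frozenset((a.index,)), GroupType.PI,
                                       "C-(sp2)", 2), True, False))
        elif (a.element in ("N", "O")
              and a.hybridisation is Hybridisation.SP3):
            out.append((HyperGroup(frozenset((a.index,)), GroupType.PI,
                                   f"{a.element}(sp3)", 2), True, False))
    return out


def find_hyperconjugated_pairs(graph: MolecularGraph) -> list[HyperconjugatedPair]:
    """Enumerate σ/π donor–acceptor pairs at ≤ 3 bonds separation.

    Every pair couples exactly one σ group with one π group on disjoint atom
    sets.  When both direction assignments are admissible the π group is
    taken as the donor.
    """
    g = graph.to_networkx()
    sigma = _sigma_groups(graph)
    pis = _pi_groups(graph)
    pairs: list[HyperconjugatedPair] = []
    for sg in sigma:
        for pg, pi_donates, pi_accepts in pis:
            if sg.atoms & pg.atoms:
                continue
            best: tuple[int, tuple[int, ...]] | None = None
            for a, b in itertools.product(sorted(sg.atoms), sorted(pg.atoms)):
                try:
                    path = nx.shortest_path(g, a, b)
                except nx.NetworkXNoPath:
                    continue
                nbonds = len(path) - 1
                if best is None or nbonds < best[0]:
                    best = (nbonds, tuple(path))
            if best is None or not (1 <= best[0] <= 3):
                continue
            sigma_donates = sg.label in _SIGMA_DONORS
            sigma_accepts = sg.label in _SIGMA_ACCEPTORS
            if pi_donates and sigma_accepts:
                donor, acceptor = pg, sg
                path = tuple(reversed(best[1]))
            elif sigma_donates and pi_accepts:
                donor, acceptor = sg, pg
                path = best[1]
            else:
                continue
            pairs.append(HyperconjugatedPair(donor, acceptor, best[0], path))
    pairs.sort(key=lambda p: (min(p.donor.atoms), min(p.acceptor.atoms)))
    graph.hyper_pairs = pairs
    return pairs


def annotate(graph: MolecularGraph) -> MolecularGraph:
    """Run the full perception pipeline on a bare graph."""
    assign_node_attributes(graph)
    find_conjugated_systems(graph)
    find_hyperconjugated_pairs(graph)
    return graph


def from_structure(structure: Structure) -> MolecularGraph:
    """Build and fully annotate the molecular graph of a structure."""
    return annotate(build_graph(structure))
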