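"""Fragmentation states, fragment extraction, hydrogen capping and the
Gaussian-overlap volume model.

A fragmentation is a binary vector over the *allowed edges* of the molecular
graph: single (order-1) bridge bonds whose removal leaves both components
with at least 60 % of the target fragment size.  Severed valences are
restored by a hydrogen cap placed along the axis of the broken bond i–j:

    x(H) = x(i) + (r(i) + r(H)) / (r(i) + r(j)) · (x(j) − x(i))

with r the covalent radius.  Fragment volumes are hard-sphere sums minus
pairwise Gaussian overlaps; the reference volume scales a per-element
characteristic volume (hard sphere minus the mean overlap with bonded
neighbours) to the target fragment size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import tables
from .geom import Geometry
from .molgraph import MolecularGraph

#: Gaussian-overlap amplitude (dimensionless)
AMPLITUDE = 2.0 * math.sqrt(2.0)

#: minimum component fraction of the target size for an edge to be cuttable
MIN_SIZE_FRACTION = 0.6


@dataclass(frozen=True)
class FragmentationState:
    """Binary vector over a fixed ordering of allowed edges (1 = broken)."""

    edge_order: tuple[tuple[int, int], ...]
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.edge_order):
            raise ValueError("bits length does not match edge ordering")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")

    @property
    def broken_edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(e for e, b in zip(self.edge_order, self.bits) if b)

    @property
    def n_broken(self) -> int:
        return sum(self.bits)

    def with_bits(self, bits) -> "FragmentationState":
        return FragmentationState(self.edge_order, tuple(int(b) for b in bits))

    @classmethod
    def zeros(cls, edge_order) -> "FragmentationState":
        edge_order = tuple(edge_order)
        return cls(edge_order, (0,) * len(edge_order))

    @classmethod
    def ones(cls, edge_order) -> "FragmentationState":
        edge_order = tuple(edge_order)
        return cls(edge_order, (1,) * len(edge_order))


@dataclass
class Cap:
    """A hydrogen cap with the severed bond it stands in for."""

    coords: np.ndarray
    host: int      # atom index inside the fragment (i of the severed bond)
    severed: tuple[int, int]  # (i, j) with i inside the fragment


@dataclass
class Fragment:
    atom_indices: tuple[int, ...]
    caps: list[Cap] = field(default_factory=list)
    volume: float | None = None

    @property
    def bare_size(self) -> int:
        """Atom count excluding hydrogen caps."""
        return len(self.atom_indices)

    @property
    def size(self) -> int:
        """Atom count including hydrogen caps (the reported convention)."""
        return len(self.atom_indices) + len(self.caps)


def allowed_edges(graph: MolecularGraph, n_t: float) -> list[tuple[int, int]]:
    """Order-1 bridge bonds whose removal leaves both sides ≥ ceil(0.6·n_t).

    Returns an empty list when nothing is cuttable (the caller treats the
    system as unfragmentable).
    """
    if n_t < 2:
        raise ValueError("target fragment size must be at least 2")
    g = graph.to_networkx()
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("molecular graph is not connected")
    min_size = math.ceil(MIN_SIZE_FRACTION * n_t)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    out: list[tuple[int, int]] = []
    for b in graph.bonds:
        if b.order != 1 or frozenset((b.i, b.j)) not in bridges:
            continue
        h = g.copy()
        h.remove_edge(b.i, b.j)
        side = nx.node_connected_component(h, b.i)
        if len(side) >= min_size and (len(g) - len(side)) >= min_size:
            out.append(b.key())
    out.sort()
    return out


def extract_fragments(graph: MolecularGraph,
                      state: FragmentationState) -> list[Fragment]:
    """Connected components of the graph minus the flagged edges, each with
    its hydrogen caps, ordered by smallest member atom index."""
    g = graph.to_networkx()
    broken = set(map(tuple, state.broken_edges))
    for (i, j) in broken:
        if not g.has_edge(i, j):
            raise ValueError(f"state flags non-existent edge {(i, j)}")
        g.remove_edge(i, j)
    comps = sorted((tuple(sorted(c)) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    membership = {}
    for k, comp in enumerate(comps):
        for i in comp:
            membership[i] = k
    fragments = [Fragment(comp) for comp in comps]
    for (i, j) in sorted(broken):
        fi, fj = membership[i], membership[j]
        fragments[fi].caps.append(_make_cap(graph, i, j))
        fragments[fj].caps.append(_make_cap(graph, j, i))
    return fragments


def _make_cap(graph: MolecularGraph, i: int, j: int) -> Cap:
    """Hydrogen cap for the fragment containing i, standing in for j."""
    xi = graph.atoms[i].coords
    xj = graph.atoms[j].coords
    ri = graph.atoms[i].covalent_radius
    rj = graph.atoms[j].covalent_radius
    rh = tables.COVALENT_RADII["H"]
    frac = (ri + rh) / (ri + rj)
    return Cap(xi + frac * (xj - xi), host=i, severed=(i, j))


def cap_with_hydrogens(graph: MolecularGraph, fragment: Fragment,
                       severed_bonds) -> list[Cap]:
    """Caps for an explicit list of severed bonds incident to the fragment.

    Each severed bond must have exactly one endpoint inside the fragment;
    a bond fully inside the fragment indicates a bookkeeping bug.
    """
    members = set(fragment.atom_indices)
    caps = []
    for (i, j) in severed_bonds:
        inside = (i in members) + (j in members)
        if inside == 2:
            raise ValueError(f"severed bond {(i, j)} lies inside the fragment")
        if inside == 0:
            continue
        if j in members:
            i, j = j, i
        caps.append(_make_cap(graph, i, j))
    return caps


def capped_geometry(graph: MolecularGraph, fragment: Fragment,
                    label: str = "") -> Geometry:
    """Geometry of a capped fragment: member atoms, intra-fragment bonds,
    one H per cap bonded to its host atom."""
    members = list(fragment.atom_indices)
    remap = {g: l for l, g in enumerate(members)}
    elements = [graph.atoms[g].element for g in members]
    coords = [graph.atoms[g].coords for g in members]
    bonds = [(remap[b.i], remap[b.j], b.order) for b in graph.bonds
             if b.i in remap and b.j in remap]
    cap_idx = []
    for cap in fragment.caps:
        k = len(elements)
        elements.append("H")
        coords.append(cap.coords)
        bonds.append((remap[cap.host], k, 1))
        cap_idx.append(k)
    geo = Geometry(elements, np.asarray(coords), bonds, cap_idx, label=label)
    geo.global_indices = members  # type: ignore[attr-defined]
    return geo


def _alpha(sigma: float, amplitude: float = AMPLITUDE) -> float:
    return math.pi * (3.0 * amplitude / (4.0 * math.pi * sigma ** 3)) ** (2.0 / 3.0)


def pair_overlap_volume(sigma_i: float, sigma_j: float, r_ij: float,
                        amplitude: float = AMPLITUDE) -> float:
    """Gaussian overlap volume of two atoms (Å³)."""
    ai = _alpha(sigma_i, amplitude)
    aj = _alpha(sigma_j, amplitude)
    return (amplitude * amplitude
            * math.exp(-ai * aj * r_ij ** 2 / (ai + aj))
            * (math.pi / (ai + aj)) ** 1.5)


def hard_sphere_volume(sigma: float) -> float:
    return 4.0 / 3.0 * math.pi * sigma ** 3


def geometry_volume(elements, coords) -> float:
    """Hard-sphere sum minus all pairwise Gaussian overlaps (Å³)."""
    coords = np.asarray(coords, dtype=float)
    sig = np.array([tables.VDW_RADII[e] for e in elements])
    vol = float(np.sum(4.0 / 3.0 * math.pi * sig ** 3))
    n = len(elements)
    if n > 1:
        alpha = np.pi * (3.0 * AMPLITUDE / (4.0 * np.pi * sig ** 3)) ** (2.0 / 3.0)
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = np.sum(diff * diff, axis=-1)
        asum = alpha[:, None] + alpha[None, :]
        ov = (AMPLITUDE * AMPLITUDE * np.exp(-alpha[:, None] * alpha[None, :]
                                             * r2 / asum)
              * (np.pi / asum) ** 1.5)
        iu = np.triu_indices(n, k=1)
        vol -= float(np.sum(ov[iu]))
    return vol


def fragment_volume(graph: MolecularGraph, fragment: Fragment,
                    include_caps: bool = True) -> float:
    """Volume of a (capped) fragment, Å³.  Overlaps run over all atom pairs."""
    elements = [graph.atoms[g].element for g in fragment.atom_indices]
    coords = [graph.atoms[g].coords for g in fragment.atom_indices]
    if include_caps:
        for cap in fragment.caps:
            elements.append("H")
            coords.append(cap.coords)
    return geometry_volume(elements, coords)


def element_characteristic_volumes(graph: MolecularGraph) -> dict[str, float]:
    """Per-element characteristic volume V_s: hard sphere minus the mean
    Gaussian overlap with bonded neighbours (over every bond incident to an
    atom of that element in the whole system)."""
    pairs: dict[str, list[float]] = {}
    for b in graph.bonds:
        for s_atom, o_atom in ((b.i, b.j), (b.j, b.i)):
            el = graph.atoms[s_atom].element
            ov = pair_overlap_volume(graph.atoms[s_atom].vdw_radius,
                                     graph.atoms[o_atom].vdw_radius,
                                     b.length)
            pairs.setdefault(el, []).append(ov)
    out = {}
    for el in set(graph.elements):
        v = hard_sphere_volume(tables.VDW_RADII[el])
        if el in pairs:
            v -= sum(pairs[el]) / len(pairs[el])
        out[el] = v
    return out


def reference_volume(graph: MolecularGraph, n_t: float) -> float:
    """Target-size reference volume: n_t times the number-weighted mean of
    the per-element characteristic volumes."""
    vs = element_characteristic_volumes(graph)
    counts: dict[str, int] = {}
    for el in graph.elements:
        counts[el] = counts.get(el, 0) + 1
    n_a = graph.total_atom_count
    return n_t * sum(counts[el] * vs[el] for el in counts) / n_a
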