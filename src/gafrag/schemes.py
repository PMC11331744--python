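"""Manual protein fragmentation schemes for comparison harnesses.

The three textbook backbone-cutting schemes are recognised directly from
the bonded graph via the repeating N–Cα–C(=O) motif (no residue metadata
needed, so plain-XYZ fixtures work):

* ``naive``      — cut amide C–N bonds,
* ``semi-naive`` — cut Cα–N bonds,
* ``non-naive``  — cut Cα–C bonds.

Bonds of the scheme's class are taken greedily along the chain so fragment
sizes approach the target.
"""

from __future__ import annotations

import networkx as nx

from .molgraph import MolecularGraph

SCHEMES = ("naive", "semi-naive", "non-naive")


def backbone_motifs(graph: MolecularGraph) -> list[dict[str, int]]:
    """All N–Cα–C(=O) motifs as dicts with keys N, CA, C, O."""
    adjacency: dict[int, list[int]] = {a.index: [] for a in graph.atoms}
    order = {}
    for b in graph.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)
        order[b.key()] = b.order
    el = graph.elements
    motifs = []
    for c in range(len(el)):
        if el[c] != "C":
            continue
        oxo = [n for n in adjacency[c] if el[n] == "O"
               and order[tuple(sorted((c, n)))] == 2]
        amide_n = [n for n in adjacency[c] if el[n] == "N"]
        calpha = [n for n in adjacency[c] if el[n] == "C"]
        if not (oxo and calpha):
            continue
        for ca in calpha:
            n_of_ca = [n for n in adjacency[ca] if el[n] == "N"]
            if not n_of_ca:
                continue
            motifs.append({"N": n_of_ca[0], "CA": ca, "C": c, "O": oxo[0],
                           "amide_N": amide_n[0] if amide_n else None})
    motifs.sort(key=lambda m: m["CA"])
    return motifs


def scheme_bond_class(graph: MolecularGraph,
                      scheme: str) -> list[tuple[int, int]]:
    """All bonds of the scheme's class, ordered along the chain."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    motifs = backbone_motifs(graph)
    bonds = []
    for m in motifs:
        if scheme == "naive":
            if m["amide_N"] is not None:
                bonds.append(tuple(sorted((m["C"], m["amide_N"]))))
        elif scheme == "semi-naive":
            bonds.append(tuple(sorted((m["CA"], m["N"]))))
        else:
            bonds.append(tuple(sorted((m["CA"], m["C"]))))
    existing = {b.key() for b in graph.bonds}
    seen = set()
    out = []
    for e in bonds:
        if e in existing and e not in seen:
            out.append(e)
            seen.add(e)
    if not out:
        raise ValueError(
            f"no bonds of class {scheme!r} found (no backbone motif?)")
    return out


def manual_scheme_cuts(graph: MolecularGraph, scheme: str,
                       target_size: int = 50) -> list[tuple[int, int]]:
    """Greedy along-chain selection of scheme-class bonds so fragments
    approach the target size."""
    candidates = scheme_bond_class(graph, scheme)
    g = graph.to_networkx()
    cuts: list[tuple[int, int]] = []
    current = g.copy()
    for e in candidates:
        if not current.has_edge(*e):
            continue
        trial = current.copy()
        trial.remove_edge(*e)
        comp = nx.node_connected_component(trial, e[0])
        other = nx.node_connected_component(trial, e[1])
        # cut when the upstream side has grown to the target
        head = min((comp, other), key=lambda c: min(c))
        if len(head) >= target_size:
            cuts.append(e)
            current = trial
    return cuts
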