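"""Genetic-algorithm minimisation of the fragmentation score.

Individuals are binary vectors over the allowed edges.  The starting
population derives from inertia-frame initial guesses: the molecule's
bounding box in the principal-axis frame is split into equal intervals
along the axis of largest extent, and fragments are grown breadth-first
from the primitive monomer nearest each interval midpoint until they reach
90 % of the target size.  Tournament selection, single-point crossover and
per-gene replacement mutation evolve the population; during the first few
iterations edges whose dimer-energy correction exceeds a threshold are
blacklisted and forced intact in every individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import tables
from .forcefield import EnergyBackend, dimer_energy_correction
from .fragments import (FragmentationState, extract_fragments,
                        reference_volume, capped_geometry, Fragment)
from .molgraph import MolecularGraph
from .scoring import (PenaltyWeights, ScoreBreakdown, SigmoidParams,
                      DEFAULT_SIGMOIDS, total_score)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 16
    max_iterations: int = 100
    stagnation_limit: int = 50
    blacklist_window: int = 10
    blacklist_threshold: float = 10.0  # kJ/mol
    tournament_size: int = 3
    mutation_probability: float | None = None  # default 1/|genes|
    elitism: int = 1
    pad_flip_probability: float = 0.1

    @property
    def n_parents_for(self):  # pragma: no cover - trivial closure
        return lambda pop: 2 if pop <= 8 else int(0.25 * pop)

    def n_parents(self, population_size: int | None = None) -> int:
        pop = population_size or self.population_size
        return 2 if pop <= 8 else int(0.25 * pop)


@dataclass
class Individual:
    state: FragmentationState
    fitness: float
    breakdown: ScoreBreakdown | None = None


@dataclass
class GAResult:
    best: Individual
    trace: list[float]
    blacklist: set[tuple[int, int]]
    iterations: int
    evaluations: int


def reference_points(graph: MolecularGraph, n_t: float) -> np.ndarray:
    """Interval midpoints of the principal-axis bounding box.

    The box is split into ceil(N_A / n_t) equal intervals along the
    principal axis with the largest spatial extent; the other two axes keep
    their box centre.  As a point set this is invariant under rigid motion
    and reflection (collinear systems degrade gracefully: zero-extent axes
    simply contribute the centre).
    """
    if len(graph.atoms) < 2:
        raise ValueError("need at least two atoms")
    xyz = graph.coords
    masses = np.array([tables.ATOMIC_MASSES[e] for e in graph.elements])
    com = (masses[:, None] * xyz).sum(axis=0) / masses.sum()
    rel = xyz - com
    inertia = np.zeros((3, 3))
    for m, r in zip(masses, rel):
        inertia += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    _vals, axes = np.linalg.eigh(inertia)
    proj = rel @ axes
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extents = hi - lo
    axis = int(np.argmax(extents))
    n_intervals = max(1, math.ceil(len(graph.atoms) / n_t))
    centre = 0.5 * (lo + hi)
    points = []
    for k in range(n_intervals):
        p = centre.copy()
        p[axis] = lo[axis] + (k + 0.5) * extents[axis] / n_intervals
        points.append(com + axes @ p)
    return np.asarray(points)


@dataclass
class _Monomer:
    index: int
    atoms: frozenset[int]
    centroid: np.ndarray


def primitive_monomers(graph: MolecularGraph,
                       edges: list[tuple[int, int]]
                       ) -> tuple[list[_Monomer], dict[tuple[int, int], tuple[int, int]]]:
    """Cut every allowed edge; return the resulting minimal fragments and a
    map from each allowed edge to the pair of monomers it joins."""
    g = graph.to_networkx()
    g.remove_edges_from(edges)
    comps = sorted((tuple(sorted(c)) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    xyz = graph.coords
    monomers = [_Monomer(k, frozenset(c), xyz[list(c)].mean(axis=0))
                for k, c in enumerate(comps)]
    owner = {}
    for mon in monomers:
        for i in mon.atoms:
            owner[i] = mon.index
    edge_to_monomers = {e: (owner[e[0]], owner[e[1]]) for e in edges}
    return monomers, edge_to_monomers


def initial_guess(graph: MolecularGraph, edges: list[tuple[int, int]],
                  n_t: float, ref_point: np.ndarray) -> FragmentationState:
    """Grow fragments of primitive monomers breadth-first from the monomer
    nearest the reference point, stopping each fragment at ≥ 90 % of n_t."""
    edges = [tuple(sorted(e)) for e in edges]
    monomers, edge_mon = primitive_monomers(graph, edges)
    adjacency: dict[int, set[int]] = {m.index: set() for m in monomers}
    for (a, b) in edge_mon.values():
        adjacency[a].add(b)
        adjacency[b].add(a)
    visited: set[int] = set()
    assignment: dict[int, int] = {}
    frag_id = 0
    target = 0.9 * n_t
    while len(visited) < len(monomers):
        unvisited = [m for m in monomers if m.index not in visited]
        ref_mon = min(unvisited,
                      key=lambda m: (float(np.linalg.norm(m.centroid
                                                          - ref_point)),
                                     min(m.atoms)))
        queue = [ref_mon.index]
        members = [ref_mon.index]
        size = len(ref_mon.atoms)
        pos = 0
        while pos < len(queue) and size < target:
            v = queue[pos]
            pos += 1
            for w in sorted(adjacency[v]):
                if w in visited or w in members:
                    continue
                queue.append(w)
                members.append(w)
                size += len(monomers[w].atoms)
                if size >= target:
                    break
        for m in members:
            visited.add(m)
            assignment[m] = frag_id
        frag_id += 1
    bits = tuple(1 if assignment[edge_mon[e][0]] != assignment[edge_mon[e][1]]
                 else 0 for e in edges)
    return FragmentationState(tuple(edges), bits)


class _Evaluator:
    """Caches fitness per bit vector and dimer corrections per cut context."""

    def __init__(self, graph: MolecularGraph, edges, n_t: float,
                 weights: PenaltyWeights, backend: EnergyBackend,
                 params: SigmoidParams):
        self.graph = graph
        self.edges = tuple(tuple(sorted(e)) for e in edges)
        self.n_t = n_t
        self.weights = weights
        self.backend = backend
        self.params = params
        self.v_ref = reference_volume(graph, n_t)
        whole = Fragment(tuple(range(len(graph.atoms))))
        self.e_tot = backend.evaluate(capped_geometry(graph, whole,
                                                      label="system"))
        self._fitness: dict[tuple[int, ...], ScoreBreakdown] = {}
        self._dimer: dict[tuple, float] = {}
        self.evaluations = 0

    def score(self, bits: tuple[int, ...]) -> ScoreBreakdown:
        if bits not in self._fitness:
            state = FragmentationState(self.edges, bits)
            self._fitness[bits] = total_score(
                self.graph, state, self.weights, self.backend, self.n_t,
                self.params, v_ref=self.v_ref, e_tot=self.e_tot)
            self.evaluations += 1
        return self._fitness[bits]

    def dimer_correction(self, state: FragmentationState,
                         edge: tuple[int, int]) -> float:
        fragments = extract_fragments(self.graph, state)
        member = {}
        for k, f in enumerate(fragments):
            for i in f.atom_indices:
                member[i] = k
        ki, kj = member[edge[0]], member[edge[1]]
        context = frozenset(
            e for e in state.broken_edges
            if member[e[0]] in (ki, kj) or member[e[1]] in (ki, kj))
        key = (edge, context)
        if key not in self._dimer:
            self._dimer[key] = dimer_energy_correction(
                self.graph, state, edge, self.backend, fragments)
        return self._dimer[key]


def _tournament(rng: np.random.Generator, fitnesses: list[float],
                k: int) -> int:
    contenders = rng.integers(0, len(fitnesses), size=min(k, len(fitnesses)))
    return int(min(contenders, key=lambda i: fitnesses[i]))


def _crossover(rng: np.random.Generator, a: tuple[int, ...],
               b: tuple[int, ...]) -> tuple[int, ...]:
    if len(a) < 2:
        return a
    cut = int(rng.integers(1, len(a)))
    return a[:cut] + b[cut:]


def _mutate(rng: np.random.Generator, bits: tuple[int, ...],
            prob: float) -> tuple[int, ...]:
    out = list(bits)
    for g in range(len(out)):
        if rng.random() < prob:
            out[g] = int(rng.integers(0, 2))  # replacement, not flip
    return tuple(out)


def evolve(graph: MolecularGraph, edges: list[tuple[int, int]],
           n_t: float, weights: PenaltyWeights, backend: EnergyBackend,
           config: GAConfig = GAConfig(),
           params: SigmoidParams = DEFAULT_SIGMOIDS,
           rng: np.random.Generator | int | None = None,
           log: list | None = None,
           forbid_uncut: bool = False) -> GAResult:
    """Run the genetic algorithm and return the best individual found.

    With ``forbid_uncut`` the all-intact state is treated as infeasible
    (infinite fitness): a recursion stage exists to partition its subsystem,
    and leaving it whole would stall the recursion even though the bare
    score can favour it (every cut near a conjugated or hyperconjugated
    region carries a flat penalty that the size terms rarely repay).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    edges = [tuple(sorted(e)) for e in edges]
    evaluator = _Evaluator(graph, edges, n_t, weights, backend, params)
    n_genes = len(edges)
    if n_genes == 0:
        state = FragmentationState.zeros(())
        bd = total_score(graph, state, weights, backend, n_t, params)
        best = Individual(state, bd.total, bd)
        return GAResult(best, [bd.total], set(), 0, 1)
    mut_p = (config.mutation_probability
             if config.mutation_probability is not None else 1.0 / n_genes)
    blacklist: set[tuple[int, int]] = set()
    black_mask = [False] * n_genes

    def apply_mask(bits: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(0 if black_mask[g] else b for g, b in enumerate(bits))

    def screen(bits: tuple[int, ...]) -> tuple[int, ...]:
        """Blacklist any broken edge with a large dimer correction, then
        force those genes intact."""
        changed = True
        while changed:
            changed = False
            state = FragmentationState(evaluator.edges, bits)
            for g, e in enumerate(edges):
                if bits[g] and e not in blacklist:
                    if (evaluator.dimer_correction(state, e)
                            > config.blacklist_threshold):
                        blacklist.add(e)
                        black_mask[g] = True
                        if log is not None:
                            log.append(("blacklist", e))
                        bits = apply_mask(bits)
                        changed = True
                        break
        return bits

    # ---- initial population -------------------------------------------
    refs = reference_points(graph, n_t)
    seeds = []
    seen = set()
    for rp in refs:
        guess = initial_guess(graph, edges, n_t, rp)
        if guess.bits not in seen:
            seeds.append(guess.bits)
            seen.add(guess.bits)
    population = list(seeds)[:config.population_size]
    while len(population) < config.population_size:
        base = population[int(rng.integers(0, len(seeds)))]
        population.append(_mutate(rng, base, config.pad_flip_probability))

    def fitness(bits: tuple[int, ...]) -> float:
        if forbid_uncut and not any(bits):
            return math.inf
        return evaluator.score(bits).total

    def evaluate(bits: tuple[int, ...], iteration: int) -> tuple[tuple[int, ...], float]:
        bits = apply_mask(bits)
        if iteration <= config.blacklist_window and any(bits):
            bits = screen(bits)
        return bits, fitness(bits)

    population = [evaluate(b, 0) for b in population]
    population = [(apply_mask(b), fitness(apply_mask(b)))
                  for b, _f in population]  # re-mask after any blacklisting
    best_bits, best_fit = min(population, key=lambda t: t[1])
    trace = [best_fit]
    stagnation = 0
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        fits = [f for _b, f in population]
        n_parents = config.n_parents(len(population))
        parent_idx = [_tournament(rng, fits, config.tournament_size)
                      for _ in range(n_parents)]
        parents = [population[i][0] for i in parent_idx]
        offspring = []
        n_children = config.population_size - config.elitism
        while len(offspring) < n_children:
            ia = int(rng.integers(0, len(parents)))
            ib = int(rng.integers(0, len(parents)))
            if len(parents) > 1 and ib == ia:  # prefer distinct parents
                ib = (ib + 1) % len(parents)
            child = _crossover(rng, parents[ia], parents[ib])
            child = _mutate(rng, child, mut_p)
            for _retry in range(3):  # discourage duplicate offspring
                if child not in offspring:
                    break
                child = _mutate(rng, child, max(mut_p, 0.25))
            offspring.append(child)
        # one random immigrant per generation keeps the gene pool from
        # collapsing on small landscapes
        if offspring:
            offspring[-1] = tuple(int(v) for v in rng.integers(0, 2, n_genes))
        evaluated = [evaluate(c, iteration) for c in offspring]
        evaluated = [(apply_mask(b), fitness(apply_mask(b)))
                     for b, _f in evaluated]
        elite = (apply_mask(best_bits), fitness(apply_mask(best_bits)))
        population = [elite] + evaluated
        local_bits, local_fit = min(population, key=lambda t: t[1])
        if local_fit < best_fit:
            best_bits, best_fit = local_bits, local_fit
            stagnation = 0
        else:
            stagnation += 1
        trace.append(best_fit)
        if log is not None:
            log.append(("iteration", iteration, best_fit))
        if stagnation > config.stagnation_limit:
            break
    best_bits = apply_mask(best_bits)  # a late blacklist may touch the best
    breakdown = evaluator.score(best_bits)
    best = Individual(FragmentationState(evaluator.edges, best_bits),
                      breakdown.total, breakdown)
    return GAResult(best, trace, blacklist, iteration, evaluator.evaluations)
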