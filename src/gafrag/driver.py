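"""Top-level automatic fragmentation: recursive genetic-algorithm stages.

:class:`Fragmenter` is built from a structure plus a target fragment size
and configuration; :meth:`Fragmenter.fit` runs the recursive optimisation
and returns a :class:`FragmentationResult` carrying the final fragments,
the global cut set, per-stage diagnostics and a ``summary()`` table.

Each stage splits its subsystem into m = max(2, ceil(N/(2·n_t))) parts by
running the GA with stage target N/m; any resulting fragment still larger
than n_t recurses on its bare atoms (caps are stripped and re-applied at
the end, so cap hydrogens never become cut sites).  Recursion terminates
when every fragment is within the target or no allowed edges remain (the
fragment is then reported as-is with a warning).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as gio
from . import molgraph
from .forcefield import EnergyBackend, BondedToyBackend
from .fragments import (FragmentationState, Fragment, allowed_edges,
                        extract_fragments, fragment_volume, capped_geometry)
from .ga import GAConfig, GAResult, evolve
from .geom import Structure
from .mbe import mbe_energy, MBETerms
from .molgraph import MolecularGraph
from .scoring import (PenaltyWeights, ScoreBreakdown, SigmoidParams,
                      DEFAULT_SIGMOIDS, total_score)


@dataclass
class StageReport:
    path: tuple[int, ...]
    n_atoms: int
    stage_target: float
    n_allowed_edges: int
    ga: GAResult | None
    note: str = ""

    def as_dict(self) -> dict:
        d = {
            "path": list(self.path),
            "n_atoms": self.n_atoms,
            "stage_target": self.stage_target,
            "n_allowed_edges": self.n_allowed_edges,
            "note": self.note,
        }
        if self.ga is not None:
            d["best_score"] = self.ga.best.fitness
            d["iterations"] = self.ga.iterations
            d["score_breakdown"] = self.ga.best.breakdown.as_dict()
            d["blacklisted_edges"] = sorted(map(list, self.ga.blacklist))
        return d


@dataclass
class FragmentationResult:
    """Fragments, cuts and diagnostics of one fitted fragmentation."""

    graph: MolecularGraph
    target_size: int
    cut_bonds: list[tuple[int, int]]
    fragments: list[Fragment]
    stages: list[StageReport]
    warnings: list[str]
    seed: int
    score: ScoreBreakdown
    weights: PenaltyWeights

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def sizes(self) -> list[int]:
        """Fragment sizes including hydrogen caps."""
        return [f.size for f in self.fragments]

    @property
    def bare_sizes(self) -> list[int]:
        return [f.bare_size for f in self.fragments]

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.sizes))

    @property
    def n_stages(self) -> int:
        """Depth of the recursion (1 = a single GA stage sufficed)."""
        if not self.stages:
            return 0
        return max(len(s.path) for s in self.stages)

    def state(self) -> FragmentationState:
        edges = tuple(sorted(self.cut_bonds))
        return FragmentationState(edges, (1,) * len(edges))

    def mbe(self, backend: EnergyBackend, level: int = 2) -> MBETerms:
        """Assemble the many-body expansion over the final fragments."""
        return mbe_energy(self.graph, self.fragments, backend, level)

    def summary(self) -> str:
        lines = [
            f"Fragmentation of {self.graph.name or 'system'} "
            f"({self.graph.total_atom_count} atoms, target {self.target_size} "
            f"atoms, seed {self.seed})",
            f"  fragments: {self.n_fragments}   cut bonds: "
            f"{len(self.cut_bonds)}   stages: {self.n_stages}",
            f"  sizes incl. caps: {self.sizes} (mean {self.mean_size:.1f})",
            f"  score s = {self.score.total:.6f}  "
            f"[p_pe={self.score.p_pe:.4f} p_conj={self.score.p_conj:.4f} "
            f"p_hyper={self.score.p_hyper:.4f} p_vol={self.score.p_vol:.4f} "
            f"p_vrange={self.score.p_vrange:.4f}]",
        ]
        for k, f in enumerate(self.fragments):
            lines.append(
                f"  fragment {k}: {f.bare_size} atoms + {len(f.caps)} caps, "
                f"V = {f.volume:.1f} Å³")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "system": self.graph.name,
            "n_atoms": self.graph.total_atom_count,
            "target_size": self.target_size,
            "seed": self.seed,
            "cut_bonds": sorted(map(list, self.cut_bonds)),
            "fragments": [
                {"atoms": list(f.atom_indices), "size_with_caps": f.size,
                 "size_bare": f.bare_size, "n_caps": len(f.caps),
                 "volume_A3": f.volume}
                for f in self.fragments],
            "score": self.score.as_dict(),
            "stages": [s.as_dict() for s in self.stages],
            "warnings": self.warnings,
        }

    def write(self, outdir: str | os.PathLike) -> None:
        """One XYZ per capped fragment plus a JSON manifest."""
        os.makedirs(outdir, exist_ok=True)
        for k, f in enumerate(self.fragments):
            geo = capped_geometry(self.graph, f, label=f"fragment-{k}")
            gio.write_xyz(geo, os.path.join(outdir, f"fragment_{k:03d}.xyz"),
                          comment=f"fragment {k}: {f.bare_size} atoms "
                                  f"+ {len(f.caps)} caps")
        with open(os.path.join(outdir, "fragmentation.json"), "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def plot_sizes(self, ax=None):
        """Histogram of fragment sizes (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        ax.hist(self.sizes, bins="auto", edgecolor="black")
        ax.axvline(self.target_size, color="crimson", ls="--",
                   label=f"target {self.target_size}")
        ax.set_xlabel("fragment size (atoms, incl. caps)")
        ax.set_ylabel("count")
        ax.legend()
        return ax


class Fragmenter:
    """Automatic molecular fragmentation model.

    Parameters
    ----------
    structure:
        The molecular system (elements + coordinates, Å).
    target_size:
        Desired atom count per fragment, n_t.
    weights, backend, ga_config, sigmoid_params:
        Scoring weights (default: tuned values with the fragment-count
        penalty retired), energy backend (default: the bonded 2-body toy
        model; pass ``UFFBackend()`` for force-field screening), GA
        configuration, and penalty sigmoid constants.
    """

    def __init__(self, structure: Structure, target_size: int,
                 weights: PenaltyWeights | None = None,
                 backend: EnergyBackend | None = None,
                 ga_config: GAConfig | None = None,
                 sigmoid_params: SigmoidParams = DEFAULT_SIGMOIDS):
        if target_size < 2:
            raise ValueError("target_size must be at least 2")
        self.structure = structure
        self.target_size = int(target_size)
        self.weights = weights or PenaltyWeights()
        self.backend = backend or BondedToyBackend()
        self.ga_config = ga_config or GAConfig()
        self.sigmoid_params = sigmoid_params
        self.graph = molgraph.from_structure(structure)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> FragmentationResult:
        """Run the recursive GA fragmentation (deterministic per seed)."""
        warnings: list[str] = []
        stages: list[StageReport] = []
        global_cuts: list[tuple[int, int]] = []
        root_ss = np.random.SeedSequence(seed)
        self._recurse(self.graph, list(range(len(self.graph.atoms))),
                      (), root_ss, global_cuts, stages, warnings)
        edges = tuple(sorted(set(global_cuts)))
        state = FragmentationState(edges, (1,) * len(edges))
        fragments = extract_fragments(self.graph, state)
        for f in fragments:
            f.volume = fragment_volume(self.graph, f)
        score = total_score(self.graph, state, self.weights, self.backend,
                            self.target_size, self.sigmoid_params)
        for f in fragments:
            if f.bare_size > self.target_size:
                warnings.append(
                    f"fragment with atoms {f.atom_indices[:4]}... has "
                    f"{f.bare_size} atoms (> target {self.target_size}) and "
                    f"no allowed edges; reported as-is")
        return FragmentationResult(self.graph, self.target_size, list(edges),
                                   fragments, stages, warnings, seed, score,
                                   self.weights)

    # ------------------------------------------------------------------
    def _recurse(self, graph: MolecularGraph, global_map: list[int],
                 path: tuple[int, ...], ss: np.random.SeedSequence,
                 global_cuts: list[tuple[int, int]],
                 stages: list[StageReport], warnings: list[str]) -> None:
        n = len(graph.atoms)
        n_t = self.target_size
        if n <= n_t:
            return
        m = max(2, math.ceil(n / (2.0 * n_t)))
        stage_target = n / m
        edges = allowed_edges(graph, stage_target)
        if not edges:
            stages.append(StageReport(path, n, stage_target, 0, None,
                                      note="no allowed edges"))
            return
        ga_ss, *child_ss = ss.spawn(1 + n)  # at most n children
        rng = np.random.default_rng(ga_ss)
        result = evolve(graph, edges, stage_target, self.weights,
                        self.backend, self.ga_config, self.sigmoid_params,
                        rng=rng, forbid_uncut=True)
        stages.append(StageReport(path, n, stage_target, len(edges), result))
        local_fragments = extract_fragments(graph, result.best.state)
        if len(local_fragments) == 1:
            # optimiser preferred no cut; nothing further to do here
            stages[-1].note = "optimiser left the stage uncut"
            return
        for (i, j) in result.best.state.broken_edges:
            global_cuts.append(tuple(sorted((global_map[i], global_map[j]))))
        for k, frag in enumerate(local_fragments):
            if frag.bare_size <= n_t:
                continue
            sub = graph.subgraph(set(frag.atom_indices))
            molgraph.annotate(sub)
            sub_map = [global_map[g] for g in sub.local_to_global]
            self._recurse(sub, sub_map, path + (k,), child_ss[k],
                          global_cuts, stages, warnings)


def fragment_system(structure: Structure, n_t: int, seed: int = 0,
                    weights: PenaltyWeights | None = None,
                    backend: EnergyBackend | None = None,
                    ga_config: GAConfig | None = None) -> FragmentationResult:
    """Functional convenience wrapper around :class:`Fragmenter`."""
    return Fragmenter(structure, n_t, weights=weights, backend=backend,
                      ga_config=ga_config).fit(seed=seed)
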