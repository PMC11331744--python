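"""Many-body expansion of the system energy over a fragment set.

    E_MBE = Σ_I E_I + Σ_{I<J} ΔE_IJ + Σ_{I<J<K} ΔE_IJK + ...

with ΔE_IJ = E_IJ − E_I − E_J and
ΔE_IJK = E_IJK − ΔE_IJ − ΔE_IK − ΔE_JK − E_I − E_J − E_K.

Every n-mer geometry is the union of its member fragments with bonds
internal to the union restored and hydrogen caps only on cut bonds crossing
the union boundary; all dimers (and, at level 3, all trimers) are included
with no distance screening.  The fragmentation error is the signed gap
ΔE = E_tot − E_f against the unfragmented system from the same backend.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .forcefield import EnergyBackend
from .fragments import Fragment, capped_geometry
from .molgraph import MolecularGraph


@dataclass
class MBETerms:
    level: int
    monomer_energies: list[float]
    dimer_corrections: dict[tuple[int, int], float] = field(default_factory=dict)
    trimer_corrections: dict[tuple[int, int, int], float] = field(default_factory=dict)
    e_tot: float | None = None

    @property
    def e_mbe(self) -> float:
        e = sum(self.monomer_energies)
        if self.level >= 2:
            e += sum(self.dimer_corrections.values())
        if self.level >= 3:
            e += sum(self.trimer_corrections.values())
        return e

    @property
    def fragmentation_error(self) -> float | None:
        if self.e_tot is None:
            return None
        return self.e_tot - self.e_mbe

    def as_dict(self) -> dict:
        d = {
            "level": self.level,
            "monomer_energies": self.monomer_energies,
            "dimer_corrections": {f"{i},{j}": v for (i, j), v
                                  in self.dimer_corrections.items()},
            "e_mbe_kj_mol": self.e_mbe,
        }
        if self.level >= 3:
            d["trimer_corrections"] = {f"{i},{j},{k}": v for (i, j, k), v
                                       in self.trimer_corrections.items()}
        if self.e_tot is not None:
            d["e_tot_kj_mol"] = self.e_tot
            d["fragmentation_error_kj_mol"] = self.fragmentation_error
        return d


def enumerate_nmers(n_fragments: int, level: int):
    """All strictly increasing dimer (and trimer) index tuples."""
    if level not in (2, 3):
        raise ValueError("level must be 2 or 3")
    dimers = list(itertools.combinations(range(n_fragments), 2))
    if level == 2:
        return dimers
    return dimers + list(itertools.combinations(range(n_fragments), 3))


def _union_fragment(fragments: list[Fragment], members: tuple[int, ...]
                    ) -> Fragment:
    atoms: list[int] = []
    for k in members:
        atoms.extend(fragments[k].atom_indices)
    atoms_t = tuple(sorted(atoms))
    atom_set = set(atoms_t)
    union = Fragment(atoms_t)
    for k in members:
        for cap in fragments[k].caps:
            if cap.severed[1] not in atom_set:
                union.caps.append(cap)
    return union


def nmer_geometry(graph: MolecularGraph, fragments: list[Fragment],
                  members: tuple[int, ...], label: str = ""):
    """Capped geometry of a monomer/dimer/trimer union."""
    return capped_geometry(graph, _union_fragment(fragments, members),
                           label=label or "-".join(map(str, members)))


def mbe_energy(graph: MolecularGraph, fragments: list[Fragment],
               backend: EnergyBackend, level: int = 2,
               e_tot: float | None = None,
               compute_e_tot: bool = True) -> MBETerms:
    """Assemble the MBE energy at the requested truncation level."""
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    n = len(fragments)

    def energy(members: tuple[int, ...]) -> float:
        geo = nmer_geometry(graph, fragments, members)
        try:
            return backend.evaluate(geo)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"backend failed on n-mer {members}") from exc

    e_mono = [energy((k,)) for k in range(n)]
    terms = MBETerms(level, e_mono)
    pair_e: dict[tuple[int, int], float] = {}
    if level >= 2:
        for (i, j) in itertools.combinations(range(n), 2):
            pair_e[(i, j)] = energy((i, j))
            terms.dimer_corrections[(i, j)] = (pair_e[(i, j)] - e_mono[i]
                                               - e_mono[j])
    if level >= 3:
        for (i, j, k) in itertools.combinations(range(n), 3):
            e_ijk = energy((i, j, k))
            terms.trimer_corrections[(i, j, k)] = (
                e_ijk
                - terms.dimer_corrections[(i, j)]
                - terms.dimer_corrections[(i, k)]
                - terms.dimer_corrections[(j, k)]
                - e_mono[i] - e_mono[j] - e_mono[k])
    if e_tot is not None:
        terms.e_tot = e_tot
    elif compute_e_tot:
        whole = Fragment(tuple(range(len(graph.atoms))))
        terms.e_tot = backend.evaluate(
            capped_geometry(graph, whole, label="system"))
    return terms


def fragmentation_error(e_tot: float, e_f: float) -> tuple[float, float]:
    """Signed and absolute fragmentation error ΔE = E_tot − E_f (kJ/mol)."""
    delta = e_tot - e_f
    return delta, abs(delta)


def mbe_from_energy_table(energies: dict[tuple[int, ...], float],
                          n_fragments: int, level: int = 2) -> MBETerms:
    """Assemble MBE terms from externally computed per-n-mer energies
    (e.g. ab initio energies produced elsewhere).  Keys are strictly
    increasing fragment-index tuples; a key ``()`` may carry E_tot."""
    e_mono = [energies[(k,)] for k in range(n_fragments)]
    terms = MBETerms(level, e_mono, e_tot=energies.get((), None))
    if level >= 2:
        for (i, j) in itertools.combinations(range(n_fragments), 2):
            terms.dimer_corrections[(i, j)] = (energies[(i, j)] - e_mono[i]
                                               - e_mono[j])
    if level >= 3:
        for (i, j, k) in itertools.combinations(range(n_fragments), 3):
            terms.trimer_corrections[(i, j, k)] = (
                energies[(i, j, k)]
                - terms.dimer_corrections[(i, j)]
                - terms.dimer_corrections[(i, k)]
                - terms.dimer_corrections[(j, k)]
                - e_mono[i] - e_mono[j] - e_mono[k])
    return terms
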