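"""Classical energy backends and the dimer-energy edge screening.

A backend maps a bonded :class:`~gafrag.geom.Geometry` to a single-point
energy in kJ/mol (no geometry optimisation).  Production use goes through
UFF via RDKit; a family of closed-form toy backends exists for fast,
dependency-light and exactly analysable behaviour:

* :class:`AdditiveBackend` — per-atom terms only (strictly additive);
* :class:`BondedToyBackend` — per-atom + per-bond (+ per-angle) terms over
  the geometry's bonded topology, i.e. an exactly 2-body (or 3-body)
  Hamiltonian over that topology;
* :class:`ClusterPairBackend` / :class:`ClusterTripleBackend` — all-pairs
  (and all-triples) distance-based terms for bond-free atom clusters.

The dimer-energy correction ΔE_IJ = E_IJ − E_I − E_J measures the
force-field perturbation of restoring one cut bond; edges whose correction
exceeds a threshold get blacklisted by the optimiser.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fragments import (FragmentationState, Fragment, extract_fragments,
                        capped_geometry)
from .geom import Geometry
from .molgraph import MolecularGraph

KCAL_TO_KJ = 4.184


class EnergyBackend:
    """Contract: deterministic single-point energies in kJ/mol."""

    name: str = "abstract"
    deterministic: bool = True

    def evaluate(self, geometry: Geometry) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass
class AdditiveBackend(EnergyBackend):
    """E = Σ per-element constants (kJ/mol).  Exactly additive, so every
    many-body correction vanishes and Δ_pe closes to −(cap contributions)."""

    per_element: dict[str, float] = field(
        default_factory=lambda: {"H": 1.0})
    default: float = 2.0
    name: str = "additive"

    def evaluate(self, geometry: Geometry) -> float:
        return float(sum(self.per_element.get(el, self.default)
                         for el in geometry.elements))


# per-element coupling constants (element-distinguishable, order-unity);
# sized so a hydrogen cap roughly restores the severed bond's contribution,
# leaving a few kJ/mol of residual per cut, as a real force field would
_ELN = {"H": 0.9, "C": 1.0, "N": 1.1, "O": 1.2, "F": 1.3, "Cl": 1.15,
        "S": 1.05, "P": 0.95, "Br": 1.1, "I": 1.05}


@dataclass
class BondedToyBackend(EnergyBackend):
    """Topology-based toy Hamiltonian.

    E = Σ_atoms a(el) + Σ_bonds k·(r − r0)² + c(el_i)c(el_j)
        [+ Σ_angles t·c(el_a)c(el_b)·(cosθ − cos0)² when order=3]

    Bond and angle sets come from the geometry's own bond list, so the
    energy is an exactly 2-body (order=2) or 3-body (order=3) function of
    the bonded topology.
    """

    order: int = 2
    atom_term: float = 0.4
    bond_k: float = 3.0
    bond_r0: float = 1.45
    angle_k: float = 0.5
    angle_cos0: float = 0.0  # rest at 90° so tetrahedral angles carry energy
    name: str = "bonded-toy"

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        self.name = f"bonded-toy-{self.order}body"

    def evaluate(self, geometry: Geometry) -> float:
        xyz = geometry.coords
        e = self.atom_term * len(geometry.elements)
        for el in geometry.elements:
            e += _ELN.get(el, 1.0)
        neighbours: dict[int, list[int]] = {}
        for (i, j, _o) in geometry.bonds:
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            ci = _ELN.get(geometry.elements[i], 1.0)
            cj = _ELN.get(geometry.elements[j], 1.0)
            e += self.bond_k * (r - self.bond_r0) ** 2 + ci * cj
            neighbours.setdefault(i, []).append(j)
            neighbours.setdefault(j, []).append(i)
        if self.order == 3:
            for centre, nbs in neighbours.items():
                for a, b in itertools.combinations(sorted(nbs), 2):
                    va = xyz[a] - xyz[centre]
                    vb = xyz[b] - xyz[centre]
                    cos = float(np.dot(va, vb)
                                / (np.linalg.norm(va) * np.linalg.norm(vb)))
                    ca = _ELN.get(geometry.elements[a], 1.0)
                    cb = _ELN.get(geometry.elements[b], 1.0)
                    e += self.angle_k * ca * cb * (cos - self.angle_cos0) ** 2
        return float(e)


@dataclass
class ClusterPairBackend(EnergyBackend):
    """All-pairs Lennard-Jones-like 2-body energy for atom clusters."""

    epsilon: float = 0.8
    sigma: float = 3.4
    atom_term: float = 1.0
    name: str = "cluster-pair"

    def _pair(self, r: float) -> float:
        sr6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)

    def evaluate(self, geometry: Geometry) -> float:
        xyz = geometry.coords
        n = len(geometry.elements)
        e = self.atom_term * n
        for i in range(n):
            for j in range(i + 1, n):
                e += self._pair(float(np.linalg.norm(xyz[i] - xyz[j])))
        return float(e)


@dataclass
class ClusterTripleBackend(ClusterPairBackend):
    """Adds an Axilrod-Teller-like all-triples 3-body term."""

    nu: float = 25.0
    name: str = "cluster-triple"

    def evaluate(self, geometry: Geometry) -> float:
        e = super().evaluate(geometry)
        xyz = geometry.coords
        n = len(geometry.elements)
        for i, j, k in itertools.combinations(range(n), 3):
            rij = float(np.linalg.norm(xyz[i] - xyz[j]))
            rik = float(np.linalg.norm(xyz[i] - xyz[k]))
            rjk = float(np.linalg.norm(xyz[j] - xyz[k]))
            e += self.nu / (rij * rik * rjk) ** 3
        return float(e)


class UFFBackend(EnergyBackend):
    """Universal force field single-point energies via RDKit.

    Molecules are assembled from the perceived bonded topology (no
    re-perception), sanitised without kekulisation/aromaticity steps, and
    evaluated without geometry optimisation.  Energies convert from
    kcal/mol at 4.184.
    """

    name = "uff"

    def __init__(self) -> None:
        from rdkit import Chem  # deferred: optional heavyweight import
        from rdkit.Chem import AllChem
        from rdkit import RDLogger
        RDLogger.DisableLog("rdApp.*")
        self._chem = Chem
        self._allchem = AllChem

    def evaluate(self, geometry: Geometry) -> float:
        Chem = self._chem
        mol = Chem.RWMol()
        for el in geometry.elements:
            atom = Chem.Atom(el)
            atom.SetNoImplicit(True)
            mol.AddAtom(atom)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}
        for (i, j, o) in geometry.bonds:
            mol.AddBond(int(i), int(j), order_map[o])
        conf = Chem.Conformer(len(geometry.elements))
        for i, (x, y, z) in enumerate(geometry.coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        m = mol.GetMol()
        m.AddConformer(conf)
        try:
            Chem.SanitizeMol(
                m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
                | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                | Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
            ff = self._allchem.UFFGetMoleculeForceField(m)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"UFF setup failed for geometry {geometry.label!r}") from exc
        return float(ff.CalcEnergy()) * KCAL_TO_KJ


BACKENDS = {
    "uff": UFFBackend,
    "additive": AdditiveBackend,
    "toy": BondedToyBackend,
    "toy3": lambda: BondedToyBackend(order=3),
}


def get_backend(name: str) -> EnergyBackend:
    try:
        return BACKENDS[name]()
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(BACKENDS)}")


def ff_energy(geometry: Geometry, backend: EnergyBackend) -> float:
    """Single-point energy of a bonded geometry, kJ/mol."""
    return backend.evaluate(geometry)


def dimer_energy_correction(graph: MolecularGraph, state: FragmentationState,
                            edge: tuple[int, int], backend: EnergyBackend,
                            fragments: list[Fragment] | None = None) -> float:
    """ΔE_IJ = E_IJ − E_I − E_J for one broken edge (kJ/mol).

    E_I and E_J are the capped-monomer energies of the two fragments holding
    the edge's endpoints; E_IJ is their union with this edge (and any other
    cut bond between the same two fragments) restored, caps on all other
    broken bonds retained.
    """
    edge = tuple(sorted(edge))
    if edge not in set(map(tuple, state.broken_edges)):
        raise ValueError(f"edge {edge} is not flagged broken in the state")
    if fragments is None:
        fragments = extract_fragments(graph, state)
    member = {}
    for k, f in enumerate(fragments):
        for i in f.atom_indices:
            member[i] = k
    ki, kj = member[edge[0]], member[edge[1]]
    if ki == kj:
        raise ValueError(f"endpoints of {edge} lie in the same fragment")
    fi, fj = fragments[ki], fragments[kj]
    e_i = backend.evaluate(capped_geometry(graph, fi, label=f"monomer-{ki}"))
    e_j = backend.evaluate(capped_geometry(graph, fj, label=f"monomer-{kj}"))
    union_atoms = tuple(sorted(fi.atom_indices + fj.atom_indices))
    members = set(union_atoms)
    union = Fragment(union_atoms)
    # keep caps whose severed partner lies outside the union
    for cap in fi.caps + fj.caps:
        if cap.severed[1] not in members:
            union.caps.append(cap)
    e_ij = backend.evaluate(capped_geometry(graph, union, label="dimer"))
    return e_ij - e_i - e_j
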