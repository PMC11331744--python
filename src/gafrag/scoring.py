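"""The six-penalty fragmentation scoring function.

The score of a fragmentation state is a weighted sum

    s = β_pe·p_pe + β_conj·p_conj + β_hyper·p_hyper
        + β_vol·p_vol + β_comp·p_comp + β_vrange·p_vrange

where the first three penalties guard the chemical environment (force-field
energy gap, conjugation disruption, hyperconjugation disruption) and the
last three control fragment size (mean volume deviation, fragment count,
volume range).  The shipped default weights are the tuned values with the
fragment-count term retired (β_comp = 0); every sigmoid steepness derives
from a "within 5 % of the asymptote at the boundary" convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fragments import (FragmentationState, Fragment, extract_fragments,
                        fragment_volume, reference_volume, capped_geometry)
from .molgraph import (MolecularGraph, ConjugatedSystem, HyperconjugatedPair)

KCAL_TO_KJ = 4.184

#: tuned weights with the fragment-count penalty retired
DEFAULT_WEIGHTS_NO_COMP = (0.136010, 0.146151, 0.313773, 0.109573, 0.0, 0.294494)
#: original tuned weights including the (statistically insignificant) β_comp
TUNED_WEIGHTS_WITH_COMP = (0.135816, 0.145943, 0.313325, 0.109416, 0.001426,
                           0.294074)


@dataclass(frozen=True)
class PenaltyWeights:
    pe: float = DEFAULT_WEIGHTS_NO_COMP[0]
    conj: float = DEFAULT_WEIGHTS_NO_COMP[1]
    hyper: float = DEFAULT_WEIGHTS_NO_COMP[2]
    vol: float = DEFAULT_WEIGHTS_NO_COMP[3]
    comp: float = DEFAULT_WEIGHTS_NO_COMP[4]
    vrange: float = DEFAULT_WEIGHTS_NO_COMP[5]

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        # tolerance accommodates published weight sets rounded to 6 decimals
        if abs(sum(vals) - 1.0) > 1e-5:
            raise ValueError(f"weights must sum to 1 (got {sum(vals)!r})")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.pe, self.conj, self.hyper, self.vol, self.comp,
                self.vrange)

    @classmethod
    def from_sequence(cls, seq) -> "PenaltyWeights":
        seq = tuple(float(v) for v in seq)
        if len(seq) == 5:  # without the comp slot
            seq = seq[:4] + (0.0,) + seq[4:]
        return cls(*seq)


@dataclass(frozen=True)
class SigmoidParams:
    """Steepness/offset constants of the penalty sigmoids.

    ``lambda_pe``/``d_pe`` shape the energy-gap double logistic,
    ``vol_exponent`` the volume sigmoid, ``lambda_vrange``/``d_vrange`` the
    volume-range logistic.  The 5 % asymptote convention ties them together:
    lambda_vrange = ln 19 / 0.25 and vol_exponent = ln 39 / 0.25 to the
    printed precision.
    """

    lambda_pe: float = 1.963
    d_pe: float = 6.0
    vol_exponent: float = 14.654
    lambda_vrange: float = 11.78
    d_vrange: float = -0.25
    asymptote_fraction: float = 0.05


DEFAULT_SIGMOIDS = SigmoidParams()


@dataclass
class ScoreBreakdown:
    p_pe: float
    p_conj: float
    p_hyper: float
    p_vol: float
    p_comp: float
    p_vrange: float
    delta_pe: float          # kJ/mol
    delta_vol: float
    delta_vrange: float
    n_fragments: int
    n_disrupted_conj: int
    n_disrupted_hyper: int
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)

    @property
    def total(self) -> float:
        w = self.weights
        return (w.pe * self.p_pe + w.conj * self.p_conj
                + w.hyper * self.p_hyper + w.vol * self.p_vol
                + w.comp * self.p_comp + w.vrange * self.p_vrange)

    def as_dict(self) -> dict:
        return {
            "p_pe": self.p_pe, "p_conj": self.p_conj,
            "p_hyper": self.p_hyper, "p_vol": self.p_vol,
            "p_comp": self.p_comp, "p_vrange": self.p_vrange,
            "delta_pe_kj_mol": self.delta_pe,
            "delta_vol": self.delta_vol, "delta_vrange": self.delta_vrange,
            "n_fragments": self.n_fragments,
            "n_disrupted_conjugated_systems": self.n_disrupted_conj,
            "n_disrupted_hyperconjugated_pairs": self.n_disrupted_hyper,
            "total": self.total,
        }


def logistic(x: float) -> float:
    """Overflow-safe standard logistic 1 / (1 + e^{−x})."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def normaliser(delta: float, lam: float) -> float:
    """Odd sigmoid S(Δ) = (1 − e^{−λΔ}) / (1 + e^{−λΔ}) = tanh(λΔ/2)."""
    return math.tanh(0.5 * lam * delta)


def lambda_for_max(delta_max: float,
                   asymptote_fraction: float = 0.05) -> float:
    """Steepness putting S(delta_max) at 1 − asymptote_fraction.

    For the default 5 % convention this is ln 39 / delta_max.
    """
    s = 1.0 - asymptote_fraction
    return 2.0 * math.atanh(s) / delta_max


def potential_energy_penalty(delta_pe: float, n_fragments: int,
                             n_a_min: int, n_t: float,
                             params: SigmoidParams = DEFAULT_SIGMOIDS) -> float:
    """Mirrored-logistic penalty on the one-body energy gap (kJ/mol).

    gamma = sqrt(N_f) · N_A^min / n_t rescales the boundary window with the
    fragmentation granularity; the penalty is even in delta_pe.
    """
    if n_t <= 0 or n_fragments < 1:
        raise ValueError("n_t must be positive and N_f >= 1")
    gamma = math.sqrt(n_fragments) * n_a_min / n_t
    lam, d = params.lambda_pe, params.d_pe
    return (logistic((lam / gamma) * (delta_pe - gamma * d))
            + logistic((lam / gamma) * (-delta_pe - gamma * d)))


def _fragment_membership(fragments: list[Fragment]) -> dict[int, int]:
    member = {}
    for k, f in enumerate(fragments):
        for i in f.atom_indices:
            member[i] = k
    return member


def conjugation_penalty(systems: list[ConjugatedSystem],
                        state: FragmentationState,
                        fragments: list[Fragment],
                        asymptote_fraction: float = 0.05) -> float:
    """Mean normalised conjugation disruption over the disrupted systems.

    A system is disrupted iff a broken bond has both endpoints in it.  For
    each disrupted system,

        Δ_conj = (1/cs)·[(1/N_A) Σ_i N_e^i / N_A^i − cs]

    where N_A^i counts the system's atoms that share atom i's fragment, and
    S(Δ) uses λ = 2·atanh(1−5%) / (N_A − 1) so S(Δ_max) = 0.95 exactly.
    """
    broken = set(map(tuple, state.broken_edges))
    member = _fragment_membership(fragments)
    terms = []
    for sys_ in systems:
        if not (broken & sys_.member_bonds):
            continue
        n_a = sys_.size
        frag_counts: dict[int, int] = {}
        for i in sys_.atom_indices:
            frag_counts[member[i]] = frag_counts.get(member[i], 0) + 1
        acc = 0.0
        for i in sys_.atom_indices:
            acc += sys_.pi_contribution[i] / frag_counts[member[i]]
        cs = sys_.conjugation_score
        delta = (acc / n_a - cs) / cs
        lam = lambda_for_max(sys_.delta_max, asymptote_fraction)
        terms.append(normaliser(delta, lam))
    if not terms:
        return 0.0
    return sum(terms) / len(terms)


def _pair_is_disrupted(pair: HyperconjugatedPair,
                       broken: set[tuple[int, int]]) -> bool:
    """Broken bond on the donor–acceptor path or inside either group."""
    path_bonds = {tuple(sorted(e))
                  for e in zip(pair.path[:-1], pair.path[1:])}
    if broken & path_bonds:
        return True
    for group in (pair.donor, pair.acceptor):
        for (i, j) in broken:
            if i in group.atoms and j in group.atoms:
                return True
    return False


def hyperconjugation_penalty(pairs: list[HyperconjugatedPair],
                             state: FragmentationState,
                             fragments: list[Fragment],
                             asymptote_fraction: float = 0.05) -> float:
    """Mean (1/γ_k)·S(Δ_hyper) over the disrupted donor–acceptor pairs.

    Per fragment holding donor atoms the donated-electron count N_e^i is the
    pair's full N_e when the donor group is intact in that fragment and zero
    otherwise; an acceptor fragment receives N_e only when the entire pair
    is still connected (which cannot happen for a disrupted pair).
    """
    broken = set(map(tuple, state.broken_edges))
    member = _fragment_membership(fragments)
    terms = []
    for pair in pairs:
        if not _pair_is_disrupted(pair, broken):
            continue
        n_e = pair.donated_electrons
        donor_frags: dict[int, int] = {}
        for i in pair.donor.atoms:
            donor_frags[member[i]] = donor_frags.get(member[i], 0) + 1
        acceptor_frags: dict[int, int] = {}
        for j in pair.acceptor.atoms:
            acceptor_frags[member[j]] = acceptor_frags.get(member[j], 0) + 1
        donor_intact = len(donor_frags) == 1
        pair_connected = (donor_intact and len(acceptor_frags) == 1
                          and next(iter(donor_frags))
                          == next(iter(acceptor_frags)))
        d_term = 0.0
        for frag, count in donor_frags.items():
            ne_i = n_e if donor_intact else 0
            d_term += ne_i / count
        d_term /= len(donor_frags)
        a_term = 0.0
        for frag, count in acceptor_frags.items():
            ne_j = n_e if pair_connected else 0
            a_term += ne_j / count
        a_term /= len(acceptor_frags)
        delta = d_term - a_term
        lam = lambda_for_max(pair.delta_max, asymptote_fraction)
        terms.append(normaliser(delta, lam) / pair.separation_bonds)
    if not terms:
        return 0.0
    return sum(terms) / len(terms)


def volume_penalty(volumes: list[float], v_ref: float,
                   params: SigmoidParams = DEFAULT_SIGMOIDS) -> tuple[float, float]:
    """Sigmoid of the squared mean relative volume deviation.

    The per-fragment summand is constant in the fragment index, so the outer
    mean collapses to a single sigmoid of Δ_vol² (algebraically identical to
    the per-fragment average).  Returns (p_vol, Δ_vol).
    """
    if not volumes or v_ref <= 0:
        raise ValueError("need at least one fragment and a positive V_ref")
    delta = sum((v - v_ref) / v_ref for v in volumes) / len(volumes)
    p = logistic(params.vol_exponent * delta * delta)
    return p, delta


def volume_range_penalty(volumes: list[float], v_ref: float,
                         params: SigmoidParams = DEFAULT_SIGMOIDS
                         ) -> tuple[float, float]:
    """Logistic penalty on the spread (max − min) of fragment volumes."""
    if not volumes:
        raise ValueError("need at least one fragment")
    v_range = max(volumes) - min(volumes)
    delta = (v_range - v_ref) / v_ref
    p = logistic(params.lambda_vrange * (delta - params.d_vrange))
    return p, delta


def component_penalty(n_fragments: int) -> float:
    """Reciprocal fragment count (retired from the default score)."""
    if n_fragments < 1:
        raise ValueError("N_f must be >= 1")
    return 1.0 / n_fragments


def mbe1_energy_gap(graph: MolecularGraph, state: FragmentationState,
                    backend, fragments: list[Fragment] | None = None,
                    e_tot: float | None = None) -> float:
    """Δ_pe = E_tot − E_MBE1 (kJ/mol): whole-system energy minus the sum of
    capped-monomer energies, all from the same force-field backend."""
    if fragments is None:
        fragments = extract_fragments(graph, state)
    if e_tot is None:
        whole = capped_geometry(
            graph, Fragment(tuple(range(len(graph.atoms)))), label="system")
        e_tot = backend.evaluate(whole)
    e_mbe1 = 0.0
    for k, frag in enumerate(fragments):
        geo = capped_geometry(graph, frag, label=f"monomer-{k}")
        try:
            e_mbe1 += backend.evaluate(geo)
        except Exception as exc:  # noqa: BLE001 - annotate which fragment
            raise RuntimeError(
                f"energy backend failed on fragment {k} "
                f"(atoms {frag.atom_indices[:5]}...)") from exc
    return e_tot - e_mbe1


def total_score(graph: MolecularGraph, state: FragmentationState,
                weights: PenaltyWeights, backend, n_t: float,
                params: SigmoidParams = DEFAULT_SIGMOIDS,
                v_ref: float | None = None,
                e_tot: float | None = None,
                include_comp: bool = False) -> ScoreBreakdown:
    """Evaluate all penalties for a fragmentation state."""
    fragments = extract_fragments(graph, state)
    for f in fragments:
        f.volume = fragment_volume(graph, f)
    volumes = [f.volume for f in fragments]
    if v_ref is None:
        v_ref = reference_volume(graph, n_t)
    n_f = len(fragments)
    n_a_min = min(f.bare_size for f in fragments)
    delta_pe = mbe1_energy_gap(graph, state, backend, fragments, e_tot)
    p_pe = potential_energy_penalty(delta_pe, n_f, n_a_min, n_t, params)
    broken = set(map(tuple, state.broken_edges))
    p_conj = conjugation_penalty(graph.conjugated_systems, state, fragments,
                                 params.asymptote_fraction)
    n_disrupted_conj = sum(1 for s in graph.conjugated_systems
                           if broken & s.member_bonds)
    p_hyper = hyperconjugation_penalty(graph.hyper_pairs, state, fragments,
                                       params.asymptote_fraction)
    n_disrupted_hyper = sum(1 for p in graph.hyper_pairs
                            if _pair_is_disrupted(p, broken))
    p_vol, d_vol = volume_penalty(volumes, v_ref, params)
    p_vrange, d_vrange = volume_range_penalty(volumes, v_ref, params)
    p_comp = component_penalty(n_f) if (include_comp or weights.comp > 0) else 0.0
    return ScoreBreakdown(p_pe, p_conj, p_hyper, p_vol, p_comp, p_vrange,
                          delta_pe, d_vol, d_vrange, n_f,
                          n_disrupted_conj, n_disrupted_hyper, weights)
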