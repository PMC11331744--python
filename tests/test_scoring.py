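"""The six penalty terms and the weighted total."""

import math

import pytest

from gafrag import fixtures, molgraph
from gafrag.forcefield import AdditiveBackend
from gafrag.fragments import (FragmentationState, Fragment, allowed_edges,
                              extract_fragments)
from gafrag.scoring import (PenaltyWeights, SigmoidParams,
                            component_penalty, conjugation_penalty,
                            hyperconjugation_penalty, lambda_for_max,
                            mbe1_energy_gap, normaliser,
                            potential_energy_penalty, total_score,
                            volume_penalty, volume_range_penalty)

PARAMS = SigmoidParams()


class TestPotentialEnergyPenalty:
    def test_value_at_zero_gap_unit_gamma(self):
        # two identical mirrored logistics at the offset point
        expected = 2.0 / (1.0 + math.exp(1.963 * 6.0))
        got = potential_energy_penalty(0.0, n_fragments=1, n_a_min=10,
                                       n_t=10)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_saturates_at_large_gap(self):
        assert potential_energy_penalty(1e6, 1, 10, 10) == pytest.approx(1.0)
        assert potential_energy_penalty(-1e6, 1, 10, 10) == pytest.approx(1.0)

    def test_even_in_the_gap(self):
        for delta in (25.0, 3.7, 111.0):
            assert potential_energy_penalty(delta, 4, 18, 20) == \
                potential_energy_penalty(-delta, 4, 18, 20)


class TestEnergyGap:
    def test_uncut_state_gap_is_exactly_zero(self, toy_backend):
        g = molgraph.from_structure(fixtures.build_chain(6, "alkane"))
        edges = allowed_edges(g, 4)
        state = FragmentationState.zeros(tuple(edges))
        assert mbe1_energy_gap(g, state, toy_backend) == 0.0

    def test_additive_backend_gap_counts_caps(self):
        backend = AdditiveBackend(per_element={}, default=3.0)
        g = molgraph.from_structure(fixtures.build_chain(10, "alkane"))
        edges = allowed_edges(g, 6)
        bits = [0] * len(edges)
        bits[0] = bits[-1] = 1
        state = FragmentationState(tuple(edges), tuple(bits))
        # each cut adds two cap atoms of 3.0 each to E_MBE1
        assert mbe1_energy_gap(g, state, backend) == pytest.approx(-12.0)


class TestConjugationPenalty:
    def test_untouched_systems_cost_nothing(self, graphs):
        g = graphs("pyrrole")
        frags = [Fragment(tuple(a.index for a in g.atoms))]
        assert conjugation_penalty(g.conjugated_systems,
                                   FragmentationState((), ()), frags) == 0.0

    def test_normaliser_hits_095_at_maximum_disruption(self):
        for delta_max in (1.0, 4.0, 17.0):
            lam = lambda_for_max(delta_max)
            assert normaliser(delta_max, lam) == pytest.approx(0.95,
                                                               abs=1e-12)
            assert normaliser(0.0, lam) == 0.0

    def test_pyrrole_nitrogen_isolation_by_hand_substitution(self, graphs):
        g = graphs("pyrrole")
        sys_ = g.conjugated_systems[0]
        n_idx = next(a.index for a in g.atoms if a.element == "N")
        ring_bond = next(b for b in sys_.member_bonds if n_idx in b)
        others = tuple(a.index for a in g.atoms if a.index != n_idx)
        frags = [Fragment((n_idx,)), Fragment(others)]
        state = FragmentationState((ring_bond,), (1,))
        # hand substitution: N isolated (2/1), four carbons together (1/4 x4)
        acc = 2.0 / 1.0 + 4 * (1.0 / 4.0)
        cs = 6 / 25
        delta = (acc / 5 - cs) / cs
        expected = math.tanh(0.5 * (math.log(39) / 4) * delta)
        got = conjugation_penalty([sys_], state, frags)
        assert got == pytest.approx(expected, rel=1e-12)
        assert delta == pytest.approx(1.5)


class TestHyperconjugationPenalty:
    def test_severed_bridge_gives_printed_components(self, graphs):
        g = graphs("3-chloroprop-1-ene")
        pair = g.hyper_pairs[0]
        state = FragmentationState(((1, 2),), (1,))
        frags = extract_fragments(g, state)
        # donor C=C intact: N_d = 1, N_A^i = 2, N_e^i = 2;
        # acceptor C-Cl intact but orphaned: N_a = 1, N_A^j = 2, N_e^j = 0
        # so Delta = 2/2 - 0/2 = 1 = Delta_max and S = 0.95 at one bond.
        assert pair.donated_electrons == 2
        assert pair.delta_max == pytest.approx(1.0)
        got = hyperconjugation_penalty([pair], state, frags)
        assert got == pytest.approx(0.95, abs=1e-12)

    def test_untouched_pairs_cost_nothing(self, graphs):
        g = graphs("propene")
        frags = [Fragment(tuple(a.index for a in g.atoms))]
        assert hyperconjugation_penalty(g.hyper_pairs,
                                        FragmentationState((), ()),
                                        frags) == 0.0


class TestVolumePenalties:
    def test_matching_volumes_give_half(self):
        p, d = volume_penalty([100.0, 100.0, 100.0], 100.0)
        assert d == 0.0
        assert p == 0.5

    def test_half_deviation_value(self):
        p, d = volume_penalty([150.0], 100.0)
        assert d == pytest.approx(0.5)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-14.654 * 0.25)),
                                  rel=1e-12)
        assert p == pytest.approx(0.975, abs=5e-4)

    def test_volume_penalty_saturates(self):
        p, _ = volume_penalty([1e9], 1.0)
        assert p == pytest.approx(1.0)

    def test_identical_volumes_minimise_range_penalty(self):
        p, d = volume_range_penalty([70.0, 70.0], 100.0)
        assert d == pytest.approx(-1.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(11.78 * 0.75)),
                                  rel=1e-12)

    def test_range_equal_to_reference_sits_at_095(self):
        p, d = volume_range_penalty([40.0, 140.0], 100.0)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(0.95, abs=1e-4)

    def test_single_fragment_matches_identical_case(self):
        p1, _ = volume_range_penalty([123.0], 100.0)
        p2, _ = volume_range_penalty([55.0, 55.0], 100.0)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestComponentPenalty:
    @pytest.mark.parametrize("n,expected", [(1, 1.0), (4, 0.25), (10, 0.1)])
    def test_reciprocal(self, n, expected):
        assert component_penalty(n) == expected

    def test_retired_by_default(self):
        assert PenaltyWeights().comp == 0.0


class TestTotalScore:
    def test_score_bounded_and_deterministic(self, toy_backend):
        g = molgraph.from_structure(fixtures.build_chain(5, "peptide"))
        edges = allowed_edges(g, 12)
        bits = tuple(1 if k == len(edges) // 2 else 0
                     for k in range(len(edges)))
        state = FragmentationState(tuple(edges), bits)
        w = PenaltyWeights()
        bd1 = total_score(g, state, w, toy_backend, 12)
        bd2 = total_score(g, state, w, toy_backend, 12)
        assert bd1.total == bd2.total
        for p in (bd1.p_pe, bd1.p_conj, bd1.p_hyper, bd1.p_vol,
                  bd1.p_vrange):
            assert 0.0 <= p <= 1.0
        assert 0.0 <= bd1.total <= 1.0 + 1e-5

    def test_rigid_motion_invariance(self, toy_backend, random_rotation):
        rot, trans = random_rotation
        s = fixtures.build_chain(5, "peptide", seed=2)
        g0 = molgraph.from_structure(s)
        g1 = molgraph.from_structure(s.transformed(rot, trans))
        edges = allowed_edges(g0, 12)
        assert edges == allowed_edges(g1, 12)
        bits = tuple(1 if k % 3 == 0 else 0 for k in range(len(edges)))
        state = FragmentationState(tuple(edges), bits)
        w = PenaltyWeights()
        s0 = total_score(g0, state, w, toy_backend, 12).total
        s1 = total_score(g1, state, w, toy_backend, 12).total
        assert abs(s0 - s1) < 1e-8

    def test_weights_must_be_normalised(self):
        with pytest.raises(ValueError):
            PenaltyWeights(0.5, 0.5, 0.5, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            PenaltyWeights(-0.1, 0.4, 0.3, 0.2, 0.0, 0.2)
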