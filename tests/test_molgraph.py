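"""Bond perception, node attributes, conjugation and hyperconjugation."""

import pytest

from gafrag import fixtures, molgraph
from gafrag.geom import Structure
from gafrag.molgraph import (GroupType, Hybridisation, from_structure,
                             perceive_bonds)


class TestBondPerception:
    def test_distant_atoms_form_no_bond(self):
        s = Structure(["H", "H"], [[0, 0, 0], [10, 0, 0]])
        assert perceive_bonds(s) == []

    def test_methanol_has_five_single_bonds(self, graphs):
        g = graphs("methanol")
        assert len(g.bonds) == 5
        assert all(b.order == 1 for b in g.bonds)

    def test_ethene_double_bond_by_nearest_reference(self, graphs):
        g = graphs("ethene")
        cc = [b for b in g.bonds
              if {g.atoms[b.i].element, g.atoms[b.j].element} == {"C"}]
        assert len(cc) == 1 and cc[0].order == 2

    def test_overlapping_atoms_raise_and_name_the_pair(self):
        s = Structure(["C", "C"], [[0, 0, 0], [0.1, 0, 0]])
        with pytest.raises(ValueError, match="overlapping atoms 0 .* 1"):
            perceive_bonds(s)

    def test_unknown_element_rejected(self):
        s = Structure(["C", "Uuo"], [[0, 0, 0], [1.5, 0, 0]])
        with pytest.raises(ValueError, match="radius tables"):
            from_structure(s)

    def test_perception_invariant_under_rigid_motion(self, graphs,
                                                     random_rotation):
        rot, trans = random_rotation
        for name in ("methanol", "pyrrole", "3-chloroprop-1-ene"):
            s = fixtures.build_named_molecule(name)
            moved = s.transformed(rot, trans)
            b0 = {(b.i, b.j, b.order) for b in perceive_bonds(s)}
            b1 = {(b.i, b.j, b.order) for b in perceive_bonds(moved)}
            assert b0 == b1


class TestNodeAttributes:
    def test_pyrrole_nitrogen_contributes_two_pi_electrons(self, graphs):
        g = graphs("pyrrole")
        n = next(a for a in g.atoms if a.element == "N")
        assert n.n_pi_electrons == 2
        assert n.hybridisation is Hybridisation.SP2

    def test_methane_carbon_is_sp3_without_pi(self, graphs):
        c = next(a for a in graphs("methane").atoms if a.element == "C")
        assert c.hybridisation is Hybridisation.SP3
        assert c.n_pi_electrons == 0

    def test_butadiene_carbons_all_sp2_each_one_pi_electron(self, graphs):
        g = graphs("1,3-butadiene")
        carbons = [a for a in g.atoms if a.element == "C"]
        assert all(a.hybridisation is Hybridisation.SP2 for a in carbons)
        assert all(a.n_pi_electrons == 1 for a in carbons)

    def test_pi_electrons_zero_outside_conjugated_systems(self, graphs):
        for name in fixtures.registry_names():
            g = graphs(name)
            inside = set().union(*(s.atom_indices
                                   for s in g.conjugated_systems), set())
            for a in g.atoms:
                if a.index not in inside:
                    assert a.n_pi_electrons == 0


class TestConjugatedSystems:
    def test_pyrrole_single_system_score_six_twentyfifths(self, graphs):
        systems = graphs("pyrrole").conjugated_systems
        assert len(systems) == 1
        assert systems[0].size == 5
        assert systems[0].conjugation_score == pytest.approx(6 / 25, abs=0)

    def test_saturated_chain_has_no_conjugation(self, graphs):
        assert graphs("n-butane").conjugated_systems == []

    def test_butadiene_four_atom_system_score_one_quarter(self, graphs):
        systems = graphs("1,3-butadiene").conjugated_systems
        assert len(systems) == 1
        assert systems[0].size == 4
        assert systems[0].conjugation_score == pytest.approx(0.25, abs=1e-15)

    def test_score_recomputes_from_contributions(self, graphs):
        for name in ("pyrrole", "1,3-butadiene", "peptide174"):
            for sys_ in graphs(name).conjugated_systems:
                n = sys_.size
                expected = sum(sys_.pi_contribution.values()) / n ** 2
                assert abs(sys_.conjugation_score - expected) < 1e-12


class TestHyperconjugatedPairs:
    def test_chloropropene_single_pair_cc_donor_ccl_acceptor(self, graphs):
        pairs = graphs("3-chloroprop-1-ene").hyper_pairs
        assert len(pairs) == 1
        p = pairs[0]
        assert sorted(p.donor.atoms) == [0, 1]      # the C=C, atoms 1-2
        assert p.donor.label == "C=C"
        assert sorted(p.acceptor.atoms) == [2, 3]   # the C-Cl, atoms 3-4
        assert p.acceptor.label == "C-Cl"
        assert p.separation_bonds == 1

    def test_methane_has_no_pairs(self, graphs):
        assert graphs("methane").hyper_pairs == []

    def test_propene_allylic_ch_acceptors_at_one_bond(self, graphs):
        pairs = graphs("propene").hyper_pairs
        assert pairs, "propene must show C=C / allylic C-H hyperconjugation"
        for p in pairs:
            assert p.donor.label == "C=C"
            assert p.donor.gtype is GroupType.PI
            assert p.acceptor.label == "C-H"
            assert p.acceptor.gtype is GroupType.SIGMA
            assert p.separation_bonds == 1

    def test_every_pair_mixes_sigma_and_pi_within_three_bonds(self, graphs):
        for name in fixtures.registry_names():
            for p in graphs(name).hyper_pairs:
                assert {p.donor.gtype, p.acceptor.gtype} == {
                    GroupType.SIGMA, GroupType.PI}
                assert 1 <= p.separation_bonds <= 3
                assert not (p.donor.atoms & p.acceptor.atoms)
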