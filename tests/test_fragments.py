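"""Fragmentation states, capping geometry and the volume model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gafrag import fixtures, molgraph, tables
from gafrag.fragments import (FragmentationState, Fragment, allowed_edges,
                              cap_with_hydrogens, extract_fragments,
                              geometry_volume, hard_sphere_volume,
                              pair_overlap_volume, reference_volume)
from gafrag.geom import Structure


def _chain_graph(n_carbons, seed=0):
    return molgraph.from_structure(
        fixtures.build_chain(n_carbons, "alkane", seed=seed))


class TestAllowedEdges:
    def test_double_bond_excluded(self, graphs):
        g = graphs("ethene")
        assert allowed_edges(g, 2) == []

    def test_terminal_bonds_excluded_by_size_rule(self, graphs):
        g = graphs("n-butane")
        # n_t = 20: every cut leaves a side < 12 atoms
        assert allowed_edges(g, 20) == []

    def test_c20_chain_cuts_leave_both_sides_sufficient(self):
        import networkx as nx
        g = _chain_graph(20)
        edges = allowed_edges(g, 20)
        assert edges, "a C20H42 chain must be cuttable at n_t = 20"
        nxg = g.to_networkx()
        for e in edges:
            h = nxg.copy()
            h.remove_edge(*e)
            sizes = sorted(len(c) for c in nx.connected_components(h))
            assert sizes[0] >= 12
        # exhaustive: every excluded single C-C bridge fails the size rule
        cc = [b.key() for b in g.bonds if b.order == 1
              and g.atoms[b.i].element == "C" and g.atoms[b.j].element == "C"]
        for e in set(cc) - set(edges):
            h = nxg.copy()
            h.remove_edge(*e)
            sizes = sorted(len(c) for c in nx.connected_components(h))
            assert sizes[0] < 12


class TestExtractFragments:
    def test_zero_state_returns_whole_system(self, graphs):
        g = graphs("n-butane")
        edges = tuple(b.key() for b in g.bonds if b.order == 1)
        frags = extract_fragments(g, FragmentationState.zeros(edges))
        assert len(frags) == 1
        assert frags[0].bare_size == len(g.atoms)

    def test_all_ones_state_yields_primitive_monomers(self):
        g = _chain_graph(8)
        edges = allowed_edges(g, 4)
        frags = extract_fragments(g, FragmentationState.ones(tuple(edges)))
        assert len(frags) == len(edges) + 1

    def test_single_cut_conserves_atoms(self):
        g = _chain_graph(10)
        edges = allowed_edges(g, 6)
        bits = [0] * len(edges)
        bits[0] = 1
        frags = extract_fragments(
            g, FragmentationState(tuple(edges), tuple(bits)))
        assert len(frags) == 2
        assert sum(f.bare_size for f in frags) == len(g.atoms)
        assert sum(f.size - len(f.caps) for f in frags) == len(g.atoms)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(bits=st.lists(st.integers(0, 1), min_size=7, max_size=7))
    def test_partition_and_cap_count_for_any_state(self, bits):
        g = _chain_graph(12)
        edges = allowed_edges(g, 4)[:7]
        frags = extract_fragments(
            g, FragmentationState(tuple(edges), tuple(bits)))
        atoms = sorted(i for f in frags for i in f.atom_indices)
        assert atoms == list(range(len(g.atoms)))
        assert sum(len(f.caps) for f in frags) == 2 * sum(bits)


class TestHydrogenCapping:
    def test_cap_coincides_with_partner_of_equal_radius(self, graphs):
        # severed C-H bond: r(j) = r(H), so the cap lands exactly on x(j)
        g = graphs("methane")
        h_bond = g.bonds[0]
        frag = Fragment((h_bond.i,))
        caps = cap_with_hydrogens(g, frag, [h_bond.endpoints])
        np.testing.assert_allclose(caps[0].coords,
                                   g.atoms[h_bond.j].coords, atol=1e-12)

    def test_carbon_carbon_cap_fraction(self):
        g = _chain_graph(4)
        cc = next(b for b in g.bonds if g.atoms[b.i].element == "C"
                  and g.atoms[b.j].element == "C")
        caps = cap_with_hydrogens(g, Fragment((cc.i,)), [cc.endpoints])
        xi, xj = g.atoms[cc.i].coords, g.atoms[cc.j].coords
        frac = (0.76 + 0.31) / (0.76 + 0.76)
        np.testing.assert_allclose(caps[0].coords, xi + frac * (xj - xi),
                                   atol=1e-12)

    def test_cap_distance_at_exact_covalent_length(self):
        r_c, r_h = tables.COVALENT_RADII["C"], tables.COVALENT_RADII["H"]
        s = Structure(["C", "C"], [[0, 0, 0], [2 * r_c, 0, 0]])
        g = molgraph.from_structure(s)
        caps = cap_with_hydrogens(g, Fragment((0,)), [(0, 1)])
        assert np.linalg.norm(caps[0].coords) == pytest.approx(r_c + r_h)

    def test_caps_collinear_with_severed_bond(self):
        g = _chain_graph(10, seed=5)
        edges = allowed_edges(g, 6)
        frags = extract_fragments(g, FragmentationState.ones(tuple(edges)))
        for f in frags:
            for cap in f.caps:
                i, j = cap.severed
                v1 = cap.coords - g.atoms[i].coords
                v2 = g.atoms[j].coords - g.atoms[i].coords
                cross = np.cross(v1, v2)
                assert np.linalg.norm(cross) < 1e-10
                assert 0 < np.dot(v1, v2)

    def test_bond_inside_fragment_is_an_error(self):
        g = _chain_graph(4)
        cc = next(b for b in g.bonds if g.atoms[b.i].element == "C"
                  and g.atoms[b.j].element == "C")
        with pytest.raises(ValueError, match="inside the fragment"):
            cap_with_hydrogens(g, Fragment((cc.i, cc.j)), [cc.endpoints])


class TestVolumeModel:
    def test_single_atom_is_hard_sphere(self):
        assert hard_sphere_volume(1.0) == pytest.approx(4 * math.pi / 3)
        v = geometry_volume(["H"], [[0.0, 0.0, 0.0]])
        assert v == pytest.approx(hard_sphere_volume(tables.VDW_RADII["H"]))

    def test_overlap_vanishes_at_large_separation(self):
        v = geometry_volume(["C", "C"], [[0, 0, 0], [1e3, 0, 0]])
        assert v == pytest.approx(2 * hard_sphere_volume(1.70), rel=1e-12)

    def test_two_carbons_against_independent_closed_form(self):
        # independent re-derivation of the Gaussian-overlap expressions
        sigma, r, a = 1.70, 1.54, 2.0 * math.sqrt(2.0)
        alpha = math.pi * (3 * a / (4 * math.pi * sigma ** 3)) ** (2 / 3)
        overlap = (a * a * math.exp(-alpha * alpha * r * r / (2 * alpha))
                   * (math.pi / (2 * alpha)) ** 1.5)
        expected = 2 * (4 / 3) * math.pi * sigma ** 3 - overlap
        got = geometry_volume(["C", "C"], [[0, 0, 0], [r, 0, 0]])
        assert got == pytest.approx(expected, rel=1e-12)
        assert pair_overlap_volume(sigma, sigma, r) == pytest.approx(
            overlap, rel=1e-12)

    def test_volume_invariant_under_rigid_motion(self, random_rotation):
        rot, trans = random_rotation
        s = fixtures.build_named_molecule("methanol")
        v0 = geometry_volume(s.elements, s.coords)
        moved = s.transformed(rot, trans)
        v1 = geometry_volume(moved.elements, moved.coords)
        assert v1 == pytest.approx(v0, abs=1e-9)


class TestReferenceVolume:
    def test_isolated_atom_keeps_hard_sphere_volume(self):
        s = Structure(["Ar"], [[0.0, 0.0, 0.0]])
        g = molgraph.from_structure(s)
        assert reference_volume(g, 1) == pytest.approx(
            hard_sphere_volume(tables.VDW_RADII["Ar"]))

    def test_methanol_oxygen_averages_exactly_two_bonded_pairs(self, graphs):
        from gafrag.fragments import element_characteristic_volumes
        g = graphs("methanol")
        o_bonds = [b for b in g.bonds if "O" in (g.atoms[b.i].element,
                                                 g.atoms[b.j].element)]
        assert len(o_bonds) == 2  # O bonded to exactly C and H
        sig_o = tables.VDW_RADII["O"]
        overlaps = []
        for b in o_bonds:
            other = b.j if g.atoms[b.i].element == "O" else b.i
            overlaps.append(pair_overlap_volume(
                sig_o, tables.VDW_RADII[g.atoms[other].element], b.length))
        expected = hard_sphere_volume(sig_o) - sum(overlaps) / 2
        assert element_characteristic_volumes(g)["O"] == pytest.approx(
            expected, rel=1e-12)

    def test_homonuclear_diatomic_reference(self):
        s = Structure(["O", "O"], [[0, 0, 0], [1.21, 0, 0]])
        g = molgraph.from_structure(s)
        sig = tables.VDW_RADII["O"]
        v_s = hard_sphere_volume(sig) - pair_overlap_volume(sig, sig, 1.21)
        assert reference_volume(g, 2) == pytest.approx(2 * v_s, rel=1e-12)
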