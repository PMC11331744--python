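"""Many-body expansion assembly and exactness properties."""

import itertools

import numpy as np
import pytest

from gafrag import fixtures, molgraph
from gafrag.forcefield import (BondedToyBackend, ClusterPairBackend,
                               ClusterTripleBackend)
from gafrag.fragments import (FragmentationState, allowed_edges,
                              extract_fragments)
from gafrag.geom import Structure
from gafrag.mbe import (enumerate_nmers, fragmentation_error,
                        mbe_energy, mbe_from_energy_table, nmer_geometry)


def _molecular_case(bits_rule, n_c=12, n_t=5, seed=0):
    g = molgraph.from_structure(fixtures.build_chain(n_c, "alkane",
                                                     seed=seed))
    edges = allowed_edges(g, n_t)
    bits = tuple(bits_rule(k) for k in range(len(edges)))
    frags = extract_fragments(g, FragmentationState(tuple(edges), bits))
    return g, frags


def _cluster(n=7, seed=1, box=9.0):
    rng = np.random.default_rng(seed)
    # rejection-spaced points: no covalent contacts, meaningful interactions
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, box, 3)
        if all(np.linalg.norm(p - q) > 3.0 for q in pts):
            pts.append(p)
    g = molgraph.from_structure(Structure(["Ar"] * n, np.array(pts)))
    assert not g.bonds
    frags = extract_fragments(g, FragmentationState((), ()))
    return g, frags


class TestEnumeration:
    def test_dimer_counts(self):
        assert len(enumerate_nmers(4, 2)) == 6
        assert enumerate_nmers(1, 2) == []

    def test_trimer_counts(self):
        nmers = enumerate_nmers(5, 3)
        assert sum(1 for t in nmers if len(t) == 2) == 10
        assert sum(1 for t in nmers if len(t) == 3) == 10

    def test_index_tuples_strictly_increasing(self):
        for t in enumerate_nmers(6, 3):
            assert list(t) == sorted(set(t))


class TestExactness:
    def test_two_body_topological_hamiltonian_exact_at_mbe2(self):
        for rule in (lambda k: k % 2, lambda k: 1, lambda k: int(k < 2)):
            g, frags = _molecular_case(rule)
            terms = mbe_energy(g, frags, BondedToyBackend(order=2), level=2)
            assert abs(terms.fragmentation_error) < 1e-9

    def test_three_body_hamiltonian_exact_at_mbe3_not_mbe2(self):
        # adjacent cuts create angle terms spanning three fragments
        g = molgraph.from_structure(fixtures.build_chain(12, "alkane"))
        edges = allowed_edges(g, 4)
        bits = tuple(1 if k in (2, 3) else 0 for k in range(len(edges)))
        frags = extract_fragments(g, FragmentationState(tuple(edges), bits))
        be = BondedToyBackend(order=3)
        t3 = mbe_energy(g, frags, be, level=3)
        t2 = mbe_energy(g, frags, be, level=2)
        assert abs(t3.fragmentation_error) < 1e-9
        assert abs(t2.fragmentation_error) > 1e-6
        # closed-form bookkeeping: the MBE2 error is exactly the summed
        # trimer corrections (all higher orders vanish for a 3-body model)
        assert t2.fragmentation_error == pytest.approx(
            sum(t3.trimer_corrections.values()), abs=1e-9)

    def test_cluster_pairwise_backend_exact_at_mbe2(self):
        g, frags = _cluster()
        terms = mbe_energy(g, frags, ClusterPairBackend(), level=2)
        assert abs(terms.fragmentation_error) < 1e-9

    def test_cluster_triple_backend_exact_at_mbe3(self):
        g, frags = _cluster(n=6)
        be = ClusterTripleBackend()
        t3 = mbe_energy(g, frags, be, level=3)
        t2 = mbe_energy(g, frags, be, level=2)
        assert abs(t3.fragmentation_error) < 1e-9
        assert abs(t2.fragmentation_error) > 1e-8
        # independent oracle: the 3-body residue summed over atom triples
        # spanning three distinct fragments
        xyz = g.coords
        member = {}
        for k, f in enumerate(frags):
            for i in f.atom_indices:
                member[i] = k
        resid = 0.0
        for i, j, k in itertools.combinations(range(len(g.atoms)), 3):
            if len({member[i], member[j], member[k]}) == 3:
                rij = np.linalg.norm(xyz[i] - xyz[j])
                rik = np.linalg.norm(xyz[i] - xyz[k])
                rjk = np.linalg.norm(xyz[j] - xyz[k])
                resid += be.nu / (rij * rik * rjk) ** 3
        assert t2.fragmentation_error == pytest.approx(resid, abs=1e-9)


class TestAssembly:
    def test_single_fragment_reduces_to_total_energy(self, toy_backend):
        g, frags = _molecular_case(lambda k: 0)
        assert len(frags) == 1
        terms = mbe_energy(g, frags, toy_backend, level=1)
        assert terms.e_mbe == pytest.approx(terms.e_tot)

    def test_level3_minus_level2_is_the_trimer_sum(self, toy_backend):
        g, frags = _molecular_case(lambda k: k % 2, n_c=14, n_t=4)
        t3 = mbe_energy(g, frags, toy_backend, level=3)
        t2 = mbe_energy(g, frags, toy_backend, level=2)
        assert t3.e_mbe - t2.e_mbe == pytest.approx(
            sum(t3.trimer_corrections.values()), abs=1e-10)

    def test_fragment_order_does_not_change_the_energy(self, toy_backend):
        g, frags = _molecular_case(lambda k: k % 2)
        t = mbe_energy(g, frags, toy_backend, level=2)
        tp = mbe_energy(g, list(reversed(frags)), toy_backend, level=2)
        assert t.e_mbe == pytest.approx(tp.e_mbe, abs=1e-10)

    def test_external_energy_table_matches_direct_assembly(self, toy_backend):
        g, frags = _molecular_case(lambda k: int(k == 1), n_c=10, n_t=5)
        table = {}
        for k in range(len(frags)):
            table[(k,)] = toy_backend.evaluate(nmer_geometry(g, frags, (k,)))
        for pair in enumerate_nmers(len(frags), 2):
            table[pair] = toy_backend.evaluate(nmer_geometry(g, frags, pair))
        direct = mbe_energy(g, frags, toy_backend, level=2,
                            compute_e_tot=False)
        external = mbe_from_energy_table(table, len(frags), level=2)
        assert external.e_mbe == pytest.approx(direct.e_mbe, abs=1e-10)

    def test_fragmentation_error_signed_and_absolute(self):
        assert fragmentation_error(0.0, 0.0) == (0.0, 0.0)
        assert fragmentation_error(-100.0, -95.0) == (-5.0, 5.0)
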