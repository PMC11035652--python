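import numpy as np
import pytest

from condnet.graphs import (bead_adjacency, degree_distribution,
                            graph_pipeline, molecular_adjacency,
                            average_distributions)
from condnet.rdf import NoMinimumError
from condnet.synth import make_fcc, make_toy_condensate
from condnet.topology import Frame


def brute_adjacency(frame, ia, ib, r_cut):
    """All-pairs strict-< contact matrix (oracle)."""
    d = frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :]
    d -= frame.box * np.round(d / frame.box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    return r < r_cut


class TestBeadAdjacency:
    def test_edge_just_inside_cutoff(self):
        box = np.array([50.0] * 3)
        fr = Frame.from_unwrapped(
            np.array([[1.0, 1, 1], [1.0, 1, 1 + 2.0 - 1e-6]]), box)
        ba = bead_adjacency(fr, [0], [1], 2.0)
        assert len(ba.pairs) == 1

    def test_edge_just_outside_cutoff(self):
        box = np.array([50.0] * 3)
        fr = Frame.from_unwrapped(
            np.array([[1.0, 1, 1], [1.0, 1, 1 + 2.0 + 1e-6]]), box)
        ba = bead_adjacency(fr, [0], [1], 2.0)
        assert len(ba.pairs) == 0

    def test_brute_force_oracle_bipartite(self, rng):
        box = np.array([6.0] * 3)
        fr = Frame.from_unwrapped(rng.random((40, 3)) * box, box)
        ia, ib = np.arange(15), np.arange(15, 40)
        ba = bead_adjacency(fr, ia, ib, 1.2)
        ref = brute_adjacency(fr, ia, ib, 1.2)
        mat = np.zeros_like(ref)
        for i, j in ba.pairs:
            mat[i, j - 15] = True
        assert np.array_equal(mat, ref)

    def test_overlapping_sets_rejected(self, rng):
        fr = Frame.from_unwrapped(rng.random((10, 3)) * 5, [5.0] * 3)
        with pytest.raises(ValueError, match="overlap"):
            bead_adjacency(fr, np.arange(6), np.arange(4, 10), 1.0)

    def test_bipartite_blocks_empty_within_class(self, rng):
        """Only cross-set edges can exist by construction."""
        box = np.array([5.0] * 3)
        fr = Frame.from_unwrapped(rng.random((30, 3)) * box, box)
        ba = bead_adjacency(fr, np.arange(10), np.arange(10, 30), 1.5)
        assert np.all(ba.pairs[:, 0] < 10)
        assert np.all(ba.pairs[:, 1] >= 10)


class TestMolecularAdjacency:
    def test_empty_bead_adjacency(self):
        box = np.array([50.0] * 3)
        fr = Frame.from_unwrapped(np.array([[1.0, 1, 1], [30.0, 30, 30]]), box)
        ba = bead_adjacency(fr, [0], [1], 1.0)
        mg = molecular_adjacency(ba)
        assert len(mg.edges) == 0
        assert np.all(mg.degrees() == 0)

    def test_single_contact_single_edge(self):
        topo, fr, ff = make_toy_condensate(2, 6, seed=1, box=90.0)
        acid = topo.select(region="A1")
        base = topo.select(charge_sign=1)
        # move one acid bead of molecule 0 next to one base bead of mol 7
        coords = fr.coords.copy()
        coords[acid[0]] = coords[base[30]] + np.array([0.5, 0, 0])
        fr2 = Frame(coords=np.mod(coords, fr.box), box=fr.box)
        ba = bead_adjacency(fr2, acid, base, 1.0, topo=topo)
        mg = molecular_adjacency(ba)
        assert len(mg.edges) == 1
        assert mg.weights[0] == 1
        ma, mb = topo.mol_id[acid[0]], topo.mol_id[base[30]]
        mols = np.unique(ba.mol_of)
        expect = tuple(sorted((np.searchsorted(mols, ma),
                               np.searchsorted(mols, mb))))
        assert tuple(mg.edges[0]) == expect

    @pytest.mark.parametrize("seed", range(5))
    def test_block_reduction_equals_fast_path(self, seed):
        """The unique-pair fast path equals explicit block reduction."""
        rng = np.random.default_rng(seed)
        topo, fr, ff = make_toy_condensate(2, 8, seed=seed, box=90.0)
        acid = topo.select(charge_sign=-1)
        base = topo.select(charge_sign=1)
        for rep in range(20):
            coords = rng.random((topo.n_beads, 3)) * fr.box
            f = Frame(coords=coords, box=fr.box)
            ba = bead_adjacency(f, acid, base, 12.0, topo=topo)
            mg = molecular_adjacency(ba)
            mols = np.unique(ba.mol_of)
            w = ba.block_nonempty({int(m): i for i, m in enumerate(mols)},
                                  len(mols))
            coo = w.tocoo()
            ref_edges = {(min(i, j), max(i, j))
                         for i, j in zip(coo.row, coo.col)}
            fast_edges = {tuple(e) for e in mg.edges}
            assert fast_edges == ref_edges
            # weighted variant: block sums match edge contact counts
            for (i, j), wt in zip(mg.edges, mg.weights):
                assert w[i, j] == wt


class TestDegreeDistribution:
    def test_isolated_node(self):
        box = np.array([50.0] * 3)
        fr = Frame.from_unwrapped(np.array([[1.0, 1, 1], [30.0, 30, 30]]), box)
        ba = bead_adjacency(fr, np.arange(2), np.arange(2), 1.0)
        dd = degree_distribution([molecular_adjacency(ba)])
        assert dd.pk[0] == 1.0

    def test_complete_bipartite_2_3(self):
        box = np.array([100.0] * 3)
        coords = np.array([[0, 0, 0], [0.5, 0, 0],
                           [0, 0.3, 0], [0.25, 0.3, 0], [0.5, 0.3, 0]],
                          dtype=float) + 10
        fr = Frame.from_unwrapped(coords, box)
        ba = bead_adjacency(fr, np.arange(2), np.arange(2, 5), 1.0)
        mg = molecular_adjacency(ba)
        assert sorted(mg.degrees()) == [2, 2, 2, 3, 3]
        dd = degree_distribution([mg])
        assert dd.pk[2] == pytest.approx(0.6)
        assert dd.pk[3] == pytest.approx(0.4)
        assert dd.pk.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degree_sum_is_twice_edges(self, rng):
        box = np.array([6.0] * 3)
        fr = Frame.from_unwrapped(rng.random((50, 3)) * box, box)
        sel = np.arange(50)
        ba = bead_adjacency(fr, sel, sel, 1.3)
        mg = molecular_adjacency(ba)
        assert mg.degrees().sum() == 2 * len(mg.edges)

    def test_matches_networkx_degrees(self, rng):
        import networkx as nx

        box = np.array([6.0] * 3)
        fr = Frame.from_unwrapped(rng.random((60, 3)) * box, box)
        sel = np.arange(60)
        mg = molecular_adjacency(bead_adjacency(fr, sel, sel, 1.2))
        g = mg.to_networkx()
        ref = np.array([d for _, d in sorted(g.degree())])
        assert np.array_equal(mg.degrees(), ref)

    def test_mtx_export_round_trip(self, rng, tmp_path):
        from scipy.io import mmread

        box = np.array([6.0] * 3)
        fr = Frame.from_unwrapped(rng.random((40, 3)) * box, box)
        sel = np.arange(40)
        mg = molecular_adjacency(bead_adjacency(fr, sel, sel, 1.2))
        p = tmp_path / "adj.mtx"
        mg.save_mtx(p)
        back = mmread(p).toarray()
        assert np.array_equal(back, mg.adjacency().toarray())

    def test_replicate_sem(self):
        from condnet.graphs import DegreeDistribution

        d1 = DegreeDistribution(k=np.arange(3), pk=np.array([0.2, 0.3, 0.5]))
        d2 = DegreeDistribution(k=np.arange(3), pk=np.array([0.4, 0.3, 0.3]))
        avg = average_distributions([d1, d2])
        assert avg.pk[0] == pytest.approx(0.3)
        assert avg.sem[0] == pytest.approx(np.std([0.2, 0.4], ddof=1) /
                                           np.sqrt(2))


class TestGraphPipeline:
    def test_fcc_all_degrees_twelve(self):
        frame, truth = make_fcc(3, 1.4)
        from condnet.topology import Trajectory

        traj = Trajectory([frame])
        sel = np.arange(frame.n_beads)
        cut = 1.2 * truth["nn_distance"]
        res = graph_pipeline(traj, None, sel, sel, dr=0.02, cutoff=cut)
        assert np.all(res.graphs[0].degrees() == 12)
        assert res.degrees.mode == 12

    def test_ideal_gas_surfaces_no_minimum(self, rng):
        from condnet.topology import Trajectory

        box = np.array([12.0] * 3)
        frames = [Frame.from_unwrapped(rng.random((300, 3)) * box, box,
                                       time=float(i)) for i in range(10)]
        traj = Trajectory(frames)
        sel = np.arange(300)
        with pytest.raises(NoMinimumError):
            graph_pipeline(traj, None, sel, sel, dr=0.4)

    def test_toy_condensate_hand_counted(self):
        """Pentamers and peptides placed at known contacts give the
        hand-counted bipartite degrees."""
        topo, fr, ff = make_toy_condensate(2, 2, seed=0, box=400.0)
        acid = topo.select(charge_sign=-1)
        base = topo.select(charge_sign=1)
        coords = fr.coords.copy()
        # separate everything, then wire: the first peptide (molecule 2)
        # contacts pentamer 0; the second peptide (molecule 3) contacts both
        mol_of = topo.mol_id
        for m in range(4):
            coords[mol_of == m] = coords[mol_of == m] - \
                coords[mol_of == m].mean(axis=0) + 80.0 * (m + 1)
        coords[acid[0]] = 10.0
        coords[base[0]] = 10.4          # pep 2 (first peptide) near pent 0
        pent1_acid = acid[topo.mol_id[acid] == 1]
        pep3_base = base[topo.mol_id[base] == 3]
        coords[pent1_acid[0]] = 20.0
        coords[pep3_base[0]] = 20.4
        pent0_acid2 = acid[topo.mol_id[acid] == 0]
        coords[pent0_acid2[1]] = 30.0
        coords[pep3_base[1]] = 30.4
        fr2 = Frame(coords=np.mod(coords, fr.box), box=fr.box)
        ba = bead_adjacency(fr2, acid, base, 1.5, topo=topo)
        mg = molecular_adjacency(ba)
        deg = {m: d for m, d in zip(np.unique(ba.mol_of), mg.degrees())}
        assert deg[0] == 2   # pent 0: pep 2 and pep 3
        assert deg[1] == 1   # pent 1: pep 3
        assert deg[2] == 1
        assert deg[3] == 2
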