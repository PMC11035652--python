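"""Graph-theoretic network analysis: bead adjacency, block-summed
molecular adjacency, and degree distributions.

Two bead selections (e.g. acidic beads of one tract of the pentamer and
basic peptide beads) define a bipartite bead adjacency: an edge whenever
the minimum-image distance is strictly below the cutoff radius, which is
taken from the first minimum of the inter-set g(r).  Summing the bead
adjacency over molecule blocks gives the molecule-level graph: two
molecules are adjacent when any of their selected beads are in contact
(the weighted variant stores the block edge count).  Degrees are row sums
of the unweighted molecular adjacency; distributions are computed
per-snapshot and then averaged.

For atomic systems (the Lennard-Jones phases) every particle is its own
molecule and the two selections coincide; the same machinery then yields
the unipartite contact graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .rdf import RDFResult, compute_rdf, first_minimum
from .topology import Frame, Topology, Trajectory


@dataclass
class BeadAdjacency:
    """Sparse symmetric bead contact matrix over the selected beads."""

    pairs: np.ndarray          # (M, 2) selection-local index pairs, a-block first
    n_a: int
    n_b: int
    mol_of: np.ndarray         # molecule id per selected bead (length n_a+n_b)
    cutoff: float
    bipartite: bool

    @property
    def n_selected(self) -> int:
        return self.n_a + (self.n_b if self.bipartite else 0)

    def matrix(self) -> sp.coo_matrix:
        n = self.n_selected
        if len(self.pairs) == 0:
            return sp.coo_matrix((n, n), dtype=bool)
        i, j = self.pairs.T
        data = np.ones(len(i) * 2, dtype=bool)
        return sp.coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))

    def block_nonempty(self, mol_index: dict[int, int], n_mol: int):
        """Oracle path: explicit block reduction of the full bead matrix."""
        m = self.matrix().tocoo()
        rows = np.array([mol_index[self.mol_of[i]] for i in m.row], dtype=int)
        cols = np.array([mol_index[self.mol_of[j]] for j in m.col], dtype=int)
        w = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(n_mol, n_mol)).tocsr()
        w.setdiag(0)
        w.eliminate_zeros()
        return w


@dataclass
class MolecularGraph:
    """Molecule-level adjacency with no self-loops."""

    n_nodes: int
    edges: np.ndarray          # (E, 2) node pairs, i < j
    weights: np.ndarray        # block edge counts, aligned with edges
    node_class: np.ndarray     # molecule class label per node
    time: float = 0.0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        if len(self.edges) == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        i, j = self.edges.T
        d = self.weights if weighted else np.ones(len(i))
        return sp.coo_matrix((np.r_[d, d], (np.r_[i, j], np.r_[j, i])),
                             shape=(self.n_nodes, self.n_nodes)).tocsr()

    def save_mtx(self, path, weighted: bool = False) -> None:
        """Write the adjacency as a MatrixMarket sparse matrix."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.adjacency(weighted=weighted))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from((int(a), int(b), {"weight": int(w)})
                         for (a, b), w in zip(self.edges, self.weights))
        return g


@dataclass
class DegreeDistribution:
    k: np.ndarray
    pk: np.ndarray
    sem: np.ndarray | None = None
    n_frames: int = 1

    @property
    def mean_degree(self) -> float:
        return float((self.k * self.pk).sum())

    @property
    def mode(self) -> int:
        return int(self.k[np.argmax(self.pk)])


# ---------------------------------------------------------------------------


def bead_adjacency(frame: Frame, set_a, set_b, r_cut: float,
                   topo: Topology | None = None) -> BeadAdjacency:
    """Contact pairs between two bead selections at minimum-image distance
    strictly below ``r_cut``.

    Selections must be disjoint (bipartite, only cross-set edges possible)
    or identical (unipartite atomic case, self-pairs excluded).
    """
    if r_cut <= 0:
        raise ValueError("cutoff must be positive")
    ia = np.asarray(set_a, dtype=np.int64)
    ib = np.asarray(set_b, dtype=np.int64)
    identical = ia.size == ib.size and np.array_equal(np.sort(ia), np.sort(ib))
    if not identical and np.intersect1d(ia, ib).size:
        raise ValueError("overlapping (non-identical) selections")
    box = frame.box
    if r_cut > 0.5 * box.min():
        raise ValueError("cutoff exceeds the minimum-image radius")
    pa = np.mod(frame.coords[ia], box)
    ta = cKDTree(pa, boxsize=box)
    if identical:
        cand = ta.query_pairs(r=r_cut, output_type="ndarray")
        if cand.size:
            d = pa[cand[:, 0]] - pa[cand[:, 1]]
            d -= box * np.round(d / box)
            keep = (d ** 2).sum(axis=1) < r_cut ** 2  # strict <
            cand = cand[keep]
        pairs = cand
        mol_of_sel = _mol_of(topo, ia)
    else:
        pb = np.mod(frame.coords[ib], box)
        tb = cKDTree(pb, boxsize=box)
        res = ta.query_ball_tree(tb, r=r_cut)
        ai, bj = [], []
        for i, lst in enumerate(res):
            for j in lst:
                ai.append(i)
                bj.append(j)
        pairs = np.array([ai, bj], dtype=np.int64).T.reshape(-1, 2)
        if pairs.size:
            d = pa[pairs[:, 0]] - pb[pairs[:, 1]]
            d -= box * np.round(d / box)
            keep = (d ** 2).sum(axis=1) < r_cut ** 2
            pairs = pairs[keep]
            pairs = pairs.copy()
            pairs[:, 1] += ia.size  # b-block offset
        mol_of_sel = np.concatenate([_mol_of(topo, ia), _mol_of(topo, ib)])
    return BeadAdjacency(pairs=pairs, n_a=ia.size, n_b=ib.size,
                         mol_of=mol_of_sel, cutoff=r_cut, bipartite=not identical)


def _mol_of(topo: Topology | None, idx: np.ndarray) -> np.ndarray:
    if topo is None:
        return idx.copy()  # atomic: each bead its own molecule
    return topo.mol_id[idx]


def molecular_adjacency(bead_adj: BeadAdjacency, time: float = 0.0,
                        node_class: np.ndarray | None = None,
                        ) -> MolecularGraph:
    """Block-summed molecule graph from a bead adjacency.

    Fast path: unique molecule-id pairs of the contact pairs.  The
    explicit block-reduction path (:meth:`BeadAdjacency.block_nonempty`)
    must give the identical graph and is kept as a cross-check.
    """
    mols = np.unique(bead_adj.mol_of)
    n_mol = mols.size
    mol_index = {int(m): i for i, m in enumerate(mols)}
    if node_class is None:
        node_class = np.array(["mol"] * n_mol, dtype=object)
    if len(bead_adj.pairs) == 0:
        return MolecularGraph(n_nodes=n_mol, edges=np.empty((0, 2), np.int64),
                              weights=np.empty(0, np.int64),
                              node_class=node_class, time=time)
    ma = bead_adj.mol_of[bead_adj.pairs[:, 0]]
    mb = bead_adj.mol_of[bead_adj.pairs[:, 1]]
    na = np.array([mol_index[int(m)] for m in ma])
    nb = np.array([mol_index[int(m)] for m in mb])
    lo, hi = np.minimum(na, nb), np.maximum(na, nb)
    off_diag = lo != hi  # no self-loops
    key = lo[off_diag] * n_mol + hi[off_diag]
    uniq, counts = np.unique(key, return_counts=True)
    edges = np.column_stack([uniq // n_mol, uniq % n_mol])
    return MolecularGraph(n_nodes=n_mol, edges=edges, weights=counts,
                          node_class=node_class, time=time)


def degree_distribution(graphs, node_class: str | None = None,
                        ) -> DegreeDistribution:
    """Frame-averaged degree distribution P(k).

    Per-frame degree histograms are normalized and then averaged over
    frames (histogram mean, not graph union).  ``node_class`` restricts
    the nodes whose degrees enter the histogram.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one graph")
    per_frame = []
    kmax = 0
    for g in graphs:
        deg = g.degrees()
        if node_class is not None:
            deg = deg[g.node_class == node_class]
        per_frame.append(deg)
        kmax = max(kmax, int(deg.max()) if deg.size else 0)
    k = np.arange(kmax + 1)
    hists = np.zeros((len(per_frame), kmax + 1))
    for fi, deg in enumerate(per_frame):
        h = np.bincount(deg, minlength=kmax + 1)
        hists[fi] = h / h.sum()
    pk = hists.mean(axis=0)
    return DegreeDistribution(k=k, pk=pk, n_frames=len(graphs))


def average_distributions(dists: list[DegreeDistribution]) -> DegreeDistribution:
    """Replicate average with SEM (uncertainty across independent runs)."""
    if len(dists) < 2:
        raise ValueError("need at least two replicates for a SEM")
    kmax = max(int(d.k.max()) for d in dists)
    mat = np.zeros((len(dists), kmax + 1))
    for i, d in enumerate(dists):
        mat[i, d.k] = d.pk
    return DegreeDistribution(k=np.arange(kmax + 1), pk=mat.mean(axis=0),
                              sem=mat.std(axis=0, ddof=1) / np.sqrt(len(dists)),
                              n_frames=sum(d.n_frames for d in dists))


@dataclass
class GraphPipelineResult:
    rdf: RDFResult
    cutoff: float
    graphs: list[MolecularGraph]
    degrees: DegreeDistribution


def graph_pipeline(traj: Trajectory, topo: Topology | None, set_a, set_b,
                   dr: float, r_max: float | None = None, frames=None,
                   cutoff: float | None = None, node_class=None,
                   smooth_window: int = 5) -> GraphPipelineResult:
    """g(r) -> first minimum -> per-frame adjacency -> degree distribution.

    The first-minimum failure of a structureless g(r) propagates as
    :class:`condnet.rdf.NoMinimumError`.
    """
    rdf_res = compute_rdf(traj, set_a, set_b, dr=dr, r_max=r_max, frames=frames)
    if cutoff is None:
        cutoff = first_minimum(rdf_res, smooth_window=smooth_window)
    frames_list = traj.frames if frames is None else (
        traj.frames[frames] if isinstance(frames, slice)
        else [traj.frames[i] for i in np.atleast_1d(frames)])
    graphs = []
    for fr in frames_list:
        ba = bead_adjacency(fr, set_a, set_b, cutoff, topo=topo)
        graphs.append(molecular_adjacency(ba, time=fr.time,
                                          node_class=node_class))
    return GraphPipelineResult(rdf=rdf_res, cutoff=cutoff, graphs=graphs,
                               degrees=degree_distribution(graphs))
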