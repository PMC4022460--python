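"""Mate-pair-constrained recursive spectral clustering of read vectors.

Reads are vertices of a 50-nearest-neighbor graph in standardized k-mer
feature space; edge weights decrease with Euclidean distance.  Mate-pair
relationships are overlaid as maximum-weight (1.0) edges, encoding the
physical linkage of the two ends of a clone insert.  The graph is split
recursively by the normalized-cut criterion (second generalized eigenvector
of (D-W)v = mu*Dv, followed by a sweep over thresholds), and a binary split
is accepted only when both daughter clusters retain a self-mate-pair (SMP)
frequency above a threshold (default 0.8) — the signature of reads drawn
from a contiguous satellite array longer than the clone insert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix


@dataclass
class ReadGraph:
    n: int
    weights: sp.csr_matrix  # symmetric combined weights (kNN, possibly pairs)
    pairs: np.ndarray  # (m, 2) vertex index pairs, may be empty
    k_nn: int
    d_max: float
    read_ids: list | None = None


@dataclass
class ClusterNode:
    members: np.ndarray
    smp: float | None = None
    split_accepted: bool = False
    children: list = field(default_factory=list)
    label: int | None = None
    ncut: float | None = None

    @property
    def is_leaf(self):
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class ClusterParams:
    smp_threshold: float = 0.8
    min_cluster_size: int | None = None  # default 2 * k_nn
    eig_tol: float = 1e-8
    sweep_max_thresholds: int = 512  # used when a node exceeds 10,000 vertices

    def __post_init__(self):
        if not 0 < self.smp_threshold <= 1:
            raise ValueError("smp_threshold must be in (0, 1]")


def build_knn_graph(fm: FeatureMatrix, k_nn: int = 50) -> ReadGraph:
    """Symmetric k-nearest-neighbor graph in the standardized feature space.

    Edge (i, j) exists iff j is among i's k_nn nearest neighbors (Euclidean)
    or vice versa.  Weights map distance d to ``1 - d/d_max`` (d_max = the
    largest kNN-edge distance), so weights lie in (0, 1] and mate-pair
    weight 1.0 is the maximum; the single farthest edge is floored at a
    tiny positive value instead of 0 to keep it present.
    """
    if fm.state != "standardized":
        raise ValueError("build_knn_graph requires a standardized matrix")
    n = fm.n_reads
    if n <= k_nn:
        raise ValueError("need more reads than k_nn")
    nn = NearestNeighbors(n_neighbors=k_nn + 1, algorithm="auto")
    nn.fit(fm.values)
    dist, idx = nn.kneighbors(fm.values)
    # drop self (always the nearest at distance 0, possibly tied)
    rows = np.repeat(np.arange(n), k_nn)
    cols, dists = [], []
    for i in range(n):
        neigh = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i][:k_nn]
        while len(neigh) < k_nn:  # duplicate points: self removed twice
            neigh.append(neigh[-1])
        cols.extend(j for _, j in neigh)
        dists.extend(d for d, _ in neigh)
    cols = np.array(cols)
    dists = np.array(dists, dtype=float)
    d_max = float(dists.max())
    if d_max == 0:
        w = np.ones_like(dists)
    else:
        w = 1.0 - dists / d_max
        w[w <= 0] = 1e-12
    m = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    sym = m.maximum(m.T)
    sym.setdiag(0)
    sym.eliminate_zeros()
    return ReadGraph(n, sym, np.empty((0, 2), dtype=int), k_nn, d_max, list(fm.read_ids))


def add_matepair_edges(graph: ReadGraph, pairs) -> ReadGraph:
    """Overlay mate-pair edges with maximum weight 1.0.

    ``pairs`` holds vertex index pairs or read-id pairs (resolved through
    ``graph.read_ids``); pairs with an end missing from the graph are
    skipped.  Duplicate rows collapse to a single edge.
    """
    index = None
    if graph.read_ids is not None:
        index = {rid: i for i, rid in enumerate(graph.read_ids)}
    resolved = set()
    for a, b in pairs:
        if index is not None and not (isinstance(a, (int, np.integer))):
            if a not in index or b not in index:
                continue
            a, b = index[a], index[b]
        a, b = int(a), int(b)
        if a == b or not (0 <= a < graph.n and 0 <= b < graph.n):
            continue
        resolved.add((min(a, b), max(a, b)))
    if not resolved:
        return ReadGraph(graph.n, graph.weights, np.empty((0, 2), dtype=int),
                         graph.k_nn, graph.d_max, graph.read_ids)
    arr = np.array(sorted(resolved), dtype=int)
    w = graph.weights.tolil(copy=True)
    for a, b in arr:
        w[a, b] = 1.0
        w[b, a] = 1.0
    return ReadGraph(graph.n, w.tocsr(), arr, graph.k_nn, graph.d_max, graph.read_ids)


def _fiedler_vector(w: sp.csr_matrix, tol: float) -> np.ndarray:
    """Second-smallest generalized eigenvector of (D - W)v = mu * D v."""
    n = w.shape[0]
    deg = np.asarray(w.sum(axis=1)).ravel()
    deg[deg == 0] = 1e-12
    dmh = sp.diags(1.0 / np.sqrt(deg))
    lsym = sp.eye(n) - dmh @ w @ dmh
    if n < 300:
        vals, vecs = np.linalg.eigh(lsym.toarray())
        u = vecs[:, 1]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        try:
            vals, vecs = sp.linalg.eigsh(
                lsym.tocsc(), k=2, sigma=-1e-5, which="LM", v0=v0, tol=tol
            )
        except Exception:
            vals, vecs = sp.linalg.eigsh(lsym, k=2, which="SA", v0=v0, tol=max(tol, 1e-6))
        order = np.argsort(vals)
        u = vecs[:, order[1]]
    v = np.asarray(dmh @ u).ravel()
    nz = np.nonzero(v)[0]
    if len(nz) and v[nz[0]] < 0:
        v = -v
    return v


def _sweep_ncut(w: sp.csr_matrix, order: np.ndarray, candidates: np.ndarray):
    """Normalized cut of every prefix split along ``order``.

    Returns the best candidate prefix length and its ncut, computed with an
    incremental cut/volume update in O(E).
    """
    n = w.shape[0]
    deg = np.asarray(w.sum(axis=1)).ravel()
    total_vol = deg.sum()
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    indptr, indices, data = w.indptr, w.indices, w.data
    cut = 0.0
    vol_a = 0.0
    best = (np.inf, None)
    cand = set(int(c) for c in candidates)
    moved = np.zeros(n, dtype=bool)
    for t in range(n - 1):
        v = order[t]
        row = slice(indptr[v], indptr[v + 1])
        w_to_a = data[row][moved[indices[row]]].sum()
        cut += deg[v] - 2.0 * w_to_a
        vol_a += deg[v]
        moved[v] = True
        if (t + 1) in cand:
            vol_b = total_vol - vol_a
            if vol_a > 0 and vol_b > 0:
                nc = cut / vol_a + cut / vol_b
                if nc < best[0]:
                    best = (nc, t + 1)
    return best


def spectral_bipartition(graph_or_w, params: ClusterParams = ClusterParams()):
    """Binary normalized-cut split of a weighted graph.

    Disconnected graphs split along components (ncut 0).  Otherwise the
    generalized Fiedler vector is swept over candidate thresholds (all n-1
    order statistics, or ``sweep_max_thresholds`` quantiles for nodes over
    10,000 vertices) and the minimum-ncut split is returned as
    ``(idx_a, idx_b, ncut)`` with both sides non-empty.
    """
    w = graph_or_w.weights if isinstance(graph_or_w, ReadGraph) else graph_or_w
    n = w.shape[0]
    if n < 2:
        raise ValueError("cannot bipartition fewer than 2 vertices")
    ncomp, labels = connected_components(w, directed=False)
    if ncomp > 1:
        a = np.nonzero(labels == 0)[0]
        b = np.nonzero(labels != 0)[0]
        return a, b, 0.0
    v = _fiedler_vector(w, params.eig_tol)
    order = np.argsort(v, kind="stable")
    if n - 1 <= params.sweep_max_thresholds or n <= 10000:
        candidates = np.arange(1, n)
    else:
        candidates = np.unique(
            np.linspace(1, n - 1, params.sweep_max_thresholds).astype(int)
        )
    nc, t = _sweep_ncut(w, order, candidates)
    if t is None:
        raise RuntimeError(f"sweep found no valid split (n={n})")
    a = np.sort(order[:t])
    b = np.sort(order[t:])
    return a, b, float(nc)


def self_mate_pair_frequency(members, pairs, other=None):
    """Fraction of mate pairs touching a cluster with both ends inside it.

    Without ``other``: (#pairs with both ends in the cluster) / (#pairs with
    at least one end in it).  With ``other``: the denominator is restricted
    to pairs whose second end lies in the cluster or in ``other`` — the
    (A->A)/(A->A + A->B) form used for pairwise cluster comparisons.
    Returns None when the denominator is zero.
    """
    mem = set(int(i) for i in members)
    oth = set(int(i) for i in other) if other is not None else None
    both = touch = 0
    for a, b in pairs:
        a, b = int(a), int(b)
        ina, inb = a in mem, b in mem
        if not (ina or inb):
            continue
        if ina and inb:
            both += 1
            touch += 1
        else:
            out_end = b if ina else a
            if oth is None or out_end in oth:
                touch += 1
    if touch == 0:
        return None
    return both / touch


def recursive_cluster(
    graph: ReadGraph, pairs=None, params: ClusterParams = ClusterParams()
) -> ClusterNode:
    """Recursive binary spectral clustering gated by self-mate-pair frequency.

    Each node is split by `spectral_bipartition`; the split is accepted only
    if both children reach at least ``min_cluster_size`` members and both
    have SMP above ``smp_threshold`` (computed against the sibling, i.e.
    over mate pairs internal to the parent).  Rejected splits make the node
    a leaf.  Leaves are labeled deterministically: by decreasing size, ties
    by smallest member index.
    """
    if pairs is None:
        pairs = graph.pairs
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    min_size = params.min_cluster_size
    if min_size is None:
        min_size = 2 * graph.k_nn
    root = ClusterNode(members=np.arange(graph.n))
    root.smp = self_mate_pair_frequency(root.members, pairs)
    stack = [root]
    while stack:
        node = stack.pop()
        m = node.members
        if len(m) < 2 * min_size or len(m) < 2:
            continue
        sub = graph.weights[m][:, m]
        try:
            ia, ib, nc = spectral_bipartition(sub, params)
        except Exception:
            continue
        a, b = m[ia], m[ib]
        if len(a) < min_size or len(b) < min_size:
            continue
        # restrict to pairs internal to this node, per the sibling-relative
        # (A->A)/(A->A + A->B) definition
        smp_a = self_mate_pair_frequency(a, pairs, other=b)
        smp_b = self_mate_pair_frequency(b, pairs, other=a)
        if smp_a is None or smp_b is None:
            continue
        if smp_a > params.smp_threshold and smp_b > params.smp_threshold:
            node.split_accepted = True
            node.ncut = nc
            ca = ClusterNode(members=a, smp=smp_a)
            cb = ClusterNode(members=b, smp=smp_b)
            node.children = [ca, cb]
            stack.extend([ca, cb])
    leaves = sorted(root.leaves(), key=lambda l: (-len(l.members), int(l.members.min())))
    for i, leaf in enumerate(leaves):
        leaf.label = i
    return root


def leaf_assignments(root: ClusterNode, n: int) -> np.ndarray:
    labels = np.full(n, -1, dtype=int)
    for leaf in root.leaves():
        labels[leaf.members] = leaf.label
    return labels


def pairwise_smp_matrix(root: ClusterNode, pairs) -> np.ndarray:
    """SMP of every ordered leaf pair: (A->A)/(A->A + A->B)."""
    leaves = sorted(root.leaves(), key=lambda l: l.label)
    k = len(leaves)
    out = np.full((k, k), np.nan)
    for i, la in enumerate(leaves):
        for j, lb in enumerate(leaves):
            if i == j:
                continue
            v = self_mate_pair_frequency(la.members, pairs, other=lb.members)
            out[i, j] = np.nan if v is None else v
    return out


def tree_to_json(root: ClusterNode, path=None):
    def conv(node):
        d = {
            "size": int(len(node.members)),
            "smp": None if node.smp is None else float(node.smp),
            "split_accepted": bool(node.split_accepted),
        }
        if node.is_leaf:
            d["label"] = int(node.label) if node.label is not None else None
        else:
            d["ncut"] = float(node.ncut)
            d["children"] = [conv(c) for c in node.children]
        return d

    obj = conv(root)
    if path:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    return obj
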