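"""kNN graph construction, normalized-cut bipartition, SMP-gated recursion."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from satkit import calibration, features, satgraph, simdata


def _fm(points):
    vals = np.asarray(points, dtype=float)
    return features.FeatureMatrix(
        [f"r{i}" for i in range(len(vals))], vals, k=5, state="standardized"
    )


def brute_force_ncut(w, members_a):
    """Independent ncut evaluation from the definition."""
    w = np.asarray(w.todense()) if sp.issparse(w) else np.asarray(w)
    n = w.shape[0]
    a = np.zeros(n, dtype=bool)
    a[list(members_a)] = True
    cut = w[a][:, ~a].sum()
    vol_a = w[a].sum()
    vol_b = w[~a].sum()
    return cut / vol_a + cut / vol_b


class TestKnnGraph:
    def test_three_points_on_a_line(self):
        fm = _fm([[0.0], [1.0], [3.0]])
        g = satgraph.build_knn_graph(fm, k_nn=1)
        w = g.weights.toarray()
        assert w[0, 1] > 0 and w[1, 2] > 0
        assert w[0, 2] == 0

    def test_identical_points_get_weight_one(self):
        fm = _fm([[1.0, 2.0]] * 5)
        g = satgraph.build_knn_graph(fm, k_nn=2)
        assert np.all(g.weights.data == 1.0)

    def test_weights_in_unit_interval(self, two_subfamily_features):
        g = satgraph.build_knn_graph(two_subfamily_features, k_nn=10)
        assert g.weights.data.min() > 0
        assert g.weights.data.max() <= 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            satgraph.build_knn_graph(_fm([[0.0], [1.0]]), k_nn=2)

    def test_matches_bruteforce_neighbors(self):
        """The indexed kNN graph equals a brute-force all-pairs scan."""
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((2000, 16))
        fm = _fm(pts)
        k = 10
        g = satgraph.build_knn_graph(fm, k_nn=k)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(len(pts)):
            for j in np.argsort(d[i], kind="stable")[:k]:
                expected.add((min(i, j), max(i, j)))
        got = {
            (min(i, j), max(i, j))
            for i, j in zip(*g.weights.nonzero())
        }
        assert got == expected


class TestMatePairEdges:
    def test_empty_pairs_unchanged(self, two_subfamily_features):
        g = satgraph.build_knn_graph(two_subfamily_features, k_nn=10)
        g2 = satgraph.add_matepair_edges(g, [])
        assert (g2.weights != g.weights).nnz == 0

    def test_cross_edge_present_with_max_weight(self):
        fm = _fm(np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 10]))
        g = satgraph.build_knn_graph(fm, k_nn=2)
        g2 = satgraph.add_matepair_edges(g, [(0, 9)])
        assert g2.weights[0, 9] == 1.0 and g2.weights[9, 0] == 1.0

    def test_duplicate_pairs_idempotent(self):
        fm = _fm(np.random.default_rng(0).standard_normal((8, 2)))
        g = satgraph.build_knn_graph(fm, k_nn=2)
        g2 = satgraph.add_matepair_edges(g, [(0, 5), (5, 0), (0, 5)])
        assert g2.pairs.shape == (1, 2)


class TestSpectralBipartition:
    def _clique_pair(self, n=20, bridge=0.01):
        w = np.zeros((2 * n, 2 * n))
        w[:n, :n] = 1.0
        w[n:, n:] = 1.0
        np.fill_diagonal(w, 0.0)
        w[n - 1, n] = w[n, n - 1] = bridge
        return sp.csr_matrix(w)

    def test_two_cliques_recovered(self):
        w = self._clique_pair()
        a, b, nc = satgraph.spectral_bipartition(w)
        groups = {frozenset(a.tolist()), frozenset(b.tolist())}
        assert groups == {frozenset(range(20)), frozenset(range(20, 40))}
        assert nc == pytest.approx(brute_force_ncut(w, range(20)))

    def test_disconnected_components_split_at_zero_cost(self):
        w = sp.block_diag([np.ones((3, 3)) - np.eye(3)] * 2).tocsr()
        a, b, nc = satgraph.spectral_bipartition(w)
        assert nc == 0.0
        assert len(a) + len(b) == 6 and len(a) > 0 and len(b) > 0

    def test_path_graph_split(self):
        # path v0-v1-v2-v3-v4, unit weights
        w = sp.lil_matrix((5, 5))
        for i in range(4):
            w[i, i + 1] = w[i + 1, i] = 1.0
        a, b, nc = satgraph.spectral_bipartition(w.tocsr())
        sizes = sorted([len(a), len(b)])
        assert sizes == [2, 3]
        best = min(
            brute_force_ncut(w.tocsr(), range(t)) for t in (1, 2, 3, 4)
        )
        assert nc == pytest.approx(best)

    @pytest.mark.parametrize("seed", range(6))
    def test_sweep_equals_bruteforce_on_small_graphs(self, seed):
        """On <=12-vertex graphs the chosen split attains the minimum ncut over
        every prefix of the eigenvector ordering (independent enumeration)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        # ensure connectivity with a weak ring
        for i in range(n):
            j = (i + 1) % n
            w[i, j] = max(w[i, j], 0.05)
            w[j, i] = w[i, j]
        ws = sp.csr_matrix(w)
        a, b, nc = satgraph.spectral_bipartition(ws)
        v = satgraph._fiedler_vector(ws, 1e-10)
        order = np.argsort(v, kind="stable")
        best = min(brute_force_ncut(ws, order[:t]) for t in range(1, n))
        assert nc == pytest.approx(best)
        assert nc == pytest.approx(brute_force_ncut(ws, a))


class TestSelfMatePair:
    def test_all_internal(self):
        assert satgraph.self_mate_pair_frequency([0, 1, 2], [(0, 1), (1, 2)]) == 1.0

    def test_eight_internal_two_crossing(self):
        pairs = [(i, i + 10) for i in range(8)] + [(0, 99), (1, 98)]
        members = list(range(20))
        assert satgraph.self_mate_pair_frequency(members, pairs) == pytest.approx(0.8)

    def test_zero_denominator_is_missing(self):
        assert satgraph.self_mate_pair_frequency([0, 1], [(5, 6)]) is None

    def test_restricted_denominator(self):
        # A->A = 2, A->B = 1, A->C = 3: against B only, smp = 2/3
        pairs = [(0, 1), (0, 2), (1, 10), (0, 20), (1, 21), (2, 22)]
        a, b = [0, 1, 2], [10, 11]
        assert satgraph.self_mate_pair_frequency(a, pairs, other=b) == pytest.approx(2 / 3)


@pytest.fixture(scope="module")
def clustered(two_subfamily_features_module):
    fm, pairs, truth = two_subfamily_features_module
    g = satgraph.build_knn_graph(fm, k_nn=50)
    g = satgraph.add_matepair_edges(g, pairs)
    tree = satgraph.recursive_cluster(g)
    return g, tree, truth


@pytest.fixture(scope="module")
def two_subfamily_features_module(two_subfamily_features, two_subfamily_masked, subfamily_truth):
    _, pairs = two_subfamily_masked
    return two_subfamily_features, pairs, subfamily_truth


class TestRecursiveCluster:
    def test_two_planted_subfamilies_recovered(self, clustered):
        g, tree, truth = clustered
        labels = satgraph.leaf_assignments(tree, g.n)
        assert len(tree.leaves()) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_leaves_partition_reads(self, clustered):
        g, tree, _ = clustered
        members = np.concatenate([l.members for l in tree.leaves()])
        assert sorted(members.tolist()) == list(range(g.n))

    def test_accepted_splits_have_high_smp(self, clustered):
        _, tree, _ = clustered

        def walk(node):
            if node.split_accepted:
                for c in node.children:
                    assert c.smp > 0.8
                    walk(c)

        walk(tree)

    def test_homogeneous_array_stays_single_leaf(self):
        """One contiguous array with dense internal pairing never splits."""
        units = {0: simdata.gen_subfamily_units(1, 1770, 0.3, seed=50)[0]}
        genome = simdata.build_genome(
            [("c", 25_000, 0, 150_000)], units, {"c": 200_000}, seed=50
        )
        cfg = simdata.SimConfig(seed=50, coverage=3.0, unpaired_frac=0.0)
        reads, pairs = simdata.sim_sanger_pairs(genome, cfg)
        from satkit import readprep

        annos = readprep.annotations_from_records(simdata.truth_annotations(genome, reads))
        masked = [
            readprep.preprocess_read(r, annos[r.read_id])
            for r in reads
            if r.read_id in annos
        ]
        acc, pairs = readprep.orient_and_dedupe([m for m in masked if m.accepted], pairs)
        fm = features.standardize_matrix(features.kmer_feature_matrix(acc, k=5))
        g = satgraph.build_knn_graph(fm, k_nn=50)
        g = satgraph.add_matepair_edges(g, pairs)
        tree = satgraph.recursive_cluster(g)
        assert len(tree.leaves()) == 1

    def test_four_subfamilies_hierarchy(self):
        """Four planted subfamilies -> four leaves through at least two levels
        of accepted splits, each with SMP above threshold."""
        units = dict(enumerate(simdata.gen_subfamily_units(4, 1770, 0.3, seed=51)))
        spec = [(f"chr{i}", 20_000, i, 130_000) for i in range(4)]
        lens = {f"chr{i}": 170_000 for i in range(4)}
        genome = simdata.build_genome(spec, units, lens, seed=51)
        reads, pairs = simdata.sim_sanger_pairs(
            genome, simdata.SimConfig(seed=51, coverage=3.0)
        )
        from satkit import readprep

        annos = readprep.annotations_from_records(simdata.truth_annotations(genome, reads))
        masked = [
            readprep.preprocess_read(r, annos[r.read_id])
            for r in reads
            if r.read_id in annos
        ]
        acc, pairs = readprep.orient_and_dedupe([m for m in masked if m.accepted], pairs)
        fm = features.standardize_matrix(features.kmer_feature_matrix(acc, k=5))
        g = satgraph.build_knn_graph(fm, k_nn=50)
        g = satgraph.add_matepair_edges(g, pairs)
        tree = satgraph.recursive_cluster(g)
        labels = satgraph.leaf_assignments(tree, g.n)
        truth = [genome.truth.read_origins[r][0] for r in fm.read_ids]
        assert len(tree.leaves()) == 4
        assert adjusted_rand_score(truth, labels) >= 0.99

        def depth(node):
            return 1 + max((depth(c) for c in node.children), default=0)

        assert depth(tree) >= 3  # root + two levels of splits


def test_smp_calibration_monotone_in_array_length():
    """SMP grows with array length toward 1 for a fixed insert distribution."""
    lengths = [20_000, 50_000, 100_000, 400_000]
    curve = calibration.smp_curve(lengths, seeds=(0, 1))
    assert all(np.diff(curve) > -0.01)
    assert curve[-1] > 0.95
    assert curve[-1] > curve[0]


def test_pairwise_smp_matrix(clustered):
    from satkit.satgraph import pairwise_smp_matrix

    g, tree, _ = clustered
    m = pairwise_smp_matrix(tree, g.pairs)
    k = len(tree.leaves())
    assert m.shape == (k, k)
    off = m[~np.eye(k, dtype=bool)]
    assert np.all((off[~np.isnan(off)] >= 0) & (off[~np.isnan(off)] <= 1))
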