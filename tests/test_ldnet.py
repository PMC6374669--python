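import numpy as np
import networkx as nx
import pytest

from ldcohorts.ld import LDEdgeList
from ldcohorts.ldnet import (
    LDNetworkClusters,
    NetworkConfig,
    build_cluster_tree,
    extract_outlier_clusters,
    lambda_scores,
)


def random_edges(rng, n_loci, density=0.25):
    iu = np.triu_indices(n_loci, 1)
    keep = rng.random(len(iu[0])) < density
    a, b = iu[0][keep], iu[1][keep]
    r2 = np.round(rng.random(len(a)), 3)
    ok = r2 >= 0.1
    return LDEdgeList(a=a[ok], b=b[ok], r2=r2[ok], n_loci=n_loci, min_r2_stored=0.1)


def edges_to_graph(edges, threshold):
    g = nx.Graph()
    g.add_nodes_from(np.unique(np.concatenate([edges.a, edges.b])))
    for a, b, r in zip(edges.a, edges.b, edges.r2):
        if r >= threshold:
            g.add_edge(int(a), int(b))
    return g


def test_forced_merge_order():
    """r2(a,b)=0.9, r2(a,c)=r2(b,c)=0.2: {a,b} first, then all three."""
    edges = LDEdgeList(
        a=np.array([0, 0, 1]),
        b=np.array([1, 2, 2]),
        r2=np.array([0.9, 0.2, 0.2]),
        n_loci=3,
        min_r2_stored=0.1,
    )
    tree = build_cluster_tree(edges)
    merges = sorted(
        ((nd.level, tuple(nd.members)) for nd in tree.merge_nodes()), reverse=True
    )
    assert merges == [(0.9, (0, 1)), (0.2, (0, 1, 2))]


def test_tree_matches_connected_components_oracle():
    """At every threshold, the maximal clusters of the merge forest equal the
    connected components of the thresholded LD graph (100 random instances,
    up to 30 loci)."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(4, 31))
        edges = random_edges(rng, n)
        if len(edges) == 0:
            continue
        tree = build_cluster_tree(edges)
        levels = np.unique(edges.r2)
        thresholds = np.concatenate([levels, (levels[:-1] + levels[1:]) / 2, [0.05]])
        for t in thresholds:
            ours = {frozenset(nd.members.tolist()) for nd in tree.clusters_at(t)}
            truth = {
                frozenset(c) for c in nx.connected_components(edges_to_graph(edges, t))
            }
            assert ours == truth


def test_tree_invariant_to_edge_input_order():
    rng = np.random.default_rng(5)
    edges = random_edges(rng, 20)
    perm = rng.permutation(len(edges))
    shuffled = LDEdgeList(
        a=edges.a[perm], b=edges.b[perm], r2=edges.r2[perm],
        n_loci=20, min_r2_stored=0.1,
    )
    t1 = build_cluster_tree(edges)
    t2 = build_cluster_tree(shuffled)
    assert t1.to_newick() == t2.to_newick()


def brute_force_lambda(tree, edges, stat=np.mean):
    """Recompute every lambda from explicit pair enumeration."""
    R = edges.dense()
    np.fill_diagonal(R, 0.0)
    universe = set(np.unique(np.concatenate([edges.a, edges.b])).tolist())
    out = {}
    for nd in tree.nodes:
        if nd.size < 2:
            out[nd.id] = 0.0
            continue
        mem = list(nd.members)
        within = [R[i, j] for k, i in enumerate(mem) for j in mem[k + 1 :]]
        if nd.parent is not None:
            others = [x for x in tree.nodes[nd.parent].members if x not in set(mem)]
        else:
            others = sorted(universe - set(mem))
        between = [R[i, j] for i in mem for j in others]
        s_b = stat(between) if between else 0.0
        out[nd.id] = max(0.0, nd.size * (stat(within) - s_b))
    return out


@pytest.mark.parametrize("stat_name,stat_fn", [("mean", np.mean), ("median", np.median)])
def test_lambda_matches_brute_force(stat_name, stat_fn):
    rng = np.random.default_rng(3)
    edges = random_edges(rng, 20, density=0.4)
    tree = lambda_scores(build_cluster_tree(edges), edges, stat=stat_name)
    expected = brute_force_lambda(tree, edges, stat=stat_fn)
    for nd in tree.nodes:
        assert nd.lam == pytest.approx(expected[nd.id], abs=1e-12)


def test_lambda_closed_form_clique():
    """A 5-locus r2=1 clique with every cross-pair at r2=0: lambda = 5 under
    either contrast statistic."""
    # clique 0..4 at 1.0; a disconnected pair 6-7 provides the background
    a = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 3, 6])
    b = np.array([1, 2, 3, 4, 2, 3, 4, 3, 4, 4, 7])
    r2 = np.array([1.0] * 10 + [0.2])
    edges = LDEdgeList(a=a, b=b, r2=r2, n_loci=8, min_r2_stored=0.1)
    for stat in ("mean", "median"):
        tree = lambda_scores(build_cluster_tree(edges), edges, stat=stat)
        clique = next(nd for nd in tree.nodes if nd.size == 5)
        assert clique.lam == pytest.approx(5 * (1.0 - 0.0))


def test_lambda_zero_when_no_contrast():
    a = np.array([0, 0, 1, 0, 1, 2])
    b = np.array([1, 2, 2, 3, 3, 3])
    r2 = np.array([0.8] * 6)  # uniform LD: no internal/external contrast
    edges = LDEdgeList(a=a, b=b, r2=r2, n_loci=4, min_r2_stored=0.1)
    tree = lambda_scores(build_cluster_tree(edges), edges)
    for nd in tree.merge_nodes():
        if nd.parent is not None:
            assert nd.lam == pytest.approx(0.0, abs=1e-12)


def clique_edges(members, r2_val, n_loci, extra=()):
    a, b, r = [], [], []
    for k, i in enumerate(members):
        for j in members[k + 1 :]:
            a.append(i), b.append(j), r.append(r2_val)
    for i, j, v in extra:
        a.append(i), b.append(j), r.append(v)
    return LDEdgeList(
        a=np.array(a), b=np.array(b), r2=np.array(r), n_loci=n_loci, min_r2_stored=0.1
    )


def test_single_clique_is_reported():
    edges = clique_edges(list(range(6)), 0.95, n_loci=10)  # 15 edges >= 10
    tree = lambda_scores(build_cluster_tree(edges), edges)
    found = extract_outlier_clusters(tree, NetworkConfig())
    assert len(found) == 1
    assert set(found[0].members) == set(range(6))
    assert found[0].label == "X"


def test_small_clique_fails_edge_minimum():
    edges = clique_edges([0, 1, 2, 3], 0.95, n_loci=8)  # 6 edges < 10
    tree = lambda_scores(build_cluster_tree(edges), edges)
    assert extract_outlier_clusters(tree, NetworkConfig()) == []


def test_outlier_count_monotone_in_e_min_and_phi():
    rng = np.random.default_rng(11)
    X_blocks = []
    edges = clique_edges(
        list(range(8)), 0.9, n_loci=40,
        extra=[(i, j, 0.3) for i in (10, 11, 12, 13, 14) for j in (15, 16, 17)],
    )
    tree = lambda_scores(build_cluster_tree(edges), edges)
    base = len(extract_outlier_clusters(tree, NetworkConfig(e_min=5, phi=1)))
    for e_min, phi in [(5, 2), (10, 1), (10, 2), (20, 4)]:
        n = len(extract_outlier_clusters(tree, NetworkConfig(e_min=e_min, phi=phi)))
        assert n <= base


def test_reported_clusters_disjoint_and_estimator_facade():
    rng = np.random.default_rng(21)
    blockA = rng.integers(0, 3, 120).astype(np.int8)
    blockB = rng.integers(0, 3, 120).astype(np.int8)
    X = np.concatenate(
        [
            np.tile(blockA[:, None], (1, 8)),
            np.tile(blockB[:, None], (1, 6)),
            rng.integers(0, 3, size=(120, 30)).astype(np.int8),
        ],
        axis=1,
    )
    est = LDNetworkClusters(e_min=10, phi=2).fit(X)
    labels = {c.label: set(c.members.tolist()) for c in est.clusters_}
    assert set(labels) == {"X", "A"}
    sets = list(labels.values())
    assert sets[0].isdisjoint(sets[1])
    assert {frozenset(s) for s in sets} == {
        frozenset(range(8)), frozenset(range(8, 14))
    }


def test_loners_excluded_and_newick_renders():
    edges = clique_edges([1, 2, 3], 0.9, n_loci=10)
    tree = build_cluster_tree(edges)
    members = set(np.concatenate([nd.members for nd in tree.nodes]).tolist())
    assert members == {1, 2, 3}  # loci without stored edges never appear
    nwk = tree.to_newick()
    assert nwk.count("L") == 3 and nwk.endswith(";")
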