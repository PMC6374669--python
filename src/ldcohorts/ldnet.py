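"""Linkage disequilibrium network analysis.

Loci are vertices and r² values are edges.  Sweeping the r² threshold downward
and merging connected clusters with union–find yields the single-linkage
dendrogram of the (sparse) r² similarity matrix; absent edges count as r² = 0.

Each cluster is scored when it loses its identity — i.e. when it is absorbed
into a larger cluster at some merge level, or, for a component that never
merges further, against the disconnected background:

    lambda = n * (median within-cluster r² - median cluster-to-merged r²)

where n is the cluster size and both medians run over *all* locus pairs
(absent edges as 0), clipped at 0.  Clusters whose lambda exceeds
``median(lambda) + phi * MAD(lambda)`` over all merge events, and that carry at
least ``e_min`` edges at their defining level, are outlier clusters; among
nested outliers the highest-lambda cluster per lineage is reported, so reported
clusters are mutually disjoint.  Labels follow the convention of naming the
highest-r² sizable cluster "X", then "A", "B", ... by descending defining r².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ld import LDEdgeList, pairwise_r2
from sklearn.base import BaseEstimator


@dataclass
class NetworkConfig:
    """Outlier-cluster extraction settings.

    e_min : minimum number of edges at a cluster's defining r² level for the
        cluster to be reportable (default 10).
    phi : multiplier on the MAD of the lambda distribution (default 2).
    r2_grid_step : threshold resolution used when reporting defining levels.
    min_loci : optional minimum cluster size for the headline report
        (the analysis of the beetle data kept clusters above 1% of loci).
    """

    e_min: int = 10
    phi: float = 2.0
    r2_grid_step: float = 0.01
    min_loci: int | None = None

    def __post_init__(self) -> None:
        if self.e_min < 1:
            raise ValueError("e_min must be >= 1")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not 0 < self.r2_grid_step <= 0.1:
            raise ValueError("r2_grid_step outside (0, 0.1]")


@dataclass
class ClusterNode:
    """One cluster in the merge forest.

    ``level`` is the r² at which the cluster attained its membership (leaves:
    infinity).  ``absorbed_at`` is the r² of the merge that dissolved it into a
    larger cluster (None for final roots).  ``lam`` and ``n_edges`` are filled
    by :func:`lambda_scores`.
    """

    id: int
    level: float
    members: np.ndarray
    children: tuple = ()
    absorbed_at: float | None = None
    parent: int | None = None
    lam: float | None = None
    n_edges: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Single-linkage merge forest over loci connected by stored edges."""

    nodes: list = field(default_factory=list)
    roots: list = field(default_factory=list)
    n_loci: int = 0

    def merge_nodes(self):
        return [nd for nd in self.nodes if not nd.is_leaf]

    def clusters_at(self, t: float):
        """Maximal clusters at threshold ``t``: components of the r² >= t graph."""
        out = []
        for nd in self.nodes:
            formed = nd.is_leaf or nd.level >= t
            dissolved = nd.absorbed_at is not None and nd.absorbed_at >= t
            if formed and not dissolved:
                out.append(nd)
        return out

    def to_newick(self) -> str:
        """Newick forest (one tree per component); heights are 1 - r² level."""

        def h(nd):
            return 0.0 if nd.is_leaf else 1.0 - nd.level

        def render(nd, parent_height):
            name = f"L{nd.members[0]}" if nd.is_leaf else f"N{nd.id}"
            bl = max(parent_height - h(nd), 0.0) if parent_height is not None else 0.0
            if nd.is_leaf:
                return f"{name}:{bl:.6g}"
            inner = ",".join(
                render(self.nodes[c], h(nd)) for c in nd.children
            )
            return f"({inner}){name}:{bl:.6g}"

        return ";\n".join(render(self.nodes[r], None) for r in self.roots) + ";"


@dataclass
class OutlierCluster:
    """A reported high-LD cluster ("cohort") of loci."""

    label: str
    members: np.ndarray
    level: float          # defining r² (formation level of the cluster)
    level_grid: float     # level rounded down to the reporting grid
    lam: float
    n_edges: int
    node_id: int

    @property
    def size(self) -> int:
        return len(self.members)

    def to_dict(self, locus_ids=None) -> dict:
        members = (
            [str(locus_ids[i]) for i in self.members]
            if locus_ids is not None
            else [int(i) for i in self.members]
        )
        return {
            "label": self.label,
            "size": self.size,
            "r2_level": self.level,
            "r2_level_grid": self.level_grid,
            "lambda": self.lam,
            "n_edges": self.n_edges,
            "members": members,
        }


def build_cluster_tree(edges: LDEdgeList) -> ClusterTree:
    """Union–find construction of the single-linkage forest.

    Edges are processed in descending r², ties broken by (a, b) locus index
    pair, so the result is invariant to edge input order.  Loci appearing in no
    stored edge are not part of the forest.
    """
    if len(edges) == 0:
        raise ValueError("edge list is empty")
    order = np.lexsort((edges.b, edges.a, -edges.r2))
    ea, eb, er = edges.a[order], edges.b[order], edges.r2[order]

    involved = np.unique(np.concatenate([ea, eb]))
    tree = ClusterTree(n_loci=edges.n_loci)
    node_of = {}  # union-find root locus -> current node id
    parent = {}   # union-find parent pointers

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for locus in involved:
        nid = len(tree.nodes)
        tree.nodes.append(
            ClusterNode(id=nid, level=np.inf, members=np.array([locus]))
        )
        parent[locus] = locus
        node_of[locus] = nid

    for a, b, r in zip(ea, eb, er):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        na, nb = tree.nodes[node_of[ra]], tree.nodes[node_of[rb]]
        nid = len(tree.nodes)
        merged = ClusterNode(
            id=nid,
            level=float(r),
            members=np.sort(np.concatenate([na.members, nb.members])),
            children=(na.id, nb.id),
        )
        tree.nodes.append(merged)
        for child in (na, nb):
            child.absorbed_at = float(r)
            child.parent = nid
        parent[rb] = ra
        node_of[ra] = nid

    tree.roots = [nd.id for nd in tree.nodes if nd.parent is None]
    return tree


_STATS = {"mean": np.mean, "median": np.median}


def _pair_stat(R: np.ndarray, rows: np.ndarray, cols: np.ndarray, stat) -> float:
    return float(stat(R[np.ix_(rows, cols)]))


def _within_stat(R: np.ndarray, members: np.ndarray, stat) -> float:
    sub = R[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(stat(sub[iu]))


def lambda_scores(
    tree: ClusterTree, edges: LDEdgeList, stat: str = "mean"
) -> ClusterTree:
    """Fill ``lam`` and ``n_edges`` for every cluster of size >= 2.

    The focal cluster C is compared, at the moment of its absorption, with the
    cluster M it merges into; final roots are compared with the disconnected
    remainder of the locus universe (all absent pairs, r² = 0).  Edge counts
    are within-cluster stored edges with r² strictly above the absorption
    level (all stored within-edges for roots).

    ``stat`` chooses the location statistic for the pairwise-r² contrast:
    ``"mean"`` (default) or ``"median"``.  The mean is the default because the
    median saturates on large tight blocks — while a block's internal pairs
    outnumber the pairs added by weakly linked hangers-on, the median contrast
    cannot see the dilution, and λ then grows with cluster size alone, which
    drags the per-lineage maximum onto straggler-inflated superclusters.
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {sorted(_STATS)}, got {stat!r}")
    loc = _STATS[stat]
    R = edges.dense()
    np.fill_diagonal(R, 0.0)
    all_involved = np.unique(np.concatenate([edges.a, edges.b]))
    in_universe = np.zeros(edges.n_loci, dtype=bool)
    in_universe[all_involved] = True

    member_mask = np.zeros(edges.n_loci, dtype=bool)
    for nd in tree.nodes:
        if nd.size < 2:
            nd.lam = 0.0
            nd.n_edges = 0
            continue
        within = _within_stat(R, nd.members, loc)
        member_mask[:] = False
        member_mask[nd.members] = True
        if nd.parent is not None:
            parent = tree.nodes[nd.parent]
            others = parent.members[~member_mask[parent.members]]
            absorb_level = nd.absorbed_at
        else:
            others = np.flatnonzero(in_universe & ~member_mask)
            absorb_level = 0.0
        between = _pair_stat(R, nd.members, others, loc) if len(others) else 0.0
        nd.lam = max(0.0, nd.size * (within - between))
        within = member_mask[edges.a] & member_mask[edges.b]
        nd.n_edges = int((within & (edges.r2 > absorb_level)).sum())
    return tree


def extract_outlier_clusters(
    tree: ClusterTree, cfg: NetworkConfig | None = None
) -> list[OutlierCluster]:
    """MAD-based outlier extraction over the lambda distribution.

    Candidates are all clusters of size >= 2 with computed lambda.  The outlier
    threshold is ``median(lambda) + phi * MAD(lambda)`` (MAD unscaled).  Among
    nested outliers the highest-lambda cluster per lineage wins, so the
    reported clusters are mutually disjoint.  Raising ``e_min`` or ``phi``
    never adds clusters.
    """
    cfg = cfg or NetworkConfig()
    candidates = [nd for nd in tree.nodes if nd.size >= 2]
    if not candidates:
        return []
    if any(nd.lam is None for nd in candidates):
        raise ValueError("lambda scores not computed; run lambda_scores first")
    lams = np.array([nd.lam for nd in candidates])
    med = float(np.median(lams))
    mad = float(np.median(np.abs(lams - med)))
    threshold = med + cfg.phi * mad

    passed = [
        nd
        for nd in candidates
        if nd.lam > threshold
        and nd.n_edges >= cfg.e_min
        and (cfg.min_loci is None or nd.size >= cfg.min_loci)
    ]
    # highest lambda per lineage: greedy accept, disjointness rejects nesting
    passed.sort(key=lambda nd: (-nd.lam, nd.id))
    taken = np.zeros(tree.n_loci, dtype=bool)
    accepted = []
    for nd in passed:
        if not taken[nd.members].any():
            accepted.append(nd)
            taken[nd.members] = True

    accepted.sort(key=lambda nd: (-nd.level, -nd.size))
    labels = ["X", "A", "B"] + [chr(c) for c in range(ord("C"), ord("W") + 1)]
    out = []
    for k, nd in enumerate(accepted):
        label = labels[k] if k < len(labels) else f"C{k}"
        grid = np.floor(nd.level / cfg.r2_grid_step) * cfg.r2_grid_step
        out.append(
            OutlierCluster(
                label=label,
                members=nd.members.copy(),
                level=nd.level,
                level_grid=float(round(grid, 10)),
                lam=nd.lam,
                n_edges=nd.n_edges,
                node_id=nd.id,
            )
        )
    return out


def clusters_to_json(clusters, locus_ids=None, **kwargs) -> str:
    return json.dumps([c.to_dict(locus_ids) for c in clusters], indent=2, **kwargs)


class LDNetworkClusters(BaseEstimator):
    """Estimator facade: dosages in, outlier LD clusters out.

    fit(X) computes pairwise r², builds the single-linkage forest, scores
    every merge with lambda, and extracts outlier clusters.  Fitted
    attributes: ``edges_``, ``tree_``, ``clusters_``, ``labels_`` (per-locus
    cluster label, '' for background loci).
    """

    def __init__(
        self,
        min_r2_stored: float = 0.1,
        e_min: int = 10,
        phi: float = 2.0,
        r2_grid_step: float = 0.01,
        min_loci: int | None = None,
        lambda_stat: str = "mean",
    ):
        self.min_r2_stored = min_r2_stored
        self.e_min = e_min
        self.phi = phi
        self.r2_grid_step = r2_grid_step
        self.min_loci = min_loci
        self.lambda_stat = lambda_stat

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.n_features_in_ = X.shape[1]
        self.edges_ = pairwise_r2(X, min_r2_stored=self.min_r2_stored)
        cfg = NetworkConfig(
            e_min=self.e_min,
            phi=self.phi,
            r2_grid_step=self.r2_grid_step,
            min_loci=self.min_loci,
        )
        self.tree_ = build_cluster_tree(self.edges_)
        lambda_scores(self.tree_, self.edges_, stat=self.lambda_stat)
        self.clusters_ = extract_outlier_clusters(self.tree_, cfg)
        labels = np.full(X.shape[1], "", dtype=object)
        for c in self.clusters_:
            labels[c.members] = c.label
        self.labels_ = labels
        return self
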