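"""Standard connectivity-network features used as classification
baselines, plus the global features correlated with the embedding axes.

All features operate on the binarized graph (an edge exists iff its
correlation survived the threshold), the baseline form of the standard
brain-connectivity toolbox measures. Fixed-length per-node feature
vectors require graphs built with per-ROI voxel selection so every
subject has the same node count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.preprocessing import StandardScaler

from .classify import ClassifierConfig, Metrics, _make_svm, detection_metrics
from .network import AttributedGraph, pearson_corr

__all__ = [
    "BaselineConfig",
    "degree_feature",
    "gtom",
    "clustering_coefficient",
    "local_efficiency",
    "rich_club_curve",
    "global_features",
    "feature_axis_correlation",
    "baseline_classify",
]


@dataclass
class BaselineConfig:
    gtom_steps: int = 5  # m-step neighborhood size for topological overlap
    rich_club_max_k: int = 0  # K: max degree over training nodes
    rich_club_k: int = 1  # single level used as a global feature
    pow_threshold: float = 0.85  # powTH for the high-power node fraction
    binarize: bool = True

    def __post_init__(self) -> None:
        if self.gtom_steps < 1:
            raise ValueError("gtom_steps must be >= 1")
        if self.rich_club_max_k < 0:
            raise ValueError("rich_club_max_k must be >= 0")


def _to_networkx(g: AttributedGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    a = g.adjacency(binarize=True)
    G.add_edges_from(zip(*np.nonzero(np.triu(a, 1))))
    return G


def degree_feature(g: AttributedGraph) -> np.ndarray:
    """Unweighted per-node degree: the number of neighbors. Distinct from
    the weighted degree inside node signatures."""
    return g.adjacency(binarize=True).sum(axis=1).astype(int)


def gtom(g: AttributedGraph, m: int = 5) -> np.ndarray:
    """Per-node generalized topological overlap at m steps (row mean of
    the pairwise GTOM-m matrix).

    N_m(i) is the set of nodes reachable from i by a path of length at
    most m, excluding i itself; the pairwise overlap is

        (|N_m(i) & N_m(j)| + a_ij) / (min(|N_m(i)|, |N_m(j)|) + 1 - a_ij).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    a = g.adjacency(binarize=True)
    n = a.shape[0]
    if n == 0:
        return np.array([])
    reach = np.linalg.matrix_power(a + np.eye(n), m) > 0
    np.fill_diagonal(reach, False)  # N_m(i) excludes i
    sizes = reach.sum(axis=1)
    overlap = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = int(np.count_nonzero(reach[i] & reach[j]))
            denom = min(sizes[i], sizes[j]) + 1 - a[i, j]
            overlap[i, j] = overlap[j, i] = (shared + a[i, j]) / denom
    if n == 1:
        return np.zeros(1)
    return overlap.sum(axis=1) / (n - 1)


def clustering_coefficient(g: AttributedGraph) -> np.ndarray:
    """Fraction of closed triangles around each node; degree < 2 gives 0."""
    G = _to_networkx(g)
    cc = nx.clustering(G)
    return np.array([cc[i] for i in range(g.n_nodes)])


def local_efficiency(g: AttributedGraph) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph (mean
    inverse shortest-path length among its neighbors); fewer than 2
    neighbors gives 0."""
    G = _to_networkx(g)
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = list(G.neighbors(i))
        if len(nbrs) >= 2:
            out[i] = nx.global_efficiency(G.subgraph(nbrs))
    return out


def rich_club_curve(g: AttributedGraph, K: int) -> np.ndarray:
    """Rich-club coefficient phi(k) for k = 0..K: the edge density of the
    subgraph induced by nodes of degree strictly greater than k; fewer
    than 2 such nodes encodes 0."""
    if K < 0:
        raise ValueError("K must be >= 0")
    a = g.adjacency(binarize=True)
    deg = a.sum(axis=1)
    phi = np.zeros(K + 1)
    for k in range(K + 1):
        rich = deg > k
        n_rich = int(rich.sum())
        if n_rich < 2:
            continue
        e_rich = a[np.ix_(rich, rich)].sum() / 2.0
        phi[k] = 2.0 * e_rich / (n_rich * (n_rich - 1))
    return phi


def global_features(
    g: AttributedGraph, cfg: BaselineConfig | None = None
) -> tuple[float, float, float, float]:
    """Per-subject scalars: edge density, global efficiency, rich-club
    coefficient at the configured k, and the fraction of nodes whose
    power exceeds powTH."""
    cfg = cfg or BaselineConfig()
    n = g.n_nodes
    a = g.adjacency(binarize=True)
    n_edges = a.sum() / 2.0
    density = 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    geff = nx.global_efficiency(_to_networkx(g)) if n > 1 else 0.0
    rc = float(rich_club_curve(g, cfg.rich_club_k)[cfg.rich_club_k])
    high = sum(nd.power > cfg.pow_threshold for nd in g.nodes) / n
    return (float(density), float(geff), rc, float(high))


def feature_axis_correlation(
    features: Sequence[float], coords: Sequence[float]
) -> float:
    """Pearson correlation of a per-subject global feature with one axis
    of the projected space."""
    features = np.asarray(features, float)
    coords = np.asarray(coords, float)
    if features.size != coords.size or features.size < 3:
        raise ValueError("need >= 3 paired values")
    return pearson_corr(features, coords)


def baseline_classify(
    feature_vectors: Sequence[Sequence[float]],
    labels: Sequence[str],
    protocol: str = "loocv",
    ccfg: ClassifierConfig | None = None,
    train_idx: Sequence[int] | None = None,
    test_idx: Sequence[int] | None = None,
) -> Metrics:
    """SVM classification straight on feature vectors, with the same
    kernel and protocols as the embedding pipeline."""
    ccfg = ccfg or ClassifierConfig()
    lengths = {len(v) for v in feature_vectors}
    if len(lengths) != 1:
        raise ValueError("ragged feature vectors; use per-ROI voxel selection")
    X = np.asarray(feature_vectors, float)
    y = np.asarray(list(labels))
    if protocol == "loocv":
        Xs = StandardScaler().fit_transform(X)
        pred = []
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            clf = _make_svm(ccfg).fit(Xs[keep], y[keep])
            pred.append(str(clf.predict(Xs[i : i + 1])[0]))
        return detection_metrics(pred, list(y))
    if protocol == "train_test":
        if train_idx is None or test_idx is None:
            raise ValueError("train_test protocol needs index sets")
        tr = np.asarray(train_idx, int)
        te = np.asarray(test_idx, int)
        scaler = StandardScaler().fit(X[tr])
        clf = _make_svm(ccfg).fit(scaler.transform(X[tr]), y[tr])
        pred = [str(p) for p in clf.predict(scaler.transform(X[te]))]
        return detection_metrics(pred, list(y[te]))
    raise ValueError(f"unknown protocol {protocol!r}")
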