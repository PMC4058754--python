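"""Assignment-based distance between attributed connectivity graphs.

Two graphs are compared by matching the nodes of the smaller graph onto
the larger one so that the total node-signature distance is minimal
(Hungarian / Munkres assignment); that minimal cost is the graph
distance. A node pair's distance is a weighted sum of five components,
each normalized to [0, 1]:

    d1  |degree difference| / max training degree
    d2  positional L1 gap of zero-padded descending neighbor-degree
        profiles, / (max degree * padded length)
    d3  |power difference| / max training power
    d4  as d2, with powers
    d5  sigmoid of the inter-node Euclidean distance in world mm

The default weights are W = (0.2, 0.1, 0.2, 0.1, 0.4): spatial mismatch
is penalized hardest, so nodes far apart in the brain rarely match.
Degree and power maxima come from the training graphs; values beyond
them are clamped so components never exceed 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import AttributedGraph, NodeSignature

__all__ = [
    "WeightVector",
    "NormalizationConstants",
    "GraphDistanceResult",
    "SpatialConfig",
    "training_constants",
    "spatial_component",
    "profile_distance",
    "node_distance",
    "node_cost_matrix",
    "solve_assignment",
    "graph_distance",
    "pairwise_distances",
    "write_distance_matrix",
    "read_distance_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.2, 0.1, 0.2, 0.1, 0.4)


@dataclass(frozen=True)
class WeightVector:
    """Weights of the five node-distance components, order
    (degree, neighbor degrees, power, neighbor powers, spatial)."""

    w: tuple[float, float, float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if len(self.w) != 5 or any(x < 0 for x in self.w):
            raise ValueError("need 5 nonnegative weights")

    @property
    def total(self) -> float:
        return float(sum(self.w))


@dataclass(frozen=True)
class SpatialConfig:
    """Parameters of the spatial sigmoid d5 = 1 / (1 + scale *
    exp(-dist/decay_mm)).

    ``scale`` = 300 and ``decay_mm`` = 4 keep d5 near zero for coincident
    nodes and push it toward 1 for nodes far apart. ``printed_variant``
    flips the exponent sign to the literal published formula, which
    *decreases* with distance and contradicts its own description; it is
    kept only for archaeology.
    """

    scale: float = 300.0
    decay_mm: float = 4.0
    printed_variant: bool = False


@dataclass(frozen=True)
class NormalizationConstants:
    """Maximum weighted degree and node power over every node of every
    training graph; they normalize d1-d4."""

    max_degree: float
    max_power: float


@dataclass
class GraphDistanceResult:
    total_cost: float
    assignment: list[tuple[int, int]]  # (row index, column index) pairs


def training_constants(graphs: Iterable[AttributedGraph]) -> NormalizationConstants:
    """Scan the training graphs for the largest weighted degree and node
    power. A zero maximum would zero out a distance component's
    denominator, so zeros are guarded by replacing them with 1 (the
    component then compares raw values, which are all 0 anyway unless the
    test set exceeds training — where clamping applies)."""
    max_deg = 0.0
    max_pow = 0.0
    n_nodes = 0
    for g in graphs:
        for sig in g.signatures.values():
            n_nodes += 1
            max_deg = max(max_deg, sig.degree)
            max_pow = max(max_pow, sig.power)
    if n_nodes == 0:
        raise ValueError("no nodes in training graphs")
    if max_deg == 0.0 and max_pow == 0.0:
        raise ValueError("degenerate training set: all degrees and powers zero")
    return NormalizationConstants(
        max_degree=max_deg if max_deg > 0 else 1.0,
        max_power=max_pow if max_pow > 0 else 1.0,
    )


def spatial_component(
    c1: np.ndarray, c2: np.ndarray, cfg: SpatialConfig | None = None
) -> float:
    """Sigmoid spatial penalty, strictly increasing in the Euclidean
    distance between the two coordinates: 1/(1+scale) at zero separation,
    approaching 1 far apart."""
    cfg = cfg or SpatialConfig()
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    if not math.isfinite(d):
        raise ValueError("non-finite coordinates")
    sign = 1.0 if cfg.printed_variant else -1.0
    return 1.0 / (1.0 + cfg.scale * math.exp(sign * d / cfg.decay_mm))


def profile_distance(a1: Sequence[float], a2: Sequence[float], max_val: float) -> float:
    """Positional L1 distance of two descending profiles.

    The shorter profile is zero-padded at the end to the common length L;
    the absolute positional differences are summed and divided by
    (max_val * L). Two empty profiles are at distance 0.
    """
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    L = max(a1.size, a2.size)
    if L == 0:
        return 0.0
    p1 = np.zeros(L)
    p2 = np.zeros(L)
    p1[: a1.size] = a1
    p2[: a2.size] = a2
    return float(min(1.0, np.abs(p1 - p2).sum() / (max_val * L)))


def node_distance(
    s1: NodeSignature,
    s2: NodeSignature,
    w: WeightVector | None = None,
    nc: NormalizationConstants | None = None,
    spatial: SpatialConfig | None = None,
) -> float:
    """Weighted sum of the five signature-difference components; each
    component is clamped to [0, 1] before weighting."""
    w = w or WeightVector()
    if nc is None:
        raise ValueError("normalization constants required")
    d1 = min(1.0, abs(s1.degree - s2.degree) / nc.max_degree)
    d2 = profile_distance(s1.neighbor_degrees, s2.neighbor_degrees, nc.max_degree)
    d3 = min(1.0, abs(s1.power - s2.power) / nc.max_power)
    d4 = profile_distance(s1.neighbor_powers, s2.neighbor_powers, nc.max_power)
    d5 = spatial_component(s1.coord, s2.coord, spatial)
    return float(np.dot(w.w, (d1, d2, d3, d4, d5)))


def node_cost_matrix(
    g1: AttributedGraph,
    g2: AttributedGraph,
    w: WeightVector | None = None,
    nc: NormalizationConstants | None = None,
    spatial: SpatialConfig | None = None,
) -> tuple[np.ndarray, AttributedGraph, AttributedGraph]:
    """Node-to-node cost matrix with rows indexed by the smaller graph
    (ties keep ``g1`` as rows). Returns (matrix, row_graph, col_graph)."""
    if g1.n_nodes == 0 or g2.n_nodes == 0:
        raise ValueError("cannot match an empty graph")
    row_g, col_g = (g1, g2) if g1.n_nodes <= g2.n_nodes else (g2, g1)
    c = np.empty((row_g.n_nodes, col_g.n_nodes))
    for i, ni in enumerate(row_g.nodes):
        si = row_g.signatures[ni.node_id]
        for j, nj in enumerate(col_g.nodes):
            c[i, j] = node_distance(si, col_g.signatures[nj.node_id], w, nc, spatial)
    return c, row_g, col_g


def solve_assignment(c: np.ndarray) -> GraphDistanceResult:
    """Minimum-cost injective assignment of rows to columns (Hungarian
    algorithm). Every row is matched; unmatched columns contribute
    nothing to the cost."""
    c = np.asarray(c, dtype=float)
    if c.ndim != 2:
        raise ValueError("cost matrix must be 2D")
    if c.shape[0] > c.shape[1]:
        raise ValueError("cost matrix must have rows <= cols; orient the caller")
    rows, cols = linear_sum_assignment(c)
    return GraphDistanceResult(
        total_cost=float(c[rows, cols].sum()),
        assignment=[(int(r), int(col)) for r, col in zip(rows, cols)],
    )


def graph_distance(
    g1: AttributedGraph,
    g2: AttributedGraph,
    w: WeightVector | None = None,
    nc: NormalizationConstants | None = None,
    spatial: SpatialConfig | None = None,
    normalize_by_nodes: bool = False,
) -> float:
    """Distance between two attributed graphs: the optimal total
    node-matching cost. Symmetric by construction. The raw cost is the
    distance; dividing by the matched node count is available but off by
    default."""
    c, row_g, _ = node_cost_matrix(g1, g2, w, nc, spatial)
    res = solve_assignment(c)
    if normalize_by_nodes:
        return res.total_cost / row_g.n_nodes
    return res.total_cost


def pairwise_distances(
    graphs: Sequence[AttributedGraph],
    w: WeightVector | None = None,
    nc: NormalizationConstants | None = None,
    spatial: SpatialConfig | None = None,
) -> np.ndarray:
    """Full symmetric inter-subject distance matrix.

    The diagonal is forced to 0 — the raw self-matching cost is N*w5/301
    rather than 0 because coincident nodes still pay the sigmoid floor,
    but a metric embedding needs zero self-dissimilarity; the raw value
    is logged once instead.
    """
    n = len(graphs)
    if n < 2:
        raise ValueError("need at least 2 graphs")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = graph_distance(graphs[i], graphs[j], w, nc, spatial)
    w_ = w or WeightVector()
    sp = spatial or SpatialConfig()
    floor = graphs[0].n_nodes * w_.w[4] / (1.0 + sp.scale)
    logger.debug("diagonal forced to 0 (raw self-cost of first graph: %.5f)", floor)
    return D


def write_distance_matrix(
    D: np.ndarray,
    subject_ids: Sequence[str],
    path,
    sidecar: dict | None = None,
) -> None:
    """Square TSV with subject ids as header row and column; provenance
    (weights, constants) goes to a JSON sidecar next to it."""
    import pandas as pd

    pd.DataFrame(D, index=list(subject_ids), columns=list(subject_ids)).to_csv(
        path, sep="\t"
    )
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def read_distance_matrix(path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
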