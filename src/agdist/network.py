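"""Construction of attributed functional connectivity graphs.

One subject's in-mask voxel time series become a graph whose nodes are
ROI-clustered high-power voxels and whose edges are thresholded positive
Pearson correlations between node mean series. Each node carries a
signature — weighted degree, sorted neighbor degrees, power, sorted
neighbor powers and mean world coordinate — consumed by the graph
distance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import RoiAtlas, VoxelSeriesSet

__all__ = [
    "NetworkConfig",
    "Node",
    "NodeSignature",
    "AttributedGraph",
    "voxel_power",
    "normalize_powers",
    "select_active_voxels",
    "pearson_corr",
    "build_graph",
    "compute_signature",
]

GRAPH_SCHEMA_VERSION = 1


@dataclass
class NetworkConfig:
    """Knobs of the network construction step.

    power_percentile
        Voxels ranked at or above this power percentile are kept (default
        98, i.e. the top 2% most active voxels).
    corr_threshold
        Edges with correlation below this value are discarded; only
        positive correlations ever form edges.
    roiwise_selection
        Apply the percentile cut inside each ROI separately instead of
        over the whole brain, which fixes the node count across subjects
        (needed by fixed-length baseline feature vectors).
    """

    power_percentile: float = 98.0
    corr_threshold: float = 0.5
    edge_sign: str = "positive"
    roiwise_selection: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.power_percentile < 100.0:
            raise ValueError("power_percentile must lie in (0, 100)")
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [0, 1]")
        if self.edge_sign != "positive":
            raise NotImplementedError(
                "only positive-correlation edges are supported"
            )


@dataclass
class Node:
    node_id: int
    roi_label: int
    member_voxels: list[int]
    mean_coord: np.ndarray  # world mm
    mean_series: np.ndarray | None
    power: float  # mean of members' normalized powers, in [0, 1]


@dataclass
class NodeSignature:
    """Local descriptor of one node.

    ``degree`` is the sum of incident edge weights (weighted degree);
    neighbor profiles are sorted descending so that profiles of different
    nodes compare positionally after zero padding.
    """

    degree: float
    neighbor_degrees: np.ndarray  # descending
    power: float
    neighbor_powers: np.ndarray  # descending
    coord: np.ndarray  # world mm


@dataclass
class AttributedGraph:
    subject_id: str
    nodes: list[Node]
    edges: list[tuple[int, int, float]]  # (node_id, node_id, weight), id pairs i < j
    signatures: dict[int, NodeSignature] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node {node_id} in graph {self.subject_id}")

    def neighbors(self, node_id: int) -> list[tuple[int, float]]:
        out = []
        for i, j, w in self.edges:
            if i == node_id:
                out.append((j, w))
            elif j == node_id:
                out.append((i, w))
        return out

    def adjacency(self, binarize: bool = False) -> np.ndarray:
        """Dense adjacency over nodes in list order."""
        index = {n.node_id: k for k, n in enumerate(self.nodes)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, w in self.edges:
            v = 1.0 if binarize else w
            a[index[i], index[j]] = v
            a[index[j], index[i]] = v
        return a

    def to_json(self) -> str:
        doc = {
            "schema_version": GRAPH_SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "roi_label": int(n.roi_label),
                    "coord_mm": [float(c) for c in n.mean_coord],
                    "power": float(n.power),
                    "n_member_voxels": len(n.member_voxels),
                }
                for n in self.nodes
            ],
            "edges": [[int(i), int(j), float(w)] for i, j, w in self.edges],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AttributedGraph":
        doc = json.loads(text)
        if doc.get("schema_version") != GRAPH_SCHEMA_VERSION:
            raise ValueError("unsupported graph schema version")
        nodes = [
            Node(
                node_id=d["node_id"],
                roi_label=d["roi_label"],
                member_voxels=[],
                mean_coord=np.asarray(d["coord_mm"], dtype=float),
                mean_series=None,
                power=float(d["power"]),
            )
            for d in doc["nodes"]
        ]
        g = cls(
            subject_id=doc["subject_id"],
            nodes=nodes,
            edges=[(int(i), int(j), float(w)) for i, j, w in doc["edges"]],
        )
        g.signatures = {n.node_id: compute_signature(g, n.node_id) for n in g.nodes}
        return g

    def edge_table(self) -> str:
        """Edge list as 3-column TSV text."""
        lines = ["node_a\tnode_b\tweight"]
        lines += [f"{i}\t{j}\t{w:.6f}" for i, j, w in self.edges]
        return "\n".join(lines) + "\n"


def voxel_power(series: np.ndarray) -> float:
    """Mean squared amplitude of a time series, the voxel activity proxy:
    P(T) = (1/n) sum t_i^2."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series has no power")
    return float(np.mean(series**2))


def normalize_powers(powers: np.ndarray) -> np.ndarray:
    """Min-max rescale per-voxel powers to [0, 1] over one subject's
    in-mask voxels; a constant input maps to all zeros."""
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("no voxels to normalize")
    lo, hi = powers.min(), powers.max()
    if hi == lo:
        return np.zeros_like(powers)
    return (powers - lo) / (hi - lo)


def select_active_voxels(norm_powers: np.ndarray, percentile: float = 98.0) -> np.ndarray:
    """Indices of voxels ranked at or above ``percentile`` by power.

    Nearest-rank rule: the top ceil((1 - p/100) * n) voxels are kept, and
    every voxel tied with the cutoff value is kept too.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    p = np.asarray(norm_powers, dtype=float)
    n = p.size
    # cushioned ceil: (100-98)/100*100 must give exactly 2, not ceil(2+eps)
    k = max(1, math.ceil((100.0 - percentile) * n / 100.0 - 1e-9))
    cutoff = np.sort(p)[n - k]
    return np.flatnonzero(p >= cutoff)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series.

    A zero-variance series makes the coefficient undefined; by convention
    this returns 0 (so such a pair never crosses an edge threshold) and
    warns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        warnings.warn("zero-variance series: correlation set to 0", stacklevel=2)
        return 0.0
    return float(np.clip((sx @ sy) / denom, -1.0, 1.0))


def _select_indices(vs: VoxelSeriesSet, norm: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    if vs.labels is None:
        raise ValueError("voxel set carries no atlas labels; pass an atlas "
                         "to extract_voxel_series")
    if not cfg.roiwise_selection:
        return select_active_voxels(norm, cfg.power_percentile)
    picked: list[np.ndarray] = []
    for lab in np.unique(vs.labels):
        if lab == 0:
            continue
        in_roi = np.flatnonzero(vs.labels == lab)
        local = select_active_voxels(norm[in_roi], cfg.power_percentile)
        picked.append(in_roi[local])
    return np.concatenate(picked) if picked else np.array([], dtype=int)


def build_graph(
    vs: VoxelSeriesSet,
    atlas: RoiAtlas | None = None,
    cfg: NetworkConfig | None = None,
    subject_id: str = "",
) -> AttributedGraph:
    """Build one subject's attributed connectivity graph.

    Steps: (1) power each voxel and min-max normalize; (2) keep voxels at
    or above the power percentile (whole-brain, or per ROI when
    ``cfg.roiwise_selection``); (3) cluster kept voxels by ROI label into
    nodes, each represented by the unweighted mean of its members' series,
    the mean world coordinate and the mean normalized power; (4) connect
    node pairs whose mean-series correlation reaches ``corr_threshold``
    (positive correlations only); (5) attach signatures.

    ROIs that received no selected voxel are absent, so node counts vary
    across subjects. Nodes left edgeless by the threshold are kept — their
    power and position still feed the graph distance.
    """
    cfg = cfg or NetworkConfig()
    if len(vs) == 0:
        raise ValueError("empty voxel set")
    if vs.labels is None and atlas is not None:
        raise ValueError("voxel set has no labels; re-extract with the atlas")

    powers = np.mean(np.asarray(vs.series, dtype=float) ** 2, axis=1)
    norm = normalize_powers(powers)
    selected = _select_indices(vs, norm, cfg)
    selected = selected[vs.labels[selected] > 0]
    if selected.size == 0:
        raise ValueError("empty network: no voxel survives power selection")

    nodes: list[Node] = []
    for node_id, lab in enumerate(np.unique(vs.labels[selected])):
        members = selected[vs.labels[selected] == lab]
        nodes.append(
            Node(
                node_id=node_id,
                roi_label=int(lab),
                member_voxels=[int(m) for m in sorted(members)],
                mean_coord=vs.coords_world[members].mean(axis=0),
                mean_series=vs.series[members].mean(axis=0),
                power=float(norm[members].mean()),
            )
        )

    edges: list[tuple[int, int, float]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                r = pearson_corr(nodes[a].mean_series, nodes[b].mean_series)
                if r >= cfg.corr_threshold and r > 0.0:
                    edges.append((nodes[a].node_id, nodes[b].node_id, r))

    g = AttributedGraph(subject_id=subject_id, nodes=nodes, edges=edges)
    g.signatures = {n.node_id: compute_signature(g, n.node_id) for n in g.nodes}
    return g


def rethreshold_graph(g: AttributedGraph, corr_threshold: float) -> AttributedGraph:
    """New graph keeping only edges at or above ``corr_threshold``.

    Node membership never depends on the threshold, so sweeping corrTh
    only needs the edges re-filtered and the signatures recomputed.
    """
    out = AttributedGraph(
        subject_id=g.subject_id,
        nodes=g.nodes,
        edges=[(i, j, w) for i, j, w in g.edges if w >= corr_threshold],
    )
    out.signatures = {n.node_id: compute_signature(out, n.node_id) for n in out.nodes}
    return out


def compute_signature(g: AttributedGraph, node_id: int) -> NodeSignature:
    """Signature of one node: weighted degree, descending neighbor degree
    and power profiles, own power and mean coordinate."""
    node = g.node(node_id)
    deg = {n.node_id: 0.0 for n in g.nodes}
    for i, j, w in g.edges:
        deg[i] += w
        deg[j] += w
    nbrs = [nid for nid, _ in g.neighbors(node_id)]
    nbr_deg = np.sort([deg[n] for n in nbrs])[::-1] if nbrs else np.array([])
    nbr_pow = (
        np.sort([g.node(n).power for n in nbrs])[::-1] if nbrs else np.array([])
    )
    return NodeSignature(
        degree=deg[node_id],
        neighbor_degrees=nbr_deg,
        power=node.power,
        neighbor_powers=nbr_pow,
        coord=np.asarray(node.mean_coord, dtype=float),
    )
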