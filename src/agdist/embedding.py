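"""Metric multidimensional scaling of the inter-subject distance matrix.

Subjects live in an unknown graph space; MDS places them in a
low-dimensional Euclidean space so that embedded distances reproduce the
graph distances as closely as possible under the metric stress

    stress(D, X) = sqrt( sum_{i<j} (D_ij - |x_i - x_j|)^2
                         / sum_{i<j} D_ij^2 ).

The minimization is SMACOF majorization started from the classical
(eigendecomposition) solution, so stress is non-increasing across
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["EmbeddingConfig", "Embedding", "stress", "classical_mds", "mds_embed"]


@dataclass
class EmbeddingConfig:
    n_dims: int = 2
    max_iter: int = 100_000
    seed: int = 0
    criterion: str = "metric_stress"
    rel_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if self.criterion != "metric_stress":
            raise NotImplementedError("only metric stress is supported")


@dataclass
class Embedding:
    coords: np.ndarray  # (n_subjects, n_dims)
    stress: float
    n_iter: int
    stress_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if (D < 0).any():
        raise ValueError("D must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("D must have a zero diagonal")
    return D


def stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Normalized metric stress of an embedding against the target
    dissimilarities. 0 means exact reproduction; collapsing every point
    onto one location gives 1."""
    D = _check_dissimilarity(D)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != D.shape[0]:
        raise ValueError("coords row count must match D")
    denom = float((squareform(D) ** 2).sum())
    if denom == 0.0:
        raise ValueError("all-zero dissimilarity matrix: stress undefined")
    d_emb = pdist(coords)
    num = float(((squareform(D) - d_emb) ** 2).sum())
    return float(np.sqrt(num / denom))


def classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson's classical scaling: eigendecomposition of the
    double-centered squared dissimilarities; negative eigenvalues are
    dropped and missing dimensions zero-padded."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(vals)
    if X.shape[1] < n_dims:
        X = np.hstack([X, np.zeros((n, n_dims - X.shape[1]))])
    return X


def mds_embed(D: np.ndarray, cfg: EmbeddingConfig | None = None) -> Embedding:
    """Embed a symmetric dissimilarity matrix by SMACOF majorization.

    Initialized from the classical solution (plus a tiny seeded jitter if
    that collapses), iterated with the Guttman transform until the
    relative stress change drops below ``rel_tol`` or ``max_iter`` is
    reached. Stress never increases between iterations.
    """
    cfg = cfg or EmbeddingConfig()
    D = _check_dissimilarity(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if float(D.sum()) == 0.0:
        raise ValueError("all-zero dissimilarity matrix")

    X = classical_mds(D, cfg.n_dims)
    if not np.any(np.abs(X) > 0):
        rng = np.random.default_rng(cfg.seed)
        X = rng.normal(scale=1e-6, size=(n, cfg.n_dims))

    trace = [stress(D, X)]
    for it in range(cfg.max_iter):
        # Guttman transform: X <- (1/n) B(X) X
        d = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / np.where(d > 0, d, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        s = stress(D, X)
        trace.append(s)
        prev = trace[-2]
        if prev - s < cfg.rel_tol * max(prev, 1e-300):
            break
    return Embedding(
        coords=X, stress=trace[-1], n_iter=len(trace) - 1, stress_trace=np.array(trace)
    )
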