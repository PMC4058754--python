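"""Model / Results facade over the pipeline.

``GraphClassificationModel`` bundles a cohort's inter-subject distance
matrix with its diagnosis labels; ``fit()`` runs the embedding and the
chosen evaluation protocol and returns a results object carrying the
detection metrics, their binomial uncertainty, the embedding diagnostics
and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import ClassifierConfig, Metrics, classify_loocv, classify_train_test
from .distance import (
    NormalizationConstants,
    SpatialConfig,
    WeightVector,
    pairwise_distances,
    training_constants,
)
from .embedding import Embedding, EmbeddingConfig, mds_embed
from .network import AttributedGraph

__all__ = ["GraphClassificationModel", "GraphClassificationResults"]


def _wilson_interval(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 100.0)
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (100.0 * max(0.0, center - half), 100.0 * min(1.0, center + half))


class GraphClassificationModel:
    """Classify subjects from their pairwise graph-distance matrix.

    Parameters
    ----------
    D : (n, n) array
        Symmetric inter-subject distances with zero diagonal.
    labels : sequence of {"control", "case"}
    subject_ids : optional sequence of ids for reporting.
    split : optional sequence of {"train", "test"}; required for the
        train/test protocol.
    """

    def __init__(
        self,
        D: np.ndarray,
        labels: Sequence[str],
        subject_ids: Sequence[str] | None = None,
        split: Sequence[str] | None = None,
        embedding_config: EmbeddingConfig | None = None,
        classifier_config: ClassifierConfig | None = None,
    ):
        self.D = np.asarray(D, float)
        self.labels = list(labels)
        if self.D.shape[0] != len(self.labels):
            raise ValueError("distance matrix and labels disagree in length")
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else [f"S{i:03d}" for i in range(len(self.labels))]
        )
        self.split = list(split) if split is not None else ["train"] * len(self.labels)
        self.embedding_config = embedding_config or EmbeddingConfig()
        self.classifier_config = classifier_config or ClassifierConfig()

    @classmethod
    def from_graphs(
        cls,
        graphs: Sequence[AttributedGraph],
        labels: Sequence[str],
        weights: WeightVector | None = None,
        constants: NormalizationConstants | None = None,
        spatial: SpatialConfig | None = None,
        **kwargs,
    ) -> "GraphClassificationModel":
        """Build the model straight from attributed graphs; normalization
        constants default to the maxima over the given graphs (treat them
        as the training set)."""
        nc = constants or training_constants(graphs)
        D = pairwise_distances(list(graphs), weights, nc, spatial)
        return cls(
            D,
            labels,
            subject_ids=[g.subject_id for g in graphs],
            **kwargs,
        )

    def fit(self, method: str = "loocv") -> "GraphClassificationResults":
        """Embed and classify.

        method "loocv" scores every subject by leave-one-out; method
        "train_test" fits on the train split and scores the test split
        through a joint embedding.
        """
        emb = mds_embed(self.D, self.embedding_config)
        if method == "loocv":
            metrics = classify_loocv(
                self.D, self.labels, self.embedding_config, self.classifier_config
            )
            scored = self.labels
        elif method == "train_test":
            tr = [i for i, s in enumerate(self.split) if s == "train"]
            te = [i for i, s in enumerate(self.split) if s == "test"]
            if not te:
                raise ValueError("no test subjects in split")
            metrics = classify_train_test(
                self.D,
                tr,
                te,
                [self.labels[i] for i in tr],
                [self.labels[i] for i in te],
                self.embedding_config,
                self.classifier_config,
            )
            scored = [self.labels[i] for i in te]
        else:
            raise ValueError(f"unknown method {method!r}")
        return GraphClassificationResults(
            model=self, method=method, metrics=metrics, embedding=emb,
            n_scored=len(scored),
        )


@dataclass
class GraphClassificationResults:
    model: GraphClassificationModel
    method: str
    metrics: Metrics
    embedding: Embedding
    n_scored: int

    @property
    def detection_rate(self) -> float:
        return self.metrics.detection_rate

    @property
    def detection_rate_ci(self) -> tuple[float, float]:
        """95% Wilson interval of the detection rate."""
        correct = round(self.metrics.detection_rate / 100.0 * self.metrics.n)
        return _wilson_interval(correct, self.metrics.n)

    def summary(self) -> str:
        lo, hi = self.detection_rate_ci
        lines = [
            "Graph classification results",
            "=" * 46,
            f"protocol            {self.method}",
            f"subjects scored     {self.n_scored}",
            f"embedding dims      {self.embedding.coords.shape[1]}",
            f"embedding stress    {self.embedding.stress:.6f}",
            f"detection rate      {self.metrics.detection_rate:.2f}%"
            f"  (95% CI {lo:.2f}-{hi:.2f})",
            f"specificity         {self.metrics.specificity:.2f}%",
            f"sensitivity         {self.metrics.sensitivity:.2f}%",
            f"degenerate          {self.metrics.degenerate}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_embedding(self, ax=None):
        """Scatter of subjects in the projected space, colored by label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.embedding.coords
        for lab, marker in (("control", "o"), ("case", "x")):
            sel = [i for i, l in enumerate(self.model.labels) if l == lab]
            ax.scatter(xy[sel, 0], xy[sel, 1], marker=marker, label=lab)
        ax.set_xlabel("axis 1")
        ax.set_ylabel("axis 2")
        ax.legend()
        return ax
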