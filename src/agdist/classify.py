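"""Subject classification in the MDS-projected space, and the full
site-by-site evaluation protocol.

Training cohorts are scored by leave-one-out cross-validation on their
own distance matrix; test cohorts are embedded jointly with their
training cohort (transductive MDS — labels never touch the embedding)
and predicted by an SVM fitted on the training coordinates. Networks are
rebuilt over a grid of correlation thresholds; the threshold with the
best (non-degenerate) training detection rate is carried to the test
split. Runs where specificity or sensitivity is exactly zero — the SVM
collapsed onto one class — are flagged degenerate and never win the
threshold selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .distance import (
    NormalizationConstants,
    SpatialConfig,
    WeightVector,
    pairwise_distances,
    training_constants,
)
from .embedding import Embedding, EmbeddingConfig, mds_embed
from .io import SubjectRecord, VoxelSeriesSet
from .network import AttributedGraph, NetworkConfig, build_graph, rethreshold_graph

__all__ = [
    "ClassifierConfig",
    "Metrics",
    "SweepRow",
    "EvaluationReport",
    "DEFAULT_CORRTH_GRID",
    "detection_metrics",
    "classify_loocv",
    "classify_train_test",
    "threshold_sweep",
    "weighted_average_rates",
]

logger = logging.getLogger(__name__)

DEFAULT_CORRTH_GRID: tuple[float, ...] = (0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

CONTROL, CASE = "control", "case"


@dataclass
class ClassifierConfig:
    """Polynomial-kernel SVM settings. Degree 3 and unit regularization
    follow the reference implementation's documented defaults; the kernel
    is (x.y + 1)^degree on standardized coordinates."""

    kernel: str = "polynomial"
    poly_degree: int = 3
    regularization: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel != "polynomial":
            raise NotImplementedError("only the polynomial kernel is supported")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass
class Metrics:
    detection_rate: float  # percent
    specificity: float  # percent, accuracy on controls
    sensitivity: float  # percent, accuracy on cases
    n: int

    @property
    def degenerate(self) -> bool:
        return self.specificity == 0.0 or self.sensitivity == 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.detection_rate, self.specificity, self.sensitivity)


def detection_metrics(
    predicted: Sequence[str], truth: Sequence[str]
) -> Metrics:
    """Overall detection rate, specificity (accuracy on controls) and
    sensitivity (accuracy on cases), all in percent."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    if not truth:
        raise ValueError("empty input")
    for lab in (*predicted, *truth):
        if lab not in (CONTROL, CASE):
            raise ValueError(f"unknown label {lab!r}")
    correct = [p == t for p, t in zip(predicted, truth)]
    n_ctrl = truth.count(CONTROL)
    n_case = truth.count(CASE)
    spec = (
        100.0 * sum(c for c, t in zip(correct, truth) if t == CONTROL) / n_ctrl
        if n_ctrl
        else 0.0
    )
    sens = (
        100.0 * sum(c for c, t in zip(correct, truth) if t == CASE) / n_case
        if n_case
        else 0.0
    )
    return Metrics(
        detection_rate=100.0 * sum(correct) / len(truth),
        specificity=spec,
        sensitivity=sens,
        n=len(truth),
    )


def _make_svm(ccfg: ClassifierConfig) -> SVC:
    return SVC(
        kernel="poly",
        degree=ccfg.poly_degree,
        C=ccfg.regularization,
        gamma=1.0,
        coef0=1.0,
    )


def classify_loocv(
    D_train: np.ndarray,
    labels: Sequence[str],
    ecfg: EmbeddingConfig | None = None,
    ccfg: ClassifierConfig | None = None,
) -> Metrics:
    """Leave-one-out cross-validation on one cohort.

    The embedding is computed once from the label-free distance matrix
    (so holding a subject out of the SVM leaks nothing); each fold
    refits the SVM without the held-out subject and predicts it.
    """
    ecfg = ecfg or EmbeddingConfig()
    ccfg = ccfg or ClassifierConfig()
    labels = list(labels)
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError("LOOCV needs both classes present")
    if min(labels.count(c) for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    emb = mds_embed(np.asarray(D_train, float), ecfg)
    X = StandardScaler().fit_transform(emb.coords)
    y = np.asarray(labels)
    n = len(y)
    pred = []
    for i in range(n):
        keep = np.arange(n) != i
        clf = _make_svm(ccfg).fit(X[keep], y[keep])
        pred.append(str(clf.predict(X[i : i + 1])[0]))
    return detection_metrics(pred, labels)


def classify_train_test(
    D_joint: np.ndarray,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    labels_train: Sequence[str],
    labels_test: Sequence[str],
    ecfg: EmbeddingConfig | None = None,
    ccfg: ClassifierConfig | None = None,
) -> Metrics:
    """Train-on-train / test-on-test protocol with a joint (transductive)
    embedding: MDS sees the full train+test distance matrix (no labels),
    the SVM sees only training coordinates."""
    ecfg = ecfg or EmbeddingConfig()
    ccfg = ccfg or ClassifierConfig()
    train_idx = np.asarray(train_idx, int)
    test_idx = np.asarray(test_idx, int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    n = np.asarray(D_joint).shape[0]
    if len(train_idx) + len(test_idx) != n:
        raise ValueError("index sets must cover the joint matrix")
    emb = mds_embed(np.asarray(D_joint, float), ecfg)
    scaler = StandardScaler().fit(emb.coords[train_idx])
    Xtr = scaler.transform(emb.coords[train_idx])
    Xte = scaler.transform(emb.coords[test_idx])
    clf = _make_svm(ccfg).fit(Xtr, list(labels_train))
    pred = [str(p) for p in clf.predict(Xte)]
    return detection_metrics(pred, list(labels_test))


def weighted_average_rates(
    rates: Sequence[float], counts: Sequence[int]
) -> float:
    """Subject-count-weighted mean of per-site percentage rates."""
    rates = np.asarray(rates, float)
    counts = np.asarray(counts, float)
    if rates.shape != counts.shape:
        raise ValueError("rates and counts differ in length")
    if rates.size == 0 or (counts <= 0).any():
        raise ValueError("counts must be positive and nonempty")
    return float((rates * counts).sum() / counts.sum())


@dataclass
class SweepRow:
    site: str
    group: str  # "all" | "male" | "female"
    split: str  # "train" | "test"
    corr_threshold: float
    metrics: Metrics
    degenerate: bool


@dataclass
class EvaluationReport:
    """Outcome of the correlation-threshold sweep: every (site, group,
    corrTh) training cell, the chosen threshold per site and group, the
    test-split metrics at that threshold, and subject-weighted averages
    across sites."""

    rows: list[SweepRow] = field(default_factory=list)
    chosen_corrth: dict[tuple[str, str], float] = field(default_factory=dict)
    best_train: dict[tuple[str, str], Metrics] = field(default_factory=dict)
    test_results: dict[tuple[str, str], Metrics] = field(default_factory=dict)
    averages: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def m(x: Metrics) -> dict:
            return {
                "detection_rate": x.detection_rate,
                "specificity": x.specificity,
                "sensitivity": x.sensitivity,
                "n": x.n,
            }

        return {
            "rows": [
                {
                    "site": r.site,
                    "group": r.group,
                    "split": r.split,
                    "corr_threshold": r.corr_threshold,
                    "degenerate": r.degenerate,
                    **m(r.metrics),
                }
                for r in self.rows
            ],
            "chosen_corrth": {f"{s}/{g}": v for (s, g), v in self.chosen_corrth.items()},
            "best_train": {f"{s}/{g}": m(v) for (s, g), v in self.best_train.items()},
            "test_results": {f"{s}/{g}": m(v) for (s, g), v in self.test_results.items()},
            "averages": dict(self.averages),
        }


def _build_base_graphs(
    subjects: Sequence[tuple[VoxelSeriesSet, SubjectRecord]],
    cfg: NetworkConfig,
) -> dict[str, AttributedGraph]:
    """Graphs at threshold 0 — node membership does not depend on corrTh,
    so per-threshold graphs are re-derived by dropping edges."""
    base_cfg = NetworkConfig(
        power_percentile=cfg.power_percentile,
        corr_threshold=0.0,
        roiwise_selection=cfg.roiwise_selection,
    )
    return {
        rec.subject_id: build_graph(vs, cfg=base_cfg, subject_id=rec.subject_id)
        for vs, rec in subjects
    }


def _members(records, site, split, group):
    out = []
    for rec in records:
        if rec.site != site or rec.split != split:
            continue
        if group != "all" and rec.sex != group:
            continue
        out.append(rec)
    return out


def threshold_sweep(
    subjects: Sequence[tuple[VoxelSeriesSet, SubjectRecord]],
    corrth_grid: Sequence[float] = DEFAULT_CORRTH_GRID,
    stratify_by_sex: bool = False,
    net_cfg: NetworkConfig | None = None,
    weights: WeightVector | None = None,
    spatial: SpatialConfig | None = None,
    ecfg: EmbeddingConfig | None = None,
    ccfg: ClassifierConfig | None = None,
) -> EvaluationReport:
    """Run the full per-site protocol over a correlation-threshold grid.

    For every site and group (all subjects, or male / female separately),
    networks are rebuilt at each threshold and scored by LOOCV on the
    training split; the best non-degenerate training threshold is then
    applied to the test split through a joint embedding. Sex-stratified
    results are additionally pooled into one subject-weighted rate per
    site, and across-site subject-weighted averages are reported.
    Groups with fewer than 4 subjects are skipped with a warning.
    """
    if len(corrth_grid) == 0:
        raise ValueError("empty corrTh grid")
    net_cfg = net_cfg or NetworkConfig()
    ecfg = ecfg or EmbeddingConfig()
    ccfg = ccfg or ClassifierConfig()

    records = [rec for _, rec in subjects]
    base = _build_base_graphs(subjects, net_cfg)
    sites = sorted({r.site for r in records})
    groups = ("male", "female") if stratify_by_sex else ("all",)
    report = EvaluationReport()

    for site in sites:
        for th in corrth_grid:
            graphs_th = {
                r.subject_id: rethreshold_graph(base[r.subject_id], th)
                for r in records
                if r.site == site
            }
            train_site = _members(records, site, "train", "all")
            nc = training_constants([graphs_th[r.subject_id] for r in train_site])
            for group in groups:
                train = _members(records, site, "train", group)
                if len(train) < 4:
                    warnings.warn(
                        f"skipping {site}/{group}: only {len(train)} training subjects"
                    )
                    continue
                labels = [r.label for r in train]
                if len(set(labels)) < 2 or min(
                    labels.count(c) for c in set(labels)
                ) < 2:
                    warnings.warn(f"skipping {site}/{group}: class too small")
                    continue
                D = pairwise_distances(
                    [graphs_th[r.subject_id] for r in train], weights, nc, spatial
                )
                met = classify_loocv(D, labels, ecfg, ccfg)
                report.rows.append(
                    SweepRow(site, group, "train", th, met, met.degenerate)
                )

        # pick the best non-degenerate training threshold per group
        for group in groups:
            cells = [
                r for r in report.rows
                if r.site == site and r.group == group and r.split == "train"
            ]
            if not cells:
                continue
            usable = [r for r in cells if not r.degenerate] or cells
            best = max(usable, key=lambda r: (r.metrics.detection_rate, -r.corr_threshold))
            report.chosen_corrth[(site, group)] = best.corr_threshold
            report.best_train[(site, group)] = best.metrics

            test = _members(records, site, "test", group)
            train = _members(records, site, "train", group)
            if not test:
                continue
            th = best.corr_threshold
            graphs_th = {
                r.subject_id: rethreshold_graph(base[r.subject_id], th)
                for r in train + test
            }
            nc = training_constants([graphs_th[r.subject_id] for r in train])
            pool = train + test
            D = pairwise_distances(
                [graphs_th[r.subject_id] for r in pool], weights, nc, spatial
            )
            tr_idx = list(range(len(train)))
            te_idx = list(range(len(train), len(pool)))
            met = classify_train_test(
                D, tr_idx, te_idx,
                [r.label for r in train], [r.label for r in test], ecfg, ccfg,
            )
            report.test_results[(site, group)] = met
            report.rows.append(SweepRow(site, group, "test", th, met, met.degenerate))

    _fill_averages(report, stratify_by_sex)
    return report


def _fill_averages(report: EvaluationReport, stratified: bool) -> None:
    for split, source in (("train", report.best_train), ("test", report.test_results)):
        if stratified:
            # pool male+female per site (subject-weighted), then across sites
            site_rates: dict[str, tuple[float, int]] = {}
            per_site: dict[str, list[Metrics]] = {}
            for (site, group), met in source.items():
                per_site.setdefault(site, []).append(met)
            for site, mets in per_site.items():
                rate = weighted_average_rates(
                    [m.detection_rate for m in mets], [m.n for m in mets]
                )
                site_rates[site] = (rate, sum(m.n for m in mets))
        else:
            site_rates = {
                site: (met.detection_rate, met.n)
                for (site, group), met in source.items()
                if group == "all"
            }
        if site_rates:
            rates = [v[0] for v in site_rates.values()]
            counts = [v[1] for v in site_rates.values()]
            key = f"{split}_{'mf' if stratified else 'all'}"
            report.averages[key] = weighted_average_rates(rates, counts)
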