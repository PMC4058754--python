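import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from agdist import (
    DEFAULT_CORRTH_GRID,
    EmbeddingConfig,
    classify_loocv,
    classify_train_test,
    detection_metrics,
    threshold_sweep,
    weighted_average_rates,
)


def cluster_distance_matrix(rng, n_per_class, separation=10.0, spread=0.3):
    """Euclidean distances of two planted 2D clusters; labels attached."""
    a = rng.normal(scale=spread, size=(n_per_class, 2))
    b = rng.normal(scale=spread, size=(n_per_class, 2)) + separation
    pts = np.vstack([a, b])
    labels = ["control"] * n_per_class + ["case"] * n_per_class
    return squareform(pdist(pts)), labels


class TestDetectionMetrics:
    def test_kki_training_row_arithmetic(self):
        """57/57 controls and 2/21 cases correct reproduce the published
        KKI training rates."""
        truth = ["control"] * 57 + ["case"] * 21
        pred = ["control"] * 57 + ["case"] * 2 + ["control"] * 19
        m = detection_metrics(pred, truth)
        assert m.detection_rate == pytest.approx(75.64, abs=0.005)
        assert m.specificity == 100.0
        assert m.sensitivity == pytest.approx(9.52, abs=0.005)

    def test_all_correct(self):
        m = detection_metrics(["case", "control"], ["case", "control"])
        assert m.as_tuple() == (100.0, 100.0, 100.0)

    def test_hand_confusion(self):
        # TP=3, TN=5, FP=2, FN=1
        truth = ["case"] * 4 + ["control"] * 7
        pred = ["case"] * 3 + ["control"] + ["control"] * 5 + ["case"] * 2
        m = detection_metrics(pred, truth)
        assert m.detection_rate == pytest.approx(72.73, abs=0.005)
        assert m.specificity == pytest.approx(71.43, abs=0.005)
        assert m.sensitivity == pytest.approx(75.00, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics([], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics(["adhd"], ["case"])

    def test_degenerate_flag(self):
        m = detection_metrics(["control", "control"], ["control", "case"])
        assert m.degenerate


class TestWeightedAverages:
    def test_training_all_subjects_average(self):
        rates = [75.64, 64.10, 60.61, 61.20]
        counts = [78, 39, 66, 183]
        assert weighted_average_rates(rates, counts) == pytest.approx(64.48, abs=0.005)

    def test_test_mf_average(self):
        rates = [54.55, 100.0, 61.76, 72.55]
        counts = [11, 25, 34, 51]
        assert weighted_average_rates(rates, counts) == pytest.approx(73.55, abs=0.005)

    def test_equal_rates_identity(self):
        assert weighted_average_rates([42.0, 42.0], [10, 90]) == pytest.approx(42.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_average_rates([1.0], [1, 2])


class TestLoocv:
    def test_separated_clusters_fully_detected(self, rng):
        D, labels = cluster_distance_matrix(rng, 10)
        m = classify_loocv(D, labels)
        assert m.detection_rate == 100.0

    def test_unstructured_distances_near_chance(self, rng):
        # one diffuse cloud: distances carry no label signal at all
        pts = rng.normal(size=(60, 2))
        D = squareform(pdist(pts))
        labels = ["control", "case"] * 30
        shuffled = [labels[i] for i in rng.permutation(60)]
        m = classify_loocv(D, shuffled)
        # 3 sigma around 50% for 60 Bernoulli trials is about +/- 19.4
        assert 30.0 <= m.detection_rate <= 70.0

    def test_deterministic_rerun(self, rng):
        D, labels = cluster_distance_matrix(rng, 8, separation=2.0, spread=1.0)
        a = classify_loocv(D, labels, EmbeddingConfig(seed=5))
        b = classify_loocv(D, labels, EmbeddingConfig(seed=5))
        assert a.as_tuple() == b.as_tuple()

    def test_single_class_rejected(self, rng):
        D, _ = cluster_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            classify_loocv(D, ["control"] * 8)


class TestTrainTest:
    def make_joint(self, rng, n=8):
        """Test points duplicate the training points exactly."""
        D_train, labels = cluster_distance_matrix(rng, n // 2)
        n_tr = D_train.shape[0]
        D = np.zeros((2 * n_tr, 2 * n_tr))
        D[:n_tr, :n_tr] = D_train
        D[n_tr:, n_tr:] = D_train
        D[:n_tr, n_tr:] = D_train
        D[n_tr:, :n_tr] = D_train
        np.fill_diagonal(D, 0.0)
        return D, labels

    def test_duplicated_test_points_perfectly_recovered(self, rng):
        D, labels = self.make_joint(rng)
        n = len(labels)
        m = classify_train_test(D, range(n), range(n, 2 * n), labels, labels)
        assert m.detection_rate == 100.0

    def test_planted_clusters_with_held_out(self, rng):
        D, labels = cluster_distance_matrix(rng, 15)
        n = len(labels)
        test_idx = list(range(0, n, 3))
        train_idx = [i for i in range(n) if i not in test_idx]
        m = classify_train_test(
            D, train_idx, test_idx,
            [labels[i] for i in train_idx], [labels[i] for i in test_idx],
        )
        assert m.detection_rate >= 90.0

    def test_invariant_to_test_ordering(self, rng):
        D, labels = cluster_distance_matrix(rng, 6)
        n = len(labels)
        train_idx = list(range(0, n, 2))
        test_idx = [i for i in range(n) if i not in train_idx]
        m1 = classify_train_test(
            D, train_idx, test_idx,
            [labels[i] for i in train_idx], [labels[i] for i in test_idx],
        )
        m2 = classify_train_test(
            D, train_idx, test_idx[::-1],
            [labels[i] for i in train_idx], [labels[i] for i in test_idx[::-1]],
        )
        assert m1.as_tuple() == m2.as_tuple()

    def test_overlapping_split_rejected(self, rng):
        D, labels = cluster_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            classify_train_test(D, [0, 1, 2], [2, 3, 4, 5, 6, 7], labels[:3], labels[3:])


class TestThresholdSweep:
    def test_grid_and_report_shape(self, small_cohort):
        _, pairs = small_cohort
        report = threshold_sweep(pairs, corrth_grid=(0.3, 0.5, 0.7))
        train_rows = [r for r in report.rows if r.split == "train"]
        assert sorted({r.corr_threshold for r in train_rows}) == [0.3, 0.5, 0.7]
        assert ("SYN", "all") in report.chosen_corrth
        assert report.chosen_corrth[("SYN", "all")] in (0.3, 0.5, 0.7)
        assert ("SYN", "all") in report.test_results
        assert "train_all" in report.averages and "test_all" in report.averages
        for r in report.rows:
            assert 0.0 <= r.metrics.detection_rate <= 100.0
            assert r.degenerate == (
                r.metrics.specificity == 0.0 or r.metrics.sensitivity == 0.0
            )

    def test_default_grid_is_the_published_sweep(self):
        assert DEFAULT_CORRTH_GRID == (0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

    def test_best_avoids_degenerate_cells(self, small_cohort):
        _, pairs = small_cohort
        report = threshold_sweep(pairs, corrth_grid=(0.3, 0.5, 0.7))
        for (site, group), th in report.chosen_corrth.items():
            cells = [
                r for r in report.rows
                if r.site == site and r.group == group and r.split == "train"
            ]
            if any(not r.degenerate for r in cells):
                chosen = [r for r in cells if r.corr_threshold == th]
                assert not chosen[0].degenerate

    def test_sex_stratified_pooling(self, small_cohort):
        _, pairs = small_cohort
        report = threshold_sweep(
            pairs, corrth_grid=(0.4, 0.6), stratify_by_sex=True
        )
        groups = {g for (_, g) in report.chosen_corrth}
        assert groups <= {"male", "female"} and groups
        if "train_mf" in report.averages:
            assert 0.0 <= report.averages["train_mf"] <= 100.0

    def test_small_group_skipped_with_warning(self, small_cohort):
        _, pairs = small_cohort
        # leave only two female subjects in the cohort
        females = [p for p in pairs if p[1].sex == "female"]
        males = [p for p in pairs if p[1].sex == "male"]
        subset = males + females[:2]
        with pytest.warns(UserWarning, match="skipping"):
            threshold_sweep(subset, corrth_grid=(0.5,), stratify_by_sex=True)

    def test_empty_grid_rejected(self, small_cohort):
        _, pairs = small_cohort
        with pytest.raises(ValueError):
            threshold_sweep(pairs, corrth_grid=())
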