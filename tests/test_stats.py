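import math

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

import pepgan as pg
from pepgan.stats import ConfusionCounts


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        res = pg.fisher_z_test(0.5, 100, 0.5, 57)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_value(self):
        res = pg.fisher_z_test(0.5, 103, 0.0, 103)
        assert res.statistic == pytest.approx(math.atanh(0.5) / math.sqrt(2 / 100))
        assert res.statistic == pytest.approx(3.884, abs=5e-4)

    def test_antisymmetry(self):
        a = pg.fisher_z_test(0.7, 50, 0.2, 80)
        b = pg.fisher_z_test(0.2, 80, 0.7, 50)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pg.fisher_z_test(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            pg.fisher_z_test(0.5, 3, 0.5, 10)


class TestSampleCorrelation:
    def test_identical_and_opposite(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        c = pg.sample_correlation_matrix(x)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_constant_row_convention(self):
        x = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        c = pg.sample_correlation_matrix(x)
        assert c[0, 1] == 0.0
        assert c[0, 0] == 1.0

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=(4, 12))
            c = pg.sample_correlation_matrix(x)
            for i in range(4):
                for j in range(4):
                    xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                    ref = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                    assert c[i, j] == pytest.approx(ref, abs=1e-12)


class TestWardOrder:
    def test_pairs_adjacent_within_groups(self):
        x = np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 0, 0], [0, 1.0, 0]]) + \
            np.random.default_rng(0).normal(0, 0.01, (4, 3))
        corr = pg.sample_correlation_matrix(x)
        order = pg.ward_cluster_order(corr, groups=["g"] * 4)
        pos = {int(i): k for k, i in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1
        assert abs(pos[1] - pos[3]) == 1

    def test_outlier_at_edge(self):
        corr = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        order = list(pg.ward_cluster_order(corr))
        assert order.index(2) in (0, 2)

    def test_permutation_bijection(self, rng):
        x = rng.normal(size=(9, 6))
        corr = pg.sample_correlation_matrix(x)
        order = pg.ward_cluster_order(corr, groups=["a"] * 4 + ["b"] * 5)
        assert sorted(order.tolist()) == list(range(9))


class TestSilhouette:
    def test_tight_far_clusters(self, rng):
        a = rng.normal(0, 0.01, size=(10, 2))
        b = rng.normal(10, 0.01, size=(10, 2)) + 100
        pts = np.vstack([a, b])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        scores, med = pg.silhouette_scores(d, ["a"] * 10 + ["b"] * 10)
        assert med > 0.9

    def test_identical_points_score_zero(self):
        d = np.zeros((6, 6))
        scores, med = pg.silhouette_scores(d, ["a"] * 3 + ["b"] * 3)
        assert np.all(scores == 0)

    def test_hand_example_and_sklearn_agreement(self):
        pts = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
        d = np.abs(pts[:, 0][:, None] - pts[:, 0][None, :])
        labels = ["a", "a", "b", "b"]
        scores, _ = pg.silhouette_scores(d, labels)
        # manual: point 0: a=1, b=(10+11)/2=10.5 -> (10.5-1)/10.5
        assert scores[0] == pytest.approx((10.5 - 1) / 10.5)
        ref = silhouette_samples(d, labels, metric="precomputed")
        assert np.allclose(scores, ref)

    def test_singleton_cluster_scores_zero(self):
        d = np.array([[0.0, 1, 2], [1, 0, 2], [2, 2, 0.0]])
        scores, _ = pg.silhouette_scores(d, ["a", "a", "b"])
        assert scores[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            pg.silhouette_scores(np.zeros((3, 3)), ["a"] * 3)


class TestCorrelationEntropy:
    def test_identity_is_log2_n(self):
        assert pg.correlation_entropy(np.eye(16)) == pytest.approx(4.0)

    def test_rank_one_is_zero(self):
        assert pg.correlation_entropy(np.ones((8, 8))) == pytest.approx(0.0, abs=1e-9)

    def test_two_equal_blocks_give_one_bit(self):
        c = np.kron(np.eye(2), np.ones((5, 5)))
        assert pg.correlation_entropy(c) == pytest.approx(1.0)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            pg.correlation_entropy(bad)


class TestMannWhitneyAndAdjustment:
    def test_identical_samples(self):
        res = pg.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.9

    def test_u_statistic_by_pair_counting(self):
        # U of the first sample counts pairs x > y: none here
        res = pg.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0

    def test_exact_method_used_for_small_samples(self):
        res = pg.mann_whitney([1.0, 2.0, 5.0], [3.0, 4.0, 6.0])
        assert res.method == "mann_whitney_exact"

    def test_bonferroni_multiplication(self):
        adj = pg.adjust_pvalues([0.01, 0.04], method="bonferroni")
        assert np.allclose(adj, [0.02, 0.08])

    def test_bh_never_exceeds_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(8)
            bh = pg.adjust_pvalues(p, method="bh")
            bf = pg.adjust_pvalues(p, method="bonferroni")
            assert np.all(bh <= bf + 1e-12)

    def test_bh_preserves_ordering(self, rng):
        p = np.sort(rng.random(10))
        bh = pg.adjust_pvalues(p, method="bh")
        assert np.all(np.diff(bh) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pg.mann_whitney([], [1.0])


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = pg.classification_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_hand_computed_mcc(self):
        m = pg.classification_metrics(ConfusionCounts(tp=50, fp=10, tn=30, fn=10))
        assert m["mcc"] == pytest.approx(1400 / 2400)

    def test_label_swap_mcc_invariance(self):
        a = pg.classification_metrics(ConfusionCounts(tp=40, fp=7, tn=22, fn=13))["mcc"]
        b = pg.classification_metrics(ConfusionCounts(tp=22, fp=13, tn=40, fn=7))["mcc"]
        assert a == pytest.approx(b)

    def test_zero_denominators_return_zero(self):
        m = pg.classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m["precision"] == 0.0
        assert m["recall"] == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)


class TestStratifiedKFold:
    def test_balanced_folds(self):
        labels = ["s"] * 100 + ["w"] * 100
        folds = pg.stratified_kfold(labels, k=10, seed=3)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 20
            assert sum(mask[:100]) == 10

    def test_seed_reproducibility_and_partition(self):
        labels = ["s"] * 30 + ["w"] * 50
        a = pg.stratified_kfold(labels, k=5, seed=9)
        b = pg.stratified_kfold(labels, k=5, seed=9)
        assert np.array_equal(a, b)
        assert sorted(np.unique(a)) == list(range(5))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            pg.stratified_kfold(["s"] * 3 + ["w"] * 30, k=10)


def test_cross_validated_metrics_harness(study_set):
    """The metric harness accepts any sklearn-style probability scorer."""
    from sklearn.linear_model import LogisticRegression

    recs = [r for r in study_set if r.label in ("strong", "weak")]
    recs = recs[:100] + recs[-100:]
    df = pg.descriptor_frame([r.sequence for r in recs])
    labels = [r.label for r in recs]
    out = pg.cross_validated_metrics(
        LogisticRegression(max_iter=500), pg.robust_scale(df).array, labels, k=5, seed=0
    )
    assert set(out.columns) >= {"mcc", "f1", "balanced_accuracy"}
    assert len(out) == 5
    assert out["balanced_accuracy"].mean() > 0.6
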