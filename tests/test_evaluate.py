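import numpy as np
import pytest
from sklearn.metrics import f1_score

import metann as m
from metann.evaluate import ConfusionSummary, EvaluationError, _stratified_folds


def _conf(y_true, y_pred):
    return ConfusionSummary.from_predictions(np.asarray(y_true), np.asarray(y_pred))


class TestF1:
    def test_perfect_predictions(self):
        c = _conf(list("aabb"), list("aabb"))
        assert m.f1_micro(c) == 1.0
        assert m.f1_macro(c) == 1.0

    def test_micro_is_accuracy(self):
        y = list("aaaabbbbcc")
        p = list("aaaabbbbaa")  # 8 of 10 correct
        assert m.f1_micro(_conf(y, p)) == pytest.approx(0.8)

    def test_micro_invariant_to_relabeling(self):
        y, p = list("aabbcc"), list("abbbcc")
        swap = str.maketrans("abc", "cab")
        assert m.f1_micro(_conf(y, p)) == m.f1_micro(
            _conf([s.translate(swap) for s in y], [s.translate(swap) for s in p])
        )

    def test_macro_unweighted_mean(self):
        c = ConfusionSummary(
            classes=np.array(["a", "b"]),
            tp=np.array([2, 1]),
            fp=np.array([1, 0]),
            fn=np.array([0, 3]),
            n=6,
        )
        # per-class F1: 4/5 = 0.8 and 2/5 = 0.4 -> mean 0.6
        assert m.f1_macro(c) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sklearn_on_random_predictions(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 4, 60)
        p = rng.integers(0, 4, 60)
        c = _conf(y, p)
        assert m.f1_micro(c) == pytest.approx(f1_score(y, p, average="micro"))
        assert m.f1_macro(c) == pytest.approx(f1_score(y, p, average="macro"))


def _pooled_pair_auc(scores, labels):
    """Brute-force concordant-pair oracle on the pooled one-vs-rest points."""
    classes = np.unique(labels)
    onehot = (np.asarray(labels)[:, None] == classes[None, :]).astype(int)
    z = onehot.ravel()
    s = np.asarray(scores, dtype=float).ravel()
    pos, neg = s[z == 1], s[z == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = np.array(["a", "a", "b", "b"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert m.roc_auc(scores, labels) == pytest.approx(1.0)

    def test_constant_scores_give_chance(self):
        labels = np.array(["a", "b"] * 10)
        scores = np.full((20, 2), 0.5)
        assert m.roc_auc(scores, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels = np.array(["x"] * (n // 2) + ["y"] * (n - n // 2))
        scores = rng.random((n, 2))
        assert m.roc_auc(scores, labels) == pytest.approx(
            _pooled_pair_auc(scores, labels)
        )

    def test_multiclass_oracle_agreement(self, rng):
        labels = rng.choice(list("abc"), 15)
        while np.unique(labels).size < 3:
            labels = rng.choice(list("abc"), 15)
        scores = rng.random((15, 3))
        assert m.roc_auc(scores, labels) == pytest.approx(
            _pooled_pair_auc(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            m.roc_auc(np.ones((3, 1)), np.array(["a"] * 3))


class TestPerformanceGain:
    def test_printed_gain_rows(self):
        assert round(m.performance_gain(0.56, 0.43)) == 30
        assert round(m.performance_gain(0.86, 0.82)) == 5

    def test_equal_scores_zero_gain(self):
        assert m.performance_gain(0.7, 0.7) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(EvaluationError):
            m.performance_gain(0.5, 0.0)


class TestQQPoints:
    def test_identical_vectors_on_diagonal(self, rng):
        a = rng.integers(0, 100, 25)
        pts = m.qq_points(a, a)
        np.testing.assert_allclose(pts[:, 0], pts[:, 1])

    def test_scaling_gives_slope_two(self, rng):
        a = rng.integers(1, 50, 30)
        pts = m.qq_points(a, 2 * a)
        np.testing.assert_allclose(pts[:, 1], 2 * pts[:, 0])

    def test_unequal_lengths_interpolated(self, rng):
        pts = m.qq_points(rng.random(10), rng.random(7))
        assert pts.shape == (10, 2)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            m.qq_points([], [1, 2])


class TestAdjustedRSquared:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        assert m.adjusted_r_squared(x, 3 * x - 2) == pytest.approx(1.0)

    def test_hand_example(self):
        # frozen from an independent OLS computation
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        assert m.adjusted_r_squared(x, y) == pytest.approx(0.5675675675675675)

    def test_independent_noise_near_zero(self, rng):
        x = rng.random(3000)
        y = rng.random(3000)
        assert abs(m.adjusted_r_squared(x, y)) < 0.02

    def test_constant_x_rejected(self):
        with pytest.raises(EvaluationError):
            m.adjusted_r_squared(np.ones(5), np.arange(5.0))


class TestCrossValidate:
    def test_folds_partition_samples(self):
        labels = np.array(["a"] * 20 + ["b"] * 20)
        folds = _stratified_folds(labels, 5, seed=0)
        seen = np.concatenate([val for _, val in folds])
        assert sorted(seen) == list(range(40))
        for train, val in folds:
            assert set(train).isdisjoint(val)

    def test_small_class_falls_back_with_warning(self):
        labels = np.array(["a"] * 18 + ["b"] * 2)
        with pytest.warns(UserWarning, match="unstratified"):
            folds = _stratified_folds(labels, 5, seed=0)
        assert len(folds) == 5

    def test_deterministic_report_with_augmentation(self, small_table):
        models = {"mnb": m.BaselineSpec("mnb")}
        cfg = dict(seed=5, n_folds=3, n_runs=2, augment=True, min_prevalence=0.0)
        a = m.cross_validate(small_table, models, m.RunConfig(**cfg))
        b = m.cross_validate(small_table, models, m.RunConfig(**cfg))
        assert a.summary.equals(b.summary)
        assert a.fold_scores.equals(b.fold_scores)

    def test_validation_counts_untouched_by_augmentation(self, small_table):
        # each (run, fold) cell scores exactly the held-out real samples
        models = {"mnb": m.BaselineSpec("mnb")}
        cfg = m.RunConfig(seed=5, n_folds=3, n_runs=1, augment=True,
                          min_prevalence=0.0)
        rep = m.cross_validate(small_table, models, cfg)
        assert len(rep.fold_scores) == 3
        assert rep.summary.loc["mnb", "f1_micro_mean"] <= 1.0

    def test_gain_reported_between_nn_and_baselines(self, small_table):
        models = {
            "mnb": m.BaselineSpec("mnb"),
            "mlp": m.MLPSpec((16, 8), epochs=30),
        }
        rep = m.cross_validate(
            small_table, models,
            m.RunConfig(seed=2, n_folds=3, n_runs=1, min_prevalence=0.0),
        )
        assert set(rep.gain_percent) == {"f1_macro", "f1_micro"}
        for v in rep.gain_percent.values():
            assert isinstance(v, int)

    def test_augmentation_with_dropout_does_not_hurt(self, small_table):
        # directional claim: over several seeds, mean validation F1 with
        # NB augmentation + input dropout stays within one SD of (or beats)
        # the plain model
        plain_scores, aug_scores = [], []
        for seed in range(5):
            base = {"mlp": m.MLPSpec((32, 16), epochs=60)}
            augd = {"mlp": m.MLPSpec((32, 16), epochs=60, input_dropout_q=0.5)}
            cfg = dict(seed=seed, n_folds=3, n_runs=1, min_prevalence=0.0)
            plain = m.cross_validate(
                small_table, base, m.RunConfig(augment=False, **cfg)
            )
            aug = m.cross_validate(
                small_table, augd, m.RunConfig(augment=True, **cfg)
            )
            plain_scores.append(plain.mean("mlp", "f1_micro"))
            aug_scores.append(aug.mean("mlp", "f1_micro"))
        sd = np.std(plain_scores) + 1e-3
        assert np.mean(aug_scores) >= np.mean(plain_scores) - sd
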