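import numpy as np
import pytest

import metann as m
from metann.nn_models import NNError, default_hidden_sizes, predict


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(m.softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_shift_invariance(self, rng):
        z = rng.normal(size=7)
        np.testing.assert_allclose(m.softmax(z), m.softmax(z + 123.4))

    def test_hand_evaluated(self):
        out = m.softmax(np.log(np.array([1.0, 3.0])))
        np.testing.assert_allclose(out, [0.25, 0.75])

    def test_empty_vector_rejected(self):
        with pytest.raises(NNError):
            m.softmax(np.array([]))


class TestCrossEntropy:
    def test_perfect_predictions_give_zero(self):
        probs = np.eye(3)
        assert m.cross_entropy_loss(probs, np.array([0, 1, 2])) == pytest.approx(0.0)

    def test_uniform_predictions_closed_form(self):
        n, k = 6, 4
        probs = np.full((n, k), 1 / k)
        assert m.cross_entropy_loss(probs, np.zeros(n, int)) == pytest.approx(
            n * np.log(k)
        )

    def test_hand_sum(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        got = m.cross_entropy_loss(probs, np.array([0, 1]))
        assert got == pytest.approx(-(np.log(0.5) + np.log(0.75)))

    def test_label_out_of_range_rejected(self):
        with pytest.raises(NNError):
            m.cross_entropy_loss(np.full((1, 2), 0.5), np.array([2]))


class TestInputDropout:
    def test_evaluation_mode_is_identity(self, rng):
        x = rng.random((5, 8))
        np.testing.assert_array_equal(
            m.apply_input_dropout(x, 0.5, rng, training=False), x
        )

    def test_zero_rate_is_identity(self, rng):
        x = rng.random((5, 8))
        np.testing.assert_array_equal(m.apply_input_dropout(x, 0.0, rng), x)

    def test_half_rate_zeroes_half_and_rescales(self, rng):
        x = np.ones((200, 200))
        out = m.apply_input_dropout(x, 0.5, rng)
        dropped = (out == 0).mean()
        se = np.sqrt(0.25 / x.size)
        assert abs(dropped - 0.5) < 4 * se
        # survivors carry the inverted-dropout scale
        assert out.max() == pytest.approx(2.0)
        assert out.mean() == pytest.approx(1.0, abs=0.02)

    def test_rate_one_rejected(self, rng):
        with pytest.raises(NNError):
            m.apply_input_dropout(np.ones((2, 2)), 1.0, rng)


class TestPhyloSort:
    def test_alphabetical_by_taxonomy(self):
        perm = m.phylo_sort(
            ["a", "b"],
            {"a": "Firmicutes;Bacilli", "b": "Bacteroidetes;Bacteroidia"},
        )
        np.testing.assert_array_equal(perm, [1, 0])

    def test_identical_strings_keep_original_order(self):
        perm = m.phylo_sort(["x", "y", "z"], {o: "Same;Tax" for o in "xyz"})
        np.testing.assert_array_equal(perm, [0, 1, 2])

    def test_no_taxonomy_identity(self):
        np.testing.assert_array_equal(m.phylo_sort(["q", "a", "z"], None), [0, 1, 2])
        np.testing.assert_array_equal(m.phylo_sort(["q", "a", "z"], {}), [0, 1, 2])

    def test_unannotated_sort_last_by_id(self):
        perm = m.phylo_sort(
            ["zz", "aa", "mm"], {"mm": "Bacteroidetes;X"}
        )
        # annotated mm first, then aa/zz alphabetically
        np.testing.assert_array_equal(perm, [2, 1, 0])


class TestHiddenSizeRule:
    @pytest.mark.parametrize(
        "p,expected", [(512, (512, 256)), (100, (128, 64)), (3, (4, 2))]
    )
    def test_power_of_two_halving(self, p, expected):
        assert default_hidden_sizes(p) == expected

    def test_depth_three(self):
        assert default_hidden_sizes(512, depth=3) == (512, 256, 128)

    def test_depth_limits_enforced_at_fit(self):
        spec = m.MLPSpec(hidden_sizes=(8, 8, 8, 8))
        with pytest.raises(NNError, match="two or three"):
            spec.resolve_hidden(10)


def _separable_toy(n=20, rng=None):
    rng = rng or np.random.default_rng(0)
    x0 = rng.uniform(0.0, 0.3, size=(n // 2, 2))
    x1 = rng.uniform(0.7, 1.0, size=(n // 2, 2))
    x = np.vstack([x0, x1])
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    return x, y


class TestMLPTraining:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        x, y = _separable_toy()
        model = m.train_mlp(x, y, m.MLPSpec(hidden_sizes=(8, 4)),
                            np.random.default_rng(1))
        assert (predict(model, x) == y).all()

    def test_loss_decreases(self):
        x, y = _separable_toy(40)
        model = m.train_mlp(x, y, m.MLPSpec(hidden_sizes=(8, 4)),
                            np.random.default_rng(2))
        assert model.loss_trace[-1] < model.loss_trace[0]
        assert len(model.loss_trace) == 100  # fixed epoch budget, never early-stopped

    def test_same_seed_identical_weights(self):
        x, y = _separable_toy()
        spec = m.MLPSpec(hidden_sizes=(6, 4), epochs=10, input_dropout_q=0.3)
        a = m.train_mlp(x, y, spec, np.random.default_rng(3))
        b = m.train_mlp(x, y, spec, np.random.default_rng(3))
        for la, lb in zip(a.layers, b.layers):
            if hasattr(la, "W"):
                np.testing.assert_array_equal(la.W, lb.W)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).random((6, 3))
        with pytest.raises(NNError, match="two classes"):
            m.train_mlp(x, np.array(["a"] * 6), m.MLPSpec((4, 4)))


class TestCNN:
    def test_flattened_length_p100(self):
        # 100 features -> two same-padded conv / pool-2 stages -> 25 per
        # channel, 8 channels -> 200 inputs to the fully connected head
        x, y = np.random.default_rng(0).random((12, 100)), np.array(["a", "b"] * 6)
        model = m.train_cnn(x, y, spec=m.CNNSpec(epochs=1),
                            rng=np.random.default_rng(0))
        assert model.layers[-1].W.shape[0] == 200

    def test_flattened_length_p7(self):
        # floor(floor(7/2)/2) = 1 position per channel
        x, y = np.random.default_rng(0).random((8, 7)), np.array(["a", "b"] * 4)
        model = m.train_cnn(x, y, spec=m.CNNSpec(epochs=1),
                            rng=np.random.default_rng(0))
        assert model.layers[-1].W.shape[0] == 8

    def test_too_few_features_rejected(self):
        x = np.random.default_rng(0).random((4, 3))
        with pytest.raises(NNError, match="at least 4"):
            m.train_cnn(x, np.array(["a", "b", "a", "b"]))

    def test_separable_toy_with_ordering(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.uniform(0, 0.3, (10, 8)), rng.uniform(0.7, 1, (10, 8))])
        y = np.array(["lo"] * 10 + ["hi"] * 10)
        ordering = np.arange(8)[::-1]
        model = m.train_cnn(x, y, ordering, m.CNNSpec(epochs=60),
                            np.random.default_rng(5))
        assert (predict(model, x) == y).all()

    def test_same_seed_identical_weights(self):
        x, y = np.random.default_rng(0).random((10, 12)), np.array(["a", "b"] * 5)
        a = m.train_cnn(x, y, spec=m.CNNSpec(epochs=3), rng=np.random.default_rng(7))
        b = m.train_cnn(x, y, spec=m.CNNSpec(epochs=3), rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.layers[1].W, b.layers[1].W)
        np.testing.assert_array_equal(a.layers[-1].W, b.layers[-1].W)


class TestPredictProba:
    def test_rows_sum_to_one_and_pure_function(self):
        x, y = _separable_toy()
        model = m.train_mlp(x, y, m.MLPSpec((6, 4), epochs=5, input_dropout_q=0.5),
                            np.random.default_rng(8))
        q = np.vstack([x, x[:1]])
        probs = m.predict_proba(model, q)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        # dropout disabled at evaluation: duplicates map identically
        np.testing.assert_array_equal(probs[0], probs[-1])
        np.testing.assert_array_equal(
            probs[:-1], m.predict_proba(model, x)
        )

    def test_dimension_mismatch_rejected(self):
        x, y = _separable_toy()
        model = m.train_mlp(x, y, m.MLPSpec((6, 4), epochs=2),
                            np.random.default_rng(9))
        with pytest.raises(NNError, match="features"):
            m.predict_proba(model, np.ones((2, 5)))
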