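"""Fusion, squeeze-and-excitation weights, classifier, attention report."""

import numpy as np
import pytest

from facepheno._nn import sigmoid
from facepheno.fusion import (
    SEAttentionClassifier,
    apply_attention,
    attention_report,
    attention_weights,
    classify,
    fuse,
)


class TestFuse:
    def test_k6_e1_gives_24(self):
        out = fuse(np.zeros(18), np.zeros(6))
        assert out.shape == (24,)

    def test_k1_e1_gives_4(self):
        assert fuse(np.zeros(3), np.zeros(1)).shape == (4,)

    def test_fine_block_positions(self, rng):
        coarse = rng.integers(0, 2, 18).astype(float)
        fine = rng.normal(size=6)
        O = fuse(coarse, fine)
        for k in range(1, 7):
            assert O[18 + k - 1] == fine[k - 1]

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(18), np.zeros(5))


class TestAttentionWeights:
    def test_zero_parameters_give_half_everywhere(self):
        A = attention_weights(np.ones(24), np.zeros((24, 6)), np.zeros(6),
                              np.zeros((6, 24)), np.zeros(24))
        assert np.allclose(A, 0.5)

    def test_two_channel_toy_hand_evaluated(self):
        # W1=[[1],[0]] compresses (1,1)->1; W2=[[2,0]] restores -> (2,0)
        W1 = np.array([[1.0], [0.0]])
        W2 = np.array([[2.0, 0.0]])
        A = attention_weights(np.array([1.0, 1.0]), W1, np.zeros(1),
                              W2, np.zeros(2))
        assert A == pytest.approx([sigmoid(np.array([2.0]))[0], 0.5])

    def test_weights_strictly_inside_unit_interval(self, rng):
        W1 = rng.normal(size=(24, 6))
        W2 = rng.normal(size=(6, 24))
        A = attention_weights(rng.normal(size=(10, 24)), W1, np.zeros(6),
                              W2, np.zeros(24))
        assert np.all((A > 0) & (A < 1))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_weights(np.ones(10), rng.normal(size=(24, 6)),
                              np.zeros(6), rng.normal(size=(6, 24)), np.zeros(24))


class TestApplyAttention:
    def test_limits(self, rng):
        O = rng.normal(size=24)
        assert np.allclose(apply_attention(O, np.full(24, 0.5)), O / 2)
        assert np.allclose(apply_attention(O, np.full(24, 1 - 1e-12)), O)

    def test_matches_elementwise_loop(self, rng):
        O, A = rng.normal(size=7), rng.uniform(size=7)
        loop = np.array([O[i] * A[i] for i in range(7)])
        assert np.allclose(apply_attention(O, A), loop)

    def test_weights_never_amplify(self, rng):
        O = rng.normal(size=24)
        A = sigmoid(rng.normal(size=24))
        assert np.all(np.abs(apply_attention(O, A)) <= np.abs(O))

    def test_zero_channel_stays_zero(self, rng):
        O = rng.normal(size=24)
        O[5] = 0.0
        assert apply_attention(O, sigmoid(rng.normal(size=24)))[5] == 0.0


class TestClassify:
    def test_zero_weights_give_uniform_probabilities(self):
        p = classify(np.ones(24), np.zeros((24, 2)), np.zeros(2))
        assert p == pytest.approx([0.5, 0.5])

    def test_probabilities_sum_to_one(self, rng):
        Wc, bc = rng.normal(size=(24, 2)), rng.normal(size=2)
        p = classify(rng.normal(size=(20, 24)), Wc, bc)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_negating_logits_flips_the_argmax(self, rng):
        Wc, bc = rng.normal(size=(24, 2)), rng.normal(size=2)
        x = rng.normal(size=24)
        p = classify(x, Wc, bc)
        q = classify(x, -Wc, -bc)
        if not np.isclose(p[0], p[1]):
            assert np.argmax(p) != np.argmax(q)


TABLE_STYLE_PATTERN = {
    # slice: (fine, head pose, category, intensity)
    1: (1, 1, 0, 0),
    2: (0, 0, 1, 0),
    3: (1, 1, 0, 0),
    4: (0, 1, 1, 0),
    5: (1, 0, 1, 1),
    6: (1, 0, 0, 0),
}


class TestAttentionReport:
    def test_constant_weights_binarize_uniformly(self):
        rep_low = attention_report(np.full(24, 0.4), K=6)
        rep_high = attention_report(np.full(24, 0.6), K=6)
        cols = ["fine_grained", "head_pose", "expression_category",
                "expression_intensity"]
        assert (rep_low[cols].to_numpy() == 0).all()
        assert (rep_high[cols].to_numpy() == 1).all()

    def test_reference_retention_pattern_reproduced(self):
        """Weights placed at a known 11-of-24 retention layout map back to
        the slice-by-feature table exactly."""
        K = 6
        A = np.full(24, 0.1)
        for k, (fine, hp, cat, inten) in TABLE_STYLE_PATTERN.items():
            if fine:
                A[3 * K + k - 1] = 0.9
            if hp:
                A[2 * K + k - 1] = 0.9
            if cat:
                A[K + k - 1] = 0.9
            if inten:
                A[k - 1] = 0.9
        rep = attention_report(A, K=6)
        cols = ["fine_grained", "head_pose", "expression_category",
                "expression_intensity"]
        got = {int(r["slice"]): tuple(int(r[c]) for c in cols)
               for _, r in rep.iterrows()}
        assert got == TABLE_STYLE_PATTERN
        assert rep[cols].to_numpy().sum() == 11

    def test_raw_weights_retained_alongside_binary(self):
        A = np.linspace(0.01, 0.99, 24)
        rep = attention_report(A, K=6)
        assert rep["weight_expression_intensity"].to_numpy() == pytest.approx(A[:6])

    def test_layout_only_defined_for_e_one(self):
        with pytest.raises(ValueError):
            attention_report(np.full(30, 0.5), K=6, e=2)


class TestSEAttentionClassifier:
    def test_perfect_separation_reaches_full_training_accuracy(self, rng):
        # one coarse flag equals the label: linearly separable by design
        n = 40
        y = np.array(["ASD"] * 20 + ["TD"] * 20)
        X = rng.integers(0, 2, size=(n, 24)).astype(float)
        X[:, 3] = (y == "ASD").astype(float)
        clf = SEAttentionClassifier(attention=False, learning_rate=1e-2,
                                    batch_size=8, epochs=200, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_training_loss_trends_down(self, rng):
        y = np.array(["ASD"] * 20 + ["TD"] * 20)
        X = rng.normal(size=(40, 24)) + (y == "ASD")[:, None]
        clf = SEAttentionClassifier(attention=True, learning_rate=1e-3,
                                    batch_size=8, epochs=100, random_state=0)
        clf.fit(X, y)
        assert np.mean(clf.loss_history_[-10:]) < np.mean(clf.loss_history_[:10])

    def test_refit_same_seed_identical_parameters(self, rng):
        y = np.array(["ASD"] * 10 + ["TD"] * 10)
        X = rng.normal(size=(20, 24))
        kw = dict(learning_rate=1e-3, batch_size=4, epochs=20, random_state=9)
        a = SEAttentionClassifier(**kw).fit(X, y)
        b = SEAttentionClassifier(**kw).fit(X, y)
        for key in a.params_:
            assert np.array_equal(a.params_[key], b.params_[key])

    def test_attention_backprop_matches_numeric_gradient(self, rng):
        """End-to-end gradient of the SE + classifier stack."""
        X = rng.normal(size=(5, 8))
        y = np.array([0, 1, 0, 1, 1])
        clf = SEAttentionClassifier(attention=True, reduction=4, epochs=1,
                                    batch_size=5, learning_rate=0.0,
                                    random_state=0)
        clf.classes_ = np.array([0, 1])
        rng2 = np.random.default_rng(0)
        from facepheno._nn import uniform_init

        p = {"W1": uniform_init(rng2, (8, 2), 8), "b1": np.zeros(2),
             "W2": uniform_init(rng2, (2, 8), 2), "b2": np.zeros(8),
             "Wc": uniform_init(rng2, (8, 2), 8), "bc": np.zeros(2)}
        clf.params_ = p
        Y = np.eye(2)[y]

        def loss():
            probs, *_ = clf._forward(X)
            return -float((Y * np.log(probs + 1e-12)).sum()) / 5

        probs, hidden, A, Xw = clf._forward(X)
        dlogits = (probs - Y) / 5
        grads = {"Wc": Xw.T @ dlogits, "bc": dlogits.sum(axis=0)}
        dXw = dlogits @ p["Wc"].T
        dA = dXw * X
        dz2 = dA * A * (1 - A)
        grads["W2"] = hidden.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dhidden = (dz2 @ p["W2"].T) * (hidden > 0)
        grads["W1"] = X.T @ dhidden
        grads["b1"] = dhidden.sum(axis=0)
        eps = 1e-6
        for key in grads:
            num = np.zeros_like(p[key])
            flat, nflat = p[key].ravel(), num.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss()
                flat[i] = orig - eps
                lo = loss()
                flat[i] = orig
                nflat[i] = (hi - lo) / (2 * eps)
            assert np.allclose(grads[key], num, atol=1e-6), key
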