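"""Feature fusion with squeeze-and-excitation channel attention.

The coarse and fine vectors concatenate into O = [Oc | Of] (24 channels
for K=6, e=1).  Because each entry is already a single feature channel,
the global-pooling stage of the original squeeze-and-excitation block is
unnecessary; the weights come straight from the two affine layers

    A = sigmoid(W2 . relu(W1 . O + b1) + b2),        A in (0, 1)^C

with the first layer compressing C channels to C/r and the second
restoring them.  The reweighted vector O' = O * A feeds a softmax binary
classifier.  Reported attention tables binarize the (input-averaged)
weights at 0.5, mirroring how retained/suppressed channels are read off,
while the forward pass always uses the continuous weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, relu, sigmoid, softmax, uniform_init

__all__ = [
    "fuse",
    "attention_weights",
    "apply_attention",
    "classify",
    "attention_report",
    "SEAttentionClassifier",
]

#: Attention-report columns: the fine feature and the three coarse blocks.
REPORT_COLUMNS = ("fine_grained", "head_pose", "expression_category",
                  "expression_intensity")


def fuse(coarse: np.ndarray, fine: np.ndarray) -> np.ndarray:
    """Concatenate [coarse (3K) | fine (K*e)] after a K-consistency check."""
    coarse = np.asarray(coarse, dtype=float)
    fine = np.asarray(fine, dtype=float)
    if coarse.shape[-1] % 3:
        raise ValueError("coarse block length must be 3K")
    K = coarse.shape[-1] // 3
    if fine.shape[-1] % K:
        raise ValueError(
            f"fine block length {fine.shape[-1]} not a multiple of K={K}"
        )
    return np.concatenate([coarse, fine], axis=-1)


def attention_weights(O: np.ndarray, W1, b1, W2, b2) -> np.ndarray:
    """A = sigmoid(W2 relu(W1 O + b1) + b2); supports (C,) or (B, C)."""
    O = np.asarray(O, dtype=float)
    if O.shape[-1] != np.asarray(W1).shape[0]:
        raise ValueError("input width does not match W1")
    return sigmoid(relu(O @ W1 + b1) @ W2 + b2)


def apply_attention(O: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Elementwise channel reweighting O' = O * A."""
    O, A = np.asarray(O, dtype=float), np.asarray(A, dtype=float)
    if O.shape != A.shape:
        raise ValueError(f"shape mismatch {O.shape} vs {A.shape}")
    return O * A


def classify(O_prime: np.ndarray, Wc, bc) -> np.ndarray:
    """Softmax two-class probabilities from the reweighted features."""
    logits = np.asarray(O_prime, dtype=float) @ Wc + bc
    return softmax(logits, axis=-1)


def attention_report(A: np.ndarray, K: int, e: int = 1) -> pd.DataFrame:
    """Map channel weights back to (slice, feature-type) and binarize at 0.5.

    Rows are slices 1..K; columns are the fine-grained feature and the three
    coarse feature types.  Only defined for e=1 (the 4-column layout).
    Binarized indicators sit next to the raw continuous weights.
    """
    if e != 1:
        raise ValueError("the 4-column report layout requires e=1")
    A = np.asarray(A, dtype=float)
    if A.shape != (K * (3 + e),):
        raise ValueError(f"expected {K * (3 + e)} weights, got {A.shape}")
    rows = []
    for k in range(1, K + 1):
        # Oc ordering: [intensity block | happy block | attention block].
        raw = {
            "fine_grained": A[3 * K + (k - 1)],
            "head_pose": A[2 * K + (k - 1)],
            "expression_category": A[K + (k - 1)],
            "expression_intensity": A[k - 1],
        }
        row = {"slice": k}
        row.update({c: int(raw[c] >= 0.5) for c in REPORT_COLUMNS})
        row.update({f"weight_{c}": raw[c] for c in REPORT_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


class SEAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Binary softmax classifier with optional SE channel attention.

    With ``attention=True`` the forward pass is
    ``softmax(Wc (O * A(O)) + bc)`` where ``A`` comes from the two-layer
    squeeze/excitation block (hidden width ``max(1, C // reduction)``);
    with ``attention=False`` it is plain softmax regression, which serves
    as the classifier of the coarse-only / fine-only / plain-concatenation
    ablation arms.  Trained with Adam on cross-entropy.
    """

    def __init__(self, attention: bool = True, reduction: int = 4,
                 learning_rate: float = 1e-3, batch_size: int = 8,
                 epochs: int = 200, random_state: int = 0):
        self.attention = attention
        self.reduction = reduction
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _forward(self, X):
        p = self.params_
        if self.attention:
            hidden = relu(X @ p["W1"] + p["b1"])
            A = sigmoid(hidden @ p["W2"] + p["b2"])
            Xw = X * A
        else:
            hidden, A, Xw = None, None, X
        probs = softmax(Xw @ p["Wc"] + p["bc"], axis=-1)
        return probs, hidden, A, Xw

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("binary classifier needs exactly 2 classes")
        n, C = X.shape
        rng = np.random.default_rng(self.random_state)
        hidden_w = max(1, C // self.reduction)
        p: dict[str, np.ndarray] = {}
        if self.attention:
            p["W1"] = uniform_init(rng, (C, hidden_w), C)
            p["b1"] = np.zeros(hidden_w)
            p["W2"] = uniform_init(rng, (hidden_w, C), hidden_w)
            p["b2"] = np.zeros(C)
        p["Wc"] = uniform_init(rng, (C, 2), C)
        p["bc"] = np.zeros(2)
        self.params_ = p
        opt = Adam(p, lr=self.learning_rate)
        Y = np.eye(2)[y_idx]
        order = np.arange(n)
        self.loss_history_ = []
        for _ in range(self.epochs):
            rng.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                rows = order[start:start + self.batch_size]
                Xb, Yb = X[rows], Y[rows]
                B = len(rows)
                probs, hidden, A, Xw = self._forward(Xb)
                epoch_loss -= float(
                    (Yb * np.log(probs + 1e-12)).sum()
                )
                dlogits = (probs - Yb) / B
                grads = {
                    "Wc": Xw.T @ dlogits,
                    "bc": dlogits.sum(axis=0),
                }
                if self.attention:
                    dXw = dlogits @ p["Wc"].T
                    dA = dXw * Xb
                    dz2 = dA * A * (1 - A)
                    grads["W2"] = hidden.T @ dz2
                    grads["b2"] = dz2.sum(axis=0)
                    dhidden = (dz2 @ p["W2"].T) * (hidden > 0)
                    grads["W1"] = Xb.T @ dhidden
                    grads["b1"] = dhidden.sum(axis=0)
                opt.step(grads)
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = C
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        probs, *_ = self._forward(np.asarray(X, dtype=float))
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=-1)]

    def transform_attention(self, X) -> np.ndarray:
        """Per-input attention weights A(O) of shape (n, C)."""
        check_is_fitted(self, "params_")
        if not self.attention:
            raise ValueError("model was fitted without attention")
        p = self.params_
        return attention_weights(np.asarray(X, dtype=float),
                                 p["W1"], p["b1"], p["W2"], p["b2"])

    def mean_attention_weights(self, X) -> np.ndarray:
        """Channel weights averaged over a cohort (used for reporting)."""
        return self.transform_attention(X).mean(axis=0)
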