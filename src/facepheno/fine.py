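"""Fine-grained analysis: routed recurrent encoding of per-frame streams.

Each slice contributes an L x 11 matrix: column 0 the happiness-expression
intensity (the other five intensity channels are dropped as redundant),
columns 1-7 the full 7-class category probability distribution (its
flatness carries the *ambiguity* of the expression), and columns 8-10 the
Euler angles.

Two LSTM encoders of identical structure process the slices, selected by
the slice's coarse happy indicator: slices coarse-labelled "happy" go to
the happy-route encoder, all others to the other-route encoder.  Routing
lets each encoder specialize on temporal differences *within* slices whose
coarse summaries look alike.  The encoder's final hidden state t_k is
reduced by a slice-specific linear map LN_k to ``e`` values (e=1 by
default), and the K slice outputs concatenate into the fine feature
vector Of of length K*e.

During phase-1 training each route carries a small auxiliary logistic head
on the projected feature; it provides the group-label gradient and is
discarded afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, lstm_backward, lstm_forward, lstm_init, sigmoid, uniform_init
from .coarse import CoarseThresholds, binarize_happy, count_happy, happy_labels
from .streams import (
    HAPPY_INTENSITY_INDEX,
    SessionRecording,
    SliceStream,
)

__all__ = [
    "FINE_INPUT_DIM",
    "EncoderConfig",
    "assemble_fine_input",
    "RouteEncoder",
    "encode_slice",
    "project_feature",
    "fine_vector",
    "FineFeatureEncoder",
]

#: 1 (happy intensity) + 7 (category probabilities) + 3 (Euler angles).
FINE_INPUT_DIM = 11


@dataclass(frozen=True)
class EncoderConfig:
    """Structure of one route's recurrent encoder."""

    hidden_size: int = 32
    num_layers: int = 1
    e: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hidden_size >= self.e >= 1):
            raise ValueError("need hidden_size >= e >= 1")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


def assemble_fine_input(s: SliceStream) -> np.ndarray:
    """Stack the L x 11 fine input [happy intensity | 7 probs | pose]."""
    return np.concatenate(
        [
            s.intensities[:, HAPPY_INTENSITY_INDEX:HAPPY_INTENSITY_INDEX + 1],
            s.probabilities,
            s.pose,
        ],
        axis=1,
    )


class RouteEncoder:
    """One route: stacked LSTM + per-slice projections + auxiliary head.

    Parameters live in a flat dict (``lstm{i}.*``, ``proj{k}.*``, ``aux.*``)
    so a single Adam instance trains the whole route.
    """

    def __init__(self, d_in: int, K: int, config: EncoderConfig,
                 rng: np.random.Generator):
        self.d_in = d_in
        self.K = K
        self.config = config
        H, e = config.hidden_size, config.e
        params: dict[str, np.ndarray] = {}
        d = d_in
        for layer in range(config.num_layers):
            params.update(lstm_init(rng, d, H, f"lstm{layer}"))
            d = H
        for k in range(1, K + 1):
            params[f"proj{k}.W"] = uniform_init(rng, (H, e), H)
            params[f"proj{k}.b"] = np.zeros(e)
        params["aux.W"] = uniform_init(rng, (e, 1), e)
        params["aux.b"] = np.zeros(1)
        self.params = params

    def forward(self, X: np.ndarray):
        """Encode a batch (B, L, d_in) -> final hidden (B, H), with caches."""
        caches = []
        h = None
        inp = X
        for layer in range(self.config.num_layers):
            h, cache = lstm_forward(self.params, f"lstm{layer}", inp)
            caches.append(cache)
            inp = cache["H_seq"]
        return h, caches

    def backward(self, caches, dh_T: np.ndarray) -> dict:
        grads: dict[str, np.ndarray] = {}
        dh, dH_seq = dh_T, None
        for layer in range(self.config.num_layers - 1, -1, -1):
            g, dX = lstm_backward(self.params, caches[layer], dh, dH_seq)
            grads.update(g)
            dh, dH_seq = None, dX
        return grads

    def project(self, h: np.ndarray, k: int) -> np.ndarray:
        """Slice-specific linear map LN_k: hidden -> e values."""
        return h @ self.params[f"proj{k}.W"] + self.params[f"proj{k}.b"]


def encode_slice(fine_input: np.ndarray, happy_flag: int, encoders) -> np.ndarray:
    """Route one L x d slice to the encoder picked by its coarse happy flag.

    ``encoders`` is the (happy_route, other_route) pair; flag 1 selects the
    first.  Returns the final-step hidden state.
    """
    fine_input = np.asarray(fine_input, dtype=float)
    enc = encoders[0] if happy_flag == 1 else encoders[1]
    if fine_input.ndim != 2 or fine_input.shape[1] != enc.d_in:
        raise ValueError(
            f"expected (L, {enc.d_in}) input, got {fine_input.shape}"
        )
    h, _ = enc.forward(fine_input[None])
    return h[0]


def project_feature(t_k: np.ndarray, k: int, encoder: RouteEncoder) -> np.ndarray:
    """Apply the slice-k projection LN_k of ``encoder`` to a hidden vector."""
    return encoder.project(np.asarray(t_k, dtype=float)[None], k)[0]


def _session_happy_flags(session: SessionRecording, t2: int) -> np.ndarray:
    return np.array(
        [binarize_happy(count_happy(happy_labels(s)), t2) for s in session.slices]
    )


def fine_vector(session: SessionRecording, happy_flags, encoders) -> np.ndarray:
    """The K*e fine feature vector of one session, slice-ascending."""
    out = []
    for s, flag in zip(session.slices, happy_flags):
        enc = encoders[0] if flag == 1 else encoders[1]
        t_k = encode_slice(assemble_fine_input(s), int(flag), encoders)
        out.append(project_feature(t_k, s.index, enc))
    return np.concatenate(out)


class FineFeatureEncoder(TransformerMixin, BaseEstimator):
    """Trainable transformer: sessions -> (n, K*e) fine temporal features.

    ``fit`` trains the two route encoders (with their per-slice projections
    and auxiliary logistic heads) on the session group labels using Adam
    and binary cross-entropy; ``transform`` routes every slice by its
    coarse happy flag and returns the projected features.

    Parameters
    ----------
    hidden_size, num_layers, e : encoder structure (default 32 / 1 / 1).
    learning_rate, batch_size, epochs : phase-1 training schedule; the
        defaults follow the reference protocol (1e-5, 2 sessions, 200).
    t2 : happy-count threshold used for routing.
    random_state : seed for initialization and batch shuffling.
    """

    def __init__(self, hidden_size: int = 32, num_layers: int = 1, e: int = 1,
                 learning_rate: float = 1e-5, batch_size: int = 2,
                 epochs: int = 200, t2: int = 10, random_state: int = 0):
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.e = e
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.t2 = t2
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(self.hidden_size, self.num_layers, self.e,
                             self.random_state)

    @staticmethod
    def _labels(X, y):
        if y is None:
            y = [s.group for s in X]
        y = np.asarray(y)
        if y.dtype.kind in "US":
            y = (y == "ASD").astype(int)
        return y.astype(int)

    def _route_step(self, enc: RouteEncoder, opt: Adam, Xb: np.ndarray,
                    ks: np.ndarray, yb: np.ndarray) -> float:
        """One Adam step on a batch of same-route slices; returns the loss."""
        B = Xb.shape[0]
        h, caches = enc.forward(Xb)
        dh = np.zeros_like(h)
        grads = {k: np.zeros_like(v) for k, v in enc.params.items()}
        Wa, ba = enc.params["aux.W"], enc.params["aux.b"]
        loss = 0.0
        for k in np.unique(ks):
            rows = np.flatnonzero(ks == k)
            f = enc.project(h[rows], int(k))
            logit = f @ Wa + ba
            p = sigmoid(logit[:, 0])
            yk = yb[rows]
            eps = 1e-12
            loss -= float(
                (yk * np.log(p + eps) + (1 - yk) * np.log(1 - p + eps)).sum()
            )
            dlogit = ((p - yk) / B)[:, None]
            grads["aux.W"] += f.T @ dlogit
            grads["aux.b"] += dlogit.sum(axis=0)
            df = dlogit @ Wa.T
            grads[f"proj{int(k)}.W"] += h[rows].T @ df
            grads[f"proj{int(k)}.b"] += df.sum(axis=0)
            dh[rows] += df @ enc.params[f"proj{int(k)}.W"].T
        for key, g in enc.backward(caches, dh).items():
            grads[key] += g
        opt.step(grads)
        return loss / B

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        """Train the two route encoders on labelled sessions."""
        y = self._labels(X, y)
        if len(X) == 0:
            raise ValueError("empty training set")
        cfg = self._encoder_config()
        K = X[0].n_slices
        rng = np.random.default_rng(self.random_state)
        self.encoders_ = (
            RouteEncoder(FINE_INPUT_DIM, K, cfg, rng),
            RouteEncoder(FINE_INPUT_DIM, K, cfg, rng),
        )
        # Flatten the cohort into per-slice training rows.
        inputs, routes, slice_ks, labels, sess_ids = [], [], [], [], []
        for i, sess in enumerate(X):
            flags = _session_happy_flags(sess, self.t2)
            for s, flag in zip(sess.slices, flags):
                inputs.append(assemble_fine_input(s))
                routes.append(int(flag))
                slice_ks.append(s.index)
                labels.append(y[i])
                sess_ids.append(i)
        inputs = np.stack(inputs)
        routes = np.array(routes)
        slice_ks = np.array(slice_ks)
        labels = np.array(labels)
        sess_ids = np.array(sess_ids)
        for name, route_val in (("happy", 1), ("other", 0)):
            if not np.any(routes == route_val):
                warnings.warn(
                    f"no training slices on the {name} route; "
                    "its encoder keeps its initialization"
                )
        opts = tuple(
            Adam(enc.params, lr=self.learning_rate) for enc in self.encoders_
        )
        n_sessions = len(X)
        order = np.arange(n_sessions)
        self.loss_history_ = []
        for _ in range(self.epochs):
            rng.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, n_sessions, self.batch_size):
                batch_sessions = order[start:start + self.batch_size]
                in_batch = np.isin(sess_ids, batch_sessions)
                for enc, opt, route_val in zip(self.encoders_, opts, (1, 0)):
                    rows = np.flatnonzero(in_batch & (routes == route_val))
                    if rows.size == 0:
                        continue
                    epoch_loss += self._route_step(
                        enc, opt, inputs[rows], slice_ks[rows], labels[rows]
                    )
            self.loss_history_.append(epoch_loss)
        self.n_slices_ = K
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "encoders_")
        out = []
        for sess in X:
            flags = _session_happy_flags(sess, self.t2)
            out.append(fine_vector(sess, flags, self.encoders_))
        return np.stack(out)
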