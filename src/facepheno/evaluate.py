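"""Two-phase training, stratified three-fold evaluation, and the ablation.

Training is staged: phase 1 fits the two route-specific recurrent encoders
on the training folds (auxiliary heads supply the group-label gradient),
phase 2 freezes them and trains the attention + classifier stack on the
fused feature vectors.  Evaluation is stratified three-fold
cross-validation over subjects; the four-arm ablation compares
coarse-only, fine-only, plain concatenation, and concatenation with SE
attention under identical fold splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .coarse import CoarseFeatureExtractor, CoarseThresholds
from .fine import FineFeatureEncoder
from .fusion import SEAttentionClassifier, fuse

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "AblationResult",
    "stratified_three_fold",
    "accuracy_percent",
    "evaluate",
    "CoarseFinePipeline",
    "cross_validate_pipeline",
    "run_ablation",
    "ablation_table",
    "ARM_NAMES",
]

ARM_NAMES = ("coarse_only", "fine_only", "concatenated", "concatenated_attention")


@dataclass(frozen=True)
class TrainConfig:
    """One training phase's schedule.

    Defaults follow the reference protocol: learning rate 1e-5, batch
    size 2, 200 epochs over the training set, adaptive-moment optimizer,
    binary cross-entropy loss.
    """

    learning_rate: float = 1e-5
    batch_size: int = 2
    epochs: int = 200
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("training hyperparameters must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimizer is available")


@dataclass
class FoldSplit:
    """Three disjoint, class-stratified subject groups."""

    folds: list  # three arrays of subject indices
    class_tallies: list = field(default_factory=list)  # per fold {label: n}

    def __post_init__(self) -> None:
        n = sum(len(f) for f in self.folds)
        all_idx = np.sort(np.concatenate(self.folds))
        if not np.array_equal(all_idx, np.arange(n)):
            raise ValueError("folds must partition the cohort")


def stratified_three_fold(y, seed: int = 0) -> FoldSplit:
    """Split subjects into three class-stratified folds, shuffled by seed.

    ``y`` is the per-subject label sequence (or a list of sessions, whose
    ``group`` attributes are used).
    """
    if len(y) and hasattr(y[0], "group"):
        y = [s.group for s in y]
    y = np.asarray(y)
    if len(y) < 3:
        raise ValueError("need at least 3 subjects for three folds")
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    tallies = [
        {str(lbl): int((y[f] == lbl).sum()) for lbl in np.unique(y)} for f in folds
    ]
    return FoldSplit(folds=folds, class_tallies=tallies)


def accuracy_percent(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    return float((y_true == y_pred).mean() * 100.0)


def evaluate(model, X, y=None) -> float:
    """(correct / total) x 100 on a held-out set."""
    if y is None:
        y = [s.group for s in X]
    return accuracy_percent(np.asarray(y), model.predict(X))


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


class CoarseFinePipeline(ClassifierMixin, BaseEstimator):
    """End-to-end session classifier: coarse + routed-LSTM fine + SE fusion.

    ``features`` selects the ablation arm ("coarse", "fine" or "both");
    ``attention`` toggles the SE block in front of the softmax classifier.
    A prefit :class:`FineFeatureEncoder` may be passed as ``fine_encoder``
    so ablation arms can share phase-1 training; encoders stay frozen
    during phase 2 either way.
    """

    def __init__(self, features: str = "both", attention: bool = True,
                 t1: float = 0.3, t2: int = 10,
                 t3: float = float(np.pi / 3),
                 hidden_size: int = 32, num_layers: int = 1, e: int = 1,
                 encoder_train: TrainConfig | None = None,
                 fusion_train: TrainConfig | None = None,
                 reduction: int = 4, random_state: int = 0,
                 fine_encoder: FineFeatureEncoder | None = None):
        self.features = features
        self.attention = attention
        self.t1 = t1
        self.t2 = t2
        self.t3 = t3
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.e = e
        self.encoder_train = encoder_train
        self.fusion_train = fusion_train
        self.reduction = reduction
        self.random_state = random_state
        self.fine_encoder = fine_encoder

    def _feature_matrix(self, X) -> np.ndarray:
        blocks = []
        if self.features in ("coarse", "both"):
            blocks.append(self.coarse_extractor_.transform(X).astype(float))
        if self.features in ("fine", "both"):
            blocks.append(self.fine_encoder_.transform(X))
        if not blocks:
            raise ValueError("features must be 'coarse', 'fine' or 'both'")
        if len(blocks) == 2:
            return fuse(blocks[0], blocks[1])
        return blocks[0]

    def fit(self, X, y=None):
        if y is None:
            y = [s.group for s in X]
        y = np.asarray(y)
        et = self.encoder_train or TrainConfig()
        ft = self.fusion_train or TrainConfig()
        self.coarse_extractor_ = CoarseFeatureExtractor(
            t1=self.t1, t2=self.t2, t3=self.t3
        ).fit(X)
        if self.features in ("fine", "both"):
            if self.fine_encoder is not None and hasattr(
                self.fine_encoder, "encoders_"
            ):
                self.fine_encoder_ = self.fine_encoder
            else:
                self.fine_encoder_ = FineFeatureEncoder(
                    hidden_size=self.hidden_size, num_layers=self.num_layers,
                    e=self.e, learning_rate=et.learning_rate,
                    batch_size=et.batch_size, epochs=et.epochs, t2=self.t2,
                    random_state=self.random_state,
                ).fit(X, y)
        F = self._feature_matrix(X)
        self.classifier_ = SEAttentionClassifier(
            attention=self.attention, reduction=self.reduction,
            learning_rate=ft.learning_rate, batch_size=ft.batch_size,
            epochs=ft.epochs, random_state=self.random_state,
        ).fit(F, y)
        self.classes_ = self.classifier_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(self._feature_matrix(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict_proba(self._feature_matrix(X))

    def attention_weights(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        return self.classifier_.transform_attention(self._feature_matrix(X))


def cross_validate_pipeline(make_pipeline, X, y=None, seed: int = 0):
    """Three-fold CV of a pipeline factory; returns per-fold accuracies.

    ``make_pipeline(fold_seed)`` must return an unfitted estimator.  No
    leakage: everything (encoders included) is fitted on the training folds
    only.
    """
    if y is None:
        y = [s.group for s in X]
    y = np.asarray(y)
    split = stratified_three_fold(y, seed)
    accs = []
    for fold, test_idx in enumerate(split.folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        model = make_pipeline(_fold_seed(seed, fold))
        model.fit([X[i] for i in train_idx], y[train_idx])
        accs.append(accuracy_percent(y[test_idx],
                                     model.predict([X[i] for i in test_idx])))
    return np.array(accs)


@dataclass
class AblationResult:
    """Per-arm fold accuracies (percent) and their means."""

    fold_accuracies: dict  # arm name -> np.ndarray of 3 accuracies
    fold_split: FoldSplit

    @property
    def means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.fold_accuracies.items()}


def run_ablation(X, y=None, seed: int = 0,
                 thresholds: CoarseThresholds | None = None,
                 hidden_size: int = 32, num_layers: int = 1, e: int = 1,
                 encoder_train: TrainConfig | None = None,
                 fusion_train: TrainConfig | None = None,
                 reduction: int = 4) -> AblationResult:
    """The four-arm ablation under shared stratified three-fold splits.

    Arms: (1) coarse -> classifier, (2) fine -> classifier,
    (3) concatenated -> classifier, (4) concatenated -> SE attention ->
    classifier.  The fold splits are identical across arms, and the
    phase-1 encoders of each fold are shared by arms 2-4 (they are
    identically specified, so sharing only removes redundant recomputation).
    """
    if y is None:
        y = [s.group for s in X]
    y = np.asarray(y)
    th = thresholds or CoarseThresholds()
    et = encoder_train or TrainConfig()
    ft = fusion_train or TrainConfig()
    split = stratified_three_fold(y, seed)
    accs: dict[str, list] = {name: [] for name in ARM_NAMES}
    arm_spec = {
        "coarse_only": ("coarse", False),
        "fine_only": ("fine", False),
        "concatenated": ("both", False),
        "concatenated_attention": ("both", True),
    }
    for fold, test_idx in enumerate(split.folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        X_train = [X[i] for i in train_idx]
        X_test = [X[i] for i in test_idx]
        fs = _fold_seed(seed, fold)
        encoder = FineFeatureEncoder(
            hidden_size=hidden_size, num_layers=num_layers, e=e,
            learning_rate=et.learning_rate, batch_size=et.batch_size,
            epochs=et.epochs, t2=th.t2, random_state=fs,
        ).fit(X_train, y[train_idx])
        for name, (features, attention) in arm_spec.items():
            model = CoarseFinePipeline(
                features=features, attention=attention,
                t1=th.t1, t2=th.t2, t3=th.t3,
                hidden_size=hidden_size, num_layers=num_layers, e=e,
                encoder_train=et, fusion_train=ft, reduction=reduction,
                random_state=fs, fine_encoder=encoder,
            ).fit(X_train, y[train_idx])
            accs[name].append(accuracy_percent(y[test_idx],
                                               model.predict(X_test)))
    return AblationResult(
        fold_accuracies={k: np.array(v) for k, v in accs.items()},
        fold_split=split,
    )


def ablation_table(result: AblationResult) -> pd.DataFrame:
    """Tabulate the ablation: one row per arm, fold accuracies plus mean."""
    rows = []
    for name in ARM_NAMES:
        acc = result.fold_accuracies[name]
        row = {"experiment": name}
        row.update({f"fold_{i + 1}": round(float(a), 2)
                    for i, a in enumerate(acc)})
        row["mean_accuracy"] = round(float(np.mean(acc)), 2)
        rows.append(row)
    return pd.DataFrame(rows)
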