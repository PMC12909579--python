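"""Two-tier classifier: CNN feature extractor (L1) + gradient boosting (L2).

The tier-1 CNN is trained end-to-end on 32x32 RGB images and then truncated
at its dropout layer; the activations feeding the dropout are the per-sample
embeddings.  Those embeddings, split 70/30 with class stratification, train
a tier-2 XGBoost or LightGBM multiclass model.  Every hyperparameter of both
tiers is exposed as a genotype dimension so the optimizers in
:mod:`stageopt.optimizer` can search them; the fitness surfaced to the
optimizer is always the multiclass MCC from :mod:`stageopt.metrics`.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``transform`` for embeddings, trailing-underscore fitted
attributes) and compose with sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedShuffleSplit

from ._nn import SmallCNN
from .metrics import ClassificationReport, classification_report, mcc_multiclass, confusion_matrix
from .search_space import builtin_space

__all__ = [
    "TrainProtocol",
    "EmbeddingSet",
    "CNNClassifier",
    "BoosterClassifier",
    "DualLayerClassifier",
    "build_cnn",
    "train_eval_cnn",
    "truncate_and_embed",
    "split_70_30",
    "build_booster",
    "fit_dual_layer",
    "make_cnn_objective",
    "make_booster_objective",
]

LABELS = (0, 1, 2, 3)


@dataclass
class TrainProtocol:
    """Fixed training protocol for the tier-1 CNN."""

    batch_size: int = 512
    input_shape: tuple[int, int, int] = (32, 32, 3)
    n_classes: int = 4
    validation_fraction: float = 0.2  # internal early-stopping/fitness split


@dataclass
class EmbeddingSet:
    """Per-sample CNN feature vectors with labels and provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) aligned with labels")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def width(self) -> int:
        return self.features.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.features, columns=[f"f{i}" for i in range(self.width)]
        )
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingSet":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=np.float32), labels)


def _stratified_indices(y, test_fraction: float, seed: int):
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=test_fraction, random_state=seed
    )
    train_idx, test_idx = next(splitter.split(np.zeros(len(y)), y))
    return train_idx, test_idx


class CNNClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Tier-1 CNN on 32x32 RGB images, sklearn-style.

    Parameters mirror the published search ranges: learning rate
    [1e-4, 3e-3], dropout [0.05, 0.2], epochs [10, 30], 1-2 conv and dense
    layers with widths in [32, 96].  Early stopping monitors loss on an
    internal stratified validation split, with patience floor(epochs/3) and
    best-weight restoration; ``validation_mcc_`` (the fitness surfaced to
    the optimizers) is the multiclass MCC on that internal split.
    ``transform`` returns the dropout-input embeddings.
    """

    def __init__(
        self,
        learning_rate: float = 0.001,
        dropout: float = 0.1,
        epochs: int = 15,
        conv_widths: Sequence[int] = (32,),
        dense_widths: Sequence[int] = (64,),
        batch_size: int = 512,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.epochs = epochs
        self.conv_widths = conv_widths
        self.dense_widths = dense_widths
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed

    @classmethod
    def from_genotype(
        cls, genotype: Sequence[float], seed: int = 0, **overrides
    ) -> "CNNClassifier":
        """Decode a 9-dim L1 genotype (inactive widths dropped)."""
        space = builtin_space("L1_CNN")
        cfg = space.decode(genotype)
        conv = [cfg["conv_width_1"]]
        if "conv_width_2" in cfg:
            conv.append(cfg["conv_width_2"])
        dense = [cfg["dense_width_1"]]
        if "dense_width_2" in cfg:
            dense.append(cfg["dense_width_2"])
        return cls(
            learning_rate=cfg["learning_rate"],
            dropout=cfg["dropout"],
            epochs=cfg["epochs"],
            conv_widths=tuple(conv),
            dense_widths=tuple(dense),
            seed=seed,
            **overrides,
        )

    def _check_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != (32, 32, 3):
            raise ValueError(f"expected images of shape (n, 32, 32, 3), got {X.shape}")
        return X

    def fit(self, X, y) -> "CNNClassifier":
        X = self._check_images(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        tr, vl = _stratified_indices(y, self.validation_fraction, self.seed)
        self.model_ = SmallCNN(
            conv_widths=list(self.conv_widths),
            dense_widths=list(self.dense_widths),
            dropout=self.dropout,
            n_classes=4,
            seed=self.seed,
        )
        self.history_ = self.model_.fit(
            X[tr], y[tr], X[vl], y[vl],
            epochs=int(self.epochs),
            learning_rate=float(self.learning_rate),
            batch_size=int(self.batch_size),
        )
        val_pred = self.model_.predict(X[vl])
        self.validation_report_ = classification_report(y[vl], val_pred, LABELS)
        self.validation_mcc_ = self.validation_report_.mcc
        self.n_features_out_ = self.model_.embedding_width
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._require_fitted()
        return self.model_.predict_proba(self._check_images(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def transform(self, X) -> np.ndarray:
        """Dropout-input embeddings (inference mode, dropout inactive)."""
        self._require_fitted()
        return self.model_.embed(self._check_images(X))

    def score(self, X, y) -> float:
        """Multiclass MCC (the framework's objective), not accuracy."""
        cm = confusion_matrix(np.asarray(y), self.predict(X), LABELS)
        return mcc_multiclass(cm)

    def _require_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("CNNClassifier is not fitted")


class BoosterClassifier(BaseEstimator, ClassifierMixin):
    """Tier-2 multiclass boosted-tree model configured from a genotype.

    ``kind`` selects XGBoost (6 tuned parameters) or LightGBM (10 tuned
    parameters); every other setting stays at the library default, except
    that LightGBM's bagging is given a frequency of 1 so the tuned bagging
    fraction actually takes effect, and both libraries are pinned to one
    thread and the pipeline seed for reproducibility.
    """

    def __init__(self, kind: str = "lgbm", genotype: Optional[Sequence[float]] = None,
                 seed: int = 0):
        self.kind = kind
        self.genotype = genotype
        self.seed = seed

    def _make_model(self):
        if self.kind not in ("xgb", "lgbm"):
            raise ValueError(f"unknown booster kind {self.kind!r}")
        space = builtin_space("L2_XGB" if self.kind == "xgb" else "L2_LGBM")
        g = self.genotype
        if g is None:
            g = (space.lows + space.highs) / 2.0
        g = np.asarray(g, dtype=float)
        if g.shape != (space.dimensionality,):
            raise ValueError(
                f"{self.kind} genotype needs {space.dimensionality} values, "
                f"got {g.shape}"
            )
        cfg = space.decode(g)
        if self.kind == "xgb":
            from xgboost import XGBClassifier

            return XGBClassifier(
                learning_rate=cfg["learning_rate"],
                min_child_weight=cfg["min_child_weight"],
                subsample=cfg["subsample"],
                colsample_bytree=cfg["colsample_bytree"],
                max_depth=cfg["max_depth"],
                gamma=cfg["gamma"],
                random_state=self.seed,
                n_jobs=1,
            )
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=cfg["n_rounds"],
            max_depth=cfg["max_depth"],
            num_leaves=cfg["n_leaves"],
            min_child_weight=cfg["min_child_weight"],
            feature_fraction=cfg["feature_fraction"],
            bagging_fraction=cfg["bagging_fraction"],
            bagging_freq=1,
            min_split_gain=cfg["min_split_gain"],
            reg_alpha=cfg["lambda_l1"],
            reg_lambda=cfg["lambda_l2"],
            learning_rate=cfg["learning_rate"],
            random_state=self.seed,
            n_jobs=1,
            verbose=-1,
        )

    def fit(self, X, y) -> "BoosterClassifier":
        self.model_ = self._make_model()
        self.classes_ = np.unique(y)
        self.model_.fit(np.asarray(X), np.asarray(y))
        return self

    def predict(self, X) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return self.model_.predict(np.asarray(X))

    def predict_proba(self, X) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return self.model_.predict_proba(np.asarray(X))

    def score(self, X, y) -> float:
        cm = confusion_matrix(np.asarray(y), self.predict(X), LABELS)
        return mcc_multiclass(cm)


class DualLayerClassifier(BaseEstimator, ClassifierMixin):
    """Full two-tier pipeline: CNN -> embeddings -> 70/30 split -> booster.

    ``fit`` trains the CNN on the images, embeds every sample, makes a
    stratified 70/30 embedding split, trains the booster on the 70% side and
    evaluates both tiers on the 30% side.  Fitted attributes:
    ``l1_report_`` / ``l2_report_`` (tier reports on the common test split),
    ``embeddings_`` (the full :class:`EmbeddingSet`).
    """

    def __init__(
        self,
        cnn_genotype: Optional[Sequence[float]] = None,
        booster_kind: str = "lgbm",
        booster_genotype: Optional[Sequence[float]] = None,
        protocol: Optional[TrainProtocol] = None,
        seed: int = 0,
    ):
        self.cnn_genotype = cnn_genotype
        self.booster_kind = booster_kind
        self.booster_genotype = booster_genotype
        self.protocol = protocol
        self.seed = seed

    def fit(self, X, y) -> "DualLayerClassifier":
        proto = self.protocol or TrainProtocol()
        y = np.asarray(y, dtype=np.int64)
        if self.cnn_genotype is not None:
            cnn = CNNClassifier.from_genotype(
                self.cnn_genotype, seed=self.seed,
                batch_size=proto.batch_size,
                validation_fraction=proto.validation_fraction,
            )
        else:
            cnn = CNNClassifier(seed=self.seed, batch_size=proto.batch_size)
        self.cnn_ = cnn.fit(X, y)
        features = self.cnn_.transform(X)
        self.embeddings_ = EmbeddingSet(
            features, y,
            provenance={"seed": self.seed, "cnn_params": cnn.get_params()},
        )
        train_idx, test_idx = _stratified_indices(y, 0.3, self.seed)
        self.train_idx_, self.test_idx_ = train_idx, test_idx
        self.booster_ = BoosterClassifier(
            self.booster_kind, self.booster_genotype, seed=self.seed
        ).fit(features[train_idx], y[train_idx])
        X = np.asarray(X, dtype=np.float32)
        self.l1_report_ = classification_report(
            y[test_idx], self.cnn_.predict(X[test_idx]), LABELS
        )
        self.l2_report_ = classification_report(
            y[test_idx], self.booster_.predict(features[test_idx]), LABELS
        )
        self.classes_ = np.unique(y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.booster_.predict(self.cnn_.transform(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.booster_.predict_proba(self.cnn_.transform(X))

    def score(self, X, y) -> float:
        cm = confusion_matrix(np.asarray(y), self.predict(X), LABELS)
        return mcc_multiclass(cm)


# ---------------------------------------------------------------------------
# functional surface (thin wrappers over the estimators)

def build_cnn(genotype: Sequence[float], protocol: Optional[TrainProtocol] = None,
              seed: int = 0) -> CNNClassifier:
    proto = protocol or TrainProtocol()
    return CNNClassifier.from_genotype(
        genotype, seed=seed, batch_size=proto.batch_size,
        validation_fraction=proto.validation_fraction,
    )


def train_eval_cnn(
    model: CNNClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    eval_set: tuple[np.ndarray, np.ndarray],
) -> tuple[CNNClassifier, ClassificationReport]:
    """Fit on the training set, report on the held-out evaluation set."""
    x_tr, y_tr = train_set
    x_ev, y_ev = eval_set
    if len(x_tr) == 0 or len(x_ev) == 0:
        raise ValueError("train and eval sets must be non-empty")
    model.fit(x_tr, y_tr)
    report = classification_report(y_ev, model.predict(x_ev), LABELS)
    return model, report


def truncate_and_embed(model: CNNClassifier, X, y) -> EmbeddingSet:
    """Embeddings of a dataset from a fitted CNN (dropout-layer output)."""
    return EmbeddingSet(model.transform(X), np.asarray(y),
                        provenance={"cnn_params": model.get_params()})


def split_70_30(embeddings: EmbeddingSet, seed: int = 0
                ) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Stratified 70/30 partition of an embedding set."""
    y = embeddings.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class to split 70/30")
    tr, te = _stratified_indices(y, 0.3, seed)
    prov = dict(embeddings.provenance, split_seed=seed)
    return (
        EmbeddingSet(embeddings.features[tr], y[tr], dict(prov, part="train")),
        EmbeddingSet(embeddings.features[te], y[te], dict(prov, part="test")),
    )


def build_booster(kind: str, genotype: Sequence[float], seed: int = 0
                  ) -> BoosterClassifier:
    b = BoosterClassifier(kind, genotype, seed=seed)
    b._make_model()  # validate kind/genotype eagerly
    return b


def fit_dual_layer(
    X, y,
    cnn_genotype: Sequence[float],
    booster_kind: str,
    booster_genotype: Sequence[float],
    protocol: Optional[TrainProtocol] = None,
    seed: int = 0,
) -> tuple[ClassificationReport, ClassificationReport, EmbeddingSet]:
    """Run the full chain; returns (L1 report, L2 report, embeddings)."""
    clf = DualLayerClassifier(
        cnn_genotype, booster_kind, booster_genotype, protocol, seed
    ).fit(X, y)
    return clf.l1_report_, clf.l2_report_, clf.embeddings_


# ---------------------------------------------------------------------------
# optimizer objectives

def make_cnn_objective(X, y, protocol: Optional[TrainProtocol] = None,
                       seed: int = 0):
    """Objective for the L1 search: genotype -> internal-validation MCC."""

    def objective(genotype) -> float:
        model = build_cnn(genotype, protocol, seed=seed)
        model.fit(X, y)
        return model.validation_mcc_

    return objective


def make_booster_objective(kind: str, train: EmbeddingSet, seed: int = 0,
                           validation_fraction: float = 0.2):
    """Objective for the L2 search: genotype -> MCC on an internal
    stratified validation split of the training embeddings."""
    tr, vl = _stratified_indices(train.labels, validation_fraction, seed)
    x_tr, y_tr = train.features[tr], train.labels[tr]
    x_vl, y_vl = train.features[vl], train.labels[vl]

    def objective(genotype) -> float:
        model = BoosterClassifier(kind, genotype, seed=seed).fit(x_tr, y_tr)
        cm = confusion_matrix(y_vl, model.predict(x_vl), LABELS)
        return mcc_multiclass(cm)

    return objective
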