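"""Normalization + PCA reduction, the uniform classifier contract, and
feature-layer fusion.

Reduction fits a z-score scaler and PCA on training data only and retains
the principal components whose explained-variance ratio (contribution rate)
exceeds 1% (strict).  Classifier families: ``knn`` and ``random_forest``
(scikit-learn) on flat vectors, and the numpy sequence nets (``cnn1d``,
``tcn``, ``lstm``, ``tcn_cnn``, ``lstm_cnn``) on ``[batch, channels, 8]``
fine-grained curves (``cnn1d`` also accepts flat vectors, read as a
one-channel sequence over the feature axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .nn import SequenceClassifier, TrainConfig
from .preprocess import EMOTIONS

SKLEARN_FAMILIES = ("knn", "random_forest")
NEURAL_FAMILIES = ("cnn1d", "tcn", "lstm", "tcn_cnn", "lstm_cnn")
SEQUENCE_FAMILIES = ("tcn", "lstm", "tcn_cnn", "lstm_cnn")


@dataclass
class ReductionModel:
    """Fitted z-score + PCA projection with the >1% contribution-rate rule."""

    scaler: StandardScaler
    pca: PCA
    kept_feature_idx: np.ndarray
    n_components: int
    contribution_rates: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = self.scaler.transform(X[:, self.kept_feature_idx])
        return self.pca.transform(Z)[:, : self.n_components]

    def transform_curves(self, X3: np.ndarray) -> np.ndarray:
        """Apply the fitted projection to every time column of (B, F, T)."""
        B, F, T = X3.shape
        flat = np.moveaxis(X3, 1, 2).reshape(B * T, F)
        red = self.transform(flat)
        return np.moveaxis(red.reshape(B, T, self.n_components), 2, 1)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Back to the (kept) standardized feature space (retained subspace)."""
        full = np.zeros((Z.shape[0], self.pca.n_components_))
        full[:, : self.n_components] = Z
        return self.pca.inverse_transform(full)


def fit_reduction(train_features: np.ndarray,
                  contribution_threshold: float = 0.01) -> ReductionModel:
    """Fit z-score normalization then PCA, keeping components with
    explained-variance ratio strictly above ``contribution_threshold``.

    Zero-variance features are dropped with a warning before scaling.  At
    least one component is always retained.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim == 3:
        B, F, T = X.shape
        X = np.moveaxis(X, 1, 2).reshape(B * T, F)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    # constant columns (zero peak-to-peak) carry no information and break scaling
    kept = np.flatnonzero(np.ptp(X, axis=0) > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(kept)} zero-variance feature(s)")
    if len(kept) == 0:
        raise ValueError("all features have zero variance")
    scaler = StandardScaler().fit(X[:, kept])
    Z = scaler.transform(X[:, kept])
    pca = PCA(n_components=min(Z.shape), svd_solver="full").fit(Z)
    rates = pca.explained_variance_ratio_
    # strict "greater than": a rate equal to the threshold (up to float fuzz)
    # is not retained
    n_comp = max(1, int(np.sum(rates > contribution_threshold + 1e-12)))
    return ReductionModel(scaler, pca, kept, n_comp, rates)


@dataclass
class ClassifierSpec:
    """Family + hyperparameters + seed + input-shape contract."""

    family: str
    params: Dict = field(default_factory=dict)
    seed: int = 0
    input_shape: str = "flat"  # "flat" or "curves"

    def __post_init__(self) -> None:
        if self.family not in SKLEARN_FAMILIES + NEURAL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in SEQUENCE_FAMILIES and self.input_shape != "curves":
            raise ValueError(f"{self.family} requires input_shape='curves'")
        if self.family in SKLEARN_FAMILIES and self.input_shape != "flat":
            raise ValueError(f"{self.family} requires input_shape='flat'")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    model: object
    classes: List[str]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        want3 = self.spec.family in NEURAL_FAMILIES
        if want3 and X.ndim == 2:
            if self.spec.family != "cnn1d":
                raise ValueError(
                    f"{self.spec.family} expects [batch, channels, time] input, got 2-D"
                )
            X = X[:, None, :]  # one channel over the feature axis
        if want3 and X.ndim != 3:
            raise ValueError(f"expected 3-D input, got shape {X.shape}")
        if not want3 and X.ndim != 2:
            raise ValueError(f"{self.spec.family} expects flat 2-D input, got shape {X.shape}")
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(X)
        if self.spec.family in SKLEARN_FAMILIES:
            return np.asarray(self.model.predict(X))
        idx = self.model.predict(X)
        return np.array([self.classes[i] for i in idx], dtype=object)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores aligned with ``self.classes`` (for AUC)."""
        X = self._prepare(X)
        if self.spec.family in SKLEARN_FAMILIES:
            proba = self.model.predict_proba(X)
            # align sklearn's class order with ours
            order = [list(self.model.classes_).index(c) for c in self.classes]
            return proba[:, order]
        return self.model.predict_proba(X)


def fit_classifier(spec: ClassifierSpec, X: np.ndarray, y: Sequence[str],
                   classes: Sequence[str] = EMOTIONS) -> FittedClassifier:
    """Fit a classifier per the spec's family and shape contract."""
    y = np.asarray(y, dtype=object)
    classes = [c for c in classes if c in set(y)] or sorted(set(y))
    X = np.asarray(X, dtype=float)
    if spec.family == "knn":
        model = KNeighborsClassifier(**{"n_neighbors": 5, **spec.params})
        model.fit(X, y)
    elif spec.family == "random_forest":
        model = RandomForestClassifier(
            **{"n_estimators": 200, "random_state": spec.seed, **spec.params}
        )
        model.fit(X, y)
    else:
        tc = TrainConfig(**{"seed": spec.seed, **spec.params.get("train", {})})
        arch = {k: v for k, v in spec.params.items() if k != "train"}
        model = SequenceClassifier(spec.family, n_classes=len(classes),
                                   train_config=tc, **arch)
        y_idx = np.array([classes.index(v) for v in y])
        if X.ndim == 2:
            if spec.family != "cnn1d":
                raise ValueError(f"{spec.family} expects [batch, channels, time] input")
            X = X[:, None, :]
        model.fit(X, y_idx)
    return FittedClassifier(spec, model, list(classes))


def feature_layer_fusion(blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate per-modality reduced features sample-wise.

    Flat 2-D blocks concatenate column-wise (eye || audio || video); 3-D
    fine-grained blocks concatenate along the channel axis, preserving the
    time axis.  All blocks must share the sample count and dimensionality.
    """
    if not blocks:
        raise ValueError("nothing to fuse")
    dims = {b.ndim for b in blocks}
    if len(dims) != 1 or dims <= {0, 1} or next(iter(dims)) not in (2, 3):
        raise ValueError("blocks must all be 2-D or all 3-D")
    ns = {b.shape[0] for b in blocks}
    if len(ns) != 1:
        raise ValueError("blocks must share the sample count")
    return np.concatenate(list(blocks), axis=1)
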