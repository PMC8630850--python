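"""The hybrid model: CNN feature learning + gradient-boosted classification.

``HybridDMRClassifier.fit`` first trains the convolutional network on the
labeled one-hot windows, then re-expresses every window as the 32 pooled
first-conv-layer activations, and finally fits an XGBoost model on those
features. Prediction always goes through the boosted stage — the CNN's own
softmax head is used only to drive feature learning. The boosted stage
counters class imbalance with a positive-class weight of
n_nonDMR / n_DMR.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .features import reexpress
from .network import ConvNetClassifier


def make_boosted_classifier(
    n_estimators: int = 200,
    max_depth: int = 6,
    learning_rate: float = 0.1,
    scale_pos_weight: float = 1.0,
    seed: int = 0,
    **extra,
) -> XGBClassifier:
    """The XGBoost stage with the package defaults."""
    return XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        scale_pos_weight=scale_pos_weight,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        **extra,
    )


def train_classifier(features: np.ndarray, labels, params: dict | None = None,
                     seed: int = 0) -> XGBClassifier:
    """Fit the boosted-tree stage on an (n, 32) feature matrix.

    Applies the default imbalance weight (n_negative / n_positive) on the
    positive class unless overridden in ``params``.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if features.size == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    params = dict(params or {})
    if "scale_pos_weight" not in params:
        n_pos = int((labels == 1).sum())
        n_neg = int((labels == 0).sum())
        params["scale_pos_weight"] = n_neg / max(n_pos, 1)
    model = make_boosted_classifier(seed=seed, **params)
    model.fit(features, labels)
    return model


def feature_importance(model: XGBClassifier) -> list[tuple[int, float]]:
    """Gain-based importance per feature, sorted descending.

    Every input feature appears in the ranking; features never used in a
    split score 0.
    """
    check_is_fitted(model)
    booster = model.get_booster()
    gains = booster.get_score(importance_type="gain")
    n = model.n_features_in_
    scores = np.zeros(n)
    for name, g in gains.items():
        scores[int(name.lstrip("f"))] = g
    order = np.argsort(-scores, kind="stable")
    return [(int(i), float(scores[i])) for i in order]


class HybridDMRClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage DMR classifier: CNN features into gradient-boosted trees.

    Parameters
    ----------
    network : ConvNetClassifier, optional
        Prototype for the feature-learning stage (cloned at fit time).
    n_estimators, max_depth, learning_rate
        XGBoost stage hyperparameters.
    pooling : {"max", "mean"}
        How per-position conv-1 activations become one feature per kernel.
    extra_features : callable, optional
        Hook mapping the raw one-hot batch to extra named feature columns
        appended after the learned ones: returns (names, matrix).
    random_state : int
        Seeds both stages.

    Attributes
    ----------
    network_ : fitted ConvNetClassifier
    booster_ : fitted XGBClassifier
    feature_importances_ : gain importances aligned to feature ids
    """

    def __init__(self, network=None, n_estimators=200, max_depth=6,
                 learning_rate=0.1, pooling="mean", extra_features=None,
                 random_state=0):
        self.network = network
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.pooling = pooling
        self.extra_features = extra_features
        self.random_state = random_state

    def _features(self, X) -> np.ndarray:
        feats = reexpress(self.network_, X, pooling=self.pooling)
        if self.extra_features is not None:
            _, extra = self.extra_features(X)
            feats = np.concatenate([feats, np.asarray(extra)], axis=1)
        return feats

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        proto = self.network if self.network is not None else ConvNetClassifier()
        net = clone(proto)
        net.set_params(random_state=self.random_state)
        self.network_ = net.fit(X, y)
        self.classes_ = self.network_.classes_
        yi = (y == self.classes_[1]).astype(np.int64)
        feats = self._features(X)
        self.booster_ = train_classifier(
            feats, yi,
            params={
                "n_estimators": self.n_estimators,
                "max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
            },
            seed=self.random_state,
        )
        ranking = feature_importance(self.booster_)
        imp = np.zeros(feats.shape[1])
        for i, s in ranking:
            imp[i] = s
        self.feature_importances_ = imp
        self.feature_ranking_ = ranking
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        return self.booster_.predict_proba(self._features(np.asarray(X, dtype=np.float32)))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba >= 0.5).astype(int)]
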