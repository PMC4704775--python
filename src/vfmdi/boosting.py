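"""Stagewise additive logistic regression (LogitBoost-style) classifier.

Fits an additive model F(x) = sum_m 0.5 * f_m(x) to the binomial
log-likelihood by Newton steps: at each stage the working response
z = (y - p) / (p (1 - p)) is fitted with a weighted depth-1 regression tree
(weights w = p (1 - p)), and the class probability is the logistic of 2F.
Working responses are clipped (``z_max``) for numerical stability, the
standard safeguard.  Scikit-learn compatible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["AdditiveLogisticRegression"]


class AdditiveLogisticRegression(ClassifierMixin, BaseEstimator):
    """LogitBoost with regression stumps.

    Parameters
    ----------
    n_estimators :
        Number of boosting stages.
    learning_rate :
        Shrinkage applied to each stage.
    max_depth :
        Depth of the base regression trees (1 = stumps).
    z_max :
        Clip limit for the working response.
    """

    def __init__(
        self,
        n_estimators: int = 30,
        learning_rate: float = 1.0,
        max_depth: int = 1,
        z_max: float = 4.0,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.z_max = z_max
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classifier: need exactly 2 classes")
        yb = (y == self.classes_[1]).astype(float)
        n = len(yb)
        F = np.zeros(n)
        p = np.full(n, 0.5)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            w = np.clip(p * (1.0 - p), 1e-8, None)
            z = np.clip((yb - p) / w, -self.z_max, self.z_max)
            tree = DecisionTreeRegressor(
                max_depth=self.max_depth, random_state=self.random_state
            )
            tree.fit(X, z, sample_weight=w)
            self.estimators_.append(tree)
            F += self.learning_rate * 0.5 * tree.predict(X)
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for tree in self.estimators_:
            F += self.learning_rate * 0.5 * tree.predict(X)
        return 2.0 * F

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
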