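"""Twice-nested cross-validated classification and ROC reporting.

Outer stratified k-fold cross-validation estimates generalization; inside
each outer training set, a wrapper performs greedy forward feature selection
scored by inner-CV AUC (level 2), then tunes hyperparameters by inner-CV
grid search on the selected subset (level 1), and the winning configuration
is refitted on the full outer-train set.  Standardization and orthogonal
projection are fitted inside the outer-train set only, so no test-fold
information leaks into the model.  Out-of-fold probabilities are pooled
into a ROC curve, AUC, and sensitivity/specificity/accuracy at requested
sensitivity targets.

The statsmodels-style entry points are :class:`MDIModel` (built from a
feature table or, via :meth:`MDIModel.from_records`, from raw shock records
with per-fold prototype selection) and the :class:`MDIResults` object its
``fit`` returns.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .boosting import AdditiveLogisticRegression
from .exceptions import (
    ConfigError,
    DataError,
    EvaluationError,
    ParameterError,
    StratificationError,
)
from .feature_space import orthogonalize, reduce as reduce_components, split_outcome

__all__ = [
    "ModelSpec",
    "ROCCurve",
    "CVReport",
    "roc_curve",
    "metrics_at_sensitivity",
    "nested_cv",
    "fit_outer_fold",
    "train_final",
    "FittedMDI",
    "MDIModel",
    "MDIResults",
    "default_hyperparameters",
]

ALGORITHMS = (
    "ADDITIVE_LOGISTIC",
    "RANDOM_FOREST",
    "BAYES_LOGISTIC",
    "BACKPROP_NN",
    "ADABOOST_TREES",
)


def default_hyperparameters(algorithm: str) -> dict:
    """Reference hyperparameters per algorithm (the tuned values reported
    for the clinical comparison; grid search at L1 may override them)."""
    return {
        "ADDITIVE_LOGISTIC": {"n_estimators": 30, "learning_rate": 1.0},
        "RANDOM_FOREST": {"n_estimators": 100, "max_features": 0.8},
        "BAYES_LOGISTIC": {"prior": "gaussian", "C": 1.0},
        "BACKPROP_NN": {"max_iter": 500, "learning_rate_init": 0.3, "momentum": 0.4},
        "ADABOOST_TREES": {"n_estimators": 100, "criterion": "entropy"},
    }[algorithm]


@dataclass
class ModelSpec:
    """Classifier choice, hyperparameter grid, and selection cap."""

    algorithm: str = "ADDITIVE_LOGISTIC"
    param_grid: List[dict] = field(default_factory=lambda: [{}])
    max_features: int = 20

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        if len(self.param_grid) == 0 or self.max_features < 1:
            raise ParameterError("grid must be nonempty and max_features >= 1")


def build_estimator(algorithm: str, params: dict, seed: Optional[int]):
    """Instantiate a classifier with defaults overridden by grid params."""
    p = {**default_hyperparameters(algorithm), **params}
    if algorithm == "ADDITIVE_LOGISTIC":
        return AdditiveLogisticRegression(random_state=seed, **p)
    if algorithm == "RANDOM_FOREST":
        return RandomForestClassifier(random_state=seed, **p)
    if algorithm == "BAYES_LOGISTIC":
        # MAP logistic regression: gaussian prior = L2 (sklearn default
        # ridge), laplace prior = L1
        prior = p.pop("prior", "gaussian")
        if prior == "laplace":
            return LogisticRegression(penalty="l1", solver="liblinear",
                                      max_iter=2000, random_state=seed, **p)
        return LogisticRegression(max_iter=2000, random_state=seed, **p)
    if algorithm == "BACKPROP_NN":
        return MLPClassifier(solver="sgd", hidden_layer_sizes=(10,),
                             random_state=seed, **p)
    if algorithm == "ADABOOST_TREES":
        crit = p.pop("criterion", "entropy")
        depth = p.pop("max_depth", 3)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion=crit, max_depth=depth),
            random_state=seed, **p)
    raise ParameterError(algorithm)


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray
    outcomes: np.ndarray


def roc_curve(scores: Sequence[float], outcomes: Sequence[int]) -> ROCCurve:
    """ROC points and trapezoid AUC (equals Mann–Whitney concordance)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC undefined with a single class")
    fpr, tpr, thr = _sk_roc(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thr, fpr, tpr, auc, s, y)


def metrics_at_sensitivity(
    roc: ROCCurve, targets: Sequence[float] = (0.80, 0.90)
) -> Dict[float, dict]:
    """Largest threshold whose sensitivity meets each target.

    Achieved sensitivity may exceed the target on finite data; if no
    threshold reaches it (cannot happen with the degenerate -inf point,
    kept as a guard), metrics at threshold 0 are reported.
    """
    n_pos = int(np.sum(roc.outcomes == 1))
    n_neg = int(np.sum(roc.outcomes == 0))
    out = {}
    for t in targets:
        if not 0.0 < t < 1.0:
            raise ParameterError("sensitivity targets must be in (0, 1)")
        ok = np.flatnonzero(roc.tpr >= t)
        if ok.size:
            i = ok[0]          # thresholds are nonincreasing -> largest
            thr = float(roc.thresholds[i])
            sens, spec = float(roc.tpr[i]), 1.0 - float(roc.fpr[i])
        else:
            thr, sens, spec = 0.0, 1.0, 0.0
        acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
        out[t] = {"threshold": thr, "sensitivity": sens,
                  "specificity": spec, "accuracy": acc}
    return out


def _best_accuracy(roc: ROCCurve) -> Tuple[float, float]:
    n_pos = int(np.sum(roc.outcomes == 1))
    n_neg = int(np.sum(roc.outcomes == 0))
    acc = (roc.tpr * n_pos + (1.0 - roc.fpr) * n_neg) / (n_pos + n_neg)
    i = int(np.argmax(acc))
    return float(acc[i]), float(roc.thresholds[i])


@dataclass
class CVReport:
    """Out-of-fold cross-validation results."""

    oof_prob: np.ndarray
    outcomes: np.ndarray
    roc: ROCCurve
    auc: float
    accuracy_best: float
    best_threshold: float
    at_sensitivity: Dict[float, dict]
    fold_features: List[List[str]]
    fold_params: List[dict]
    folds: List[Tuple[np.ndarray, np.ndarray]]


# --------------------------------------------------------------------------
# Nested cross-validation
# --------------------------------------------------------------------------

def _make_folds(y, k, seed, groups=None):
    y = np.asarray(y)
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(cv.split(np.zeros_like(y), y, groups))
    else:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(cv.split(np.zeros_like(y), y))
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 1:
            raise StratificationError("a fold lost an outcome class")
    return splits


def _inner_auc(est_factory, X, y, cols, inner_splits) -> float:
    aucs = []
    for tr, te in inner_splits:
        est = est_factory()
        est.fit(X[np.ix_(tr, cols)], y[tr])
        p = est.predict_proba(X[np.ix_(te, cols)])[:, 1]
        aucs.append(roc_curve(p, y[te]).auc)
    return float(np.mean(aucs))


def _forward_select(est_factory, X, y, max_features, inner_splits) -> List[int]:
    """Greedy forward selection by mean inner-CV AUC; ties -> lower index."""
    n_feat = X.shape[1]
    selected: List[int] = []
    best_score = -np.inf
    remaining = list(range(n_feat))
    while remaining and len(selected) < max_features:
        scores = [
            _inner_auc(est_factory, X, y, selected + [j], inner_splits)
            for j in remaining
        ]
        j_best = int(np.argmax(scores))     # argmax takes first on ties
        if scores[j_best] <= best_score + 1e-12:
            break
        best_score = scores[j_best]
        selected.append(remaining.pop(j_best))
    if not selected:
        selected = [0] if n_feat else []
    return selected


def _tune(spec: ModelSpec, X, y, cols, inner_splits, seed) -> dict:
    if len(spec.param_grid) == 1:
        return spec.param_grid[0]
    best, best_score = spec.param_grid[0], -np.inf
    for params in spec.param_grid:
        score = _inner_auc(
            lambda: build_estimator(spec.algorithm, params, seed), X, y, cols,
            inner_splits,
        )
        if score > best_score + 1e-12:
            best, best_score = params, score
    return best


@dataclass
class _FoldModel:
    scaler: Optional[StandardScaler]
    projection: Optional[object]
    retained: int
    selected: List[int]
    params: dict
    estimator: object
    feature_names: List[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = X
        if self.scaler is not None:
            Z = self.scaler.transform(Z)
        if self.projection is not None:
            Z = (Z @ self.projection)[:, : self.retained]
        return Z[:, self.selected]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(self.transform(X))[:, 1]


def fit_outer_fold(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    train_idx: np.ndarray,
    seed: int,
    inner_k: int = 10,
    project: bool = True,
    var_threshold: float = 0.99,
    feature_names: Optional[List[str]] = None,
) -> _FoldModel:
    """Fit one outer fold's full pipeline using training rows only."""
    Xtr, ytr = X[train_idx], y[train_idx]
    scaler = proj_mat = None
    retained = Xtr.shape[1]
    Z = Xtr
    if project:
        scaler = StandardScaler().fit(Xtr)
        Zs = scaler.transform(Xtr)
        # principal axes of the training cloud
        _, s, Vt = np.linalg.svd(Zs - Zs.mean(axis=0), full_matrices=False)
        eig = s**2
        frac = np.cumsum(eig) / eig.sum()
        retained = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
        proj_mat = Vt.T
        Z = (Zs @ proj_mat)[:, :retained]
    inner = _make_folds(ytr, inner_k, seed + 1)
    factory = lambda: build_estimator(spec.algorithm, spec.param_grid[0], seed)
    selected = _forward_select(factory, Z, ytr, spec.max_features, inner)
    params = _tune(spec, Z, ytr, selected, inner, seed)
    est = build_estimator(spec.algorithm, params, seed)
    est.fit(Z[:, selected], ytr)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    sel_names = ([f"pc{j + 1}" for j in selected] if project
                 else [names[j] for j in selected])
    fm = _FoldModel(scaler, proj_mat, retained, selected, params, est, sel_names)
    return fm


def nested_cv(
    matrix: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    seed: int = 0,
    groups: Optional[Sequence] = None,
    inner_k: Optional[int] = None,
    project: bool = True,
    var_threshold: float = 0.99,
    fold_features_fn=None,
) -> CVReport:
    """Twice-nested stratified k-fold CV on an assembled feature table.

    ``groups`` (e.g. patient ids) keeps all shocks of one patient in the
    same fold.  ``inner_k`` defaults to ``k`` (same fold count at every
    level); smaller values trade fidelity for speed.  ``fold_features_fn``,
    if given, receives the outer-train row indices and returns extra
    feature columns (a DataFrame over *all* rows) built from training
    information only — e.g. prototype distances with prototypes selected
    inside the training fold.
    """
    X_df, y = split_outcome(matrix)
    X = X_df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    inner_k = inner_k or k
    folds = _make_folds(y, k, seed, groups)
    oof = np.full(len(y), np.nan)
    fold_features, fold_params = [], []
    for f, (tr, te) in enumerate(folds):
        Xf, names = X, list(X_df.columns)
        if fold_features_fn is not None:
            extra = fold_features_fn(tr)
            Xf = np.hstack([X, extra.to_numpy(dtype=float)]) if X.size else extra.to_numpy(dtype=float)
            names = names + list(extra.columns)
        fm = fit_outer_fold(
            Xf, y, spec, tr, seed + 1000 * f, inner_k, project, var_threshold,
            feature_names=names,
        )
        oof[te] = fm.predict_proba(Xf[te])
        fold_features.append(fm.feature_names)
        fold_params.append(fm.params)
    roc = roc_curve(oof, y)
    acc, thr = _best_accuracy(roc)
    return CVReport(
        oof_prob=oof, outcomes=y, roc=roc, auc=roc.auc, accuracy_best=acc,
        best_threshold=thr, at_sensitivity=metrics_at_sensitivity(roc),
        fold_features=fold_features, fold_params=fold_params, folds=folds,
    )


# --------------------------------------------------------------------------
# Final model and prediction
# --------------------------------------------------------------------------

@dataclass
class FittedMDI:
    """Deployable model: schema-checked single-vector prediction."""

    fold_model: _FoldModel
    schema: List[str]
    spec: ModelSpec
    seed: int

    def predict(self, features) -> float:
        """Probability of successful defibrillation for one feature vector."""
        if isinstance(features, dict):
            missing = [c for c in self.schema if c not in features]
            if missing:
                raise ConfigError(f"missing features: {missing}")
            vec = np.array([features[c] for c in self.schema], dtype=float)
        else:
            vec = np.asarray(features, dtype=float)
            if vec.shape != (len(self.schema),):
                raise ConfigError(
                    f"expected {len(self.schema)} features, got {vec.shape}"
                )
        return float(self.fold_model.predict_proba(vec[None, :])[0])

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedMDI":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_final(
    matrix: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    seed: int = 0,
    inner_k: int = 10,
    project: bool = True,
    var_threshold: float = 0.99,
) -> FittedMDI:
    """Fit the deployable model on the whole table (selection via inner CV)."""
    X_df, y = split_outcome(matrix)
    X = X_df.to_numpy(dtype=float)
    fm = fit_outer_fold(
        X, y, spec, np.arange(len(y)), seed, inner_k, project, var_threshold,
        feature_names=list(X_df.columns),
    )
    return FittedMDI(fm, list(X_df.columns), spec, seed)


# --------------------------------------------------------------------------
# statsmodels-style facade
# --------------------------------------------------------------------------

class MDIModel:
    """Multiple Domain Integrative model of defibrillation outcome.

    Build from an assembled feature table (``MDIModel(matrix)``) or from raw
    shock records (:meth:`from_records`), then call :meth:`fit` to run the
    nested cross-validation and obtain an :class:`MDIResults`.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        spec: ModelSpec = ModelSpec(),
        groups: Optional[Sequence] = None,
        k: int = 10,
        inner_k: Optional[int] = None,
        project: bool = True,
        var_threshold: float = 0.99,
        fold_features_fn=None,
    ):
        self.matrix = matrix
        self.spec = spec
        self.groups = groups
        self.k = k
        self.inner_k = inner_k
        self.project = project
        self.var_threshold = var_threshold
        self.fold_features_fn = fold_features_fn

    @classmethod
    def from_records(cls, records, config=None, use_petco2: bool = False, **kw):
        """Assemble features from shock records (see :mod:`vfmdi.pipeline`).

        Static (wavelet, time-domain, PetCO2) features are precomputed;
        prototype-distance features are rebuilt inside each outer training
        fold so prototype selection never sees test shocks.
        """
        from .pipeline import CohortFeatures, PipelineConfig

        config = config or PipelineConfig()
        feats = CohortFeatures.from_records(records, config, use_petco2=use_petco2)
        return cls(
            feats.static_matrix,
            groups=feats.groups,
            fold_features_fn=feats.kd_features_for_train,
            **kw,
        )

    def fit(self, seed: int = 0) -> "MDIResults":
        report = nested_cv(
            self.matrix, self.spec, self.k, seed, self.groups, self.inner_k,
            self.project, self.var_threshold, self.fold_features_fn,
        )
        return MDIResults(self, report, seed)


class MDIResults:
    """Cross-validated results: out-of-fold predictions and ROC metrics."""

    def __init__(self, model: MDIModel, report: CVReport, seed: int):
        self.model = model
        self.report = report
        self.seed = seed
        self.auc = report.auc
        self.accuracy = report.accuracy_best
        self.at_sensitivity = report.at_sensitivity

    def summary(self) -> str:
        r = self.report
        lines = [
            "MDI nested cross-validation summary",
            "===================================",
            f"algorithm        : {self.model.spec.algorithm}",
            f"shocks           : {len(r.outcomes)} "
            f"({int(r.outcomes.sum())} successful / "
            f"{int((1 - r.outcomes).sum())} unsuccessful)",
            f"outer folds      : {len(r.folds)}   seed: {self.seed}",
            f"ROC AUC          : {r.auc:.3f}",
            f"best accuracy    : {r.accuracy_best:.3f} "
            f"(threshold {r.best_threshold:.2f})",
        ]
        for t, m in r.at_sensitivity.items():
            lines.append(
                f"at {t:.0%} sensitivity: spec {m['specificity']:.3f}, "
                f"acc {m['accuracy']:.3f} (threshold {m['threshold']:.2f})"
            )
        return "\n".join(lines)
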