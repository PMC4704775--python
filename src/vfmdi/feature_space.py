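"""Orthogonalization, variance-based reduction, and statistical validation.

The assembled features (prototype distances, wavelet statistics, time-domain
descriptors) live on incommensurate scales, so they are z-scored and
projected onto the orthogonal principal axes; components are retained until
the cumulative eigenvalue fraction reaches a threshold (default 99% of total
variance) and the rest are discarded as presumably spurious.

Validation battery: per-feature two-class ANOVA (equivalently a pooled
t-test, F = t^2) and Kruskal–Wallis (equivalently Mann–Whitney–Wilcoxon for
two classes), a Hotelling two-sample T^2 (two-group MANOVA) on the reduced
orthogonal set, and the running accumulated false-positive probability
1 - prod(1 - p_i) across feature batches for diagnostic plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EvaluationError, ParameterError, RankError, ScalingError

__all__ = [
    "Projection",
    "orthogonalize",
    "reduce",
    "anova_per_feature",
    "kw_per_feature",
    "manova",
    "accumulate_fp",
    "validation_report",
    "split_outcome",
]


def split_outcome(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (features, outcome array)."""
    if "outcome" not in matrix.columns:
        raise ParameterError("feature matrix lacks 'outcome' column")
    y = matrix["outcome"].to_numpy(dtype=int)
    X = matrix.drop(columns=["outcome"])
    return X, y


@dataclass
class Projection:
    """Fitted orthogonal projection (principal axes of the feature cloud)."""

    center: np.ndarray
    scale: Optional[np.ndarray]     # None when standardize was off
    loadings: np.ndarray            # columns are orthonormal axis vectors
    eigenvalues: np.ndarray         # nonincreasing variances along axes
    feature_names: list

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float) - self.center
        if self.scale is not None:
            Z = Z / self.scale
        return Z @ self.loadings

    def retained(self, var_threshold: float = 0.99) -> int:
        """Smallest k whose cumulative eigenvalue fraction >= threshold."""
        if not 0.0 < var_threshold <= 1.0:
            raise ParameterError("threshold must be in (0, 1]")
        total = self.eigenvalues.sum()
        if total == 0:
            return 0
        frac = np.cumsum(self.eigenvalues) / total
        return int(np.searchsorted(frac, var_threshold - 1e-12) + 1)


def orthogonalize(
    matrix: pd.DataFrame, standardize: bool = True
) -> Tuple[Projection, pd.DataFrame]:
    """Project features onto uncorrelated orthogonal axes (PCA via SVD).

    Returns the fitted projection and the projected table (component
    columns ``pc1..pck`` plus the outcome column).  With ``standardize``
    each feature is z-scored first; a constant column then raises
    :class:`ScalingError` naming the column.
    """
    X, y = split_outcome(matrix)
    names = list(X.columns)
    A = X.to_numpy(dtype=float)
    if A.shape[0] < 2:
        raise ParameterError("need at least 2 rows")
    center = A.mean(axis=0)
    Z = A - center
    scale = None
    if standardize:
        scale = Z.std(axis=0, ddof=1)
        bad = np.flatnonzero(scale == 0)
        if bad.size:
            raise ScalingError(f"constant feature column: {names[bad[0]]!r}")
        Z = Z / scale
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (A.shape[0] - 1)
    proj = Projection(center, scale, Vt.T, eig, names)
    scores = Z @ Vt.T
    out = pd.DataFrame(scores, columns=[f"pc{i + 1}" for i in range(scores.shape[1])],
                       index=matrix.index)
    out["outcome"] = y
    return proj, out


def reduce(
    projection: Projection, projected: pd.DataFrame, var_threshold: float = 0.99
) -> pd.DataFrame:
    """Keep the leading components reaching the cumulative-variance threshold."""
    k = projection.retained(var_threshold)
    cols = [f"pc{i + 1}" for i in range(k)]
    out = projected[cols].copy()
    out["outcome"] = projected["outcome"].to_numpy()
    return out


def _two_groups(matrix: pd.DataFrame):
    X, y = split_outcome(matrix)
    g0, g1 = X[y == 0], X[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise EvaluationError("need >= 2 rows in each class")
    return X, g0.to_numpy(float), g1.to_numpy(float)


def anova_per_feature(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-way two-class ANOVA per feature (F = t^2 of the pooled t-test)."""
    X, a, b = _two_groups(matrix)
    F, p = stats.f_oneway(a, b)
    return pd.DataFrame({"feature": X.columns, "F": F, "p": p})


def kw_per_feature(matrix: pd.DataFrame) -> pd.DataFrame:
    """Kruskal–Wallis per feature (two classes: MWW rank-sum), tie-corrected."""
    X, a, b = _two_groups(matrix)
    rows = []
    for j, name in enumerate(X.columns):
        if np.ptp(np.r_[a[:, j], b[:, j]]) == 0.0:
            H, p = 0.0, 1.0    # every value tied: no evidence against H0
        else:
            H, p = stats.kruskal(a[:, j], b[:, j])
        rows.append({"feature": name, "H": H, "p": p})
    return pd.DataFrame(rows)


def manova(matrix: pd.DataFrame) -> dict:
    """Two-sample Hotelling T^2 on the (reduced, orthogonal) components.

    Returns T^2, its exact F transform with (p, n1+n2-p-1) degrees of
    freedom, and the p-value.  Requires more rows than retained dimensions.
    """
    X, y = split_outcome(matrix)
    A = X.to_numpy(float)
    a, b = A[y == 0], A[y == 1]
    n1, n2, p_dim = len(a), len(b), A.shape[1]
    if min(n1, n2) < 2:
        raise EvaluationError("both classes required with >= 2 rows")
    if n1 + n2 <= p_dim + 2:
        raise ParameterError("need rows > dimensions + 2 for the F transform")
    diff = a.mean(axis=0) - b.mean(axis=0)
    S = ((n1 - 1) * np.cov(a, rowvar=False, ddof=1).reshape(p_dim, p_dim)
         + (n2 - 1) * np.cov(b, rowvar=False, ddof=1).reshape(p_dim, p_dim)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise RankError("singular pooled covariance") from exc
    t2 = float((n1 * n2) / (n1 + n2) * diff @ sol)
    df2 = n1 + n2 - p_dim - 1
    F = t2 * df2 / ((n1 + n2 - 2) * p_dim)
    p_val = float(stats.f.sf(F, p_dim, df2))
    return {"t2": t2, "F": float(F), "df": (p_dim, df2), "p": p_val}


def validation_report(
    matrix: pd.DataFrame, var_threshold: float = 0.99
) -> Tuple[pd.DataFrame, dict]:
    """Full statistical validation of an assembled feature table.

    Returns a per-feature table (F, p_anova, H, p_kw) and a summary dict
    (Hotelling T², its p-value on the reduced orthogonal set, retained
    component count, discarded feature fraction).
    """
    an = anova_per_feature(matrix)
    kw = kw_per_feature(matrix)
    per_feature = an.merge(kw, on="feature").rename(
        columns={"p_x": "p_anova", "p_y": "p_kw"})
    proj, scores = orthogonalize(matrix, standardize=True)
    red = reduce(proj, scores, var_threshold)
    k = red.shape[1] - 1
    mv = manova(red)
    summary = {
        "t2": mv["t2"],
        "p_manova": mv["p"],
        "retained_components": k,
        "discarded_fraction": 1.0 - k / (matrix.shape[1] - 1),
        "var_threshold": var_threshold,
    }
    return per_feature, summary


def accumulate_fp(p_values: Sequence[float], scale: float = 10.0,
                  batch: int = 40) -> pd.DataFrame:
    """Accumulated false-positive probability across feature batches.

    Running ``1 - prod(1 - p_i)`` evaluated after each batch of features
    (independence approximation), optionally scaled for plotting alongside
    raw statistic values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    log_surv = np.cumsum(np.log1p(-np.minimum(p, 1 - 1e-300)))
    cum = 1.0 - np.exp(log_surv)
    ends = np.arange(batch - 1, len(p), batch)
    if len(ends) == 0 or ends[-1] != len(p) - 1:
        ends = np.append(ends, len(p) - 1)
    return pd.DataFrame({
        "n_features": ends + 1,
        "p_fp": cum[ends],
        "p_fp_scaled": scale * cum[ends],
    })
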