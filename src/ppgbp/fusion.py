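"""Inverse-variance fusion of BP estimates, correlation, feature selection.

Two estimates x1, x2 with error variances s1^2, s2^2 combine as

    x3 = s3^2 * (x1/s1^2 + x2/s2^2),    s3^2 = (1/s1^2 + 1/s2^2)^-1,

the minimum-variance unbiased combination; fusing many sources applies the
rule pairwise (associative, order-invariant). The per-method variance is
estimated as the population variance of (estimate - reference) on training
subjects only, floored at 1e-6 mmHg^2.

Greedy-forward wrapper selection repeatedly adds the feature that most
reduces subject-level cross-validated MAE of a wrapped estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

#: variance floor before inversion, mmHg^2
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class MethodEstimate:
    """Per-subject estimates of one method with its error variance."""

    values: np.ndarray
    variance: float
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("estimates must be finite")
        if not self.variance > 0:
            raise DomainError(f"variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class FusedEstimate:
    values: np.ndarray
    variance: float
    parents: tuple[str, ...] = ()


def fuse(a: MethodEstimate, b: MethodEstimate) -> FusedEstimate:
    """Precision-weighted combination of two methods."""
    if a.values.shape != b.values.shape:
        raise ValueError("methods must cover the same subjects")
    w1, w2 = 1.0 / a.variance, 1.0 / b.variance
    var = 1.0 / (w1 + w2)
    values = var * (w1 * a.values + w2 * b.values)
    return FusedEstimate(values=values, variance=var, parents=(a.label, b.label))


def fuse_many(estimates: list[MethodEstimate]) -> FusedEstimate:
    """Associative pairwise fusion of >= 2 methods (order-invariant)."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 methods to fuse")
    acc = fuse(estimates[0], estimates[1])
    parents = [estimates[0].label, estimates[1].label]
    for est in estimates[2:]:
        acc = fuse(MethodEstimate(acc.values, acc.variance, "fused"), est)
        parents.append(est.label)
    return FusedEstimate(values=acc.values, variance=acc.variance,
                         parents=tuple(parents))


def estimate_method_variance(
    estimates: np.ndarray, references: np.ndarray
) -> float:
    """Population variance of (estimate - reference), floored at 1e-6 mmHg^2.

    In LOO use this must be computed from training-fold subjects only.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape or e.size < 3:
        raise InsufficientDataError("need >= 3 aligned estimate/reference pairs")
    return max(float(np.var(e - r)), VARIANCE_FLOOR)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """cov(x, y) / (sd_x * sd_y), population conventions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with >= 3 values")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise DomainError("correlation undefined for a constant input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


# ---------------------------------------------------------------------------
# wrapper feature selection
# ---------------------------------------------------------------------------


def _default_scorer(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """Ordinary least squares, the cheap default wrapped estimator."""
    from sklearn.linear_model import LinearRegression

    return LinearRegression().fit(Xtr, ytr).predict(Xte)


def _cv_mae(X: np.ndarray, y: np.ndarray, scorer, n_folds: int, seed: int) -> float:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    errs = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        preds = scorer(X[mask], y[mask], X[fold])
        errs.extend(np.abs(np.asarray(preds).ravel() - y[fold]))
    return float(np.mean(errs))


def greedy_forward_selection(
    features: np.ndarray,
    targets: np.ndarray,
    feature_names: list[str] | None = None,
    scorer=None,
    max_k: int | None = None,
    tol: float = 1e-3,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[int], list[float]]:
    """Forward greedy stepwise wrapper selection.

    Starting empty, repeatedly add the candidate feature whose inclusion
    minimises the cross-validated MAE of the wrapped estimator; stop when no
    addition improves MAE by more than ``tol`` mmHg or ``max_k`` is reached.
    Returns (selected indices in pick order, MAE trace).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    n_feat = X.shape[1]
    if n_feat < 2:
        raise ValueError("need >= 2 candidate features")
    scorer = scorer or _default_scorer
    max_k = max_k or n_feat
    selected: list[int] = []
    trace: list[float] = []
    best_mae = np.inf
    while len(selected) < max_k:
        candidates = [j for j in range(n_feat) if j not in selected]
        scores = {j: _cv_mae(X[:, selected + [j]], y, scorer, n_folds, seed)
                  for j in candidates}
        j_best = min(scores, key=lambda j: (scores[j], j))
        if best_mae - scores[j_best] <= tol:
            break
        selected.append(j_best)
        best_mae = scores[j_best]
        trace.append(best_mae)
    return selected, trace
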