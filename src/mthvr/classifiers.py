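"""The four classification algorithms.

* soft-margin RBF-kernel maximum-margin classification, one-against-one for
  more than two classes (production path backed by the libsvm solver in
  scikit-learn; contract-tested against an independent dual solver);
* linear and quadratic Gaussian discriminant analysis, implemented from the
  closed-form moment estimates;
* 1-nearest-neighbor under Hamming distance on the binary encoding, with
  majority voting among co-nearest references.

Dimensionality reduction is applied before SVM/LDA/QDA but never before 1NN.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.svm import SVC

from ._folds import stratified_fold_ids

#: Default coarse log2 grids for RBF hyperparameter tuning.
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


def _check_width(X: np.ndarray, expected: int, what: str) -> None:
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(f"{what}: expected width {expected}, got {X.shape}")


# ---------------------------------------------------------------------------
# Soft-margin kernel classification
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """A fitted one-against-one RBF soft-margin classifier."""

    svc: SVC
    classes: tuple
    C: float
    gamma: float
    n_features: int

    def fit_ok(self) -> bool:  # pragma: no cover - debugging aid
        return hasattr(self.svc, "support_")


def train_svm(X, y, C: float, gamma: float) -> SVMModel:
    """Solve the soft-margin problem (via its dual) for every class pair.

    ``C`` is the misclassification penalty, ``gamma`` the radial-basis kernel
    parameter of K(x1, x2) = exp(−gamma · |x1 − x2|²).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    svc = SVC(C=C, kernel="rbf", gamma=gamma, decision_function_shape="ovo")
    svc.fit(X, y)
    return SVMModel(svc=svc, classes=classes, C=C, gamma=gamma, n_features=X.shape[1])


def predict_svm(model: SVMModel, T) -> np.ndarray:
    """One-against-one voting; vote ties go to the lowest-ordered class label."""
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T.reshape(1, -1)
    _check_width(T, model.n_features, "predict_svm")
    classes = list(model.svc.classes_)  # sorted label order
    n_classes = len(classes)
    decision = np.atleast_2d(model.svc.decision_function(T))
    if n_classes == 2:
        # binary SVC: positive decision favors classes_[1]
        votes = np.zeros((T.shape[0], 2), dtype=np.int64)
        votes[:, 1] = (decision.ravel() > 0).astype(np.int64)
        votes[:, 0] = 1 - votes[:, 1]
    else:
        votes = np.zeros((T.shape[0], n_classes), dtype=np.int64)
        for col, (i, j) in enumerate(combinations(range(n_classes), 2)):
            positive = decision[:, col] > 0
            votes[positive, i] += 1
            votes[~positive, j] += 1
    winners = np.argmax(votes, axis=1)  # argmax takes the first (lowest) index on ties
    return np.asarray([classes[w] for w in winners])


def tune_svm(
    X,
    y,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> Tuple[float, float]:
    """Grid search (C, gamma) by mean CV micro-accuracy; ties to smaller values."""
    if not C_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    fold_ids = stratified_fold_ids(y, folds, seed)
    best: Optional[Tuple[float, float]] = None
    best_correct = -1
    for C in sorted(set(C_grid)):
        for gamma in sorted(set(gamma_grid)):
            correct = 0
            for fold in range(folds):
                test_mask = fold_ids == fold
                model = train_svm(X[~test_mask], y[~test_mask], C=C, gamma=gamma)
                pred = predict_svm(model, X[test_mask])
                correct += int(np.sum(pred == y[test_mask]))
            if correct > best_correct:
                best_correct = correct
                best = (C, gamma)
    assert best is not None
    return best


def solve_svm_dual(X, y_signs, C: float, gamma: float):
    """Independent reference solver for the two-class Wolfe dual (tiny problems).

    Maximizes Σα − ½ ΣΣ α_i α_j y_i y_j K(x_i, x_j) subject to 0 ≤ α ≤ C and
    Σ α_i y_i = 0, via SLSQP. Returns (alpha, intercept). Used as an oracle
    in contract tests; not a production path.
    """
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y_signs, dtype=np.float64)
    m = X.shape[0]
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    K = np.exp(-gamma * sq)
    Q = (y[:, None] * y[None, :]) * K

    def objective(alpha):
        return 0.5 * alpha @ Q @ alpha - alpha.sum()

    def gradient(alpha):
        return Q @ alpha - 1.0

    result = minimize(
        objective,
        x0=np.full(m, min(C, 1.0) / 2),
        jac=gradient,
        bounds=[(0.0, C)] * m,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    alpha = result.x
    # intercept from margin vectors (0 < alpha < C), or midpoint fallback
    on_margin = (alpha > 1e-6) & (alpha < C - 1e-6)
    decision_wo_b = (alpha * y) @ K
    if on_margin.any():
        b = float(np.mean(y[on_margin] - decision_wo_b[on_margin]))
    else:
        sv = alpha > 1e-6
        b = float(np.mean(y[sv] - decision_wo_b[sv]))
    return alpha, b


# ---------------------------------------------------------------------------
# Gaussian discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class GaussianClassifierModel:
    """Per-class Gaussian parameters (shared covariance for the linear variant)."""

    classes: tuple
    means: np.ndarray          # (K, n)
    covariances: np.ndarray    # (K, n, n); identical slices when shared
    priors: np.ndarray         # (K,)
    shared_covariance: bool

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if (self.priors <= 0).any():
            raise ValueError("priors must be positive")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def train_gaussian(
    X,
    y,
    shared_covariance: bool,
    regularization: Optional[float] = None,
    priors: Union[str, Sequence[float]] = "empirical",
) -> GaussianClassifierModel:
    """Estimate class means, covariances and priors from the training data.

    Covariances use the unbiased 1/(N−1) estimator (pooled over classes for
    the linear variant). ``regularization`` adds a ridge to the diagonals;
    ``None`` uses the default 1e-6 × mean diagonal, 0 disables it. Priors are
    empirical class frequencies unless ``"uniform"`` or an explicit vector is
    given.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    n = X.shape[1]
    K = len(classes)
    means = np.empty((K, n))
    raw_covs = []
    counts = np.empty(K)
    for g, cls in enumerate(classes):
        rows = X[y == cls]
        if rows.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        counts[g] = rows.shape[0]
        means[g] = rows.mean(axis=0)
        centered = rows - means[g]
        raw_covs.append(centered.T @ centered)
    if shared_covariance:
        pooled = sum(raw_covs) / (counts.sum() - K)
        covariances = np.broadcast_to(pooled, (K, n, n)).copy()
    else:
        covariances = np.stack(
            [raw_covs[g] / (counts[g] - 1) for g in range(K)]
        )
    if regularization is None:
        mean_diag = float(np.mean([np.trace(covariances[g]) / n for g in range(K)]))
        regularization = 1e-6 * mean_diag if mean_diag > 0 else 1e-6
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    if regularization > 0:
        covariances = covariances + regularization * np.eye(n)
    if isinstance(priors, str):
        if priors == "empirical":
            prior_vec = counts / counts.sum()
        elif priors == "uniform":
            prior_vec = np.full(K, 1.0 / K)
        else:
            raise ValueError(f"unknown priors mode {priors!r}")
    else:
        prior_vec = np.asarray(priors, dtype=np.float64)
        if prior_vec.shape != (K,):
            raise ValueError("explicit priors must have one entry per class")
    return GaussianClassifierModel(
        classes=classes,
        means=means,
        covariances=covariances,
        priors=prior_vec,
        shared_covariance=shared_covariance,
    )


def predict_gaussian(model: GaussianClassifierModel, T):
    """Posterior-maximizing class per row, computed in log space.

    Returns ``(labels, posteriors)`` where posteriors is an m × K matrix
    whose rows sum to 1.
    """
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T.reshape(1, -1)
    _check_width(T, model.n_features, "predict_gaussian")
    K = len(model.classes)
    n = model.n_features
    log_post = np.empty((T.shape[0], K))
    for g in range(K):
        cov = model.covariances[g]
        try:
            factor = cho_factor(cov, lower=True)
        except LinAlgError:
            raise ValueError(
                "singular class covariance; refit with a positive regularization ridge"
            ) from None
        diag = np.diag(factor[0])
        if diag.min() <= 1e-6 * diag.max():
            raise ValueError(
                "near-singular class covariance; refit with a positive regularization ridge"
            )
        logdet = 2.0 * np.sum(np.log(diag))
        diff = T - model.means[g]
        maha = np.sum(diff * cho_solve(factor, diff.T).T, axis=1)
        log_density = -0.5 * (n * np.log(2 * np.pi) + logdet + maha)
        log_post[:, g] = np.log(model.priors[g]) + log_density
    log_post -= log_post.max(axis=1, keepdims=True)
    posteriors = np.exp(log_post)
    posteriors /= posteriors.sum(axis=1, keepdims=True)
    labels = np.asarray([model.classes[g] for g in np.argmax(posteriors, axis=1)])
    return labels, posteriors


# ---------------------------------------------------------------------------
# Hamming-distance nearest neighbor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NNReference:
    """Reference binary matrix and labels for 1NN classification."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.shape[0] != len(self.labels):
            raise ValueError("one label per reference row required")
        if values.size and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("Hamming 1NN requires binary reference rows")
        if values.shape[0] == 0:
            raise ValueError("reference set must be non-empty")


def predict_1nn(reference: NNReference, T) -> np.ndarray:
    """Assign each row the label of its Hamming-nearest reference sample.

    When several references are equidistant-nearest, the majority label of
    that set wins; residual ties go to the lowest-ordered label.
    """
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T.reshape(1, -1)
    _check_width(T, reference.values.shape[1], "predict_1nn")
    if T.size and not np.isin(T, (0.0, 1.0)).all():
        raise ValueError("Hamming 1NN requires binary test rows")
    ref = reference.values
    labels = np.asarray(reference.labels, dtype=object)
    out = []
    for t in T:
        distances = np.count_nonzero(ref != t, axis=1)
        nearest = labels[distances == distances.min()]
        counts = Counter(nearest.tolist())
        top = max(counts.values())
        out.append(sorted(lb for lb, c in counts.items() if c == top)[0])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# sklearn-style adapters used by pipelines and model selection
# ---------------------------------------------------------------------------

class SVMClassifier:
    """fit/predict adapter around train_svm/predict_svm."""

    def __init__(self, C: float = 1.0, gamma: Optional[float] = None):
        self.C = C
        self.gamma = gamma
        self.model: Optional[SVMModel] = None

    def fit(self, X, y):
        gamma = self.gamma
        if gamma is None:
            X_arr = np.asarray(X, dtype=np.float64)
            var = float(X_arr.var())
            gamma = 1.0 / (X_arr.shape[1] * var) if var > 0 else 1.0
        self.model = train_svm(X, y, C=self.C, gamma=gamma)
        return self

    def predict(self, T):
        return predict_svm(self.model, T)


class GaussianClassifier:
    """fit/predict adapter around train_gaussian/predict_gaussian."""

    def __init__(
        self,
        shared_covariance: bool,
        regularization: Optional[float] = None,
        priors: Union[str, Sequence[float]] = "empirical",
    ):
        self.shared_covariance = shared_covariance
        self.regularization = regularization
        self.priors = priors
        self.model: Optional[GaussianClassifierModel] = None

    def fit(self, X, y):
        self.model = train_gaussian(
            X, y, self.shared_covariance, self.regularization, self.priors
        )
        return self

    def predict(self, T):
        labels, _ = predict_gaussian(self.model, T)
        return labels

    def predict_posteriors(self, T):
        return predict_gaussian(self.model, T)


class HammingNeighborClassifier:
    """fit/predict adapter around the Hamming 1NN reference search."""

    def __init__(self):
        self.reference: Optional[NNReference] = None

    def fit(self, X, y):
        self.reference = NNReference(np.asarray(X, dtype=np.float64), tuple(y))
        return self

    def predict(self, T):
        return predict_1nn(self.reference, T)


class MajorityClassifier:
    """Predicts the most frequent training label; sanity baseline."""

    def __init__(self):
        self.label = None

    def fit(self, X, y):
        counts = Counter(list(y))
        top = max(counts.values())
        self.label = sorted(lb for lb, c in counts.items() if c == top)[0]
        return self

    def predict(self, T):
        T = np.asarray(T)
        m = T.shape[0] if T.ndim > 1 else 1
        return np.asarray([self.label] * m)
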