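"""Principal component analysis with cross-validated choice of the retained dimension.

The decomposition is exact: columns are centered by training means, the
sample covariance (1/(m-1) estimator) is eigendecomposed, and axes are
ordered by decreasing eigenvalue. Only the leading ``k`` projected variables
are kept; ``k`` is chosen by 5-fold cross-validation of the downstream
classifier when not fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ._folds import stratified_fold_ids

#: Default candidate grid for the retained dimension (intersected with [1, min(m-1, n)]).
DEFAULT_K_GRID = (1, 2, 5, 10, 20, 50, 100, 150, 200)


@dataclass(frozen=True)
class PCAModel:
    """Centering means, orthogonal axes, eigenvalues and retained dimension."""

    means: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    k: int

    def __post_init__(self) -> None:
        n = self.means.shape[0]
        if self.axes.shape != (n, n):
            raise ValueError("axes must be an n × n matrix")
        if self.eigenvalues.shape != (n,):
            raise ValueError("eigenvalues must have length n")
        if not 1 <= self.k <= n:
            raise ValueError(f"k = {self.k} outside [1, {n}]")

    @property
    def n(self) -> int:
        return self.means.shape[0]

    def save(self, path: Union[str, Path]) -> None:
        np.savez(
            path, means=self.means, axes=self.axes, eigenvalues=self.eigenvalues,
            k=np.array([self.k]),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PCAModel":
        with np.load(path) as data:
            return cls(
                means=data["means"], axes=data["axes"],
                eigenvalues=data["eigenvalues"], k=int(data["k"][0]),
            )


def _as_array(matrix) -> np.ndarray:
    values = getattr(matrix, "values", matrix)
    return np.asarray(values, dtype=np.float64)


def fit_pca(matrix, k: Optional[int] = None) -> PCAModel:
    """Eigendecompose the sample covariance of the (column-centered) matrix.

    Axes are ordered by decreasing eigenvalue; each axis is oriented so its
    largest-magnitude component is positive (the eigenvector sign is
    arbitrary; fixing it makes results reproducible). Zero-variance columns
    are retained and yield zero eigenvalues.
    """
    X = _as_array(matrix)
    m, n = X.shape
    if m < 2:
        raise ValueError("PCA requires at least 2 samples")
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / (m - 1)
    eigenvalues, axes = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    axes = axes[:, order]
    # orient each axis so its largest-magnitude component is positive
    for j in range(n):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return PCAModel(means=means, axes=axes, eigenvalues=eigenvalues, k=k or n)


def transform(model: PCAModel, matrix, k: Optional[int] = None) -> np.ndarray:
    """Project rows onto the k leading axes: Y = (X − means) P[:, :k]."""
    k = k if k is not None else model.k
    X = _as_array(matrix)
    if X.shape[1] != model.n:
        raise ValueError(f"matrix has {X.shape[1]} columns, model expects {model.n}")
    if not 1 <= k <= model.n:
        raise ValueError(f"k = {k} outside [1, {model.n}]")
    return (X - model.means) @ model.axes[:, :k]


def inverse_transform(model: PCAModel, Y: np.ndarray) -> np.ndarray:
    """Back-project k-dimensional scores to the original space."""
    k = Y.shape[1]
    return Y @ model.axes[:, :k].T + model.means


def select_k(
    matrix,
    labels: Sequence,
    classifier_factory: Callable[[], object],
    folds: int = 5,
    candidates: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> int:
    """Pick the retained dimension maximizing mean CV micro-accuracy.

    ``classifier_factory`` returns a fresh estimator with sklearn-style
    ``fit``/``predict``. Ties are broken toward smaller k. PCA is refit on
    each training part so the selection is leakage-free.
    """
    X = _as_array(matrix)
    y = np.asarray(labels)
    m, n = X.shape
    if candidates is None:
        upper = min(m - 1, n)
        candidates = [k for k in DEFAULT_K_GRID if k <= upper] or [upper]
    candidates = sorted(set(int(k) for k in candidates))
    if not candidates:
        raise ValueError("candidate list is empty")
    for k in candidates:
        if k > n:
            raise ValueError(f"candidate k = {k} exceeds feature count {n}")
    fold_ids = stratified_fold_ids(y, folds, seed)
    scores = {k: 0 for k in candidates}
    for fold in range(folds):
        test_mask = fold_ids == fold
        model = fit_pca(X[~test_mask])
        train_proj = transform(model, X[~test_mask], k=model.n)
        test_proj = transform(model, X[test_mask], k=model.n)
        for k in candidates:
            clf = classifier_factory()
            clf.fit(train_proj[:, :k], y[~test_mask])
            pred = clf.predict(test_proj[:, :k])
            scores[k] += int(np.sum(pred == y[test_mask]))
    best = max(candidates, key=lambda k: (scores[k], -k))
    return best
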