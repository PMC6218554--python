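"""Supervised latent-variable projection (PLS-DA) of feature tables.

Partial least squares discriminant analysis regresses the autoscaled
feature matrix against one-hot class membership (distance group, or
healthy/diseased) and extracts the latent components that best covary with
class.  The implementation is the classic NIPALS power iteration for PLS2
with X-deflation, which makes the score vectors mutually orthogonal and
gives a clean per-component decomposition of the predictor variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "autoscale", "one_hot", "plsda_fit"]


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS-DA decomposition.

    ``x_scores`` (n_samples × k), ``x_loadings`` and ``x_weights``
    (n_features × k), ``y_loadings`` (n_classes × k).
    ``explained_x_variance`` and ``explained_y_variance`` are per-component
    fractions of the (autoscaled) predictor and class-matrix sum of squares.
    """

    n_components: int
    x_scores: np.ndarray
    x_loadings: np.ndarray
    x_weights: np.ndarray
    y_loadings: np.ndarray
    explained_x_variance: np.ndarray
    explained_y_variance: np.ndarray
    classes: tuple
    feature_names: tuple

    def __post_init__(self):
        t = self.x_scores
        gram = t.T @ t
        norms = np.sqrt(np.outer(np.diag(gram), np.diag(gram)))
        off = np.abs(gram - np.diag(np.diag(gram)))
        if norms.size and np.any(off > 1e-8 * np.maximum(norms, 1e-300)):
            raise ValueError("score vectors are not orthogonal")
        for fractions in (self.explained_x_variance, self.explained_y_variance):
            if np.any(fractions < -1e-12) or np.any(fractions > 1 + 1e-12):
                raise ValueError("explained-variance fractions must lie in [0, 1]")
            if fractions.sum() > 1 + 1e-9:
                raise ValueError("cumulative explained variance exceeds 1")


def autoscale(x: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean-centering and unit-variance scaling.

    Zero-variance columns carry no information on this scale and are dropped
    (a boolean keep-mask is returned alongside the scaled matrix).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("autoscale needs a 2-D matrix with at least 2 rows")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    centered = x[:, keep] - x[:, keep].mean(axis=0)
    return centered / sd[keep], keep


def one_hot(labels) -> tuple[np.ndarray, tuple]:
    """Class-membership indicator matrix and the ordered class labels."""
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    y = np.zeros((len(labels), len(classes)))
    for j, cls in enumerate(classes):
        y[labels == cls, j] = 1.0
    return y, classes


def plsda_fit(
    x: np.ndarray | pd.DataFrame,
    labels,
    n_components: int = 3,
    tol: float = 1e-10,
    max_iter: int = 500,
    scale: bool = True,
    feature_names=None,
) -> PLSModel:
    """NIPALS PLS2 against one-hot class membership.

    Each component is found by power iteration: the u-score starts from the
    class-matrix column with the largest variance (deterministic), weights
    ``w = Xᵀu/‖Xᵀu‖`` and scores ``t = Xw`` are alternated with class
    loadings until ``t`` changes by less than ``tol``; ``X`` is then deflated
    by the rank-one reconstruction ``t pᵀ`` and ``Y`` by ``t cᵀ``.
    Explained fractions are the deflated sum of squares over the total.
    """
    if feature_names is None and isinstance(x, pd.DataFrame):
        feature_names = tuple(x.columns)
    x = np.asarray(x, dtype=float)
    y, classes = one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if scale:
        x, keep = autoscale(x)
        if feature_names is not None:
            feature_names = tuple(np.asarray(feature_names)[keep])
    else:
        x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    if feature_names is None:
        feature_names = tuple(f"X{j}" for j in range(x.shape[1]))

    ss_x_total = float(np.sum(x ** 2))
    ss_y_total = float(np.sum(y ** 2))
    scores, weights, loadings, y_loadings = [], [], [], []
    exp_x, exp_y = [], []
    xk, yk = x.copy(), y.copy()
    for comp in range(n_components):
        u = yk[:, int(np.argmax(yk.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = xk.T @ u
            w /= np.linalg.norm(w)
            t = xk @ w
            c = yk.T @ t / (t @ t)
            u = yk @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge on component {comp + 1}")
        p = xk.T @ t / (t @ t)
        xk = xk - np.outer(t, p)
        yk = yk - np.outer(t, c)
        scores.append(t)
        weights.append(w)
        loadings.append(p)
        y_loadings.append(c)
        exp_x.append(float(t @ t) * float(p @ p) / ss_x_total)
        exp_y.append(float(t @ t) * float(c @ c) / max(ss_y_total, 1e-300))

    return PLSModel(
        n_components=n_components,
        x_scores=np.column_stack(scores),
        x_loadings=np.column_stack(loadings),
        x_weights=np.column_stack(weights),
        y_loadings=np.column_stack(y_loadings),
        explained_x_variance=np.array(exp_x),
        explained_y_variance=np.array(exp_y),
        classes=classes,
        feature_names=tuple(feature_names),
    )
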