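"""Partial least squares regression (single response) via NIPALS.

Components are extracted from mean-centered data by the classical
deflation scheme: the outer relations X = T P' + E and y = U q' + f are
linked by the inner regressions u_h = b_h t_h; for a single response the
per-component steps are closed-form, so the fit is deterministic.

The number of components is chosen by the PRESS/SS rule: component ``a``
is admitted iff PRESS_a / SS_{a-1} falls below a threshold (default
0.95^2), where PRESS_a comes from leave-one-group-out refits and
SS_{a-1} is the residual sum of squares of the all-data fit with a-1
components (SS_0 = total centered sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class RankError(ValueError):
    pass


class DegenerateResponseError(ValueError):
    pass


@dataclass(frozen=True)
class PLSRModel:
    x_mean: np.ndarray        # per-channel predictor means
    y_mean: float
    W: np.ndarray             # weight vectors, channels x a
    P: np.ndarray             # X-loadings, channels x a
    q: np.ndarray             # y-loading scalars, length a
    b: np.ndarray             # inner regression coefficients, length a
    T: np.ndarray             # X scores, samples x a
    U: np.ndarray             # y scores (response residuals), samples x a
    beta: np.ndarray          # composite coefficients on raw X
    intercept: float
    E: np.ndarray             # X residual matrix after a components
    F: np.ndarray             # y residual vector after a components

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def fit_plsr(X: np.ndarray, y: np.ndarray, a: int) -> PLSRModel:
    """Fit a PLS1 model with ``a`` components on mean-centered (X, y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if a < 1:
        raise ValueError("component count must be >= 1")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if a > rank:
        raise RankError(f"requested {a} components but centered X has rank {rank}")

    W = np.empty((k, a))
    P = np.empty((k, a))
    q = np.empty(a)
    b = np.empty(a)
    T = np.empty((n, a))
    U = np.empty((n, a))
    Xd, yd = Xc.copy(), yc.copy()
    extracted = a
    for h in range(a):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(np.linalg.norm(Xc), 1.0):
            if h == 0:
                raise RankError("X carries no covariance with the response")
            extracted = h  # response residual exhausted: exact fit reached
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        # inner relation: with u_h the current response residual, the
        # regression of u on t coincides with the y-loading for PLS1
        qh = yd @ t / tt
        W[:, h], P[:, h], T[:, h], U[:, h] = w, p, t, yd
        q[h] = b[h] = qh
        Xd -= np.outer(t, p)
        yd -= qh * t

    if extracted < a:
        W, P, T, U = (M[:, :extracted] for M in (W, P, T, U))
        q, b = q[:extracted], b[:extracted]
    beta = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - x_mean @ beta
    return PLSRModel(x_mean, y_mean, W, P, q, b, T, U, beta,
                     float(intercept), Xd, yd)


def predict_plsr(m: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict via the composite coefficients: yhat = intercept + X beta."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != m.beta.size:
        raise ValueError(
            f"query has {X.shape[1]} channels, model was trained on {m.beta.size}")
    return m.intercept + X @ m.beta


def predict_plsr_components(m: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict via the score path (deflation with W, P, q).

    Mathematically identical to :func:`predict_plsr`; kept as an
    independent code path for verification.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    Xd = X - m.x_mean
    yhat = np.full(X.shape[0], m.y_mean)
    for h in range(m.n_components):
        t = Xd @ m.W[:, h]
        yhat += m.q[h] * t
        Xd = Xd - np.outer(t, m.P[:, h])
    return yhat


def select_components(X: np.ndarray, y: np.ndarray, folds,
                      threshold: float = 0.95**2,
                      max_components: int | None = None) -> int:
    """PRESS/SS forward admission of components; returns the selected count.

    ``folds`` is a FoldAssignment-like object exposing integer labels in
    1..k (see :mod:`anthospec.evaluate`). The floor is one component: the
    rule may reject even the first, but a zero-component model is useless
    downstream.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(folds.labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 fold groups")

    # the largest a that every leave-one-group-out refit can support
    cap = np.linalg.matrix_rank(X - X.mean(axis=0))
    for g in groups:
        tr = labels != g
        cap = min(cap, np.linalg.matrix_rank(X[tr] - X[tr].mean(axis=0)))
    if max_components is not None:
        cap = min(cap, max_components)
    if cap < 1:
        return 1

    ss_prev = float(np.sum((y - y.mean()) ** 2))  # SS_0
    selected = 0
    for a in range(1, cap + 1):
        press = 0.0
        for g in groups:
            tr, te = labels != g, labels == g
            m = fit_plsr(X[tr], y[tr], a)
            press += float(np.sum((y[te] - predict_plsr(m, X[te])) ** 2))
        if press / ss_prev < threshold:
            selected = a
            m_all = fit_plsr(X, y, a)
            ss_prev = float(np.sum((y - predict_plsr(m_all, X)) ** 2))
            if ss_prev <= 1e-12 * np.sum((y - y.mean()) ** 2):
                break  # essentially exact fit; nothing left to explain
        else:
            break
    return max(selected, 1)
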