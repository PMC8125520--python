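"""Exact Gaussian-process regression with an ARD squared-exponential kernel.

The model is z = f(s) + eps with f ~ GP(0, k) on the centered response and
eps ~ N(0, sigma_n^2). The kernel is

    k(s, s') = sigma_f^2 exp(-1/2 sum_m (s_m - s'_m)^2 / sigma_m^2)

with one characteristic length scale sigma_m per input channel; a small
sigma_m marks an informative channel (automatic relevance determination).
Hyperparameters theta = (sigma_f, sigma_1..sigma_b, sigma_n) are trained by
maximizing the log marginal likelihood

    log p(z|S) = -1/2 z' Ky^-1 z - 1/2 log|Ky| - n/2 log 2pi,  Ky = K + sigma_n^2 I

with analytic gradients on the log scale and L-BFGS-B from a default
initialization plus seeded random restarts.

Inputs are standardized to zero mean / unit variance per channel before
kernel evaluation (stored on the model for prediction); the response is
centered, matching the zero-mean prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist


class ConditioningError(np.linalg.LinAlgError):
    pass


class OptimizationError(RuntimeError):
    pass


_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)
_LOG_BOUNDS = (-18.0, 18.0)


@dataclass(frozen=True)
class GPRHyper:
    """ARD-SE hyperparameters; all strictly positive."""

    sigma_f: float
    length_scales: np.ndarray
    sigma_n: float

    def __post_init__(self):
        ls = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        object.__setattr__(self, "length_scales", ls)
        if self.sigma_f <= 0 or self.sigma_n <= 0 or np.any(ls <= 0):
            raise ValueError("all hyperparameters must be strictly positive")

    def to_log_vector(self) -> np.ndarray:
        return np.log(np.concatenate(
            [[self.sigma_f], self.length_scales, [self.sigma_n]]))

    @classmethod
    def from_log_vector(cls, v: np.ndarray) -> "GPRHyper":
        v = np.exp(np.asarray(v, dtype=float))
        return cls(float(v[0]), v[1:-1], float(v[-1]))


def ard_se_kernel(S1: np.ndarray, S2: np.ndarray, h: GPRHyper) -> np.ndarray:
    S1 = np.atleast_2d(np.asarray(S1, dtype=float))
    S2 = np.atleast_2d(np.asarray(S2, dtype=float))
    b = h.length_scales.size
    if S1.shape[1] != b or S2.shape[1] != b:
        raise ValueError(
            f"input channel counts ({S1.shape[1]}, {S2.shape[1]}) do not match "
            f"the {b} length scale(s)")
    D2 = cdist(S1 / h.length_scales, S2 / h.length_scales, "sqeuclidean")
    return h.sigma_f**2 * np.exp(-0.5 * D2)


def _chol_with_jitter(Ky: np.ndarray):
    scale = max(float(np.mean(np.diag(Ky))), 1e-300)
    for jit in _JITTERS:
        try:
            return cho_factor(Ky + jit * scale * np.eye(Ky.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise ConditioningError("kernel matrix not positive-definite after max jitter")


def log_marginal_likelihood(S: np.ndarray, z: np.ndarray, h: GPRHyper):
    """Return (log marginal likelihood, gradient w.r.t. log-hyperparameters).

    Gradient uses d logp/d theta_j = 1/2 tr((alpha alpha' - Ky^-1) dKy/dtheta_j)
    with alpha = Ky^-1 z.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    z = np.asarray(z, dtype=float).ravel()
    n = z.size
    K = ard_se_kernel(S, S, h)
    Ky = K + h.sigma_n**2 * np.eye(n)
    c, low = _chol_with_jitter(Ky)
    alpha = cho_solve((c, low), z)
    lml = (-0.5 * z @ alpha
           - np.sum(np.log(np.diag(c)))
           - 0.5 * n * np.log(2 * np.pi))

    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    grad = np.empty(h.length_scales.size + 2)
    grad[0] = np.sum(A * K)                      # d/dlog sigma_f: dKy = 2K
    for m in range(h.length_scales.size):
        d2 = (S[:, m, None] - S[None, :, m]) ** 2 / h.length_scales[m] ** 2
        grad[1 + m] = 0.5 * np.sum(A * (K * d2))  # dKy = K .* D2_m / sigma_m^2
    grad[-1] = h.sigma_n**2 * np.trace(A)         # dKy = 2 sigma_n^2 I
    return float(lml), grad


@dataclass(frozen=True)
class GPRModel:
    S: np.ndarray              # standardized training inputs, n x b
    z: np.ndarray              # centered training responses
    hyper: GPRHyper
    y_mean: float
    x_mean: np.ndarray         # per-channel standardization parameters
    x_scale: np.ndarray
    chol: tuple                # cached factorization of K + sigma_n^2 I
    alpha: np.ndarray          # cached solve against z
    log_likelihood: float
    converged: bool

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"query has {X.shape[1]} channels, model expects {self.x_mean.size}")
        return (X - self.x_mean) / self.x_scale


@dataclass(frozen=True)
class GPPrediction:
    mean: np.ndarray           # nmol/cm²
    variance: np.ndarray       # (nmol/cm²)^2

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)


def default_init(z: np.ndarray, b: int) -> GPRHyper:
    s = float(np.std(z))
    s = s if s > 1e-8 else 1e-8
    return GPRHyper(s, np.ones(b), 0.1 * s)


def fit_gpr(S: np.ndarray, z: np.ndarray, init: GPRHyper | None = None,
            n_restarts: int = 4, seed: int = 0,
            max_iter: int = 200) -> GPRModel:
    """Train hyperparameters by marginal-likelihood maximization.

    Runs L-BFGS-B from ``init`` (default: sigma_f = SD(z), unit length
    scales on standardized inputs, sigma_n = 0.1 SD(z)) plus ``n_restarts``
    seeded restarts perturbed log-uniformly by +-1 in log space; keeps the
    best optimum.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    z = np.asarray(z, dtype=float).ravel()
    n, b = S.shape
    if n < 2:
        raise ValueError("need at least 2 training points")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite training data")

    x_mean = S.mean(axis=0)
    x_scale = S.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    Ss = (S - x_mean) / x_scale
    y_mean = float(z.mean())
    zc = z - y_mean

    if init is None:
        init = default_init(zc, b)
    theta0 = init.to_log_vector()
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.uniform(-1.0, 1.0, theta0.size) for _ in range(n_restarts)
    ]

    def objective(v):
        lml, grad = log_marginal_likelihood(Ss, zc, GPRHyper.from_log_vector(v))
        return -lml, -grad

    best = None
    failures = []
    for v0 in starts:
        try:
            res = optimize.minimize(
                objective, np.clip(v0, *_LOG_BOUNDS), jac=True,
                method="L-BFGS-B",
                bounds=[_LOG_BOUNDS] * v0.size,
                options={"maxiter": max_iter})
        except (ConditioningError, np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise OptimizationError(
            f"all {len(starts)} optimizer starts failed: {failures}")

    hyper = GPRHyper.from_log_vector(best.x)
    K = ard_se_kernel(Ss, Ss, hyper)
    Ky = K + hyper.sigma_n**2 * np.eye(n)
    c = _chol_with_jitter(Ky)
    alpha = cho_solve(c, zc)
    return GPRModel(Ss, zc, hyper, y_mean, x_mean, x_scale, c, alpha,
                    float(-best.fun), bool(best.success))


def predict_gpr(m: GPRModel, Sq: np.ndarray) -> GPPrediction:
    """Posterior mean and per-query variance at new inputs."""
    Sq = m.standardize(Sq)
    Ks = ard_se_kernel(Sq, m.S, m.hyper)
    mean = Ks @ m.alpha + m.y_mean
    v = cho_solve(m.chol, Ks.T)
    var = m.hyper.sigma_f**2 - np.einsum("ij,ji->i", Ks, v)
    return GPPrediction(mean, np.maximum(var, 0.0))
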