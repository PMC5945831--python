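"""Reconstruction ICA: learning a spike-bearing near-orthogonal basis.

The transform W (k x m) minimizes

    J(W) = lambda * ||W x||_1  +  1/2 * ||W^T W x - x||_F^2

over the segmented signal x (m x n). The L1 term promotes sparse basis
responses (isolated spikes); the reconstruction term is a soft surrogate
for the hard orthogonality constraint of classical ICA. The rows of
b = W x are the learned basis vectors from which motor-unit action
potentials are later extracted.

The L1 norm is non-differentiable at zero, so the optimized objective
replaces |z| with the smooth surrogate sqrt(z^2 + eps^2) (eps tiny); the
reported cost is always the exact J(W).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .preprocess import SegmentMatrix

__all__ = ["RicaConfig", "BasisModel", "rica_cost", "rica_gradient", "learn_transform"]

_SMOOTH_EPS = 1e-8


@dataclass
class RicaConfig:
    k: int = 100
    lambda_penalty: float = 0.01
    max_iter: int = 3000
    tol: float = 1e-6
    seed: int = 0
    method: str = "lbfgs"  # or "gd"

    def __post_init__(self) -> None:
        if self.lambda_penalty <= 0:
            raise ValueError("lambda_penalty must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class BasisModel:
    """Learned transform W and the basis vectors b = W x (rows)."""

    W: np.ndarray
    b: np.ndarray
    final_cost: float = np.nan
    cost_history: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return self.W.shape[0]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, SegmentMatrix):
        return x.x
    return np.atleast_2d(np.asarray(x, dtype=float))


def _check_shapes(W: np.ndarray, X: np.ndarray) -> None:
    if W.ndim != 2 or X.ndim != 2 or W.shape[1] != X.shape[0]:
        raise ValueError(
            f"shape mismatch: W is {W.shape}, x is {X.shape}; "
            "W must be k x m with x m x n"
        )


def rica_cost(W: np.ndarray, x, lambda_penalty: float) -> float:
    """Exact objective: lambda*||Wx||_1 + 1/2*||W^T W x - x||_F^2."""
    X = _as_matrix(x)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    _check_shapes(W, X)
    B = W @ X
    R = W.T @ B - X
    return float(lambda_penalty * np.abs(B).sum() + 0.5 * np.sum(R * R))


def _smoothed_cost_grad(
    W: np.ndarray, X: np.ndarray, lambda_penalty: float, eps: float = _SMOOTH_EPS
) -> tuple[float, np.ndarray]:
    B = W @ X                       # k x n basis responses
    R = W.T @ B - X                 # m x n reconstruction residual
    smooth_abs = np.sqrt(B * B + eps * eps)
    cost = lambda_penalty * smooth_abs.sum() + 0.5 * np.sum(R * R)
    # d/dW of the reconstruction term: W (X R^T + R X^T); of the smoothed L1:
    # lambda * (B / smooth_abs) X^T.
    grad = lambda_penalty * ((B / smooth_abs) @ X.T) + W @ (X @ R.T + R @ X.T)
    return float(cost), grad


def rica_gradient(W: np.ndarray, x, lambda_penalty: float) -> np.ndarray:
    """Gradient of the smoothed objective with respect to W."""
    X = _as_matrix(x)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    _check_shapes(W, X)
    return _smoothed_cost_grad(W, X, lambda_penalty)[1]


def _gradient_descent(fun, w0: np.ndarray, max_iter: int, tol: float, callback):
    """Plain backtracking (Armijo) gradient descent fallback."""
    w = w0.copy()
    f, g = fun(w)
    step = 1.0 / max(1.0, np.linalg.norm(g))
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            break
        trial = step
        for _ in range(40):
            w_new = w - trial * g
            f_new, g_new = fun(w_new)
            if f_new <= f - 1e-4 * trial * np.dot(g, g):
                break
            trial *= 0.5
        else:
            break
        w, f, g = w_new, f_new, g_new
        step = min(trial * 2.0, 1e3)
        callback(w)
    return w


def learn_transform(x, cfg: RicaConfig | None = None, **kwargs) -> BasisModel:
    """Learn W by quasi-Newton minimization of the smoothed objective.

    Deterministic given ``cfg.seed``: W is initialized with seeded
    row-normalized Gaussian rows and the optimizer is iteration-order
    deterministic. ``cost_history`` records the smoothed objective at every
    accepted iterate (non-increasing); ``final_cost`` is the exact J(W).
    """
    if cfg is None:
        cfg = RicaConfig(**kwargs)
    X = _as_matrix(x)
    m, _ = X.shape
    if cfg.k > m:
        raise ValueError(f"basis count k={cfg.k} exceeds segment count m={m}")

    rng = np.random.default_rng(cfg.seed)
    W0 = rng.standard_normal((cfg.k, m))
    W0 /= np.linalg.norm(W0, axis=1, keepdims=True)

    iteration = [0]
    history: list[float] = []
    last_eval: list = [None, None]      # (w, cost) of the latest evaluation

    def fun(wflat: np.ndarray):
        W = wflat.reshape(cfg.k, m)
        cost, grad = _smoothed_cost_grad(W, X, cfg.lambda_penalty)
        if not np.isfinite(cost) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"non-finite cost or gradient at iteration {iteration[0]}"
            )
        last_eval[0], last_eval[1] = wflat.copy(), cost
        return cost, grad.ravel()

    f0, _ = fun(W0.ravel())
    history.append(f0)

    def callback(wflat, *_args):
        iteration[0] += 1
        wflat = np.asarray(wflat).ravel()
        # the accepted iterate was almost always the last point evaluated
        # by the line search; reuse that cost instead of recomputing
        if last_eval[0] is not None and np.array_equal(wflat, last_eval[0]):
            history.append(last_eval[1])
        else:
            history.append(fun(wflat)[0])

    if cfg.method == "lbfgs":
        res = minimize(
            fun,
            W0.ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={"maxiter": cfg.max_iter, "gtol": cfg.tol, "ftol": 1e-12},
        )
        w_opt = res.x
    elif cfg.method == "gd":
        w_opt = _gradient_descent(fun, W0.ravel(), cfg.max_iter, cfg.tol, callback)
    else:
        raise ValueError(f"unknown optimizer {cfg.method!r}; expected 'lbfgs' or 'gd'")

    W = w_opt.reshape(cfg.k, m)
    return BasisModel(
        W=W,
        b=W @ X,
        final_cost=rica_cost(W, X, cfg.lambda_penalty),
        cost_history=np.asarray(history),
    )
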