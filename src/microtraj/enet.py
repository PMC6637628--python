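"""Non-negative elastic-net linear regression by cyclic coordinate descent.

Solves, for n samples, p predictors and an unpenalized intercept b0,

    min_{b >= 0, b0}  (1/2n) ||y - b0 - X b||^2
                      + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

via cyclic coordinate descent on the centered problem with a nonnegative
(projected) soft-threshold update.  The nonnegativity constraint reflects
the modelling choice that only species whose abundance rises with the
arthritis score are candidate markers.  Warm-started paths over a
descending lambda grid are provided for cross-validated penalty selection.

Working quantities are the Gram matrix G = Xc'Xc/n and covariance
c = Xc'yc/n of the centered data, so each coordinate update is O(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ElasticNetModel",
    "ElasticNetError",
    "fit_elastic_net_nn",
    "enet_path_nn",
    "lambda_max",
    "lambda_grid",
]

#: glmnet-style floor on alpha when computing lambda_max (alpha=0 has no
#: finite all-zero penalty).
_ALPHA_FLOOR = 1e-3


class ElasticNetError(ValueError):
    """Invalid input to the elastic-net solver."""


@dataclass
class ElasticNetModel:
    """A fitted non-negative elastic-net model."""

    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    converged: bool
    n_sweeps: int
    fold: int | None = None
    repeat: int | None = None
    feature_names: list | None = None
    objective_path: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta > 0))

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.beta


@njit(cache=True)
def _cd_nn_path(G, c, yy, lambdas, alpha, tol, max_sweeps, track_objective):
    """Cyclic coordinate descent over a descending lambda path (warm starts).

    Returns (betas, sweeps, converged, objectives) where objectives holds
    the per-sweep objective of the *last* lambda when tracking is on.
    """
    p = G.shape[0]
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    sweeps = np.zeros(n_lam, dtype=np.int64)
    converged = np.zeros(n_lam, dtype=np.bool_)
    objectives = np.zeros(max_sweeps if track_objective else 1)
    n_obj = 0
    beta = np.zeros(p)
    q = np.zeros(p)  # q = G @ beta, maintained incrementally
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        done = False
        sweep = 0
        track_this = track_objective and li == n_lam - 1
        if track_this:
            n_obj = 0
        while sweep < max_sweeps and not done:
            max_delta = 0.0
            for j in range(p):
                gjj = G[j, j]
                rho = c[j] - q[j] + gjj * beta[j]
                denom = gjj + l2
                if denom <= 0.0:
                    bj = 0.0
                else:
                    bj = rho - l1
                    if bj <= 0.0:
                        bj = 0.0
                    else:
                        bj = bj / denom
                delta = bj - beta[j]
                if delta != 0.0:
                    for t in range(p):
                        q[t] += G[t, j] * delta
                    beta[j] = bj
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            sweep += 1
            if track_this:
                pen = 0.0
                quad = 0.0
                lin = 0.0
                for t in range(p):
                    pen += alpha * beta[t] + 0.5 * (1.0 - alpha) * beta[t] * beta[t]
                    quad += beta[t] * q[t]
                    lin += c[t] * beta[t]
                objectives[n_obj] = 0.5 * yy - lin + 0.5 * quad + lam * pen
                n_obj += 1
            if max_delta < tol:
                done = True
        sweeps[li] = sweep
        converged[li] = done
        for t in range(p):
            betas[li, t] = beta[t]
    return betas, sweeps, converged, objectives[:n_obj]


def _center(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ElasticNetError("X must be a 2-D array")
    if y.shape[0] != X.shape[0]:
        raise ElasticNetError("X and y have inconsistent sample counts")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ElasticNetError("non-finite values in X or y")
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def lambda_max(X, y, alpha: float) -> float:
    """Smallest penalty at which the nonnegative solution is entirely zero.

    For b >= 0 only positive covariances with y can activate a coefficient;
    if none is positive the path is degenerate and a magnitude-based
    fallback keeps the grid well defined.
    """
    xc, yc, _, _ = _center(X, y)
    n = xc.shape[0]
    c = xc.T @ yc / n
    cmax = c.max(initial=0.0)
    if cmax <= 0:
        cmax = max(np.abs(c).max(initial=0.0), 1e-12)
    return float(cmax / max(alpha, _ALPHA_FLOOR))


def lambda_grid(
    X, y, alpha: float, n_lambdas: int = 100, decades: float = 4.0
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max down ``decades``."""
    lmax = lambda_max(X, y, alpha)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambdas)


def _validate_penalty(lam: float, alpha: float) -> None:
    if lam < 0:
        raise ElasticNetError(f"lambda must be >= 0, got {lam}")
    if not 0.0 <= alpha <= 1.0:
        raise ElasticNetError(f"alpha must be in [0, 1], got {alpha}")


def fit_elastic_net_nn(
    X,
    y,
    lam: float,
    alpha: float = 0.5,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    track_objective: bool = False,
    feature_names=None,
) -> ElasticNetModel:
    """Fit one non-negative elastic-net model at a fixed penalty.

    Convergence: largest coefficient change in a full sweep below ``tol``
    (default 1e-7) or ``max_sweeps`` sweeps; non-convergence is flagged on
    the returned model, not raised.  With ``track_objective`` the per-sweep
    objective values are recorded (they are non-increasing).
    """
    _validate_penalty(lam, alpha)
    xc, yc, xm, ym = _center(X, y)
    n = xc.shape[0]
    G = xc.T @ xc / n
    c = xc.T @ yc / n
    yy = float(yc @ yc / n)
    betas, sweeps, conv, objectives = _cd_nn_path(
        G,
        c,
        yy,
        np.array([float(lam)]),
        float(alpha),
        float(tol),
        int(max_sweeps),
        bool(track_objective),
    )
    beta = betas[0]
    return ElasticNetModel(
        beta=beta,
        intercept=float(ym - xm @ beta),
        lam=float(lam),
        alpha=float(alpha),
        converged=bool(conv[0]),
        n_sweeps=int(sweeps[0]),
        feature_names=list(feature_names) if feature_names is not None else None,
        objective_path=objectives.copy() if track_objective else None,
    )


def enet_path_nn(
    X,
    y,
    lambdas,
    alpha: float = 0.5,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
):
    """Warm-started coefficient path over a descending lambda grid.

    Returns (betas, intercepts) with one row per lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ElasticNetError("empty lambda grid")
    if np.any(np.diff(lambdas) > 0):
        raise ElasticNetError("lambda grid must be non-increasing")
    _validate_penalty(float(lambdas.min()), alpha)
    xc, yc, xm, ym = _center(X, y)
    n = xc.shape[0]
    G = xc.T @ xc / n
    c = xc.T @ yc / n
    yy = float(yc @ yc / n)
    betas, _, _, _ = _cd_nn_path(
        G, c, yy, lambdas, float(alpha), float(tol), int(max_sweeps), False
    )
    intercepts = ym - betas @ xm
    return betas, intercepts
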