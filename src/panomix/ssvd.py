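"""Elastic-net-penalized sparse singular value decomposition.

Rank-1 factors ``d * z w'`` are extracted by alternating updates

    z <- X w / ||X w||,        w <- S_en(X' z; lambda, alpha),

where ``S_en`` is the elastic-net thresholding operator, and successive
factors are obtained by deflation (subtracting the fitted rank-1 term).
This minimizes ``||X - Z W||_F^2 + lambda (alpha ||W||_1 + (1-alpha) ||W||_2^2)``
one axis at a time.  The penalty level is chosen per axis from a dense
lambda grid by locating the sharpest drop of the proportion of variance of
``X`` explained (PVX), i.e. the minimum discrete second derivative of
PVX(lambda).  At ``lambda = 0`` the procedure reduces exactly to the
ordinary SVD, which serves as the built-in oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .blocks import ExtendedMatrix

__all__ = [
    "en_threshold", "rank1_ssvd", "deflate", "pvx", "lambda_grid",
    "LambdaGrid", "pvx_elbow", "tune_lambda", "scree_rank", "fit_ssvd",
    "select_informative_axes", "Rank1Factor", "SSVDResult",
]


def en_threshold(w, lam: float, alpha: float, verbatim: bool = False):
    """Elementwise elastic-net thresholding operator.

    Default form is ``sign(w) max(|w| - lambda*alpha, 0) / (1 + lambda*(1-alpha))``,
    the proximal operator of ``lambda*alpha*|w| + lambda*(1-alpha)*w^2/2``.
    ``verbatim=True`` uses the denominator ``lambda*(1-alpha)`` instead
    (degenerate when ``lambda*(1-alpha) = 0``, which raises).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    arr = np.asarray(w, dtype=float)
    soft = np.sign(arr) * np.maximum(np.abs(arr) - lam * alpha, 0.0)
    if verbatim:
        denom = lam * (1 - alpha)
        if denom == 0:
            raise ZeroDivisionError(
                "verbatim thresholding divides by lambda*(1-alpha), which is "
                "zero here; use the default form or pick lambda>0, alpha<1")
        out = soft / denom
    else:
        out = soft / (1 + lam * (1 - alpha))
    return out if out.shape else float(out)


@dataclass
class Rank1Factor:
    """One sparse rank-1 factor ``d * z w'`` with unit-norm z and w."""

    d: float
    z: np.ndarray
    w: np.ndarray
    lam: float
    alpha: float
    n_iter: int
    converged: bool

    @property
    def support(self) -> np.ndarray:
        return self.w != 0


def _leading_left_vector(X: np.ndarray) -> np.ndarray:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, 0]


def rank1_ssvd(X: np.ndarray, lam: float, alpha: float = 0.5,
               tol: float = 1e-10, max_iter: int = 500,
               init: np.ndarray | None = None) -> Rank1Factor:
    """Fit one penalized rank-1 factor by alternating thresholded updates.

    Initialization is the leading left singular vector of ``X`` (so the
    ``lambda = 0`` case starts at, and stays at, the exact SVD solution);
    ``w`` is renormalized to unit norm each step with the scale absorbed
    into ``d = z' X w``.  An all-zero ``w`` at convergence yields ``d = 0``
    with empty support, signalling over-penalization.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X must be complete and finite")
    z = _leading_left_vector(X) if init is None else np.asarray(init, float)
    z = z / np.linalg.norm(z)
    w = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w_new = en_threshold(X.T @ z, lam, alpha)
        nw = np.linalg.norm(w_new)
        if nw == 0:
            return Rank1Factor(0.0, z, np.zeros(X.shape[1]), lam, alpha, it, True)
        w_new = w_new / nw
        z_new = X @ w_new
        nz = np.linalg.norm(z_new)
        if nz == 0:
            return Rank1Factor(0.0, z, np.zeros(X.shape[1]), lam, alpha, it, True)
        z_new = z_new / nz
        # sign convention: keep z continuous between iterations
        if z_new @ z < 0:
            z_new, w_new = -z_new, -w_new
        delta = max(np.abs(z_new - z).max(), np.abs(w_new - w).max())
        z, w = z_new, w_new
        if delta < tol:
            converged = True
            break
    d = float(z @ X @ w)
    if d < 0:      # flip so the scale is non-negative
        d, w = -d, -w
    return Rank1Factor(d, z, w, lam, alpha, it, converged)


def deflate(X: np.ndarray, factor: Rank1Factor) -> np.ndarray:
    """Subtract the fitted rank-1 term: ``X - d z w'``."""
    if factor.d == 0:
        return X.copy()
    return X - factor.d * np.outer(factor.z, factor.w)


def pvx(X: np.ndarray, Z: np.ndarray, W: np.ndarray,
        d: np.ndarray | None = None) -> float:
    """Proportion of variance of ``X`` explained by ``Z diag(d) W``."""
    total = float(np.sum(X ** 2))
    if total == 0:
        raise ValueError("PVX undefined for a zero matrix")
    Z = np.atleast_2d(np.asarray(Z, float))
    W = np.atleast_2d(np.asarray(W, float))
    if Z.shape[0] != X.shape[0]:
        Z = Z.T
    fitted = Z @ W if d is None else (Z * np.asarray(d, float)) @ W
    return 1.0 - float(np.sum((X - fitted) ** 2)) / total


@dataclass
class LambdaGrid:
    """Decreasing positive penalty grid, log-spaced by default."""

    values: np.ndarray
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 5:
            raise ValueError("grid needs at least 5 points")
        if np.any(self.values <= 0):
            raise ValueError("grid values must be positive")
        if not np.all(np.diff(self.values) < 0):
            raise ValueError("grid must be strictly decreasing")

    @property
    def n_points(self) -> int:
        return self.values.size


def lambda_grid(X: np.ndarray, alpha: float = 0.5, n_points: int = 50,
                span: float = 1e-4,
                init: np.ndarray | None = None) -> LambdaGrid:
    """Default grid: ``n_points`` log-spaced values in ``[lam_max*span, lam_max]``.

    ``lam_max = max|X' z0| / alpha`` is the smallest penalty that zeroes all
    loadings at the first iteration from the unpenalized start ``z0``.
    """
    z0 = _leading_left_vector(np.asarray(X, float)) if init is None else init
    lam_max = float(np.max(np.abs(X.T @ z0))) / max(alpha, 1e-12)
    vals = np.geomspace(lam_max, lam_max * span, n_points)
    return LambdaGrid(vals)


def pvx_elbow(pvx_values: np.ndarray, grid: np.ndarray | None = None,
              log_scale: bool = False) -> int:
    """Index of the sharpest PVX drop: interior minimum of the discrete
    second derivative (central differences), ties broken toward the sparser
    end (larger lambda = smaller PVX side).
    """
    p = np.asarray(pvx_values, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 PVX values")
    x = np.arange(p.size, dtype=float) if grid is None else np.asarray(grid, float)
    if log_scale:
        x = np.log(x)
    d2 = np.empty(p.size)
    d2[0] = d2[-1] = np.inf          # endpoints excluded from candidacy
    for i in range(1, p.size - 1):
        h1, h2 = x[i] - x[i - 1], x[i + 1] - x[i]
        d2[i] = 2 * (h1 * p[i + 1] - (h1 + h2) * p[i] + h2 * p[i - 1]) \
            / (h1 * h2 * (h1 + h2))
    # tie-break: among equal minima prefer the index whose PVX is lower
    # (more penalized, sparser fit)
    best = np.flatnonzero(np.isclose(d2, d2.min()))
    return int(best[np.argmin(p[best])])


def tune_lambda(X: np.ndarray, grid: LambdaGrid | None = None,
                alpha: float = 0.5,
                init: np.ndarray | None = None,
                return_path: bool = False):
    """Pick the rank-1 penalty from the PVX path over a lambda grid.

    Fits the rank-1 factorization at each grid value, computes PVX(lambda)
    and returns the lambda minimizing the discrete second derivative of the
    path on the log-lambda axis (the sharpest drop).  PVX should decrease
    monotonically in lambda; violations beyond 1e-9 trigger a warning, not
    an error (solver noise).
    """
    X = np.asarray(X, dtype=float)
    z0 = _leading_left_vector(X) if init is None else init
    if grid is None:
        grid = lambda_grid(X, alpha=alpha, init=z0)
    lams = grid.values                      # decreasing
    total = float(np.sum(X ** 2))
    path = np.empty(lams.size)
    for i, lam in enumerate(lams):
        f = rank1_ssvd(X, lam, alpha, init=z0)
        path[i] = f.d ** 2 / total
    # path is aligned to decreasing lambda -> PVX increasing along the array
    if np.any(np.diff(path) < -1e-9):
        warnings.warn("PVX not monotone in lambda beyond tolerance; "
                      "treating as solver noise")
    # analyse on increasing-lambda axis
    idx = pvx_elbow(path[::-1], grid=lams[::-1], log_scale=grid.log_scale)
    lam_star = float(lams[::-1][idx])
    if return_path:
        return lam_star, lams, path
    return lam_star


def scree_rank(singular_values: np.ndarray, override: int | None = None) -> int:
    """Elbow of the scree curve: the point with maximum perpendicular
    distance to the line joining the first and last singular values; the
    returned rank is the number of values before the elbow point.
    """
    if override is not None:
        return int(override)
    s = np.asarray(singular_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 singular values")
    if np.allclose(s, s[0]):
        warnings.warn("constant spectrum; returning rank 1")
        return 1
    n = s.size
    x = np.arange(n, dtype=float)
    dx, dy = x[-1] - x[0], s[-1] - s[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (s - s[0]) - dy * (x - x[0])) / norm
    return int(np.argmax(dist))


@dataclass
class SSVDResult:
    """Sparse factorization ``X ~ Z diag(d) W`` with per-axis penalties."""

    Z: np.ndarray                  # (n, K), unit-norm columns
    W: np.ndarray                  # (K, p), sparse rows, unit norm when nonzero
    d: np.ndarray                  # (K,)
    lambdas: np.ndarray            # (K,)
    alpha: float
    pvx_path: list[dict] = field(default_factory=list)   # per-axis lambda->PVX
    converged: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.Z.shape[1]

    @property
    def selected_axes(self) -> np.ndarray:
        """Axes retaining at least one nonzero loading."""
        return np.flatnonzero(np.any(self.W != 0, axis=1))

    @property
    def feature_support(self) -> np.ndarray:
        """Per-feature flag: nonzero loading in at least one selected axis."""
        return np.any(self.W != 0, axis=0)

    def axis_support(self, k: int) -> np.ndarray:
        return self.W[k] != 0


def fit_ssvd(X: ExtendedMatrix | np.ndarray, n_axes: int,
             grid: LambdaGrid | None = None, alpha: float = 0.5,
             lambdas: np.ndarray | None = None,
             tune: bool = True, n_grid: int = 50) -> SSVDResult:
    """Sequentially tune, fit and deflate ``n_axes`` sparse rank-1 factors.

    Per axis: the penalty is either given (``lambdas``), tuned from the PVX
    path on the residual (``tune=True``, the default), or zero.  The
    procedure is deterministic (initialization from the residual's leading
    singular vector).
    """
    A = X.values if isinstance(X, ExtendedMatrix) else np.asarray(X, float)
    n, p = A.shape
    if n_axes > min(n, p):
        raise ValueError(f"n_axes={n_axes} exceeds min(n, p)={min(n, p)}")
    R = A.copy()
    Z = np.zeros((n, n_axes))
    W = np.zeros((n_axes, p))
    d = np.zeros(n_axes)
    lams = np.zeros(n_axes)
    conv = np.zeros(n_axes, dtype=bool)
    paths: list[dict] = []
    for k in range(n_axes):
        z0 = _leading_left_vector(R)
        if lambdas is not None:
            lam = float(np.asarray(lambdas).ravel()[k])
            paths.append({})
        elif tune:
            g = grid if grid is not None else lambda_grid(R, alpha=alpha,
                                                          n_points=n_grid, init=z0)
            lam, glams, gpath = tune_lambda(R, grid=g, alpha=alpha, init=z0,
                                            return_path=True)
            paths.append({float(l): float(v) for l, v in zip(glams, gpath)})
        else:
            lam = 0.0
            paths.append({})
        f = rank1_ssvd(R, lam, alpha, init=z0)
        Z[:, k], W[k], d[k], lams[k], conv[k] = f.z, f.w, f.d, lam, f.converged
        R = deflate(R, f)
    return SSVDResult(Z, W, d, lams, alpha, paths, conv)


def select_informative_axes(result: SSVDResult, drop_leading: int = 0
                            ) -> np.ndarray:
    """Axes with nonempty support, after dropping the ``drop_leading``
    largest-variance ones; ordered by variance explained (d)."""
    order = np.argsort(-result.d)
    kept = [k for k in order[drop_leading:] if np.any(result.W[k] != 0)]
    if not kept:
        raise ValueError("no informative axes survive; decrease lambda "
                         "or drop fewer leading axes")
    return np.asarray(kept, dtype=int)
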