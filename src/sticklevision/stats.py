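"""Signal-sensory statistics: CCA with permutation Wilks-lambda tests,
linear regression, one-sample t, and the three-variable path model.

Both input blocks here are compositional (four proportions summing to 1),
so each is rank-deficient after centering. The CCA uses tolerance-based
rank truncation of each block's column space, which makes the result
invariant to the arbitrary choice of a "redundant" component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CCAResult",
    "RegressionFit",
    "OneSampleT",
    "PathEdge",
    "PathFit",
    "cca",
    "wilks_lambda",
    "wilks_sequential_test",
    "fit_regression",
    "one_sample_t",
    "fit_path_model",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class CCAResult:
    """Canonical correlations, unit-variance variate scores and loadings.

    ``x_loadings[j, a]`` is the Pearson correlation of X column j with the
    a-th X variate (likewise for Y); axes are ordered by decreasing
    canonical correlation.
    """

    correlations: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_rank: int
    y_rank: int

    @property
    def k(self) -> int:
        return self.correlations.size


def _column_space(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the centered column space, tolerance-truncated."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("matrix has no variance after centering")
    rank = int(np.sum(s > _RANK_TOL * s[0]))
    return U[:, :rank], rank


def _canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Fast path: canonical correlations only (used by the permutation test)."""
    Qx, _ = _column_space(X)
    Qy, _ = _column_space(Y)
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def _loadings(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    Zc = scores - scores.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sz = np.sqrt((Zc**2).sum(axis=0))
    sx = np.where(sx > 0, sx, np.inf)  # constant column -> loading 0
    return (Xc.T @ Zc) / np.outer(sx, sz)


def cca(X: np.ndarray, Y: np.ndarray, orient_x_column: int | None = None) -> CCAResult:
    """Canonical correlation analysis via the SVD of whitened cross-covariance.

    Parameters
    ----------
    X, Y
        n x p and n x q data matrices (rows are the same n cases).
    orient_x_column
        If given, flip each axis (jointly in X and Y) so the X loading of
        this column is nonnegative — e.g. point the first color variate
        toward increasing orange-red. Otherwise axes are oriented so the
        largest-magnitude X loading is positive.

    The number of axes is min of the tolerance-truncated ranks, so
    compositional blocks (rank 3) yield at most three axes. Variate
    scores are standardized to unit variance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= 2:
        raise ValueError("CCA needs more than two cases")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in CCA input")
    Qx, rx = _column_space(X)
    Qy, ry = _column_space(Y)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(rx, ry)
    r = np.clip(s[:k], 0.0, 1.0)
    scale = np.sqrt(n - 1)
    x_scores = Qx @ U[:, :k] * scale
    y_scores = Qy @ Vt.T[:, :k] * scale
    x_load = _loadings(X, x_scores)
    y_load = _loadings(Y, y_scores)
    for a in range(k):
        ref = (
            x_load[orient_x_column, a]
            if orient_x_column is not None
            else x_load[np.argmax(np.abs(x_load[:, a])), a]
        )
        if ref < 0:
            x_scores[:, a] *= -1
            y_scores[:, a] *= -1
            x_load[:, a] *= -1
            y_load[:, a] *= -1
    return CCAResult(r, x_scores, y_scores, x_load, y_load, rx, ry)


def wilks_lambda(correlations: np.ndarray, start_axis: int = 0) -> float:
    """Wilks' lambda for axes >= start_axis: prod (1 - r_i^2)."""
    r = np.asarray(correlations, dtype=float)[start_axis:]
    return float(np.prod(1.0 - r**2))


def wilks_sequential_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential permutation test of the canonical axes.

    For axis a the statistic is Lambda_a = prod_{i>=a} (1 - r_i^2); the
    null distribution comes from re-running the CCA with the rows of Y
    permuted (X fixed). p-values use the add-one convention
    p = (1 + #{Lambda_perm <= Lambda_obs}) / (1 + n_perm), so the minimum
    attainable p is 1/(1 + n_perm). Returns (lambdas, p_values), one entry
    per canonical axis.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    r_obs = _canonical_correlations(X, Y)
    k = r_obs.size
    lam_obs = np.array([wilks_lambda(r_obs, a) for a in range(k)])
    count = np.zeros(k, dtype=int)
    n = X.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _canonical_correlations(X, Y[perm])
        kk = min(k, r_perm.size)
        for a in range(kk):
            if wilks_lambda(r_perm, a) <= lam_obs[a]:
                count[a] += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return lam_obs, p


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares with the usual t-based two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return RegressionFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
        x.size,
    )


@dataclass(frozen=True)
class OneSampleT:
    t: float
    df: int
    p: float
    mean: float
    degenerate: bool = False


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> OneSampleT:
    """Two-sided one-sample Student's t test of mean == mu0.

    Zero sample variance is flagged (``degenerate=True``, NaN statistics)
    instead of propagating silently.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one-sample t needs at least two values")
    df = v.size - 1
    if np.ptp(v) == 0:
        return OneSampleT(np.nan, df, np.nan, float(v.mean()), degenerate=True)
    t, p = sps.ttest_1samp(v, mu0)
    return OneSampleT(float(t), df, float(p), float(v.mean()))


@dataclass(frozen=True)
class PathEdge:
    estimate: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class PathFit:
    """Saturated three-variable path model fit (standardized variables).

    Edges: two directed paths depth -> opsins and depth -> color, plus the
    residual covariance opsins <-> color, which is the direct association
    left after removing the shared depth effect. The model is
    just-identified, so the implied covariance matrix reproduces the
    sample matrix exactly; standard errors come from the ML information
    matrix and p-values are two-sided normal.
    """

    edges: dict
    implied: np.ndarray
    sample: np.ndarray
    n: int


def _path_sigma(theta: np.ndarray) -> np.ndarray:
    phi, a, b, v1, v2, psi = theta
    return np.array(
        [
            [phi, a * phi, b * phi],
            [a * phi, a * a * phi + v1, a * b * phi + psi],
            [b * phi, a * b * phi + psi, b * b * phi + v2],
        ]
    )


def _ml_discrepancy(theta: np.ndarray, S: np.ndarray) -> float:
    sigma = _path_sigma(theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(S @ np.linalg.inv(sigma)))


def fit_path_model(depth: np.ndarray, opsins: np.ndarray, color: np.ndarray) -> PathFit:
    """ML fit of the saturated depth/opsins/color path model.

    Inputs are standardized internally, so estimates are on the
    correlation scale: depth->opsins = r(d,o), depth->color = r(d,c), and
    opsins<->color = r(o,c) - r(d,o) r(d,c). SEs are computed from the
    numerically differentiated Hessian of the ML discrepancy.
    """
    cols = [np.asarray(v, dtype=float) for v in (depth, opsins, color)]
    n = cols[0].size
    if any(c.size != n for c in cols) or n < 4:
        raise ValueError("path model needs >= 4 complete cases")
    Z = np.stack(
        [(c - c.mean()) / c.std(ddof=1) for c in cols], axis=1
    )
    S = np.cov(Z, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S) < 3:
        raise ValueError("singular correlation matrix: path model unidentified")
    # just-identified => closed-form ML estimates reproduce S exactly
    phi = S[0, 0]
    a = S[0, 1] / phi
    b = S[0, 2] / phi
    v1 = S[1, 1] - a * a * phi
    v2 = S[2, 2] - b * b * phi
    psi = S[1, 2] - a * b * phi
    theta = np.array([phi, a, b, v1, v2, psi])

    H = _numerical_hessian(lambda t: _ml_discrepancy(t, S), theta)
    acov = 2.0 / (n - 1) * np.linalg.inv(H)
    se = np.sqrt(np.diag(acov))

    def edge(i: int) -> PathEdge:
        z = theta[i] / se[i]
        return PathEdge(float(theta[i]), float(se[i]), float(z), float(2 * sps.norm.sf(abs(z))))

    edges = {
        "depth->opsins": edge(1),
        "depth->color": edge(2),
        "opsins<->color": edge(5),
    }
    return PathFit(edges, _path_sigma(theta), S, n)


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth ML discrepancy."""
    k = x.size
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H
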