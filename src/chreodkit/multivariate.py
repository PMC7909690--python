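"""Multivariate canalization: the compensation matrix Theta and PLS features.

For p traits the strength of canalization generalises to a p x p matrix
Theta whose diagonal entries are per-trait canalization strengths and whose
off-diagonal entry Theta[i, j] measures how a deviation in trait i induces
compensating developmental change in trait j.  Theta is estimated as minus
the multivariate regression coefficient of the change (x_{t+1} - x_t) on
x_t, which requires n >> p; for high-dimensional data (shape coordinates)
the singular value decomposition of the cross-covariance matrix
cov(x_t, x_{t+1} - x_t) — two-block partial least squares — is the stable
alternative: its singular-vector pairs are the trait combinations with
maximal (approximately canalized) covariance between state and change, and
u_i' v_i near -1 flags pure canalization while values near 0 flag
compensation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ThetaMatrixEstimate",
    "PLSResult",
    "cross_covariance",
    "estimate_theta_matrix",
    "expected_cov_change",
    "total_canalized_variance",
    "pls_canalization",
    "reduced_rank_theta",
    "track_dimension_variance",
]

#: relative gap below which consecutive singular values are reported degenerate
DEGENERACY_RTOL = 1e-8

#: refuse the covariance inversion above this condition number
MAX_CONDITION = 1e10


@dataclass
class ThetaMatrixEstimate:
    """Estimated canalization/compensation matrix for one age step."""

    theta_hat: np.ndarray        # p x p, positive diagonal under canalization
    cross_cov: np.ndarray        # cov(x_t, x_{t+1} - x_t)
    n: int
    condition_estimate: float    # condition number of cov(x_t)

    @property
    def p(self) -> int:
        return self.theta_hat.shape[0]

    def symmetry_departure(self) -> float:
        """Relative asymmetry ||Theta - Theta'|| / ||Theta|| (Frobenius).

        The PLS reading of the cross-covariance matrix presumes roughly
        symmetric compensation (Theta[i, j] close to Theta[j, i]); large
        values signal that the approximation is doubtful.  No canonical
        threshold exists — report, don't gate.
        """
        denom = np.linalg.norm(self.theta_hat)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(self.theta_hat - self.theta_hat.T) / denom)


@dataclass
class PLSResult:
    """Singular decomposition of a state/change matrix with paired scores.

    ``left_vectors`` (u_i, columns) live in the state block, ``right_vectors``
    (v_i) in the change block; both sets are orthonormal.  For the
    cross-covariance decomposition the covariance of the paired score
    columns equals the singular values; ``slopes`` are the negated OLS
    slopes of change-scores on state-scores (per-dimension theta-style
    estimates) and ``canalization_index`` is u_i' v_i, close to -1 under
    pure canalization of that feature and close to 0 under compensation.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray       # p x k
    right_vectors: np.ndarray      # p x k
    pct_squared_covariance: np.ndarray
    state_scores: np.ndarray | None = None    # n x k
    change_scores: np.ndarray | None = None   # n x k
    slopes: np.ndarray | None = None
    correlations: np.ndarray | None = None
    canalization_index: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.singular_values)


def _as_blocks(X_t, X_next) -> tuple[np.ndarray, np.ndarray]:
    X_t = np.asarray(X_t, dtype=float)
    X_next = np.asarray(X_next, dtype=float)
    if X_t.ndim != 2 or X_next.ndim != 2:
        raise ValueError("blocks must be 2-d (individuals x traits)")
    if X_t.shape != X_next.shape:
        raise ValueError(
            f"blocks must hold the same individuals and traits, "
            f"got {X_t.shape} vs {X_next.shape}"
        )
    if X_t.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    return X_t, X_next


def cross_covariance(X_t, X_next) -> np.ndarray:
    """Cross-covariance cov(x_t, x_{t+1} - x_t) between state and change.

    Entry (i, j) is the covariance of trait i at age t with the change of
    trait j over the step, with the unbiased (n - 1) denominator.  Under the
    canalization model this matrix approximates (minus) cov(d) Theta, the
    dominant term of the covariance change due to canalization.
    """
    X_t, X_next = _as_blocks(X_t, X_next)
    n = X_t.shape[0]
    D = X_next - X_t
    Xc = X_t - X_t.mean(axis=0)
    Dc = D - D.mean(axis=0)
    return Xc.T @ Dc / (n - 1)


def estimate_theta_matrix(
    X_t, X_next, allow_pseudo_inverse: bool = False
) -> ThetaMatrixEstimate:
    """Estimate the canalization/compensation matrix at one age step.

    Returns minus the multivariate multiple-regression coefficient of the
    change on the state, Theta_hat = -cov(x_t)^{-1} cov(x_t, x_{t+1} - x_t),
    so diagonal entries are positive under canalization.

    A stable estimate requires a sample size that greatly exceeds the
    number of variables; the estimator refuses when n <= p + 1 or when
    cov(x_t) is ill-conditioned (unless ``allow_pseudo_inverse`` is set, in
    which case the Moore-Penrose inverse is used).
    """
    X_t, X_next = _as_blocks(X_t, X_next)
    n, p = X_t.shape
    if n <= p + 1:
        raise ValueError(
            f"n = {n} <= p + 1 = {p + 1}: a stable estimation of the "
            "canalization matrix requires a sample size that greatly exceeds "
            "the number of variables; use pls_canalization instead"
        )
    Xc = X_t - X_t.mean(axis=0)
    cov_x = Xc.T @ Xc / (n - 1)
    cond = float(np.linalg.cond(cov_x))
    ccov = cross_covariance(X_t, X_next)
    if cond > MAX_CONDITION:
        if not allow_pseudo_inverse:
            raise ValueError(
                f"cov(x_t) condition number {cond:.3g} exceeds {MAX_CONDITION:.0e}; "
                "pass allow_pseudo_inverse=True to force a pseudo-inverse solution"
            )
        theta = -np.linalg.pinv(cov_x) @ ccov
    else:
        theta = -scipy.linalg.solve(cov_x, ccov, assume_a="pos")
    return ThetaMatrixEstimate(
        theta_hat=theta, cross_cov=ccov, n=n, condition_estimate=cond
    )


def expected_cov_change(theta_matrix, cov_d) -> np.ndarray:
    """Expected change in covariance structure due to canalization.

    Theta' cov(d) Theta - cov(d) Theta - Theta' cov(d): the quadratic term
    is negligible for small Theta, leaving the cross-covariance matrix and
    its transpose as the dominant effect.
    """
    Th = np.asarray(theta_matrix, dtype=float)
    C = np.asarray(cov_d, dtype=float)
    if Th.shape != C.shape or Th.ndim != 2 or Th.shape[0] != Th.shape[1]:
        raise ValueError("theta_matrix and cov_d must be conforming square matrices")
    return Th.T @ C @ Th - C @ Th - Th.T @ C


def total_canalized_variance(X_t, X_next) -> float:
    """Total canalized variance approximation 1.5 * Tr(cov(x_t, x_{t+1} - x_t)).

    Equals the sum over coordinates of the univariate 1.5 x lag-covariance
    approximation; invariant under orthogonal rotation of the trait space.
    """
    return float(1.5 * np.trace(cross_covariance(X_t, X_next)))


def _canonical_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each (u_i, v_i) pair so u_i's largest-magnitude entry is positive."""
    U = U.copy()
    V = V.copy()
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    return U, V


def _svd_result(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(M)
    U, V = _canonical_signs(U[:, :k], Vt.T[:, :k])
    return U, s[:k], V


def _degeneracy_flags(s_full: np.ndarray, k: int) -> np.ndarray:
    flags = np.zeros(k, dtype=bool)
    if len(s_full) < 2 or s_full[0] == 0:
        return flags
    gaps = s_full[:-1] - s_full[1:]
    for i in range(k):
        near_next = i < len(gaps) and gaps[i] < DEGENERACY_RTOL * s_full[0]
        near_prev = i > 0 and gaps[i - 1] < DEGENERACY_RTOL * s_full[0]
        flags[i] = near_next or near_prev
    return flags


def pls_canalization(X_t, X_next, k: int | None = None) -> PLSResult:
    """Two-block PLS of state against developmental change.

    Singular value decomposition of cov(x_t, x_{t+1} - x_t): the i-th pair
    of singular vectors (u_i, v_i) gives the state feature x_t' u_i and
    change feature (x_{t+1} - x_t)' v_i with the i-th largest covariance
    (= the singular value), a proxy for canalized variance of that feature.
    Because singular values are non-negative, canalization versus
    compensation is read from u_i' v_i (the ``canalization_index``): values
    near -1 mean the change opposes the state along the same feature (pure
    canalization), values near 0 mean the change lies in an unrelated
    feature (compensation).

    Sign convention: each pair is flipped so the largest-magnitude entry of
    u_i is positive, making output deterministic across platforms.  Pairs
    whose singular values are closer than ``DEGENERACY_RTOL`` (relative to
    the largest) are flagged degenerate — only their subspace is identified.
    """
    X_t, X_next = _as_blocks(X_t, X_next)
    n, p = X_t.shape
    if k is None:
        k = min(p, n - 1)
    if not 1 <= k <= min(p, n - 1):
        raise ValueError(f"k must be in [1, min(p, n-1)] = [1, {min(p, n - 1)}]")
    M = cross_covariance(X_t, X_next)
    _, s_full, _ = np.linalg.svd(M)
    U, s, V = _svd_result(M, k)
    degenerate = _degeneracy_flags(s_full, k)
    if degenerate.any():
        warnings.warn(
            "near-degenerate singular values: the affected dimensions are "
            "identified only up to rotation within their subspace",
            stacklevel=2,
        )

    D = X_next - X_t
    state_scores = (X_t - X_t.mean(axis=0)) @ U
    change_scores = (D - D.mean(axis=0)) @ V
    # per-dimension strength of canalization: the univariate-style negated
    # slope of the change *along u_i* on the state along u_i.  Projecting the
    # change on u (not v) keeps the sign independent of the SVD sign
    # convention, is positive under canalization, and reduces exactly to the
    # univariate estimator when p = 1.
    change_on_u = (D - D.mean(axis=0)) @ U
    slopes = np.empty(k)
    corrs = np.empty(k)
    for i in range(k):
        a, b = state_scores[:, i], change_scores[:, i]
        va = np.var(a, ddof=1)
        slopes[i] = -np.cov(change_on_u[:, i], a, ddof=1)[0, 1] / va if va > 0 else np.nan
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        corrs[i] = (
            np.cov(b, a, ddof=1)[0, 1] / (sa * sb) if sa > 0 and sb > 0 else np.nan
        )

    total_sq = float(np.sum(s_full**2))
    pct = 100 * s**2 / total_sq if total_sq > 0 else np.zeros(k)
    return PLSResult(
        singular_values=s,
        left_vectors=U,
        right_vectors=V,
        pct_squared_covariance=pct,
        state_scores=state_scores,
        change_scores=change_scores,
        slopes=slopes,
        correlations=corrs,
        canalization_index=np.einsum("ij,ij->j", U, V),
        degenerate=degenerate,
    )


def reduced_rank_theta(theta_estimate: ThetaMatrixEstimate, k: int | None = None) -> PLSResult:
    """Canonical (singular value) decomposition of the estimated Theta matrix.

    The singular-vector pairs are the trait combinations with maximal
    *strength* of canalization: the OLS slope of the projected change
    (x_{t+1} - x_t)' v_1 on the projected state x_t' u_1 equals minus the
    leading singular value (reduced-rank regression).  Percent squared
    covariance here refers to Theta's squared singular values.
    """
    Th = theta_estimate.theta_hat
    p = Th.shape[0]
    if k is None:
        k = p
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    _, s_full, _ = np.linalg.svd(Th)
    U, s, V = _svd_result(Th, k)
    total_sq = float(np.sum(s_full**2))
    pct = 100 * s**2 / total_sq if total_sq > 0 else np.zeros(k)
    return PLSResult(
        singular_values=s,
        left_vectors=U,
        right_vectors=V,
        pct_squared_covariance=pct,
        canalization_index=np.einsum("ij,ij->j", U, V),
        degenerate=_degeneracy_flags(s_full, k),
    )


def track_dimension_variance(series_by_age, directions) -> dict[str, np.ndarray]:
    """Cross-sectional variance of trait-space directions across ages.

    Parameters
    ----------
    series_by_age : sequence of (n_t, p) arrays
        Trait blocks per age, all in the same coordinate system.
    directions : (p, k) array
        Directions (columns); non-unit columns are normalized with a warning.

    Returns
    -------
    dict with ``variance`` (n_ages x k) — variance of the projections per
    age — and ``canalized_var`` ((n_ages - 1) x k) — the per-step 1.5 x
    lag-covariance approximation along each direction (rows of NaN where a
    step's blocks differ in individual count).
    """
    blocks = [np.asarray(b, dtype=float) for b in series_by_age]
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.shape[0] == 1 and blocks[0].shape[1] != 1:
        dirs = dirs.T
    norms = np.linalg.norm(dirs, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero direction vector")
    if not np.allclose(norms, 1.0, atol=1e-8):
        warnings.warn("non-unit direction(s) normalized", stacklevel=2)
        dirs = dirs / norms
    T = len(blocks)
    k = dirs.shape[1]
    var = np.full((T, k), np.nan)
    for t, b in enumerate(blocks):
        if b.shape[0] >= 2:
            var[t] = np.var(b @ dirs, axis=0, ddof=1)
    canal = np.full((T - 1, k), np.nan)
    for t in range(T - 1):
        b0, b1 = blocks[t], blocks[t + 1]
        if b0.shape[0] != b1.shape[0] or b0.shape[0] < 3:
            continue
        s0 = b0 @ dirs
        s1 = b1 @ dirs
        for i in range(k):
            canal[t, i] = 1.5 * np.cov(s1[:, i] - s0[:, i], s0[:, i], ddof=1)[0, 1]
    return {"variance": var, "canalized_var": canal}
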