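"""Canonical correlation analysis of (miRNA group, mRNA group) pairs.

The strength of a group pair is the first canonical correlation: the maximal
Pearson correlation r = corr(a'X, b'Y) over coefficient vectors a, b on the
two groups' expression submatrices. Three solvers are provided:

``classical``
    Exact CCA via the SVD of Sigma_XX^{-1/2} Sigma_XY Sigma_YY^{-1/2};
    valid only when n > |C_x| + |C_y| and both covariances are invertible.
``ridge_regularized``
    Same construction with Sigma_XX + reg*I and Sigma_YY + reg*I, usable
    when covariances are (near-)singular.
``sparse_pmd``
    Diagonal-penalized sparse CCA in the penalized-matrix-decomposition
    style: rank-1 maximization of u' (X Y') v under unit l2 and l1 bounds
    on u and v, with the variance matrices approximated by the identity.
    This is the default because mRNA groups (hundreds of genes) routinely
    dwarf the sample count, making classical CCA ill-posed.

Features are standardized to zero mean and unit variance before any solver
runs. Only the first canonical correlation is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import GroupSizeError, ParameterError, SingularCovarianceError
from .grouping import Group
from .io import MatchedPair

METHODS = ("classical", "ridge_regularized", "sparse_pmd")


@dataclass
class CCAResult:
    """First canonical correlation with its coefficient vectors."""

    r: float
    a: np.ndarray
    b: np.ndarray
    method: str


@dataclass
class CORE:
    """A collective group relationship: a scored (miRNA group, mRNA group) pair."""

    mirna_group: Group
    mrna_group: Group
    strength: float
    rank: int
    method: str

    def to_json(self) -> dict:
        return {
            "rank": self.rank,
            "strength": self.strength,
            "method": self.method,
            "mirnas": self.mirna_group.sorted_members(),
            "mrnas": self.mrna_group.sorted_members(),
        }


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return Xc / sd


def _cov_blocks(X: np.ndarray, Y: np.ndarray):
    """Covariance blocks of standardized row-variables (n-1 divisor)."""
    n = X.shape[1]
    Sxx = (X @ X.T) / (n - 1)
    Syy = (Y @ Y.T) / (n - 1)
    Sxy = (X @ Y.T) / (n - 1)
    return Sxx, Syy, Sxy


def _inv_sqrt(S: np.ndarray, label: str) -> np.ndarray:
    vals, vecs = linalg.eigh(S)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(vals.max(), 0.0)
    if vals.min() <= tol:
        raise SingularCovarianceError(
            f"{label} covariance is singular under the classical method; "
            "use ridge_regularized or sparse_pmd"
        )
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def classical_cca(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Exact first canonical correlation of row-variable matrices X (p x n), Y (q x n).

    r is the largest singular value of Sigma_XX^{-1/2} Sigma_XY Sigma_YY^{-1/2};
    for p = q = 1 this reduces to |PCC|. Coefficients give unit-variance
    canonical variates. Raises SingularCovarianceError when either covariance
    is not invertible, and ParameterError when n <= p + q (ill-posed).
    """
    p, n = X.shape
    q = Y.shape[0]
    if n <= p + q:
        raise ParameterError(
            f"classical CCA needs n > |C_x| + |C_y| (got n={n}, p+q={p + q}); "
            "use ridge_regularized or sparse_pmd"
        )
    Xs, Ys = _standardize_rows(X), _standardize_rows(Y)
    Sxx, Syy, Sxy = _cov_blocks(Xs, Ys)
    Rx = _inv_sqrt(Sxx, "miRNA-side")
    Ry = _inv_sqrt(Syy, "mRNA-side")
    U, s, Vt = linalg.svd(Rx @ Sxy @ Ry)
    r = float(np.clip(s[0], 0.0, 1.0))
    a = Rx @ U[:, 0]
    b = Ry @ Vt[0, :]
    return CCAResult(r=r, a=a, b=b, method="classical")


def ridge_cca(X: np.ndarray, Y: np.ndarray, reg: float = 0.1) -> CCAResult:
    """Ridge-regularized CCA: covariances shrunk toward the identity by reg * I."""
    if reg <= 0:
        raise ParameterError("ridge regularization must be positive")
    Xs, Ys = _standardize_rows(X), _standardize_rows(Y)
    Sxx, Syy, Sxy = _cov_blocks(Xs, Ys)
    Sxx = Sxx + reg * np.eye(Sxx.shape[0])
    Syy = Syy + reg * np.eye(Syy.shape[0])
    Rx = _inv_sqrt(Sxx, "miRNA-side")
    Ry = _inv_sqrt(Syy, "mRNA-side")
    U, s, Vt = linalg.svd(Rx @ Sxy @ Ry)
    a = Rx @ U[:, 0]
    b = Ry @ Vt[0, :]
    r = _empirical_corr(Xs, Ys, a, b)
    return CCAResult(r=r, a=a, b=b, method="ridge_regularized")


def _empirical_corr(Xs, Ys, a, b) -> float:
    """|Pearson correlation| of the two canonical variates, clipped to [0, 1]."""
    u = a @ Xs
    v = b @ Ys
    su, sv = u.std(), v.std()
    if su <= 0 or sv <= 0:
        return 0.0
    r = float(np.corrcoef(u, v)[0, 1])
    return float(np.clip(abs(r), 0.0, 1.0))


def _soft(w: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)


def _l1_unit_project(w: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold w so that after l2 normalization ||.||_1 <= c.

    Standard PMD update step: binary search on the threshold.
    """
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w)
    u = w / norm
    if np.abs(u).sum() <= c:
        return u
    lo, hi = 0.0, float(np.abs(w).max())
    for _ in range(60):
        mid = (lo + hi) / 2.0
        su = _soft(w, mid)
        nrm = np.linalg.norm(su)
        if nrm == 0 or np.abs(su / nrm).sum() < c:
            hi = mid
        else:
            lo = mid
    su = _soft(w, lo)
    nrm = np.linalg.norm(su)
    return su / nrm if nrm > 0 else np.zeros_like(w)


def sparse_pmd_cca(
    X: np.ndarray,
    Y: np.ndarray,
    penalty_x: float = 0.3,
    penalty_y: float = 0.3,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CCAResult:
    """Sparse diagonal-penalized CCA via rank-1 penalized matrix decomposition.

    Maximizes u' K v with K = Xs Ys' subject to ||u||_2 <= 1, ||v||_2 <= 1,
    ||u||_1 <= penalty_x * sqrt(p), ||v||_1 <= penalty_y * sqrt(q) (bounds
    clamped to the feasible range [1, sqrt(dim)]). Initialization is the
    leading singular-vector pair of K with a fixed sign convention, so the
    solver is deterministic. The reported r is the empirical correlation of
    the resulting canonical variates.
    """
    if not (0.0 < penalty_x <= 1.0 and 0.0 < penalty_y <= 1.0):
        raise ParameterError("sparse penalties must lie in (0, 1]")
    Xs, Ys = _standardize_rows(X), _standardize_rows(Y)
    p, q = Xs.shape[0], Ys.shape[0]
    K = Xs @ Ys.T
    cx = min(max(penalty_x * np.sqrt(p), 1.0), np.sqrt(p))
    cy = min(max(penalty_y * np.sqrt(q), 1.0), np.sqrt(q))
    if not np.any(K):
        return CCAResult(r=0.0, a=np.zeros(p), b=np.zeros(q), method="sparse_pmd")
    U, _s, Vt = linalg.svd(K, full_matrices=False)
    u, v = U[:, 0], Vt[0, :]
    # deterministic sign: largest-magnitude coefficient of v positive
    sign = np.sign(v[np.argmax(np.abs(v))]) or 1.0
    u, v = u * sign, v * sign
    d_prev = -np.inf
    for _ in range(max_iter):
        u = _l1_unit_project(K @ v, cx)
        v = _l1_unit_project(K.T @ u, cy)
        d = float(u @ K @ v)
        if abs(d - d_prev) <= tol * max(1.0, abs(d)):
            break
        d_prev = d
    r = _empirical_corr(Xs, Ys, u, v)
    return CCAResult(r=r, a=u, b=v, method="sparse_pmd")


def canonical_correlation(
    X_sub: np.ndarray,
    Y_sub: np.ndarray,
    method: str = "sparse_pmd",
    **kwargs,
) -> CCAResult:
    """First canonical correlation between two expression submatrices.

    X_sub and Y_sub are |C_x| x n and |C_y| x n row-variable matrices over
    the same n samples. Each group must have at least 2 features (CCA is not
    defined on singleton groups in this pipeline) and n >= 3.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    Y_sub = np.asarray(Y_sub, dtype=float)
    if X_sub.ndim != 2 or Y_sub.ndim != 2 or X_sub.shape[1] != Y_sub.shape[1]:
        raise ParameterError("X_sub and Y_sub must be 2-D with matching sample counts")
    if X_sub.shape[1] < 3:
        raise ParameterError("canonical correlation needs n >= 3 samples")
    if X_sub.shape[0] < 2 or Y_sub.shape[0] < 2:
        raise GroupSizeError(
            "canonical correlation requires groups with at least 2 components"
        )
    if method == "classical":
        return classical_cca(X_sub, Y_sub)
    if method == "ridge_regularized":
        return ridge_cca(X_sub, Y_sub, **kwargs)
    if method == "sparse_pmd":
        return sparse_pmd_cca(X_sub, Y_sub, **kwargs)
    raise ParameterError(f"method must be one of {METHODS}, got {method!r}")


def score_group_pairs(
    groups_mirna: list[Group],
    groups_mrna: list[Group],
    pair: MatchedPair,
    rho: float = 0.5,
    method: str = "sparse_pmd",
    **kwargs,
) -> list[CORE]:
    """Score every (miRNA group, mRNA group) pair; keep those with r >= rho.

    A group may appear in multiple COREs. Pairs whose CCA fails (e.g. a
    singular covariance under the classical method) are skipped, not fatal.
    Retained COREs are ranked 1..#C by r descending, ties broken by larger
    total group size, then by lexicographically smallest members.
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"rho must be in [0, 1], got {rho}")
    scored = []
    for gm in groups_mirna:
        X_sub = pair.mirna.subset_features(gm.sorted_members())
        for gg in groups_mrna:
            Y_sub = pair.mrna.subset_features(gg.sorted_members())
            try:
                res = canonical_correlation(X_sub, Y_sub, method=method, **kwargs)
            except (GroupSizeError, SingularCovarianceError, ParameterError):
                continue
            if res.r >= rho:
                scored.append((gm, gg, res))
    scored.sort(
        key=lambda t: (
            -t[2].r,
            -(len(t[0]) + len(t[1])),
            t[0].sorted_members(),
            t[1].sorted_members(),
        )
    )
    return [
        CORE(mirna_group=gm, mrna_group=gg, strength=res.r, rank=i, method=res.method)
        for i, (gm, gg, res) in enumerate(scored, start=1)
    ]
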