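"""Soft-margin Gaussian-kernel SVM solved in the dual, with CV penalty selection.

The dual problem for labels y in {-1, +1} and kernel matrix K is

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0,

solved here by sequential minimal optimisation (SMO) with maximal-violating-
pair working-set selection: each iteration picks the pair (i, j) with the
largest KKT violation and solves the two-variable subproblem analytically.
The stopping rule is the violation gap m(a) - M(a) < tol, which bounds the
KKT residuals of the returned solution.  The inner loop is numba-jitted when
numba is importable; the pure-Python body is identical.

The decision function is f(x) = sum_s a_s y_s K(x_s, x) + b over support
vectors; the offset b is the mean KKT residual over unbounded support vectors
(0 < a < C), or the midpoint of the feasible interval when every support
vector sits on the box boundary.

Composite per-child scores are produced out-of-fold: the data are split into
stratified folds keyed to trio identity, each fold is scored by a model
trained on the others, and the penalty C is chosen on the same partition by
maximising the cross-validated AUC (ties to the smallest C).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .transmission import ScoreMatrix

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


class ConvergenceError(RuntimeError):
    """Solver hit its iteration cap; carries the remaining KKT violation gap."""

    def __init__(self, gap: float, max_iter: int):
        self.gap = gap
        super().__init__(
            f"SMO did not converge in {max_iter} iterations (violation gap {gap:.3e})"
        )


@dataclass
class KernelConfig:
    """Kernel and model-selection settings.

    sigma2
        Gaussian scale sigma_g^2; 1 by default (transmission scores share the
        [-1, 1] scale by construction, so no standardisation is applied).
    penalty_grid
        Candidate box penalties C; integers 1..10 by default.
    folds
        Stratified cross-validation folds for penalty selection and
        out-of-fold scoring; 5 by default.
    seed
        Keys the fold assignment (jointly with each trio's identity).
    """

    sigma2: float = 1.0
    penalty_grid: tuple = tuple(range(1, 11))
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not self.penalty_grid or any(c <= 0 for c in self.penalty_grid):
            raise ValueError("penalty grid must be nonempty and positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class SvmModel:
    """A fitted dual SVM: multipliers, offset and stored support rows."""

    alphas: np.ndarray
    labels: np.ndarray
    offset: float
    sigma2: float
    penalty: float
    support_index: np.ndarray
    support_rows: np.ndarray | None = None
    n_iter: int = 0
    gap: float = np.nan
    dual_objective: float = np.nan
    tol: float = 1e-5

    @property
    def support_alphas(self) -> np.ndarray:
        return self.alphas[self.support_index]

    @property
    def support_labels(self) -> np.ndarray:
        return self.labels[self.support_index]


# ---------------------------------------------------------------------------
# kernel


def gaussian_kernel(x: np.ndarray, x_prime: np.ndarray, sigma2: float = 1.0) -> float:
    """exp(-||x - x'||^2 / (2 sigma2)); 1 at zero distance."""
    x = np.asarray(x, float)
    x_prime = np.asarray(x_prime, float)
    if x.shape != x_prime.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {x_prime.shape}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    d2 = float(np.sum((x - x_prime) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma2)))


def kernel_matrix(
    X: np.ndarray, Y: np.ndarray | None = None, sigma2: float = 1.0
) -> np.ndarray:
    """Gaussian kernel Gram matrix between row sets X and Y (X with itself
    when Y is omitted, symmetrised with unit diagonal)."""
    X = np.atleast_2d(np.asarray(X, float))
    if Y is None:
        d2 = cdist(X, X, metric="sqeuclidean")
        K = np.exp(-d2 / (2.0 * sigma2))
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
        return K
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature length mismatch: {X.shape[1]} vs {Y.shape[1]}")
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma2))


# ---------------------------------------------------------------------------
# SMO


def _smo_body(K, y, C, tol, max_iter, alpha, G):
    """Maximal-violating-pair SMO; mutates alpha and G in place.

    G is the gradient of the (minimisation-form) dual 1/2 a'Qa - 1'a, i.e.
    G_t = sum_i y_t y_i K_ti a_i - 1.  Returns (iterations, gap, converged).
    """
    n = K.shape[0]
    it = 0
    gap = np.inf
    while it < max_iter:
        gmax = -1e300
        gmin = 1e300
        ii = -1
        jj = -1
        for t in range(n):
            yg = -y[t] * G[t]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if yg > gmax:
                    gmax = yg
                    ii = t
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if yg < gmin:
                    gmin = yg
                    jj = t
        gap = gmax - gmin
        if gap < tol or ii < 0 or jj < 0:
            return it, gap, True
        eta = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if eta < 1e-12:
            eta = 1e-12
        step = gap / eta
        cap_i = (C - alpha[ii]) if y[ii] > 0.0 else alpha[ii]
        cap_j = alpha[jj] if y[jj] > 0.0 else (C - alpha[jj])
        clipped_i = step >= cap_i
        clipped_j = step >= cap_j
        if step > cap_i:
            step = cap_i
        if step > cap_j:
            step = cap_j
        if clipped_i and step == cap_i:
            alpha[ii] = C if y[ii] > 0.0 else 0.0
        else:
            alpha[ii] += y[ii] * step
        if clipped_j and step == cap_j:
            alpha[jj] = 0.0 if y[jj] > 0.0 else C
        else:
            alpha[jj] -= y[jj] * step
        for t in range(n):
            G[t] += y[t] * (K[t, ii] - K[t, jj]) * step
        it += 1
    return it, gap, False


_smo = njit(cache=True)(_smo_body) if njit is not None else _smo_body


def solve_dual(
    kernel: np.ndarray,
    labels: np.ndarray,
    penalty: float,
    tol: float = 1e-5,
    max_iter: int = 100_000,
    alpha0: np.ndarray | None = None,
    rows: np.ndarray | None = None,
    sigma2: float = 1.0,
) -> SvmModel:
    """Solve the box-constrained dual QP for one penalty value.

    ``alpha0`` warm-starts the solver (it must satisfy the equality constraint
    and lie inside the box, e.g. a solution at a smaller C).  ``rows`` are the
    training feature rows; storing them enables :func:`decision_scores` on new
    data.  Raises :class:`ConvergenceError` at the iteration cap.
    """
    K = np.ascontiguousarray(0.5 * (kernel + kernel.T), dtype=float)
    y = np.asarray(labels, dtype=float)
    if K.shape[0] != K.shape[1] or K.shape[0] != y.size:
        raise ValueError("kernel matrix and labels are inconsistent")
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be -1 or +1")
    if (y > 0).all() or (y < 0).all():
        raise ValueError("both classes must be present")
    C = float(penalty)
    if C <= 0:
        raise ValueError("penalty must be positive")

    if alpha0 is None:
        alpha = np.zeros(y.size)
        G = np.full(y.size, -1.0)
    else:
        alpha = np.clip(np.asarray(alpha0, float).copy(), 0.0, C)
        G = y * (K @ (y * alpha)) - 1.0
    n_iter, gap, converged = _smo(K, y, C, float(tol), int(max_iter), alpha, G)
    if not converged:
        raise ConvergenceError(gap, max_iter)

    b = _offset(alpha, y, G, C, tol)
    Qa = y * (K @ (y * alpha))
    objective = float(alpha.sum() - 0.5 * alpha @ Qa)
    support = np.where(alpha > tol)[0]
    return SvmModel(
        alphas=alpha,
        labels=y.astype(int),
        offset=b,
        sigma2=sigma2,
        penalty=C,
        support_index=support,
        support_rows=None if rows is None else np.asarray(rows, float)[support],
        n_iter=n_iter,
        gap=gap,
        dual_objective=objective,
        tol=tol,
    )


def _offset(alpha: np.ndarray, y: np.ndarray, G: np.ndarray, C: float, tol: float) -> float:
    """Offset b from KKT: mean residual over unbounded support vectors, else
    the midpoint of the feasible interval defined by the bounded points."""
    e = -y * G  # y_t - sum_i a_i y_i K_it
    unbounded = (alpha > tol) & (alpha < C - tol)
    if unbounded.any():
        return float(e[unbounded].mean())
    at_zero = alpha <= tol
    at_c = alpha >= C - tol
    lower = (at_zero & (y > 0)) | (at_c & (y < 0))  # constraints b >= e_t
    upper = (at_zero & (y < 0)) | (at_c & (y > 0))  # constraints b <= e_t
    lo = e[lower].max() if lower.any() else -np.inf
    hi = e[upper].min() if upper.any() else np.inf
    if np.isinf(lo):
        return float(hi)
    if np.isinf(hi):
        return float(lo)
    return float(0.5 * (lo + hi))


def decision_scores(model: SvmModel, rows: np.ndarray) -> np.ndarray:
    """f(x) = sum_s a_s y_s K(x_s, x) + b for each row; higher means more
    like the +1 (unaffected) class."""
    if model.support_rows is None:
        raise ValueError("model was fitted without feature rows; cannot score")
    rows = np.atleast_2d(np.asarray(rows, float))
    Kc = kernel_matrix(model.support_rows, rows, sigma2=model.sigma2)
    return (model.support_alphas * model.support_labels) @ Kc + model.offset


# ---------------------------------------------------------------------------
# cross-validation and penalty selection


def assign_folds(
    trio_ids: list[str], labels: np.ndarray, folds: int, seed: int
) -> np.ndarray:
    """Stratified fold assignment keyed to trio identity.

    Within each class, trios are ordered by a CRC32 hash of (seed, trio_id)
    and dealt round-robin, so fold membership is a pure function of the seed
    and the identity set — permuting the input rows permutes nothing.
    """
    labels = np.asarray(labels)
    fold = np.empty(len(trio_ids), dtype=int)
    for cls in (-1, +1):
        idx = np.where(labels == cls)[0]
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has {len(idx)} members < {folds} folds; "
                "reduce the number of folds"
            )
        keys = sorted(
            range(len(idx)),
            key=lambda k: (
                zlib.crc32(f"{seed}:{trio_ids[idx[k]]}".encode()),
                trio_ids[idx[k]],
                k,
            ),
        )
        for rank, k in enumerate(keys):
            fold[idx[k]] = rank % folds
    return fold


def _cv_scores_from_kernel(
    K: np.ndarray,
    labels: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    penalty: float,
    tol: float = 1e-5,
    max_iter: int = 100_000,
    warm: list | None = None,
) -> tuple[np.ndarray, list]:
    """Out-of-fold decision scores from a precomputed Gram matrix."""
    y = np.asarray(labels, float)
    scores = np.empty(y.size)
    warm_out: list = [None] * n_folds
    for f in range(n_folds):
        te = fold_ids == f
        tr = ~te
        model = solve_dual(
            K[np.ix_(tr, tr)],
            y[tr],
            penalty,
            tol=tol,
            max_iter=max_iter,
            alpha0=None if warm is None else warm[f],
        )
        warm_out[f] = model.alphas
        scores[te] = (model.alphas * y[tr]) @ K[np.ix_(tr, te)] + model.offset
    return scores, warm_out


def cross_validated_scores(
    features: ScoreMatrix, penalty: float, config: KernelConfig
) -> np.ndarray:
    """One out-of-fold composite score per trio, in input order."""
    K = kernel_matrix(features.values, sigma2=config.sigma2)
    fold_ids = assign_folds(features.trio_ids, features.labels, config.folds, config.seed)
    scores, _ = _cv_scores_from_kernel(
        K, features.labels, fold_ids, config.folds, penalty
    )
    return scores


@dataclass
class PenaltySearch:
    """Grid-search result: chosen C, the CV-AUC table, and per-C scores."""

    chosen_penalty: float
    table: pd.DataFrame
    scores_by_penalty: dict = field(default_factory=dict)
    fold_ids: np.ndarray | None = None
    kernel: np.ndarray | None = None


def _penalty_search(
    features: ScoreMatrix,
    config: KernelConfig,
    tol: float = 1e-5,
    max_iter: int = 100_000,
) -> PenaltySearch:
    from .auc_test import auc_mann_whitney  # local import: avoids module cycle

    K = kernel_matrix(features.values, sigma2=config.sigma2)
    fold_ids = assign_folds(
        features.trio_ids, features.labels, config.folds, config.seed
    )
    grid = sorted(float(c) for c in config.penalty_grid)
    case = features.labels == -1
    warm: list | None = None
    rows = []
    scores_by: dict = {}
    for C in grid:
        scores, warm = _cv_scores_from_kernel(
            K, features.labels, fold_ids, config.folds, C,
            tol=tol, max_iter=max_iter, warm=warm,
        )
        oriented = -scores  # affected class has label -1, i.e. low f(x)
        theta = auc_mann_whitney(oriented[case], oriented[~case])
        rows.append((C, theta))
        scores_by[C] = scores
    table = pd.DataFrame(rows, columns=["penalty", "cv_auc"])
    best = grid[int(np.argmax(table["cv_auc"].to_numpy()))]  # first max: smallest C
    return PenaltySearch(best, table, scores_by, fold_ids, K)


def select_penalty(
    features: ScoreMatrix, config: KernelConfig
) -> tuple[float, pd.DataFrame]:
    """Choose C from the grid by maximal cross-validated AUC (ties -> smallest C).

    Returns the chosen penalty and the per-penalty CV-AUC table.
    """
    search = _penalty_search(features, config)
    return search.chosen_penalty, search.table
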