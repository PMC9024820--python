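"""The generalized independent noise (GIN) condition and the IV-GIN test.

For two column vectors of variables P and Q, take any nonzero omega with
omega^T E[P Q^T] = 0 and form the surrogate E_{P||Q} = omega^T P.  The pair
(Q, P) satisfies the GIN condition iff the surrogate is statistically
independent of Q.  Validity of an instrument Z for the effect X -> Y given
a conditioning set W implies that ({Z} u W, {X, Y} u W) satisfies GIN — a
*necessary* condition, which is what makes invalid instruments detectable
from purely observational non-Gaussian data.

Two routes are provided:

* :func:`gin_test` / :func:`iv_gin_test` — the finite-sample test: omega
  from the empirical cross-covariance, pairwise HSIC p-values of the
  surrogate against each member of Q, pooled by Fisher's method;
* :func:`population_gin_oracle` — the exact population answer for a known
  :class:`~ivgin.sem.LinearSEM`, through the Darmois-Skitovitch theorem:
  the surrogate and Q are dependent iff they share a non-Gaussian noise
  component with nonzero loadings on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .independence import IndependenceResult, fisher_combine, hsic_pvalue
from .sem import LinearSEM

__all__ = [
    "GINResult",
    "DegenerateCovarianceError",
    "solve_omega",
    "gin_test",
    "iv_gin_test",
    "population_gin_oracle",
    "population_iv_gin_oracle",
]

# relative singular-value threshold below which the left-null space is
# treated as multi-dimensional (a faithfulness violation)
_DEGENERATE_RTOL = 1e-8
# absolute tolerance on noise loadings in the population oracle
_LOADING_TOL = 1e-9


class DegenerateCovarianceError(ValueError):
    """Left-null space of the cross-covariance has dimension >= 2."""


@dataclass(frozen=True)
class GINResult:
    """Outcome of one (empirical) GIN test.

    ``omega`` is unit-norm with its first nonzero entry positive; the
    surrogate is the rowwise projection omega^T P.  ``holds`` is True when
    the Fisher-combined independence p-value is >= the test level.
    """

    p_columns: tuple[str, ...]
    q_columns: tuple[str, ...]
    omega: np.ndarray
    surrogate: np.ndarray | None
    independence: IndependenceResult | None
    alpha: float
    holds: bool
    degenerate: bool = False

    @property
    def pvalue(self) -> float | None:
        return None if self.independence is None else self.independence.pvalue


def solve_omega(sigma_pq: np.ndarray, *, return_degenerate: bool = False):
    """Unit-norm left-null vector of the |P| x |Q| cross-covariance.

    Requires |P| = |Q| + 1, the only regime where the null space is
    generically one-dimensional.  The vector is the left-singular vector of
    the smallest singular value, sign-normalized so its first nonzero entry
    is positive.  A second vanishing singular value flags a degenerate
    (unfaithful) covariance; a warning is emitted and, when requested, the
    flag is returned alongside omega.
    """
    sigma = np.atleast_2d(np.asarray(sigma_pq, dtype=float))
    p_dim, q_dim = sigma.shape
    if p_dim != q_dim + 1:
        raise ValueError(
            f"need |P| = |Q| + 1 for a one-dimensional null space, got"
            f" {p_dim} x {q_dim}"
        )
    U, s, _ = np.linalg.svd(sigma, full_matrices=True)
    omega = U[:, -1]
    degenerate = bool(s[0] <= 0 or s[-1] < _DEGENERATE_RTOL * s[0])
    if degenerate:
        warnings.warn(
            "cross-covariance is rank-deficient: omega is not unique"
            " (possible faithfulness violation)",
            stacklevel=2,
        )
    for val in omega:
        if abs(val) > 1e-12:
            if val < 0:
                omega = -omega
            break
    if return_degenerate:
        return omega, degenerate
    return omega


def _centered(data: pd.DataFrame, cols: list[str]) -> np.ndarray:
    mat = data[cols].to_numpy(dtype=float)
    return mat - mat.mean(axis=0, keepdims=True)


def gin_test(
    data: pd.DataFrame,
    p_columns,
    q_columns,
    alpha: float = 0.01,
    *,
    method: str = "gamma",
    n_perm: int = 500,
    max_points: int = 2000,
    seed=0,
) -> GINResult:
    """Empirical GIN test of (Q, P) on a sample table.

    Columns are centered; omega comes from the 1/n empirical cross-
    covariance of P against Q; the surrogate is tested for independence
    against each Q column by HSIC and the p-values are Fisher-combined.
    ``holds`` means the combined p-value is >= alpha (independence not
    rejected).
    """
    p_cols = list(p_columns)
    q_cols = list(q_columns)
    if not p_cols or not q_cols:
        raise ValueError("P and Q must be nonempty")
    P = _centered(data, p_cols)
    Q = _centered(data, q_cols)
    n = len(data)
    sigma_pq = P.T @ Q / n
    omega, degenerate = solve_omega(sigma_pq, return_degenerate=True)
    surrogate = P @ omega
    seed = int(np.random.default_rng(seed).integers(2**31 - len(q_cols)))
    pvals = [
        hsic_pvalue(
            surrogate,
            Q[:, k],
            method=method,
            n_perm=n_perm,
            max_points=max_points,
            seed=seed + k,
        )
        for k in range(len(q_cols))
    ]
    independence = fisher_combine(pvals)
    return GINResult(
        p_columns=tuple(p_cols),
        q_columns=tuple(q_cols),
        omega=omega,
        surrogate=surrogate,
        independence=independence,
        alpha=alpha,
        holds=bool(independence.pvalue >= alpha),
        degenerate=degenerate,
    )


def iv_gin_test(
    data: pd.DataFrame,
    z: str,
    w,
    x: str,
    y: str,
    alpha: float = 0.01,
    **options,
) -> GINResult:
    """The IV-GIN test for instrument candidate z given conditioning set w:
    GIN applied with P = {x, y} u w and Q = {z} u w (w name-sorted)."""
    w = sorted({w} if isinstance(w, str) else set(w))
    if len({z, x, y} | set(w)) != 3 + len(w):
        raise ValueError("z, x, y, w must be distinct columns")
    return gin_test(data, [x, y, *w], [z, *w], alpha, **options)


# ---------------------------------------------------------------------------
# Population oracle (Darmois-Skitovitch)
# ---------------------------------------------------------------------------

def population_gin_oracle(sem: LinearSEM, p_nodes, q_nodes) -> bool:
    """Exact population GIN answer for a known SEM.

    Computes the reduced-form noise loadings of the surrogate
    (beta = omega^T A_P) and of Q (rows of A_Q); by Darmois-Skitovitch the
    surrogate and Q are dependent iff some *non-Gaussian* noise term loads
    on both.  Returns True iff no such shared component exists.
    """
    p_nodes = list(p_nodes)
    q_nodes = list(q_nodes)
    A = sem.noise_mixing()
    omega_vars = sem.noise_variances()
    A_P = A.loc[p_nodes].to_numpy()
    A_Q = A.loc[q_nodes].to_numpy()
    sigma_pq = A_P @ np.diag(omega_vars) @ A_Q.T
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            omega = solve_omega(sigma_pq)
        except UserWarning as exc:
            raise DegenerateCovarianceError(str(exc)) from None
    beta = omega @ A_P
    order = sem.node_order
    for j, node in enumerate(order):
        if sem.noises[node].is_gaussian:
            continue
        if abs(beta[j]) > _LOADING_TOL and np.any(np.abs(A_Q[:, j]) > _LOADING_TOL):
            return False
    return True


def population_iv_gin_oracle(sem: LinearSEM, z: str, w, x: str, y: str) -> bool:
    """Population IV-GIN oracle: P = {x, y} u w, Q = {z} u w."""
    w = sorted({w} if isinstance(w, str) else set(w))
    return population_gin_oracle(sem, [x, y, *w], [z, *w])
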