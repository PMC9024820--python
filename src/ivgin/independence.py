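"""Statistical engine: kernel independence testing and p-value combination.

The GIN test needs a nonparametric independence test between a surrogate
variable and each member of Q; we use the Hilbert-Schmidt independence
criterion (HSIC) with Gaussian kernels and median-heuristic bandwidths.
The null distribution of the biased statistic is approximated either by a
moment-matched gamma distribution (fast, the default) or by permutation.
Per-pair p-values are pooled with Fisher's method: -2 sum log p_k is
chi-square with 2k degrees of freedom under joint independence.

A Fisher-z test of vanishing partial correlation backs the instrument
relevance pre-check (Z must remain dependent on X given W).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndependenceResult",
    "hsic_pvalue",
    "fisher_combine",
    "partial_correlation_test",
    "partial_correlation_pvalue",
]

# p-values are clipped here before taking logs in Fisher's method.
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class IndependenceResult:
    """Fisher-combined outcome of a battery of pairwise independence tests."""

    pvalues: tuple[float, ...]
    statistic: float
    dof: int
    pvalue: float

    def reject(self, alpha: float) -> bool:
        return self.pvalue < alpha


def _gram_rbf(v: np.ndarray) -> np.ndarray | None:
    """Gaussian-kernel Gram matrix with the median heuristic: the squared
    bandwidth is half the median positive squared distance.  Returns None
    for (near-)constant input, where no bandwidth exists.

    Computed in single precision: the Gram matrices are O(n^2) and the
    downstream moment sums are insensitive to float32 rounding."""
    v = v.astype(np.float32)
    d2 = np.subtract.outer(v, v)
    np.square(d2, out=d2)
    # median of pairwise squared distances, from a size-capped prefix of the
    # (already randomly subsampled) points — the full median partition is a
    # hotspot at n^2 entries and the bandwidth only needs a stable location
    head = d2[: min(len(v), 1024), : min(len(v), 1024)]
    pos = head[head > 0]
    if pos.size == 0:
        return None
    med = float(np.median(pos))
    if med <= 0 or not np.isfinite(med):
        return None
    d2 /= -med
    return np.exp(d2, out=d2)


def _center_gram(K: np.ndarray) -> np.ndarray:
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    out = K - row
    out -= col
    out += row.mean()
    return out


def hsic_pvalue(
    x,
    y,
    *,
    method: str = "gamma",
    n_perm: int = 500,
    max_points: int = 2000,
    seed=0,
) -> float:
    """p-value of H0: x independent of y, via the biased HSIC statistic.

    Parameters
    ----------
    method : "gamma" (moment-matched null, fast) or "permutation"
    max_points : inputs longer than this are subsampled (seeded, uniform,
        without replacement) — the Gram matrices are O(n^2)
    seed : governs the subsample and the permutations
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 20:
        raise ValueError("need at least 20 observations for the HSIC test")
    if method not in ("gamma", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    if x.size > max_points:
        idx = rng.choice(x.size, size=max_points, replace=False)
        x, y = x[idx], y[idx]
    m = x.size
    K = _gram_rbf(x)
    L = _gram_rbf(y)
    if K is None or L is None:
        warnings.warn(
            "constant input vector: no dependence detectable, returning p=1",
            stacklevel=2,
        )
        return 1.0
    Kc = _center_gram(K)
    Lc = _center_gram(L)
    prod = Kc * Lc
    stat = float(prod.sum(dtype=np.float64) / m)

    if method == "permutation":
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(m)
            perm_stat = float(
                (Kc * Lc[np.ix_(perm, perm)]).sum(dtype=np.float64) / m
            )
            if perm_stat >= stat:
                count += 1
        return (1.0 + count) / (n_perm + 1.0)

    # Gamma approximation: match the first two moments of the null statistic.
    var_term = np.square(prod / 6.0, out=prod)
    var_hsic = float(
        var_term.sum(dtype=np.float64) - np.trace(var_term, dtype=np.float64)
    ) / (m * (m - 1))
    var_hsic *= 72.0 * (m - 4) * (m - 5) / (m * (m - 1) * (m - 2) * (m - 3))
    mu_x = float(K.sum(dtype=np.float64) - np.trace(K, dtype=np.float64)) / (
        m * (m - 1)
    )
    mu_y = float(L.sum(dtype=np.float64) - np.trace(L, dtype=np.float64)) / (
        m * (m - 1)
    )
    mean_hsic = (1.0 + mu_x * mu_y - mu_x - mu_y) / m
    if var_hsic <= 0 or mean_hsic <= 0:
        # degenerate moments (tiny samples / pathological kernels)
        return 1.0
    shape = mean_hsic**2 / var_hsic
    scale = var_hsic * m / mean_hsic
    return float(stats.gamma.sf(stat, shape, scale=scale))


def fisher_combine(pvals) -> IndependenceResult:
    """Pool p-values with Fisher's method.

    The statistic -2 sum log p_k follows chi-square with 2k degrees of
    freedom when all pairs are independent; zeros are clipped to the
    smallest positive representable value before taking logs.
    """
    pvals = tuple(float(p) for p in pvals)
    if not pvals:
        raise ValueError("fisher_combine needs at least one p-value")
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    clipped = np.clip(np.asarray(pvals), _P_FLOOR, 1.0)
    statistic = float(-2.0 * np.log(clipped).sum())
    dof = 2 * len(pvals)
    pvalue = float(stats.chi2.sf(statistic, dof))
    return IndependenceResult(pvals, statistic, dof, pvalue)


def partial_correlation_pvalue(data: pd.DataFrame, a: str, b: str, w=()) -> float:
    """Fisher-z p-value for H0: zero partial correlation of a and b given w."""
    w = sorted({w} if isinstance(w, str) else set(w))
    cols = [a, b, *w]
    if len(set(cols)) != len(cols):
        raise ValueError("columns a, b, w must be distinct")
    n = len(data)
    if n <= len(w) + 3:
        raise ValueError("need n > |w| + 3 observations")
    sub = data[cols].to_numpy(dtype=float)
    cov = np.cov(sub, rowvar=False).reshape(len(cols), len(cols))
    if not np.isfinite(cov).all() or np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            f"singular covariance among columns {cols}: collinear inputs"
        )
    prec = np.linalg.inv(cov)
    r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(r) * np.sqrt(n - len(w) - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def partial_correlation_test(
    data: pd.DataFrame, a: str, b: str, w=(), alpha: float = 0.01
) -> bool:
    """True iff a and b are judged *dependent* given w at level alpha."""
    return partial_correlation_pvalue(data, a, b, w) < alpha
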