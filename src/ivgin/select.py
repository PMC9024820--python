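"""Sequential selection of candidate instruments and the ratio estimator.

The selection algorithm scans conditioning-set sizes L = 0, 1, ... and, for
each not-yet-selected candidate Z, enumerates the subsets W of the other
candidates with |W| = L in lexicographic order.  A candidate is admitted as
soon as it passes an optional relevance pre-check (Z must stay dependent on
the treatment given W) and the IV-GIN test; its conditioning set is the
first — hence smallest — W at which it passed.  The scan stops when every
candidate is admitted or L reaches the number of still-unselected
candidates.  The output is a *candidate* set: the IV-GIN condition is
necessary but not sufficient, so membership certifies only that no
detectable violation was found.

The causal effect of treatment on outcome through an admitted instrument is
the ratio of partial covariances b_YX = sigma_ZY.W / sigma_ZX.W.

A population-oracle mode runs the identical control flow with the exact
GIN oracle and graphical relevance check in place of the finite-sample
tests; it returns exact answers on a known SEM and backs the completeness
check (every graphically valid instrument appears in the output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Callable

import numpy as np
import pandas as pd

from .gin import iv_gin_test, population_iv_gin_oracle
from .graphs import d_separated, instrument_criteria_holds
from .independence import partial_correlation_pvalue
from .sem import LinearSEM

__all__ = [
    "SelectionResult",
    "TestRecord",
    "IVEstimate",
    "WeakInstrumentError",
    "select_candidates",
    "select_candidates_oracle",
    "estimate_effect",
    "estimate_effect_from_cov",
    "completeness_check",
    "max_gin_tests",
]

_MIN_ROWS = 200  # kernel independence tests are unreliable below this


class WeakInstrumentError(ValueError):
    """The instrument-treatment partial covariance is (numerically) zero."""


@dataclass(frozen=True)
class TestRecord:
    """Audit entry for one (candidate, conditioning set) attempt."""

    candidate: str
    conditioning: tuple[str, ...]
    relevance_passed: bool
    pvalue: float | None
    holds: bool


@dataclass(frozen=True)
class SelectionResult:
    """Output of the sequential scan: admitted candidates, their minimal
    conditioning sets, and the full per-test audit trail."""

    candidates: tuple[str, ...]
    conset: dict[str, tuple[str, ...]]
    audit: tuple[TestRecord, ...] = field(default=())

    @property
    def n_gin_tests(self) -> int:
        return sum(1 for rec in self.audit if rec.relevance_passed)

    def __contains__(self, name: str) -> bool:
        return name in self.candidates


def max_gin_tests(n_candidates: int) -> int:
    """Worst-case number of GIN tests: sum_L |O| * C(|O|-1, L)."""
    return sum(
        n_candidates * comb(n_candidates - 1, L) for L in range(n_candidates)
    )


def _run_selection(
    pool: list[str],
    gin_holds: Callable[[str, tuple[str, ...]], tuple[bool, float | None]],
    relevant: Callable[[str, tuple[str, ...]], bool],
    max_cond_size: int | None,
) -> SelectionResult:
    """Shared control flow of the empirical and oracle selection modes."""
    pool = sorted(pool)
    if max_cond_size is None:
        max_cond_size = len(pool) - 1
    tag = list(pool)
    selected: list[str] = []
    conset: dict[str, tuple[str, ...]] = {}
    audit: list[TestRecord] = []
    length = 0
    while tag and length < len(tag) and length <= max_cond_size:
        for z in list(tag):
            others = [o for o in pool if o != z]
            for w in itertools.combinations(others, length):
                if not relevant(z, w):
                    audit.append(TestRecord(z, w, False, None, False))
                    continue
                holds, pvalue = gin_holds(z, w)
                audit.append(TestRecord(z, w, True, pvalue, holds))
                if holds:
                    selected.append(z)
                    conset[z] = w
                    tag.remove(z)
                    break
        length += 1
    return SelectionResult(tuple(selected), conset, tuple(audit))


def select_candidates(
    data: pd.DataFrame,
    x: str,
    y: str,
    candidates,
    alpha: float = 0.01,
    *,
    method: str = "gamma",
    n_perm: int = 500,
    max_points: int = 2000,
    seed=0,
    relevance_check: bool = True,
    max_cond_size: int | None = None,
) -> SelectionResult:
    """Select candidate instruments for the effect x -> y from a sample.

    ``candidates`` is the pool O of observed variables to screen (excluding
    x and y).  Each (z, W) attempt first requires z to be dependent on x
    given W (Fisher-z partial correlation at the same alpha, skippable with
    ``relevance_check=False``), then runs the IV-GIN test.
    """
    pool = sorted(set(candidates))
    if not pool:
        return SelectionResult((), {}, ())
    if {x, y} & set(pool):
        raise ValueError("candidate pool must exclude treatment and outcome")
    missing = [c for c in [x, y, *pool] if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    if len(data) < _MIN_ROWS:
        raise ValueError(
            f"refusing to run on n={len(data)} rows: the kernel independence"
            f" test is unreliable below {_MIN_ROWS} observations"
        )
    rng = np.random.default_rng(seed)

    def gin_holds(z: str, w: tuple[str, ...]):
        res = iv_gin_test(
            data,
            z,
            w,
            x,
            y,
            alpha,
            method=method,
            n_perm=n_perm,
            max_points=max_points,
            seed=int(rng.integers(2**31 - 1)),
        )
        return res.holds, res.pvalue

    def relevant(z: str, w: tuple[str, ...]) -> bool:
        if not relevance_check:
            return True
        return partial_correlation_pvalue(data, z, x, w) < alpha

    return _run_selection(pool, gin_holds, relevant, max_cond_size)


def select_candidates_oracle(
    sem: LinearSEM,
    x: str,
    y: str,
    candidates,
    *,
    relevance_check: bool = True,
    max_cond_size: int | None = None,
) -> SelectionResult:
    """Population-oracle mode: identical control flow, exact answers.

    The IV-GIN test is replaced by the Darmois-Skitovitch population oracle
    and the relevance pre-check by graphical d-connection of z and x given
    w in the generating graph.
    """
    pool = sorted(set(candidates))
    if {x, y} & set(pool):
        raise ValueError("candidate pool must exclude treatment and outcome")

    def gin_holds(z: str, w: tuple[str, ...]):
        return population_iv_gin_oracle(sem, z, w, x, y), None

    def relevant(z: str, w: tuple[str, ...]) -> bool:
        if not relevance_check:
            return True
        return not d_separated(sem.graph, {z}, {x}, set(w))

    return _run_selection(pool, gin_holds, relevant, max_cond_size)


# ---------------------------------------------------------------------------
# Ratio estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IVEstimate:
    """The partial-covariance ratio estimate of the treatment effect."""

    b_yx: float
    numerator: float  # sigma_ZY.W
    denominator: float  # sigma_ZX.W


def _partial_cov(cov: pd.DataFrame, a: str, b: str, w: list[str]) -> float:
    if not w:
        return float(cov.loc[a, b])
    s_ab = float(cov.loc[a, b])
    s_aw = cov.loc[[a], w].to_numpy()
    s_wb = cov.loc[w, [b]].to_numpy()
    s_ww = cov.loc[w, w].to_numpy()
    return float(s_ab - (s_aw @ np.linalg.solve(s_ww, s_wb)).item())


def estimate_effect_from_cov(
    cov: pd.DataFrame, z: str, w, x: str, y: str
) -> IVEstimate:
    """Ratio estimator from a covariance matrix (population or empirical):
    b_YX = sigma_ZY.W / sigma_ZX.W."""
    w = sorted({w} if isinstance(w, str) else set(w))
    num = _partial_cov(cov, z, y, w)
    den = _partial_cov(cov, z, x, w)
    scale = np.sqrt(
        abs(_partial_cov(cov, z, z, w)) * abs(_partial_cov(cov, x, x, w))
    )
    if abs(den) <= 1e-10 * max(scale, 1e-30):
        raise WeakInstrumentError(
            f"partial covariance of {z!r} and treatment {x!r} given {w} is"
            f" numerically zero: weak or irrelevant instrument"
        )
    return IVEstimate(num / den, num, den)


def estimate_effect(data: pd.DataFrame, z: str, w, x: str, y: str) -> IVEstimate:
    """Finite-sample ratio estimator from the empirical covariance."""
    w = sorted({w} if isinstance(w, str) else set(w))
    cols = [z, x, y, *w]
    if len(data) <= len(w) + 3:
        raise ValueError("need n > |w| + 3 observations")
    cov = pd.DataFrame(
        np.cov(data[cols].to_numpy(dtype=float), rowvar=False),
        index=cols,
        columns=cols,
    )
    return estimate_effect_from_cov(cov, z, w, x, y)


# ---------------------------------------------------------------------------
# Completeness check (oracle mode)
# ---------------------------------------------------------------------------

def completeness_check(sem: LinearSEM, candidates, x: str, y: str) -> bool:
    """True iff every graphically valid instrument (for some conditioning
    set drawn from the pool) appears in the oracle-mode selection output."""
    pool = sorted(set(candidates))
    result = select_candidates_oracle(sem, x, y, pool)
    g = sem.graph
    for z in pool:
        others = [o for o in pool if o != z]
        for size in range(len(others) + 1):
            for w in itertools.combinations(others, size):
                if instrument_criteria_holds(g, z, set(w), x, y):
                    if z not in result.candidates:
                        return False
    return True
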