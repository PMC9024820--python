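"""Model/Results interface over the instrument-selection machinery.

:class:`IVGIN` is constructed from a sample table plus a designation of
treatment, outcome and candidate pool; ``fit()`` runs the sequential
IV-GIN scan and returns an :class:`IVGINResults` carrying the admitted
candidates, their minimal conditioning sets, per-test p-values, the ratio
effect estimate through each admitted instrument with a bootstrap standard
error, and a ``summary()`` table.

    >>> model = IVGIN.from_dataframe(df, treatment="X", outcome="Y")
    >>> results = model.fit(seed=0)
    >>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .select import (
    IVEstimate,
    SelectionResult,
    WeakInstrumentError,
    estimate_effect,
    select_candidates,
)

__all__ = ["IVGIN", "IVGINResults"]


class IVGIN:
    """Instrument-candidate selection model for one treatment-outcome pair.

    Parameters
    ----------
    data : sample table (rows = observations, columns = named variables)
    treatment, outcome : column names of X and Y
    candidates : columns to screen as instruments; defaults to every other
        column of ``data``
    alpha : significance level shared by the GIN test and the relevance
        pre-check (default 0.01)
    """

    def __init__(
        self,
        data: pd.DataFrame,
        treatment: str,
        outcome: str,
        candidates=None,
        alpha: float = 0.01,
    ) -> None:
        self.data = data
        self.treatment = treatment
        self.outcome = outcome
        if candidates is None:
            candidates = [
                c for c in data.columns if c not in (treatment, outcome)
            ]
        self.candidates = tuple(sorted(candidates))
        self.alpha = float(alpha)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, treatment: str, outcome: str, candidates=None,
        alpha: float = 0.01,
    ) -> "IVGIN":
        return cls(data, treatment, outcome, candidates, alpha)

    @classmethod
    def from_csv(
        cls, path, treatment: str, outcome: str, candidates=None,
        alpha: float = 0.01, *, sep: str = ",",
    ) -> "IVGIN":
        return cls(pd.read_csv(path, sep=sep), treatment, outcome, candidates, alpha)

    def fit(
        self,
        *,
        method: str = "gamma",
        n_perm: int = 500,
        max_points: int = 2000,
        seed=0,
        relevance_check: bool = True,
        max_cond_size: int | None = None,
        estimate: bool = True,
        n_boot: int = 200,
    ) -> "IVGINResults":
        """Run the sequential scan; optionally estimate the effect through
        each admitted instrument (with ``n_boot`` bootstrap replicates for
        the standard error)."""
        selection = select_candidates(
            self.data,
            self.treatment,
            self.outcome,
            self.candidates,
            self.alpha,
            method=method,
            n_perm=n_perm,
            max_points=max_points,
            seed=seed,
            relevance_check=relevance_check,
            max_cond_size=max_cond_size,
        )
        estimates: dict[str, IVEstimate] = {}
        stderr: dict[str, float] = {}
        if estimate:
            rng = np.random.default_rng(seed)
            for z in selection.candidates:
                w = selection.conset[z]
                try:
                    estimates[z] = estimate_effect(
                        self.data, z, w, self.treatment, self.outcome
                    )
                except WeakInstrumentError:
                    continue
                if n_boot > 0:
                    stderr[z] = self._bootstrap_se(z, w, n_boot, rng)
        return IVGINResults(self, selection, estimates, stderr)

    def _bootstrap_se(
        self, z: str, w, n_boot: int, rng: np.random.Generator
    ) -> float:
        n = len(self.data)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot = self.data.iloc[idx]
            try:
                draws.append(
                    estimate_effect(boot, z, w, self.treatment, self.outcome).b_yx
                )
            except WeakInstrumentError:
                continue
        if len(draws) < 2:
            return float("nan")
        return float(np.std(draws, ddof=1))


@dataclass
class IVGINResults:
    """Fitted results: admitted candidates, conditioning sets, effect
    estimates and their bootstrap uncertainties."""

    model: IVGIN
    selection: SelectionResult
    estimates: dict[str, IVEstimate]
    stderr: dict[str, float]

    @property
    def candidates(self) -> tuple[str, ...]:
        return self.selection.candidates

    @property
    def conditioning_sets(self) -> dict[str, tuple[str, ...]]:
        return dict(self.selection.conset)

    @property
    def effects(self) -> dict[str, float]:
        return {z: est.b_yx for z, est in self.estimates.items()}

    def summary(self) -> str:
        m = self.model
        lines = [
            "IV-GIN instrument candidate selection",
            "=" * 61,
            f"treatment: {m.treatment:<12s} outcome: {m.outcome:<12s} "
            f"n = {len(m.data)}",
            f"candidate pool: {', '.join(m.candidates)}",
            f"alpha = {m.alpha:g}   GIN tests run: {self.selection.n_gin_tests}",
            "-" * 61,
            f"{'candidate':<12s}{'cond. set':<16s}{'p-value':>9s}"
            f"{'effect':>12s}{'boot se':>10s}",
            "-" * 61,
        ]
        pvals = {
            (r.candidate, r.conditioning): r.pvalue
            for r in self.selection.audit
            if r.holds
        }
        if not self.candidates:
            lines.append("  (no candidate passed the IV-GIN screen)")
        for z in self.candidates:
            w = self.selection.conset[z]
            wtxt = "{" + ", ".join(w) + "}" if w else "{}"
            p = pvals.get((z, w))
            ptxt = f"{p:9.3g}" if p is not None else f"{'--':>9s}"
            if z in self.estimates:
                btxt = f"{self.estimates[z].b_yx:12.4f}"
                setxt = (
                    f"{self.stderr[z]:10.4f}" if z in self.stderr else f"{'--':>10s}"
                )
            else:
                btxt, setxt = f"{'--':>12s}", f"{'--':>10s}"
            lines.append(f"{z:<12s}{wtxt:<16s}{ptxt}{btxt}{setxt}")
        lines.append("-" * 61)
        lines.append(
            "Membership is necessary-condition screening only: a listed"
        )
        lines.append(
            "candidate is not certified valid (directed Z->Y effects can"
        )
        lines.append("evade any observational test).")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<IVGINResults: {len(self.candidates)} candidate(s) "
            f"{list(self.candidates)}>"
        )
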