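"""Clinicopathological association tests for amplification status.

Cross-tabulates per-sample amplification flags against clinical factors
(histological grade, ER, PR, HER2, treatment subtype) and tests the
association with Fisher's exact test (2x2) or the Pearson chi-square test
(r x c, no continuity correction).

The two-sided Fisher P-value follows the minimum-likelihood convention:
the sum of hypergeometric point probabilities not exceeding that of the
observed table (with a 1 + 1e-7 relative tolerance on the comparison).
This is the convention that reproduces published two-sided values from
breast-cancer amplification tables; the doubling convention does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, inf, lgamma

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "crosstab",
    "collapse_levels",
    "fisher_exact_2x2",
    "chi_square",
]


@dataclass
class AssociationResult:
    test: str  # "fisher-exact" | "chi-square"
    p: float
    statistic: float | None = None  # chi-square only
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError("P outside [0, 1]")
        self.p = min(self.p, 1.0)


@dataclass
class ContingencyTable:
    """Integer cross-tabulation: factor levels x (amplified, not amplified)."""

    rows: list[str]
    cols: list[str]
    counts: np.ndarray
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 2-D integer array")
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("labels do not match counts shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.rows, columns=self.cols)


def crosstab(
    annotations: pd.DataFrame,
    amplified: pd.Series,
    factor: str,
    level_order: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate a clinical factor against amplification status.

    ``amplified`` is a boolean Series indexed by sample id.  Samples with a
    missing factor value are excluded and counted in ``n_missing``.
    """
    if len(annotations) == 0:
        raise ValueError("empty cohort")
    fac = annotations[factor].reindex(amplified.index)
    ok = fac.notna()
    n_missing = int((~ok).sum())
    fac = fac[ok]
    amp = amplified[ok].astype(bool)
    levels = level_order if level_order is not None else sorted(fac.unique())
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    for i, lev in enumerate(levels):
        sel = fac == lev
        counts[i, 0] = int((amp & sel).sum())
        counts[i, 1] = int((~amp & sel).sum())
    return ContingencyTable(
        rows=[str(l) for l in levels], cols=["amplified", "not_amplified"],
        counts=counts, n_missing=n_missing,
    )


def collapse_levels(table: ContingencyTable, keep: list[str], label_rest: str = "rest") -> ContingencyTable:
    """Collapse to ``keep`` levels vs the pooled remainder (e.g. ER-/HER2- vs rest)."""
    keep_idx = [table.rows.index(k) for k in keep]
    rest_idx = [i for i in range(len(table.rows)) if i not in keep_idx]
    if not rest_idx:
        raise ValueError("nothing to collapse")
    top = table.counts[keep_idx].sum(axis=0)
    bottom = table.counts[rest_idx].sum(axis=0)
    return ContingencyTable(
        rows=["+".join(keep), label_rest], cols=table.cols,
        counts=np.vstack([top, bottom]), n_missing=table.n_missing,
    )


def _log_hypergeom(a: int, r1: int, r2: int, c1: int, n: int) -> float:
    """log P of a 2x2 table with top-left cell ``a`` and fixed margins."""
    return (
        lgamma(r1 + 1) + lgamma(r2 + 1) + lgamma(c1 + 1) + lgamma(n - c1 + 1)
        - lgamma(n + 1)
        - lgamma(a + 1) - lgamma(r1 - a + 1) - lgamma(c1 - a + 1) - lgamma(r2 - c1 + a + 1)
    )


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> AssociationResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability is at most that of the observed
    table, comparing in log space with a 1 + 1e-7 relative tolerance.
    A zero margin makes every table the observed one: P = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("fisher_exact_2x2 requires a non-negative 2x2 table")
    a, b = int(counts[0, 0]), int(counts[0, 1])
    c, d = int(counts[1, 0]), int(counts[1, 1])
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return AssociationResult(test="fisher-exact", p=1.0)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_hypergeom(a, r1, r2, c1, n)
    cutoff = log_obs + np.log1p(1e-7)  # relative tolerance on the probability scale
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom(k, r1, r2, c1, n)
        if lp <= cutoff:
            p += exp(lp)
    return AssociationResult(test="fisher-exact", p=min(p, 1.0))


def chi_square(table: ContingencyTable | np.ndarray) -> AssociationResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("chi_square requires a non-negative 2-D table")
    expected = stats.contingency.expected_freq(counts)
    zero = np.argwhere(expected == 0)
    if zero.size:
        i, j = zero[0]
        raise ValueError(f"zero expected count in cell ({i}, {j})")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return AssociationResult(test="chi-square", p=float(p), statistic=float(stat), df=int(df))
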