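"""Shared statistical primitives.

Thin, contract-checked wrappers around the standard scipy/statsmodels
routines, plus small summaries the pipeline stages share.  Conventions
fixed here (two-sided Fisher as the sum of tables no more probable than
the observed one; pooled-variance Student's t; Benjamini-Hochberg
step-up with monotonicity) are relied on by every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PValueSet",
    "ContingencyTable2x2",
    "geometric_mean",
    "one_tailed_t_test",
    "fisher_exact_2x2",
    "bh_adjust",
    "mann_whitney_u",
    "proportion_summary",
]


@dataclass(frozen=True)
class PValueSet:
    """Raw and multiplicity-adjusted p-values, order preserved."""

    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    method: str = "benjamini-hochberg"

    def __post_init__(self) -> None:
        if len(self.raw_p) != len(self.adjusted_p):
            raise ValueError("raw_p and adjusted_p must have equal length")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 table of nonnegative integer counts.

    Cell layout::

        [[a, b],
         [c, d]]
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def geometric_mean(values: Sequence[float]) -> float:
    """Geometric mean exp(mean(log(values))) of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean requires at least one value")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("geometric_mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def one_tailed_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """One-sided pooled-variance two-sample t-test of mean(a) > mean(b).

    Classic Student's form (equal variances pooled), not Welch.  When the
    pooled variance is zero and the means are equal the statistic is 0/0;
    by convention p = 0.5 (no evidence either way).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.allclose(a.var(ddof=1), 0.0) and np.allclose(b.var(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.5
        return 0.0 if a.mean() > b.mean() else 1.0
    res = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided convention: the sum of hypergeometric probabilities of all
    tables with the same margins whose point probability does not exceed
    the observed table's (the common definition; some software doubles
    the one-sided p instead).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(raw_p: Sequence[float]) -> PValueSet:
    """Benjamini-Hochberg step-up adjustment with monotonicity, order kept."""
    arr = np.asarray(raw_p, dtype=float)
    if arr.size == 0:
        raise ValueError("bh_adjust requires at least one p-value")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return PValueSet(raw_p=tuple(arr.tolist()), adjusted_p=tuple(adj.tolist()))


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U statistic (for sample_a) and two-sided p.

    Exact enumeration when the combined sample size is at most 20 and no
    ties are present; otherwise the normal approximation with midranks
    and the tie-corrected variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class ProportionSummary:
    mean_fraction: float
    sem: float
    n_replicates: int
    single_replicate: bool = field(default=False)


def proportion_summary(
    counts: Sequence[tuple[int, int]],
) -> ProportionSummary:
    """Mean and s.e.m. of per-replicate fractions (successes / totals).

    With a single replicate the s.e.m. is undefined; it is reported as 0
    with the ``single_replicate`` flag set.
    """
    if len(counts) == 0:
        raise ValueError("at least one replicate required")
    fracs = []
    for successes, total in counts:
        if total <= 0:
            raise ValueError("replicate totals must be positive")
        fracs.append(successes / total)
    arr = np.asarray(fracs, dtype=float)
    n = arr.size
    if n == 1:
        return ProportionSummary(float(arr[0]), 0.0, 1, single_replicate=True)
    sem = float(arr.std(ddof=1) / np.sqrt(n))
    return ProportionSummary(float(arr.mean()), sem, n)
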