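"""Descriptive statistics: contingency tests, prevalence, sample size.

Implements the screening-table toolkit: Pearson chi-square without
continuity correction, an exact conditional (Fisher) test for small
tables, the "Fisher wherever any expected count < 5" selection rule,
Clopper-Pearson exact binomial prevalence intervals, numeric summaries,
and the Fleiss two-proportion sample-size formula with continuity
correction and unequal allocation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "PrevalenceEstimate",
    "pearson_chi_square",
    "fisher_exact",
    "choose_test",
    "crude_association",
    "prevalence",
    "summarize_numeric",
    "sample_size_two_proportions",
    "inflate_for_attrition",
]

#: Probability-tie tolerance for the two-sided Fisher rule.
_FISHER_TIE_TOL = 1e-12
#: Guard on the exact-test enumeration size.
_FISHER_MAX_TABLES = 5_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need an r x c table with r, c >= 2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("empty table")
        object.__setattr__(self, "counts", counts)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        """Expected counts under independence, given the margins."""
        return np.outer(self.row_margins, self.col_margins) / self.total


@dataclass(frozen=True)
class TestResult:
    method: Literal["pearson_chi2", "fisher_exact"]
    p_value: float
    statistic: float | None = None
    df: int | None = None


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float
    method: str = "clopper_pearson"

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """(proportion, low, high) in percent, rounded for reporting."""
        return tuple(
            round(100 * v, decimals)
            for v in (self.proportion, self.ci_low, self.ci_high)
        )


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    expected = table.expected()
    stat = float(((table.counts - expected) ** 2 / expected).sum())
    r, c = table.counts.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(stat, df))
    return TestResult("pearson_chi2", p, statistic=stat, df=df)


def _log_table_prob(counts: np.ndarray, log_denominator: float) -> np.ndarray:
    """Log multivariate hypergeometric probability for stacked tables."""
    return -gammaln(counts + 1).sum(axis=(-2, -1)) - log_denominator


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Exact conditional test with fixed margins (two-sided).

    The two-sided p-value is the total null probability of all tables, with
    the observed margins, whose probability does not exceed the observed
    table's (within a small tie tolerance).  Enumeration currently covers
    2 x c tables; larger tables signal fallback to the Pearson test via
    ``ValueError``.
    """
    counts = table.counts
    if counts.shape[0] != 2:
        if counts.shape[1] == 2:
            counts = counts.T
        else:
            raise ValueError("exact enumeration implemented for 2 x c tables only")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if row.min() == 0 or col.min() == 0:
        return TestResult("fisher_exact", 1.0)  # only one table possible
    n = counts.sum()
    # number of candidate first rows (upper bound) for the guard
    bound = np.prod(np.minimum(row[0], col) + 1.0)
    if bound > _FISHER_MAX_TABLES:
        raise ValueError("table too large to enumerate; fall back to Pearson")

    c = counts.shape[1]
    # log of the constant denominator: n! / (prod row_i! prod col_j!)
    log_den = gammaln(n + 1) - gammaln(row + 1).sum() - gammaln(col + 1).sum()

    ranges = [range(int(min(row[0], col[j])) + 1) for j in range(c - 1)]
    first_rows = []
    for cells in itertools.product(*ranges):
        last = row[0] - sum(cells)
        if 0 <= last <= col[c - 1]:
            first_rows.append(cells + (int(last),))
    top = np.array(first_rows, dtype=np.int64)
    bottom = col[None, :] - top
    tables = np.stack([top, bottom], axis=1)
    probs = np.exp(_log_table_prob(tables, log_den))
    obs_prob = math.exp(float(_log_table_prob(counts[None, ...], log_den)[0]))
    p = float(probs[probs <= obs_prob * (1 + _FISHER_TIE_TOL)].sum())
    return TestResult("fisher_exact", min(p, 1.0))


def choose_test(table: ContingencyTable) -> str:
    """Return "fisher_exact" iff any expected cell count is below 5."""
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError("degenerate table: zero margin")
    return "fisher_exact" if (table.expected() < 5).any() else "pearson_chi2"


def crude_association(table: ContingencyTable) -> TestResult:
    """Apply the screening-table rule: Fisher when any expected count < 5."""
    if choose_test(table) == "fisher_exact":
        try:
            return fisher_exact(table)
        except ValueError:
            pass
    return pearson_chi_square(table)


def prevalence(numerator: int, denominator: int, level: float = 0.95) -> PrevalenceEstimate:
    """Binomial prevalence with a Clopper-Pearson exact interval.

    The interval inverts equal-tailed exact binomial tests via beta
    quantiles: ``low = B(a/2; k, n-k+1)``, ``high = B(1-a/2; k+1, n-k)``,
    with the conventional boundary values at k = 0 and k = n.
    """
    if not (0 <= numerator <= denominator) or denominator < 1:
        raise ValueError("need 0 <= numerator <= denominator, denominator >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    k, n = numerator, denominator
    a = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return PrevalenceEstimate(k, n, k / n, low, high, level)


def summarize_numeric(values: Sequence[float]) -> dict[str, float]:
    """Mean, sample (n-1) SD, median and quartiles of a numeric vector."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def sample_size_two_proportions(
    alpha: float,
    power: float,
    ratio_unexposed_to_exposed: float,
    p_unexposed: float,
    effect: float,
    effect_type: Literal["risk_ratio", "absolute_difference"] = "risk_ratio",
    continuity_correction: bool = True,
) -> dict[str, float]:
    """Fleiss two-proportion sample size with unequal allocation.

    ``effect`` is interpreted per ``effect_type``: the exposed-group
    proportion is ``p_unexposed * effect`` (risk ratio, the default) or
    ``p_unexposed + effect``.  Group sizes are rounded up separately; the
    continuity-corrected exposed-group size follows Fleiss:
    ``n' = n/4 * (1 + sqrt(1 + 2(r+1) / (n r |p1-p2|)))**2``.
    """
    if not (0 < alpha < 1 and 0 < power < 1 and 0 < p_unexposed < 1):
        raise ValueError("alpha, power in (0,1); p_unexposed in (0,1)")
    r = float(ratio_unexposed_to_exposed)
    if r <= 0:
        raise ValueError("allocation ratio must be positive")
    p1 = p_unexposed * effect if effect_type == "risk_ratio" else p_unexposed + effect
    if not 0 < p1 < 1:
        raise ValueError("implied exposed proportion outside (0, 1)")
    p2 = p_unexposed
    delta = abs(p1 - p2)
    if delta == 0:
        raise ValueError("no detectable difference: p_exposed equals p_unexposed")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    p_bar = (p1 + r * p2) / (r + 1)
    q_bar = 1 - p_bar
    n_exp = (
        z_a * math.sqrt((r + 1) / r * p_bar * q_bar)
        + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2) / r)
    ) ** 2 / delta**2
    if continuity_correction:
        n_exp = n_exp / 4 * (1 + math.sqrt(1 + 2 * (r + 1) / (n_exp * r * delta))) ** 2
    n_exposed = math.ceil(n_exp)
    n_unexposed = math.ceil(n_exp * r)
    return {
        "n_exposed": n_exposed,
        "n_unexposed": n_unexposed,
        "n_total": n_exposed + n_unexposed,
        "p_exposed": p1,
        "p_unexposed": p2,
    }


def inflate_for_attrition(n: int, rate: float = 0.20) -> int:
    """Inflate a sample size for expected loss to follow-up (default 20%)."""
    if not 0 <= rate < 1:
        raise ValueError("attrition rate must be in [0, 1)")
    return math.ceil(n * (1 + rate))
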