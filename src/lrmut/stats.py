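"""Exact and rank-based statistical tests, and the summary report.

All tests return a :class:`TestResult`.  One-sided directions are always
passed explicitly by the caller; nothing here guesses a direction from the
data.  Percentages in the report are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FractionEntry",
    "SummaryReport",
    "fisher_exact_2x2",
    "binomial_one_sided",
    "wilcoxon_one_sided",
    "chi_square_2xk",
    "percent",
    "summary_report",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    method: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], sidedness: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    ``sidedness`` is ``"greater"`` (odds ratio of the [0, 0] cell larger
    than expected), ``"less"``, or ``"two-sided"``.  An empty margin makes
    every table with the same margins equally likely, so p = 1 (flagged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(np.nan, 1.0, sidedness, "fisher_exact", ("empty_margin",))
    odds, p = sps.fisher_exact(t, alternative=sidedness)
    return TestResult(float(odds), float(min(p, 1.0)), sidedness, "fisher_exact")


def binomial_one_sided(k: int, n: int, p0: float, tail: str = "lower") -> TestResult:
    """Exact one-sided binomial test of ``k`` successes in ``n`` trials.

    ``tail="lower"`` sums P(X <= k); ``tail="upper"`` sums P(X >= k).
    ``p0 = 1`` is a documented degenerate limit: the lower tail is 0
    whenever k < n and 1 when k = n.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n and n > 0")
    if not (0.0 < p0 <= 1.0):
        raise ValueError("require 0 < p0 <= 1")
    alternative = "less" if tail == "lower" else "greater"
    flags: tuple[str, ...] = ()
    if p0 == 1.0:
        p = 1.0 if (tail == "upper" or k == n) else 0.0
        flags = ("degenerate_p0",)
        # TestResult requires p in [0, 1]; the 0 limit is kept but flagged.
        p = max(p, 0.0)
        return TestResult(float(k), p if p > 0 else np.nextafter(0, 1), alternative,
                          "binomial", flags)
    res = sps.binomtest(k, n, p0, alternative=alternative)
    return TestResult(float(k), float(res.pvalue), alternative, "binomial")


def wilcoxon_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> TestResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is <= 20 and
    there are no ties; otherwise the normal approximation with midranks
    and tie correction.  ``alternative="greater"`` tests whether values
    in ``x`` tend to exceed those in ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(np.nan, 1.0, alternative, "wilcoxon_rank_sum",
                          ("degenerate_constant",))
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size) <= 20 and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      f"wilcoxon_rank_sum[{method}]")


def chi_square_2xk(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test on a 2xk table with k-1 degrees of freedom."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2 or (t < 0).any():
        raise ValueError("table must be 2xk (k >= 2) with non-negative counts")
    expected = sps.contingency.expected_freq(t)
    if (expected == 0).any():
        raise ValueError("zero expected cell count; chi-square test refused")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(max(p, np.nextafter(0, 1))), "two-sided",
                      f"chi_square[df={dof}]")


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (printed-report parity)."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FractionEntry:
    name: str
    numerator: int
    denominator: int
    percent: Optional[float]
    flags: tuple[str, ...] = ()


@dataclass
class SummaryReport:
    fractions: list[FractionEntry] = field(default_factory=list)
    tables: dict = field(default_factory=dict)

    def get(self, name: str) -> FractionEntry:
        for f in self.fractions:
            if f.name == name:
                return f
        raise KeyError(name)


def _entry(name: str, num: int, den: int) -> FractionEntry:
    if den == 0:
        return FractionEntry(name, num, den, None, ("zero_denominator",))
    return FractionEntry(name, num, den, percent(num, den))


def summary_report(
    *,
    n_conversion_csnps: Optional[int] = None,
    n_te_snps: Optional[int] = None,
    n_csnps: Optional[int] = None,
    n_snps: Optional[int] = None,
    n_shared_svs: Optional[int] = None,
    n_svs: Optional[int] = None,
    n_shared_snps: Optional[int] = None,
    conversion_class_counts: Optional[dict] = None,
) -> SummaryReport:
    """Assemble the headline counts and fractions of the analysis.

    Every fraction is emitted with its numerator and denominator so that a
    reader can recompute it.  ``conversion_class_counts`` maps
    ``(multiplicity, distance_class)`` -> count, with multiplicity in
    {"unique", "multiple"} and class in {"proximal", "distal", "interarm"};
    from it the per-multiplicity proximal and remote (distal + interarm)
    fractions are derived.
    """
    rep = SummaryReport()
    add = rep.fractions.append
    if n_conversion_csnps is not None and n_te_snps is not None:
        add(_entry("conversion_fraction_of_te_snps", n_conversion_csnps, n_te_snps))
    if n_conversion_csnps is not None and n_csnps is not None:
        add(_entry("conversion_fraction_of_csnps", n_conversion_csnps, n_csnps))
    if n_conversion_csnps is not None and n_snps is not None:
        add(_entry("conversion_fraction_of_snps", n_conversion_csnps, n_snps))
    if n_shared_svs is not None and n_svs is not None:
        add(_entry("shared_sv_fraction", n_shared_svs, n_svs))
    if n_shared_snps is not None and n_snps is not None:
        add(_entry("shared_snp_fraction", n_shared_snps, n_snps))
    if conversion_class_counts:
        cc = conversion_class_counts
        rep.tables["conversion_classes"] = dict(cc)
        for mult in ("unique", "multiple"):
            total = sum(v for (m, _), v in cc.items() if m == mult)
            prox = cc.get((mult, "proximal"), 0)
            remote = sum(
                v for (m, c), v in cc.items() if m == mult and c in ("distal", "interarm")
            )
            add(_entry(f"proximal_fraction_{mult}_donor", prox, total))
            add(_entry(f"remote_fraction_{mult}_donor", remote, total))
    return rep
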