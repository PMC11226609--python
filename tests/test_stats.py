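"""Exact tests against enumeration oracles, and report arithmetic."""

import itertools
import math

import numpy as np
import pytest

from lrmut.stats import (
    binomial_one_sided,
    chi_square_2xk,
    fisher_exact_2x2,
    percent,
    summary_report,
    wilcoxon_one_sided,
)

# --- independent oracles -------------------------------------------------


def hypergeom_fisher_oracle(table, sidedness):
    """Exhaustive hypergeometric sum over all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = prob(a)
    if sidedness == "greater":
        return sum(prob(k) for k in support if k >= a)
    if sidedness == "less":
        return sum(prob(k) for k in support if k <= a)
    return sum(prob(k) for k in support if prob(k) <= p_obs * (1 + 1e-12))


def rank_sum_oracle(x, y, alternative):
    """Exhaustive permutation distribution of the rank-sum with midranks."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    obs = sum(ranks[: len(x)])
    stats = [sum(combo) for combo in itertools.combinations(ranks, len(x))]
    if alternative == "greater":
        hits = sum(1 for s in stats if s >= obs - 1e-9)
    else:
        hits = sum(1 for s in stats if s <= obs + 1e-9)
    return hits / len(stats)


# --- Fisher --------------------------------------------------------------


def test_fisher_one_sided_conversion_table():
    """The proximal-vs-remote donor-multiplicity table: one-sided p ~ 0.0263
    by exhaustive hypergeometric enumeration."""
    table = [[15, 19], [4, 20]]
    res = fisher_exact_2x2(table, "greater")
    assert res.p_value == pytest.approx(hypergeom_fisher_oracle(table, "greater"),
                                        rel=1e-9)
    assert res.p_value == pytest.approx(0.0263, abs=5e-4)


def test_fisher_single_term_tail():
    res = fisher_exact_2x2([[5, 0], [0, 5]], "greater")
    assert res.p_value == pytest.approx(1 / math.comb(10, 5), rel=1e-9)


def test_fisher_symmetric_table_p_one():
    assert fisher_exact_2x2([[1, 1], [1, 1]], "two-sided").p_value == 1.0


def test_fisher_empty_margin_flagged():
    res = fisher_exact_2x2([[0, 0], [3, 5]], "greater")
    assert res.p_value == 1.0 and "empty_margin" in res.flags


@pytest.mark.parametrize("sidedness", ["greater", "less", "two-sided"])
def test_fisher_matches_enumeration_on_random_tables(sidedness):
    rng = np.random.default_rng(5)
    for _ in range(20):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        res = fisher_exact_2x2(t.tolist(), sidedness)
        assert res.p_value == pytest.approx(
            hypergeom_fisher_oracle(t.tolist(), sidedness), rel=1e-6)


# --- binomial ------------------------------------------------------------


def test_binomial_closed_forms():
    assert binomial_one_sided(0, 10, 0.5, "lower").p_value == pytest.approx(2**-10)
    assert binomial_one_sided(7, 7, 0.3, "upper").p_value == pytest.approx(0.3**7)


def test_binomial_mode_inclusion():
    assert binomial_one_sided(10, 20, 0.5, "lower").p_value >= 0.5


def test_binomial_degenerate_p0_one():
    res = binomial_one_sided(5, 10, 1.0, "lower")
    assert "degenerate_p0" in res.flags
    assert res.p_value < 1e-300
    assert binomial_one_sided(10, 10, 1.0, "lower").p_value == 1.0


# --- Wilcoxon ------------------------------------------------------------


def test_wilcoxon_extreme_separation_exact():
    res = wilcoxon_one_sided([10, 11, 12], [1, 2, 3], alternative="greater")
    assert res.p_value == pytest.approx(1 / math.comb(6, 3), rel=1e-9)


def test_wilcoxon_identical_multisets():
    assert wilcoxon_one_sided([1, 2, 3], [1, 2, 3]).p_value >= 0.5


def test_wilcoxon_degenerate_constant():
    res = wilcoxon_one_sided([2, 2], [2, 2])
    assert res.p_value == 1.0 and "degenerate_constant" in res.flags


def test_wilcoxon_matches_permutation_oracle():
    """Untied small samples take the exact path and must reproduce the
    exhaustive permutation distribution."""
    rng = np.random.default_rng(9)
    tested = 0
    while tested < 10:
        x = rng.permutation(100)[:5].astype(float).tolist()
        y = rng.permutation(100)[:6].astype(float).tolist()
        if set(x) & set(y):
            continue
        res = wilcoxon_one_sided(x, y, "greater")
        assert "exact" in res.method
        assert res.p_value == pytest.approx(rank_sum_oracle(x, y, "greater"),
                                            rel=1e-9)
        tested += 1


def test_wilcoxon_normal_approximation_near_exact_at_n18():
    """At combined n = 18 the tie-corrected normal approximation agrees
    with the exact null distribution to within 0.005."""
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(3)
    x = rng.normal(0.5, 1, 9).tolist()
    y = rng.normal(0.0, 1, 9).tolist()
    exact = wilcoxon_one_sided(x, y, "greater")
    assert "exact" in exact.method
    approx = mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    assert exact.p_value == pytest.approx(float(approx.pvalue), abs=0.005)


# --- chi-square ----------------------------------------------------------


def test_chi_square_identical_rows():
    res = chi_square_2xk([[5, 5, 5], [5, 5, 5]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_diagonal():
    res = chi_square_2xk([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert res.p_value < 0.001


def test_chi_square_textbook_formula_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(10):
        t = rng.integers(1, 30, size=(2, 4)).astype(float)
        res = chi_square_2xk(t)
        row, col, tot = t.sum(axis=1), t.sum(axis=0), t.sum()
        exp = np.outer(row, col) / tot
        stat = (((t - exp) ** 2) / exp).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-9)


def test_chi_square_refuses_zero_expected():
    with pytest.raises(ValueError):
        chi_square_2xk([[0, 5], [0, 7]])


# --- report --------------------------------------------------------------


def test_percent_rounds_half_up():
    assert percent(1, 800) == 0.1  # 0.125 -> 0.1
    assert percent(15, 34) == 44.1
    assert percent(318, 337) == 94.4


def test_summary_report_fraction_arithmetic():
    rep = summary_report(
        n_conversion_csnps=217, n_te_snps=668, n_csnps=964, n_snps=1756,
        n_shared_svs=318, n_svs=337, n_shared_snps=1682,
        conversion_class_counts={("unique", "proximal"): 15,
                                 ("unique", "distal"): 12,
                                 ("unique", "interarm"): 7,
                                 ("multiple", "proximal"): 4,
                                 ("multiple", "distal"): 11,
                                 ("multiple", "interarm"): 9},
    )
    assert rep.get("conversion_fraction_of_te_snps").percent == 32.5
    assert rep.get("conversion_fraction_of_csnps").percent == 22.5
    assert rep.get("conversion_fraction_of_snps").percent == 12.4
    assert rep.get("shared_sv_fraction").percent == 94.4
    assert rep.get("shared_snp_fraction").percent == 95.8
    assert rep.get("proximal_fraction_unique_donor").percent == 44.1
    assert rep.get("remote_fraction_multiple_donor").percent == 83.3


def test_summary_report_zero_denominator_flagged():
    rep = summary_report(n_conversion_csnps=0, n_te_snps=0)
    entry = rep.get("conversion_fraction_of_te_snps")
    assert entry.percent is None and "zero_denominator" in entry.flags
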