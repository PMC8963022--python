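"""Statistical comparison of sampling methods across classifiers.

Decision tree: an Anderson–Darling normality test on the flattened
classifier × method score cells routes the comparison either to a one-way
ANOVA over methods (scores plausibly normal, p > 0.05) or to a Friedman test
with per-classifier rank tables (non-normal, p ≤ 0.05).

The Friedman statistic uses the χ² approximation

    χ² = 12 / (n k (k+1)) · Σ_j R_j² − 3 n (k+1),   df = k − 1,

where n = blocks (classifiers), k = treatments (methods) and R_j is the rank
sum of treatment j; ranks run 1 (lowest score) .. k (highest) within each
block, with average ranks on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RankTable",
    "anderson_darling_normal",
    "oneway_anova",
    "friedman_test",
    "compare_samplers",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    extras: dict = field(default_factory=dict)


@dataclass
class RankTable:
    """Within-block ranks (1 = lowest .. k = highest) and their column sums."""

    ranks: pd.DataFrame
    rank_sums: pd.Series

    @property
    def n_blocks(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.ranks.shape[1]


# ---------------------------------------------------------------------------
# Anderson–Darling (normality, case 3: mean and variance estimated)
# ---------------------------------------------------------------------------

def anderson_darling_normal(values) -> TestResult:
    """Anderson–Darling test of normality with estimated parameters.

    Returns the corrected statistic A*² = A²(1 + 4/n − 25/n²) and a p-value
    from the standard piecewise exponential approximation. Requires n ≥ 8 and
    non-constant input.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 values, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant input: normality test undefined")
    w = (x - x.mean()) / s
    logcdf = sps.norm.logcdf(w)
    logsf = sps.norm.logsf(w)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n
    a2_star = a2 * (1 + 4.0 / n - 25.0 / n**2)
    if a2_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = np.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(
        name="anderson-darling",
        statistic=float(a2_star),
        df=None,
        pvalue=p,
        extras={"A2": float(a2), "n": n},
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def oneway_anova(groups: list) -> TestResult:
    """One-way fixed-effects ANOVA with the full SS/MS/F decomposition.

    ``groups`` is a list of value sequences, one per treatment. The extras
    carry the standard table: SS_between/within/total, MS, df. A fully
    degenerate input (zero between- and within-variance) yields an undefined
    F, reported as NaN with p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ss_between == 0:
            f_val, p = float("nan"), 1.0
        else:
            f_val, p = float("inf"), 0.0
    else:
        f_val = ms_between / ms_within
        p = float(sps.f.sf(f_val, df_between, df_within))
    return TestResult(
        name="anova",
        statistic=float(f_val),
        df=(df_between, df_within),
        pvalue=p,
        extras={
            "ss_between": ss_between,
            "ss_within": ss_within,
            "ss_total": ss_between + ss_within,
            "ms_between": ms_between,
            "ms_within": ms_within,
        },
    )


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def rank_blocks(matrix: pd.DataFrame) -> RankTable:
    """Rank each row 1..k (average ranks on ties); higher score, higher rank."""
    ranked = matrix.apply(lambda row: sps.rankdata(row.to_numpy()), axis=1, result_type="broadcast")
    return RankTable(ranks=ranked, rank_sums=ranked.sum(axis=0))


def friedman_test(matrix) -> tuple[TestResult, RankTable]:
    """Friedman χ² over an n-blocks × k-treatments score matrix.

    Feeding a matrix that already contains within-row ranks reproduces those
    ranks unchanged (ranking is idempotent). Missing cells are rejected.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 treatments, got {n}x{k}")
    if matrix.isna().any().any():
        raise ValueError("missing cells in the score matrix")
    table = rank_blocks(matrix)
    r = table.rank_sums.to_numpy(dtype=float)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(r**2)) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return (
        TestResult(name="friedman", statistic=float(chi2), df=df, pvalue=p),
        table,
    )


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def compare_samplers(score_matrix, alpha: float = 0.05) -> dict:
    """Normality-gated comparison of sampling methods.

    Runs the Anderson–Darling test on the flattened cells of the
    classifiers × methods score matrix; routes to ANOVA over method columns
    when normality is not rejected (p > alpha), otherwise to the Friedman
    test with its rank table. Returns a report dict with the chosen route,
    both test results, the rank table when applicable, and a plain-text
    summary.
    """
    if not isinstance(score_matrix, pd.DataFrame):
        score_matrix = pd.DataFrame(np.asarray(score_matrix, dtype=float))
    flat = score_matrix.to_numpy(dtype=float).ravel()
    normality = anderson_darling_normal(flat)
    report: dict = {"normality": normality, "alpha": alpha}
    if normality.pvalue > alpha:
        groups = [score_matrix[c].to_numpy(dtype=float) for c in score_matrix.columns]
        test = oneway_anova(groups)
        report["route"] = "anova"
        report["test"] = test
        report["rank_table"] = None
        verdict = "no significant difference" if test.pvalue > alpha else "significant difference"
        report["summary"] = (
            f"Scores consistent with normality (AD p = {normality.pvalue:.4f}); "
            f"one-way ANOVA F = {test.statistic:.4f}, p = {test.pvalue:.4f}: {verdict} "
            "between sampling methods."
        )
    else:
        test, table = friedman_test(score_matrix)
        report["route"] = "friedman"
        report["test"] = test
        report["rank_table"] = table
        best = table.rank_sums.idxmax()
        verdict = "no significant difference" if test.pvalue > alpha else "significant difference"
        report["summary"] = (
            f"Normality rejected (AD p = {normality.pvalue:.4f}); Friedman "
            f"chi2 = {test.statistic:.4f} (df = {test.df}), p = {test.pvalue:.4f}: {verdict}. "
            f"Highest-ranked method: {best} (rank sum {table.rank_sums.max():g})."
        )
    return report
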