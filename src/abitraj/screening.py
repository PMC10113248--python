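"""Univariable screening of predictors against the binary discharge outcome.

Each candidate variable is tested for association with the positive/negative
outcome at each evaluation: continuous variables with a two-sided Welch
two-sample t-test, categorical variables with a chi-squared test of
independence, replaced by a Fisher exact test whenever any expected cell
count falls below 5.  Variables whose minimum p-value across evaluations
exceeds the screening alpha are dropped before the mixed-data PCA.

The 2xk Fisher exact test (k > 2 columns are common here: feeding modality,
diagnosis, etiology) is the exhaustive conditional test: all tables with the
observed margins are enumerated and those no more probable than the observed
one are summed under the multivariate hypergeometric null.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EVALUATIONS, VariableDictionary

#: expected-count rule below which the chi-squared approximation is distrusted
EXPECTED_COUNT_RULE = 5.0
#: enumeration guard for the exact test
MAX_EXACT_TABLES = 2_000_000


@dataclass(frozen=True)
class TestResult:
    variable: str
    evaluation: str
    kind: str  # "chi-squared" | "fisher" | "t"
    statistic: float
    p_value: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2 x k contingency table.

    Conditions on both margins; the p-value is the total null probability of
    all tables whose point probability does not exceed the observed one
    (scipy's two-sided convention, which this reproduces on 2x2 tables).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    col_tot = table.sum(axis=0)
    r1 = int(table[0].sum())
    n = int(table.sum())
    if np.prod(np.minimum(col_tot, r1) + 1.0) > MAX_EXACT_TABLES:
        raise ValueError("table too large for exhaustive Fisher enumeration")

    log_denom = _log_binom(n, r1)

    def log_prob(row1: Iterable[int]) -> float:
        return sum(_log_binom(c, x) for c, x in zip(col_tot, row1)) - log_denom

    lp_obs = log_prob(table[0])
    k = len(col_tot)
    total = 0.0

    # DFS over admissible first rows with the fixed margins
    def rec(j: int, remaining: int, acc: float):
        nonlocal total
        if j == k - 1:
            if remaining <= col_tot[j]:
                lp = acc + _log_binom(col_tot[j], remaining) - log_denom
                if lp <= lp_obs + 1e-9:
                    total += np.exp(lp)
            return
        tail = int(col_tot[j + 1 :].sum())
        lo = max(0, remaining - tail)
        hi = min(col_tot[j], remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, acc + _log_binom(col_tot[j], x))

    rec(0, r1, 0.0)
    return float(min(total, 1.0))


def association_test(
    values: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    kind: str = "auto",
    variable: str = "",
    evaluation: str = "",
) -> TestResult:
    """Test association between one variable and the binary outcome.

    ``kind='auto'`` chooses by dtype: numeric values get the Welch t-test;
    anything else is treated as categorical (chi-squared, or Fisher exact
    when any expected cell count is < 5).  Missing values are dropped
    pairwise.  Raises on degenerate input (a single outcome class, constant
    values, or too few observations per group).
    """
    values = pd.Series(values).reset_index(drop=True)
    outcome = pd.Series(outcome).reset_index(drop=True)
    keep = values.notna() & outcome.notna()
    values, outcome = values[keep], outcome[keep]
    if values.empty:
        raise ValueError("all values missing")
    classes = sorted(outcome.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two outcome classes, got {classes}")

    if kind == "auto":
        kind = "t" if pd.api.types.is_numeric_dtype(values) else "categorical"

    if kind == "t":
        g0 = values[outcome == classes[0]].to_numpy(dtype=float)
        g1 = values[outcome == classes[1]].to_numpy(dtype=float)
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError("need >= 2 observations per group for the t-test")
        if np.ptp(g0) == 0 and np.ptp(g1) == 0:
            raise ValueError("constant values in both groups: degenerate t-test")
        stat, p = stats.ttest_ind(g0, g1, equal_var=False)
        return TestResult(variable, evaluation, "t", float(stat), float(p), len(values))

    table = pd.crosstab(values, outcome).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected < EXPECTED_COUNT_RULE).any():
        # orient as 2 x k (outcome on the 2-row axis)
        p = fisher_exact_2xk(table.T)
        return TestResult(variable, evaluation, "fisher", float("nan"), p, len(values))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(variable, evaluation, "chi-squared", float(chi2), float(p), len(values))


def screen_cohort(
    long_df: pd.DataFrame,
    dictionary: VariableDictionary,
    variables: list[str] | None = None,
) -> list[TestResult]:
    """Run the univariable screen for every variable at every evaluation.

    Time-invariant variables (age, sex, etiology, ICU days) are tested at T0
    only.  Degenerate variable/evaluation combinations (all missing, constant)
    are silently omitted from the report.
    """
    if variables is None:
        variables = [v.name for v in dictionary if v.name in long_df.columns]
    results: list[TestResult] = []
    for name in variables:
        var = dictionary[name]
        evals = ("T0",) if var.time_invariant else EVALUATIONS
        for ev in evals:
            sub = long_df[long_df["evaluation"] == ev]
            if sub.empty:
                continue
            try:
                results.append(
                    association_test(
                        sub[name], sub["outcome"], kind="auto", variable=name, evaluation=ev
                    )
                )
            except ValueError:
                continue
    return results


def select_variables(results: list[TestResult], alpha: float = 0.05) -> list[str]:
    """Keep a variable iff its minimum p-value over evaluations is <= alpha."""
    if not results:
        raise ValueError("no screening results")
    best: dict[str, float] = {}
    order: list[str] = []
    for r in results:
        if r.variable not in best:
            order.append(r.variable)
            best[r.variable] = r.p_value
        else:
            best[r.variable] = min(best[r.variable], r.p_value)
    return [v for v in order if best[v] <= alpha]


def screening_report(results: list[TestResult]) -> pd.DataFrame:
    """Tabular screening report (variable, evaluation, test, statistic, p)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "evaluation": r.evaluation,
                "test": r.kind,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in results
        ]
    )
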