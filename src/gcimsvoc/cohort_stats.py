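"""Exact and rank-based cohort baseline statistics.

Baseline ("Table 1"-style) comparisons in small case-control cohorts:
continuous covariates are compared with the Kruskal–Wallis H test across all
groups plus pairwise Wilcoxon rank-sum tests; dichotomous covariates with
the Fisher–Freeman–Halton exact test across all groups plus pairwise
Fisher's exact 2×2 tests.

Both exact tests use the two-sided probability-mass rule: the p-value sums
the probabilities (hypergeometric for 2×2, multivariate hypergeometric for
r×c) of every table with the observed margins whose probability does not
exceed the observed table's by more than a relative tolerance of 1e−7 — the
convention of mainstream statistical software.  The r×c enumeration is
depth-first over cells with margin-feasibility pruning and a configurable
table budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["ContingencyTable", "TestResult", "fisher_exact_2x2",
           "fisher_freeman_halton", "kruskal_wallis", "table1_report"]

#: Relative tolerance for the probability-mass comparison of exact tests.
REL_TOL = 1e-7

#: Default enumeration budget for the r×c exact test.
ENUM_BUDGET = 10_000_000


@dataclass
class ContingencyTable:
    """r×c counts with labels; r, c ≥ 2, non-negative, positive total."""

    counts: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")
        if self.row_labels is None:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if self.col_labels is None:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    p_value: float
    method: str
    statistic: float | None = None
    sizes: tuple = ()


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(counts=np.asarray(table))


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2×2 table."""
    t = _as_table(table)
    if t.counts.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.counts.shape}")
    _, p = stats.fisher_exact(t.counts, alternative="two-sided")
    return TestResult(p_value=float(min(p, 1.0)), method="fisher_exact",
                      sizes=tuple(t.counts.sum(axis=1)))


def _log_table_prob(counts: np.ndarray, log_const: float) -> float:
    """log P(table | margins) under the multivariate hypergeometric."""
    return log_const - gammaln(counts + 1).sum()


def _iter_margin_tables(row_sums, col_sums):
    """Yield every non-negative integer matrix with the given margins.

    Depth-first over cells in row-major order with a feasibility bound:
    a partial cell value is admissible only if the remaining row total can
    still be absorbed by the remaining column capacities.
    """
    row_sums = list(map(int, row_sums))
    col_sums = list(map(int, col_sums))
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=int)
    col_left = list(col_sums)

    def rec(i):
        if i == r - 1:
            # last row is forced by the column remainders
            if sum(col_left) == row_sums[i]:
                table[i] = col_left
                yield table.copy()
            return
        yield from rec_row(i, 0, row_sums[i])

    def rec_row(i, j, left):
        if j == c - 1:
            if left <= col_left[j]:
                table[i, j] = left
                col_left[j] -= left
                yield from rec(i + 1)
                col_left[j] += left
            return
        # remaining columns after j can absorb at most sum(col_left[j+1:])
        tail_cap = sum(col_left[j + 1:])
        lo = max(0, left - tail_cap)
        hi = min(left, col_left[j])
        for v in range(lo, hi + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from rec_row(i, j + 1, left - v)
            col_left[j] += v

    yield from rec(0)


def fisher_freeman_halton(table, budget: int = ENUM_BUDGET) -> TestResult:
    """Exact two-sided test for an r×c table (generalised Fisher).

    Enumerates all tables sharing the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable
    than the observed table (relative tolerance 1e−7).

    Raises
    ------
    RuntimeError
        If the enumeration exceeds ``budget`` tables (a Monte-Carlo mode
        would be needed for such inputs; not provided).
    """
    t = _as_table(table)
    counts = t.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    log_const = (gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum()
                 - gammaln(n + 1))
    log_obs = _log_table_prob(counts, log_const)
    cut = log_obs + np.log1p(REL_TOL)

    p = 0.0
    seen = 0
    for cand in _iter_margin_tables(row_sums, col_sums):
        seen += 1
        if seen > budget:
            raise RuntimeError(
                f"enumeration budget of {budget} tables exceeded; "
                "this table needs a Monte-Carlo variant")
        lp = _log_table_prob(cand, log_const)
        if lp <= cut:
            p += float(np.exp(lp))
    return TestResult(p_value=float(min(p, 1.0)),
                      method="fisher_freeman_halton",
                      sizes=tuple(int(v) for v in row_sums))


def total_margin_probability(table, budget: int = ENUM_BUDGET) -> float:
    """Sum of probabilities over the full margin-constrained family (≈1)."""
    t = _as_table(table)
    counts = t.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    log_const = (gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum()
                 - gammaln(n + 1))
    total = 0.0
    for i, cand in enumerate(_iter_margin_tables(row_sums, col_sums)):
        if i >= budget:
            raise RuntimeError("enumeration budget exceeded")
        total += float(np.exp(_log_table_prob(cand, log_const)))
    return total


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = k − 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(p_value=1.0, statistic=0.0,
                          method="kruskal_wallis",
                          sizes=tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)
    return TestResult(p_value=float(p), statistic=float(h),
                      method="kruskal_wallis",
                      sizes=tuple(g.size for g in groups))


# --------------------------------------------------------------------------
# baseline characteristics report

CONTINUOUS_VARS = ("age", "bmi", "bristol_stool_score")
DICHOTOMOUS_VARS = ("sex", "smoking", "ppi", "antibiotics",
                    "immunosuppressants")


def _dichotomous_counts(values) -> tuple:
    """(positives, negatives) for a boolean-ish covariate column."""
    pos = sum(1 for v in values if v in (True, 1, "female", "yes"))
    return pos, len(values) - pos


def table1_report(cohort, group_order=None) -> dict:
    """Baseline-characteristics tests for every recognised covariate.

    Continuous covariates → Kruskal–Wallis over all groups + pairwise
    rank-sum tests, with per-group median and IQR.  Dichotomous covariates
    (``sex`` counts ``'female'``/True as positive) → Fisher–Freeman–Halton
    over all groups + pairwise Fisher 2×2.  Covariates missing for any
    sample are skipped with a warning.  Output is invariant to sample order.
    """
    from .selection import ranksum_pvalue

    groups = group_order or sorted({r.group for r in cohort.records})
    if len(groups) < 2:
        raise ValueError("cohort must contain at least two groups")
    by_group = {g: [r for r in cohort.records if r.group == g]
                for g in groups}
    if any(len(v) == 0 for v in by_group.values()):
        raise ValueError("every requested group must be non-empty")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]

    report = {}
    for var in CONTINUOUS_VARS + DICHOTOMOUS_VARS:
        cols = {}
        complete = True
        for g in groups:
            vals = [r.covariates.get(var) for r in by_group[g]]
            if any(v is None for v in vals):
                complete = False
                break
            cols[g] = vals
        if not complete:
            warnings.warn(f"covariate {var!r} missing for some samples; "
                          "skipped", stacklevel=2)
            continue

        entry = {"variable": var, "pairwise": {}}
        if var in CONTINUOUS_VARS:
            data = {g: np.asarray(cols[g], dtype=float) for g in groups}
            entry["kind"] = "continuous"
            entry["overall"] = kruskal_wallis([data[g] for g in groups])
            entry["summary"] = {
                g: {"median": float(np.median(data[g])),
                    "iqr": [float(np.percentile(data[g], 25)),
                            float(np.percentile(data[g], 75))]}
                for g in groups}
            for a, b in pairs:
                entry["pairwise"][(a, b)] = TestResult(
                    p_value=ranksum_pvalue(data[a], data[b]),
                    method="wilcoxon_ranksum",
                    sizes=(data[a].size, data[b].size))
        else:
            counts = {g: _dichotomous_counts(cols[g]) for g in groups}
            entry["kind"] = "dichotomous"
            entry["summary"] = {g: {"positive": counts[g][0],
                                    "n": sum(counts[g])} for g in groups}
            overall = ContingencyTable(
                counts=np.array([counts[g] for g in groups]),
                row_labels=list(groups), col_labels=["yes", "no"])
            entry["overall"] = fisher_freeman_halton(overall)
            for a, b in pairs:
                entry["pairwise"][(a, b)] = fisher_exact_2x2(
                    np.array([counts[a], counts[b]]))
        report[var] = entry
    return report
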