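"""Group-comparison statistics.

Three tests, matching the conventions of the statistical environment in
which MA studies are usually analyzed (R): a two-sided Wilcoxon rank-sum
test on per-line rates (exact null distribution for small tie-free
samples, otherwise normal approximation with tie and continuity
correction), a two-sided F-test on rate variances, and Fisher's exact
test on contingency tables (exact for 2x2, fixed-margin Monte Carlo for
larger tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "variance_f_test",
    "fisher_exact_rxc",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    method: str
    n_mc: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is
    at most 20 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction (the R ``wilcox.test``
    convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    if not ties and len(combined) <= 20:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal approximation (tie + continuity corrected)"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return TestResult(
        name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=method,
    )


def variance_f_test(x, y) -> TestResult:
    """Two-sided F-test for equal variances: F = var(x)/var(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        return TestResult(
            name="variance_f_test",
            statistic=float("nan"),
            p_value=float("nan"),
            method="undefined (zero variance in denominator)",
        )
    F = vx / vy
    dist = sps.f(len(x) - 1, len(y) - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return TestResult(
        name="variance_f_test",
        statistic=F,
        p_value=min(1.0, p),
        method=f"F({len(x) - 1}, {len(y) - 1}), two-sided",
    )


def _log_table_prob(table: np.ndarray, lgr: float, lgc: float, lgn: float) -> float:
    """Log hypergeometric probability of a table given its margins."""
    return lgr + lgc - lgn - float(gammaln(table + 1).sum())


def fisher_exact_rxc(
    table, seed: int = 0, n_mc: int = 100_000
) -> TestResult:
    """Fisher's exact test on an r x c table of counts.

    2x2 tables use the exact two-sided hypergeometric test
    (probability-mass criterion: sum over tables no more probable than
    the observed one). Larger tables use a Monte-Carlo p-value over
    ``n_mc`` tables sampled with fixed margins, reported as
    (hits + 1) / (n_mc + 1); reproducible bit-for-bit under a fixed
    seed. A zero row or column margin is degenerate and returns p = 1.
    """
    table = np.asarray(table)
    if table.ndim != 2 or np.any(table < 0) or not np.issubdtype(
        table.dtype, np.integer
    ):
        raise ValueError("table must be a 2-D array of non-negative integers")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return TestResult(
            name="fisher_exact",
            statistic=float("nan"),
            p_value=1.0,
            method="degenerate (zero margin)",
        )
    if table.shape == (2, 2):
        res = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(
            name="fisher_exact",
            statistic=float(res.statistic),
            p_value=min(1.0, float(res.pvalue)),
            method="exact 2x2",
        )
    # Monte Carlo over tables with fixed margins. Orient so rows are the
    # shorter dimension: the p-value is invariant under transposition and
    # sampling cost scales with the number of rows.
    t = table.T if table.shape[0] > table.shape[1] else table
    rows, cols = t.shape
    r_sums = t.sum(axis=1)
    c_sums = t.sum(axis=0)
    lgr = float(gammaln(r_sums + 1).sum())
    lgc = float(gammaln(c_sums + 1).sum())
    lgn = float(gammaln(t.sum() + 1))
    obs_lp = _log_table_prob(t, lgr, lgc, lgn)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        remaining = c_sums.copy()
        lp = lgr + lgc - lgn
        for i in range(rows - 1):
            draw = rng.multivariate_hypergeometric(remaining, int(r_sums[i]))
            lp -= float(gammaln(draw + 1).sum())
            remaining = remaining - draw
        lp -= float(gammaln(remaining + 1).sum())
        if lp <= obs_lp + 1e-9:
            hits += 1
    return TestResult(
        name="fisher_exact",
        statistic=float("nan"),
        p_value=(hits + 1) / (n_mc + 1),
        method="Monte Carlo, fixed margins",
        n_mc=n_mc,
        seed=seed,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (for pairwise reports)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
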