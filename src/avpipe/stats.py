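"""Statistics applied to event counts, proportions, durations and expression.

The exact two-tailed Fisher test and the Mann-Whitney U test are authored
here as explicit enumerations (the conventions are documented because
alternative two-tailed definitions exist); Wilson confidence intervals are
delegated to statsmodels, and omnibus tests (one-way ANOVA, Kruskal-Wallis)
to scipy behind the same ``TestResult`` contract.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ContingencyTable2x2", "TestResult", "fisher_exact_two_tailed",
           "mann_whitney", "percent_change", "proportion_ci",
           "ddct_expression", "fraction_ratio", "one_way_anova",
           "kruskal_wallis"]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome / not-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def fisher_exact_two_tailed(table: ContingencyTable2x2 | tuple) -> TestResult:
    """Exact two-tailed Fisher test by point-probability enumeration.

    Sums the hypergeometric probabilities of every same-margin table no more
    likely than the observed one (the convention of mainstream
    implementations; the "doubled one-tail" alternative is not used).
    The statistic reported is the sample odds ratio.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.total
    k = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    logpmf = sps.hypergeom.logpmf(k, n, r1, c1)
    log_obs = sps.hypergeom.logpmf(a, n, r1, c1)
    p = float(np.exp(logpmf[logpmf <= log_obs + 1e-7]).sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(statistic=odds, p_value=p,
                      method="fisher_exact_two_tailed", n=(r1, c + d))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x via midranks (ties get half wins)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y) -> TestResult:
    """Two-tailed Mann-Whitney U test with midrank ties.

    Exact by enumeration of all rank splits when min(n, m) ≤ 8 and the
    number of splits is tractable (valid with ties); otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0
    if min(n, m) <= 8 and math.comb(n + m, min(n, m)) <= 200_000:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = 0
        hits = 0
        offset = n * (n + 1) / 2.0
        dev_obs = abs(u_obs - mu) - 1e-9
        for idx in itertools.combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        p = hits / total
    else:
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum()
        big_n = n + m
        var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(statistic=u_obs, p_value=p, method="mann_whitney",
                      n=(n, m))


def percent_change(reference_rate: float, new_rate: float) -> float:
    """Percent change relative to ``reference_rate``; positive = decrease."""
    if reference_rate <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * (reference_rate - new_rate) / reference_rate


def proportion_ci(successes: int, n: int, level: float = 0.95
                  ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n and n > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level,
                                method="wilson")
    # the Wilson interval contains the point estimate analytically; guard
    # against floating-point fuzz at the boundaries
    p_hat = successes / n
    lo = min(max(float(lo), 0.0), p_hat)
    hi = max(min(float(hi), 1.0), p_hat)
    return lo, hi


def ddct_expression(ct_target_test: float, ct_ref_test: float,
                    ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression 2^ΔΔCt against a reference gene and control.

    ΔΔCt = (Ct_target − Ct_ref)_control − (Ct_target − Ct_ref)_test; equals
    1.0 when test and control ΔCt coincide.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_ctrl - ct_ref_ctrl) - (ct_target_test - ct_ref_test)
    return 2.0 ** ddct


def fraction_ratio(numerator_pair: tuple[float, float],
                   denominator_pair: tuple[float, float]) -> float:
    """Ratio of two phospho/total fractions, e.g. membrane vs cytosol."""
    pn, tn = numerator_pair
    pd, td = denominator_pair
    if tn <= 0 or td <= 0:
        raise ValueError("total signals must be > 0")
    if pd == 0:
        raise ValueError("denominator fraction is zero")
    return (pn / tn) / (pd / td)


def one_way_anova(*samples) -> TestResult:
    """One-way ANOVA (delegated to scipy) behind the TestResult contract."""
    f, p = sps.f_oneway(*samples)
    return TestResult(statistic=float(f), p_value=float(p),
                      method="one_way_anova",
                      n=tuple(len(s) for s in samples))


def kruskal_wallis(*samples) -> TestResult:
    """Kruskal-Wallis H test (delegated to scipy)."""
    h, p = sps.kruskal(*samples)
    return TestResult(statistic=float(h), p_value=float(p),
                      method="kruskal_wallis",
                      n=tuple(len(s) for s in samples))
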