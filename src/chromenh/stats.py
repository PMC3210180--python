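"""Statistical primitives used throughout the pipeline.

Rank correlation with its Student-t significance, Poisson and
hypergeometric tails for enrichment and sharing tests, the Wilcoxon
signed-rank test, one-way ANOVA and the chi-square goodness-of-fit test.

Conventions:

* Spearman's rho is the Pearson correlation of mid-ranks, so tied values
  (ubiquitous in binned tag counts) receive average ranks.  A vector
  with zero rank variance makes the correlation undefined; such cases
  return ``nan`` rather than raising, and callers that score genomic
  windows treat ``nan`` as a non-match.
* All tail probabilities are proper probabilities in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "spearman_rho",
    "spearman_significance",
    "poisson_sf",
    "hypergeom_left",
    "wilcoxon_signed_rank",
    "oneway_anova",
    "chi2_gof",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value and, where meaningful, df and n."""

    __test__ = False  # not a pytest class despite the name

    statistic: float
    pvalue: float
    df: float | tuple[float, float] | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns ``nan`` when either vector has zero rank variance (all
    values identical), which no correlation can be assigned to.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return float("nan")
    rho = float(rx @ ry) / denom
    return float(min(1.0, max(-1.0, rho)))


def spearman_significance(rho: float, n: int) -> TestResult:
    """Two-tailed significance of a Spearman coefficient.

    Uses ``t = rho * sqrt((n - 2) / (1 - rho**2))`` referred to a
    Student t distribution with ``n - 2`` degrees of freedom.  ``|rho| = 1``
    is reported as infinite t with p = 0 by convention.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if math.isnan(rho):
        return TestResult(float("nan"), float("nan"), df=n - 2, n=n)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1.0:
        return TestResult(math.copysign(math.inf, rho), 0.0, df=n - 2, n=n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return TestResult(t, min(1.0, p), df=n - 2, n=n)


def poisson_sf(k: int, mean: float) -> float:
    """Upper tail ``P(X >= k)`` for ``X ~ Poisson(mean)``.

    Stable for large means (computed via the regularized incomplete
    gamma function rather than term-by-term summation).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not mean > 0:
        raise ValueError("mean must be > 0")
    if k == 0:
        return 1.0
    # P(X >= k) = P(X > k - 1)
    return float(sps.poisson.sf(k - 1, mean))


def hypergeom_left(N: int, K: int, n: int, k: int) -> float:
    """Exact left tail ``P(X <= k)`` of Hypergeometric(N, K, n).

    ``N`` population size, ``K`` marked items, ``n`` draws, ``k``
    observed marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(min(1.0, sps.hypergeom.cdf(k, N, K, n)))


def _signed_rank_prep(pairs: Sequence[tuple[float, float]]):
    d = np.asarray([a - b for a, b in pairs], dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return None, None
    ranks = sps.rankdata(np.abs(d))
    return d, ranks


def _exact_signed_rank_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-tailed p by convolving the null rank-sum distribution.

    Mid-ranks are multiples of 1/2, so sums are tracked on a doubled
    integer grid.  Each rank independently joins the positive sum with
    probability 1/2 under the null.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(w * 2))
    lower = float(dist[: w2 + 1].sum())
    upper = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], *, exact_limit: int = 15
) -> TestResult:
    """Wilcoxon signed-rank test on paired observations.

    Differences of zero are dropped; tied absolute differences receive
    mid-ranks.  ``W`` is the sum of ranks of positive differences.  The
    two-tailed p-value is exact (null distribution by convolution) for
    up to ``exact_limit`` nonzero pairs, and a normal approximation with
    tie correction beyond that.  All-zero differences make the test
    undefined (``nan`` statistic and p-value).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    d, ranks = _signed_rank_prep(pairs)
    if d is None:
        return TestResult(float("nan"), float("nan"), n=0)
    m = int(d.size)
    w = float(ranks[d > 0].sum())
    if m <= exact_limit:
        p = _exact_signed_rank_p(w, ranks)
    else:
        mean = m * (m + 1) / 4.0
        # variance with tie correction: sum over tie groups of (t^3 - t)/48
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((counts**3 - counts) / 48.0).sum())
        var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
        if var <= 0:
            return TestResult(w, float("nan"), n=m)
        z = (w - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(w, p, n=m)


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA over two or more groups.

    Returns the F ratio of between- to within-group mean squares with
    ``(g - 1, N - g)`` degrees of freedom.  If both mean squares are
    zero (all observations identical) F is undefined (``nan``).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    N = sum(a.size for a in arrays)
    g = len(arrays)
    grand = sum(float(a.sum()) for a in arrays) / N
    ss_between = sum(a.size * (float(a.mean()) - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_b, df_w = g - 1, N - g
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            return TestResult(float("nan"), float("nan"), df=(df_b, df_w), n=N)
        return TestResult(math.inf, 0.0, df=(df_b, df_w), n=N)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(f, p, df=(df_b, df_w), n=N)


def chi2_gof(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Chi-square goodness of fit, df = number of cells - 1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected must be equal-length vectors (>=2)")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, df=df, n=int(obs.size))
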