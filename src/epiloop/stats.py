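"""Statistical primitives shared by every analysis stage.

Where a scipy routine implements the textbook procedure (Welch t, Pearson r,
hypergeometric tail, asymptotic rank-sum test) it is used behind this
surface; the pieces that need to be exactly checkable against enumeration
oracles (Benjamini-Hochberg step-up, the exact permutation rank-sum test)
and the empirical-Bayes moderated t used for differential expression are
implemented here.

p-values are reported as computed, never truncated at some floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats as sps
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or association test, with provenance."""

    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int
    estimate: float | None = None  # e.g. Pearson r

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at
    1; the result is returned in the input order.  The caller chooses the
    family: adjustment is applied to exactly the values passed in, never
    globally.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(pop N, successes K, draws n).

    Evaluated through log-gamma pmf terms (scipy); exact to double
    precision, as verified against rational enumeration in the test suite.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(K, n):
        raise ValueError(f"impossible configuration: k={k} > min(K={K}, n={n})")
    if k <= max(0, n + K - N):
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p for the rank-sum statistic of x.

    Midranks handle ties; doubling makes every rank an integer so the
    null distribution can be counted exactly by subset-sum dynamic
    programming over all C(n_x+n_y, n_x) splits.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(sps.rankdata(pooled) * 2).astype(int)  # doubled midranks
    w_obs = int(ranks2[:nx].sum())
    total = int(ranks2.sum())
    # counts[j][s] = number of j-subsets of the doubled ranks with sum s
    max_sum = total
    counts = [np.zeros(max_sum + 1, dtype=object) for _ in range(nx + 1)]
    counts[0][0] = 1
    for r in ranks2:
        for j in range(min(nx, len(ranks2)), 0, -1):
            shifted = np.zeros(max_sum + 1, dtype=object)
            shifted[r:] = counts[j - 1][: max_sum + 1 - r]
            counts[j] = counts[j] + shifted
    dist = counts[nx]
    n_splits = int(dist.sum())
    # two-sided: splits at least as far from the null mean as observed
    mean2 = nx * (total / (nx + ny))
    dev = abs(w_obs - mean2)
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    n_extreme = int(dist[extreme].sum())
    p = n_extreme / n_splits
    return float(w_obs / 2.0), min(1.0, p)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    mode 'exact' enumerates the permutation null (tie-aware); 'normal' uses
    the tie-corrected normal approximation with continuity correction;
    'auto' picks exact when n_x + n_y <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= 20 else "normal"
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return TestResult(0.0, 1.0, f"wilcoxon-{mode}", x.size, y.size)
    if mode == "exact":
        stat, p = _exact_rank_sum_p(x, y)
        return TestResult(stat, p, "wilcoxon-exact", x.size, y.size)
    if mode == "normal":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return TestResult(
            float(res.statistic), float(res.pvalue), "wilcoxon-normal", x.size, y.size
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Welch t and Pearson r
# ---------------------------------------------------------------------------


def welch_t(x, y) -> TestResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs >=2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch-t", x.size, y.size)
        # perfect separation limit
        sign = np.sign(x.mean() - y.mean())
        return TestResult(float(sign * np.inf), 0.0, "welch-t", x.size, y.size)
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        float(res.statistic), float(res.pvalue), "welch-t", x.size, y.size
    )


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("pearson_corr needs n >= 3")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", x.size, y.size, estimate=float(r))


def euclidean_distance_matrix(matrix) -> np.ndarray:
    """Pairwise Euclidean distances between the rows of a samples x features
    matrix; symmetric with a zero diagonal."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >=2 samples")
    if np.isnan(m).any():
        raise ValueError("NaN feature value")
    return squareform(pdist(m, metric="euclidean"))


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t (variance pooled across genes)
# ---------------------------------------------------------------------------


def fit_inverse_chisq_prior(s2, df: int) -> tuple[float, float]:
    """Fit the scaled-inverse-chi-square prior (s0^2, d0) for gene-wise
    variances by matching moments of log s^2 (the classical limma fit).

    Returns (s0_squared, d0); d0 = inf when the observed spread of log
    variances is no larger than the chi-square sampling spread alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >=2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        s0 = float(np.exp(e.mean()))
        return s0, np.inf
    f = lambda x: float(special.polygamma(1, x)) - evar
    x = optimize.brentq(f, 1e-8, 1e8)
    d0 = 2.0 * x
    s0 = float(np.exp(e.mean() + special.digamma(x) - np.log(x)))
    return s0, d0


def moderated_t_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Row-wise two-sample t with empirical-Bayes moderated variance.

    `a` and `b` are genes x replicates matrices on a roughly homoscedastic
    scale (log2 of normalized counts).  Gene-wise pooled variances are
    shrunk toward a prior fitted across genes, and the t statistic gains
    d0 prior degrees of freedom, mirroring how count-model DE engines share
    dispersion information across genes.

    Returns (t, p, d0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("need matching genes x replicates matrices")
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 replicates per group")
    df = n1 + n2 - 2
    v = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df
    s0, d0 = fit_inverse_chisq_prior(v, df)
    if np.isinf(d0):
        v_mod = np.full_like(v, s0)
        df_total: float = 1e12  # effectively normal
    else:
        v_mod = (d0 * s0 + df * v) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(v_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=1) - b.mean(axis=1)) / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return t, p, d0
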