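"""Ewens-sampling-formula machinery and neutrality tests.

Under the infinite-allele model every mutation creates a brand-new allele,
so a population of N cells is partitioned into alleles (live clones).  At
mutation-drift equilibrium the allele-size configuration follows the Ewens
Sampling Formula with scaled mutation rate theta.  Two test procedures are
provided for ensembles of simulation runs:

* a one-sample Kolmogorov-Smirnov test of the observed allele counts k
  against the ESF distribution of K;
* a two-sample two-sided Wilcoxon rank-sum test of observed singleton
  counts against the conditional expectations E(A_1 | k, n) computed from
  each run's own k (the "semi-empirical" null).

All Stirling-number and ESF computations are carried in log space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .population import PopulationState

__all__ = [
    "AlleleSample",
    "NeutralityReport",
    "NeutralityTestKind",
    "log_stirling1",
    "ewens_pmf_K",
    "conditional_mean_spectrum",
    "theta_from_model",
    "allele_count_test",
    "singleton_test",
    "allele_summary",
]


class NeutralityTestKind(str, enum.Enum):
    ALLELE_COUNT_KS = "allele_count_KS"
    SINGLETON_WILCOXON = "singleton_wilcoxon"


@dataclass
class AlleleSample:
    """Allele-size configuration of one sampled population.

    ``a[j-1]`` is the number of alleles carried by exactly j of the n
    cells; ``k = sum(a)`` alleles in total and ``sum(j * a_j) = n``.
    """

    n: int
    k: int
    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        if self.a.shape != (self.n,):
            raise ValueError("allele-size spectrum must have length n")
        j = np.arange(1, self.n + 1)
        if int((j * self.a).sum()) != self.n:
            raise ValueError("sum of j*a_j must equal n")
        if int(self.a.sum()) != self.k:
            raise ValueError("sum of a_j must equal k")

    @property
    def singletons(self) -> int:
        return int(self.a[0])


@dataclass
class NeutralityReport:
    test: NeutralityTestKind
    statistic: float
    p_value: float
    n_runs: int
    theta_used: float | None = None
    p_value_bootstrap: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@lru_cache(maxsize=256)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log|S_n^k| for k = 0..n via the recurrence
    |S_{n+1}^k| = n*|S_n^k| + |S_n^{k-1}| in log space."""
    if n == 0:
        return (0.0,)  # |S_0^0| = 1
    prev = _log_stirling_row(n - 1)
    m = n - 1  # building row n from row n-1
    row = [-np.inf] * (n + 1)
    for k in range(1, n + 1):
        terms = []
        if k <= m:
            terms.append(np.log(m) + prev[k])
        if k - 1 <= m:
            terms.append(prev[k - 1])
        row[k] = float(logsumexp(terms)) if terms else -np.inf
    return tuple(row)


def log_stirling1(n: int, k: int) -> float:
    """log of the unsigned Stirling number of the first kind |S_n^k|.

    |S_n^k| is the coefficient of theta**k in the rising factorial
    theta*(theta+1)*...*(theta+n-1).  Requires 1 <= k <= n.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    return _log_stirling_row(n)[k]


def _log_rising_factorial(theta: float, n: int) -> float:
    """log S_n(theta) = log[theta*(theta+1)*...*(theta+n-1)]."""
    return float(np.sum(np.log(theta + np.arange(n))))


def ewens_pmf_K(n: int, theta: float) -> np.ndarray:
    """ESF distribution of the number of alleles K in a sample of n cells.

    P(K = k) = |S_n^k| * theta**k / S_n(theta), k = 1..n, where S_n(theta)
    is the rising factorial.  Returned as an array indexed by k-1; sums to
    1 within 1e-12.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = np.array(_log_stirling_row(n)[1:])
    logp = row + np.arange(1, n + 1) * np.log(theta) - _log_rising_factorial(theta, n)
    pmf = np.exp(logp)
    return pmf / pmf.sum()  # remove residual rounding at the 1e-16 level


def conditional_mean_spectrum(n: int, k: int) -> np.ndarray:
    """E(A_j | k, n) for j = 1..n under the Ewens sampling formula.

    E(A_j | K=k) = n! / (j * (n-j)!) * |S_{n-j}^{k-1}| / |S_n^k|; the
    conditional spectrum is parameter-free given k.  Entries where the
    Stirling number is undefined (k-1 > n-j) are zero.  Conservation:
    sum_j j * E(A_j | k, n) = n.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    from scipy.special import gammaln

    log_snk = log_stirling1(n, k)
    out = np.zeros(n)
    for j in range(1, n + 1):
        kk = k - 1
        nn = n - j
        if kk > nn:
            continue
        if kk == 0:
            log_s = 0.0 if nn == 0 else -np.inf  # |S_0^0|=1, |S_m^0|=0 for m>0
        else:
            log_s = log_stirling1(nn, kk)
        if np.isinf(log_s):
            continue
        log_e = gammaln(n + 1) - np.log(j) - gammaln(n - j + 1) + log_s - log_snk
        out[j - 1] = np.exp(log_e)
    return out


def theta_from_model(N: int, mu: float, lam: float = 1.0) -> float:
    """Scaled mutation rate theta = N*mu/lambda for the ESF null.

    ``lambda`` is the allele fitness correction: cell generation length in
    the model is inversely proportional to fitness, so in non-neutral
    scenarios the effective per-generation mutation rate is mu/lambda.  In
    the neutral case lambda = 1.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    theta = N * mu / lam
    if theta <= 0:
        raise ValueError("theta must be positive (is mu zero?)")
    return theta


def allele_count_test(
    ks: Sequence[int],
    n: int,
    theta: float,
    *,
    bootstrap: int = 0,
    rng: np.random.Generator | int | None = 0,
) -> NeutralityReport:
    """One-sample Kolmogorov-Smirnov test of allele counts against the ESF.

    The empirical distribution of the number of alleles k observed in each
    simulation run is compared with the ESF distribution of K for the
    given n and theta.  The K-S test is applied to the discrete counts as
    is; because discreteness makes the classical p-value conservative, a
    parametric-bootstrap p-value (resampling k from the null pmf) can be
    requested as a robustness companion via ``bootstrap > 0``.
    """
    ks_arr = np.asarray(ks, dtype=np.int64)
    if ks_arr.size == 0:
        raise ValueError("empty sample of allele counts")
    if np.any((ks_arr < 1) | (ks_arr > n)):
        raise ValueError("allele counts must lie in 1..n")
    pmf = ewens_pmf_K(n, theta)
    cdf_grid = np.cumsum(pmf)
    m = ks_arr.size

    def _stat(sample: np.ndarray) -> float:
        # both CDFs are right-continuous steps jumping only on 1..n, so the
        # sup distance is attained on the support
        ecdf = np.cumsum(np.bincount(sample, minlength=n + 1)[1:]) / sample.size
        return float(np.abs(ecdf - cdf_grid).max())

    stat_obs = _stat(ks_arr)
    p_value = float(stats.kstwo.sf(stat_obs, m))
    p_boot = None
    if bootstrap > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        support = np.arange(1, n + 1)
        exceed = 0
        for _ in range(bootstrap):
            if _stat(rng.choice(support, size=m, p=pmf)) >= stat_obs:
                exceed += 1
        p_boot = (exceed + 1) / (bootstrap + 1)
    return NeutralityReport(
        test=NeutralityTestKind.ALLELE_COUNT_KS,
        statistic=stat_obs,
        p_value=min(1.0, p_value),
        n_runs=int(m),
        theta_used=float(theta),
        p_value_bootstrap=p_boot,
    )


def singleton_test(
    singletons: Sequence[int],
    ks: Sequence[int],
    n: int,
) -> NeutralityReport:
    """Two-sample Wilcoxon rank-sum test of singleton counts.

    The semi-empirical null sample consists of the conditional expectations
    E(A_1 | k_i, n) evaluated at each run's observed allele count k_i (kept
    un-rounded); the alternative sample is the observed singleton counts.
    The two-sided rank-sum test is sensitive to differences in central
    tendency, less so to shape.
    """
    s = np.asarray(singletons, dtype=float)
    k = np.asarray(ks, dtype=np.int64)
    if s.shape != k.shape:
        raise ValueError("singletons and ks must have equal length")
    if s.size == 0:
        raise ValueError("empty ensemble")
    expected = np.array([conditional_mean_spectrum(n, int(ki))[0] for ki in k])
    res = stats.mannwhitneyu(s, expected, alternative="two-sided")
    return NeutralityReport(
        test=NeutralityTestKind.SINGLETON_WILCOXON,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_runs=int(s.size),
    )


def allele_summary(state: PopulationState) -> AlleleSample:
    """Allele-size configuration of a population under the IAM.

    Every live clone is one allele; ``a_j`` counts live clones with exactly
    j cells.
    """
    live = state.live[: state.n_clones]
    sizes = live[live > 0]
    a = np.bincount(sizes, minlength=state.N + 1)[1:]
    return AlleleSample(n=state.N, k=int(len(sizes)), a=a)
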