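"""Expected site frequency spectra under comparison models.

Four families of theoretical spectra are provided for overlaying on
observed tails:

* the general coalescent expectation of Griffiths and Tavaré, which takes
  the expected coalescence times ``E[T_j]`` of the demography as input;
* the large-population exponential-growth approximations of Durrett,
  ``E S_n(k) = theta*n / (r*k*(k-1))`` for k >= 2 plus a singleton term;
* a multiclone model of neutral evolution punctuated by selective sweeps,
  whose expected spectrum is a neutral 1/(k(k-1)) tail plus one binomial
  "hump" per derived clone;
* the power-law spectrum ``c * f**-alpha`` with ``alpha = lambda0/lambda1``
  arising from a two-type supercritical birth-death model.

All binomial coefficients are evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CloneHierarchy",
    "HumpSFS",
    "gt_expected_sfs",
    "durrett_sfs",
    "multiclone_sfs",
    "power_law_tail",
    "coalescent_ET_exponential",
]


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def gt_expected_sfs(n: int, theta: float, ET: Sequence[float]) -> np.ndarray:
    """Coalescent expected SFS for an arbitrary demography.

    E S_n(k) = theta * sum_{j=2}^{n-k+1} j * p_nj(k) * E[T_j],
    p_nj(k) = C(n-k-1, j-2) / C(n-1, j-1),

    where ``E[T_j]`` is the expected total time during which the genealogy
    of the sample has exactly j lineages.

    Parameters
    ----------
    n
        Sample size (>= 2).
    theta
        Mutation rate on the coalescent time scale.
    ET
        Expected coalescence times (E[T_2], ..., E[T_n]); length n-1.

    Returns
    -------
    Array of expected counts for k = 1..n-1 (index k-1).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ET = np.asarray(ET, dtype=float)
    if ET.shape != (n - 1,):
        raise ValueError(f"ET must have length n-1={n - 1}, got {ET.shape}")
    if np.any(ET <= 0):
        raise ValueError("coalescence-time expectations must be positive")
    out = np.zeros(n - 1)
    for k in range(1, n):
        j = np.arange(2, n - k + 2)
        log_p = _log_binom(n - k - 1, j - 2) - _log_binom(n - 1, j - 1)
        out[k - 1] = theta * float(np.sum(j * np.exp(log_p) * ET[j - 2]))
    return out


def durrett_sfs(
    n: int, theta: float, r: float, N_pop: float | None = None
) -> np.ndarray:
    """Exponential-growth approximation of the expected SFS.

    E S_n(k) ~ theta*n / (r*k*(k-1)) for k = 2..n-1, with the singleton
    term E S_n(1) ~ theta*n*ln(r*N_pop)/r available only when the present
    population size ``N_pop`` is supplied (it is set to NaN otherwise).

    The non-singleton total is (n*theta/r) * (1 - 1/(n-1)).
    """
    if r <= 0:
        raise ValueError("growth rate r must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    k = np.arange(1, n)
    out = np.empty(n - 1)
    out[1:] = theta * n / (r * k[1:] * (k[1:] - 1.0))
    if N_pop is not None:
        if r * N_pop <= 1:
            raise ValueError("singleton term requires r*N_pop > 1")
        out[0] = theta * n * np.log(r * N_pop) / r
    else:
        out[0] = np.nan
    return out


@dataclass
class CloneHierarchy:
    """Clonal hierarchy for the multiclone sweep model.

    Clone i (1 <= i <= m) branches off its parent clone j_i < i at time
    ``t[i-1]``; clone 0 is ancestral.  ``t`` has length m+1 with the last
    entry the diagnosis time at which the tumor of size N is sampled.
    ``B`` is the (m+1)x(m+1) 0/1 matrix whose i-th row marks column j_i;
    row 0 is all zeros.  ``theta[i]`` and ``r[i]`` are the per-clone
    mutation and exponential growth rates.
    """

    B: np.ndarray
    t: np.ndarray
    theta: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        m1 = self.B.shape[0]
        if self.B.shape != (m1, m1):
            raise ValueError("hierarchy matrix must be square")
        if np.any(self.B[0] != 0):
            raise ValueError("row 0 of the hierarchy matrix must be zero")
        for i in range(1, m1):
            if self.B[i].sum() != 1:
                raise ValueError(f"row {i} must contain exactly one 1")
            if int(np.argmax(self.B[i])) >= i:
                raise ValueError(f"clone {i} must branch from an earlier clone")
        if self.t.shape != (m1,):
            raise ValueError("t must have length m+1 (branch times + diagnosis)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("branch times must be strictly increasing")
        if self.theta.shape != (m1 - 1 + 1,) or self.r.shape != (m1,):
            # theta and r are per clone 0..m
            raise ValueError("theta and r must have one entry per clone")

    @property
    def m(self) -> int:
        return self.B.shape[0] - 1

    def parents(self) -> np.ndarray:
        """j_i for i = 1..m (j_0 := 0)."""
        return np.array([0] + [int(np.argmax(self.B[i])) for i in range(1, self.m + 1)])

    def branch_times(self) -> np.ndarray:
        """t_0 = 0 together with t_1..t_m (diagnosis time excluded)."""
        return np.concatenate([[0.0], self.t[:-1]])

    def clone_fractions(self) -> np.ndarray:
        """p_i = exp(r_i*(t_diag - t_i)) / sum_l exp(r_l*(t_diag - t_l)).

        Each clone starts from a single cell at its branch time and grows
        exponentially until diagnosis.
        """
        t_diag = self.t[-1]
        sizes = np.exp(self.r * (t_diag - self.branch_times()))
        return sizes / sizes.sum()

    def ancestral_mutation_counts(self) -> np.ndarray:
        """K_i = theta_{j_i} * (t_i - t_{j_i}), i = 1..m (expected-value sense).

        The lineage founding clone i accumulated neutral mutations in its
        parent clone j_i between the parent's birth and t_i; those K_i
        mutations mark every cell of clone i and its descendants.
        """
        par = self.parents()
        tb = self.branch_times()
        return np.array(
            [self.theta[par[i]] * (tb[i] - tb[par[i]]) for i in range(1, self.m + 1)]
        )

    def hump_centroids(self) -> np.ndarray:
        """P_i = fraction of cells in clone i and all its descendants.

        The K_i marker mutations are carried by the whole clade rooted at
        clone i, so the binomial hump they generate is centred at the
        clade's cell fraction.
        """
        p = self.clone_fractions()
        par = self.parents()
        m = self.m
        clade = p.copy()
        for i in range(m, 0, -1):  # children have larger indices than parents
            clade[par[i]] += clade[i]
        return clade[1:]


@dataclass
class HumpSFS:
    """Expected multiclone spectrum: neutral tail plus binomial humps."""

    n: int
    A_total: float
    K: np.ndarray
    P: np.ndarray
    Q: np.ndarray  # expected counts for k = 2..n-1

    def k_values(self) -> np.ndarray:
        return np.arange(2, self.n)


def multiclone_sfs(
    n: int,
    hierarchy: CloneHierarchy | None = None,
    *,
    A: float | Sequence[float] | None = None,
    K: Sequence[float] | None = None,
    P: Sequence[float] | None = None,
    fractions: Sequence[float] | None = None,
) -> HumpSFS:
    """Expected SFS of the multiclone sweep model, k = 2..n-1.

    Q_n(k) = sum_i p_i*A_i / (k*(k-1))
             + sum_i K_i * C(n,k) * (1-P_i)**(n-k) * P_i**k

    In *hierarchy mode* the clone fractions p_i, marker counts K_i and hump
    centroids P_i are derived from the branching structure, with
    A_i = n*theta_i/r_i the per-clone neutral area.  In *direct mode* the
    caller supplies either the aggregate neutral area ``A`` (scalar; the
    p_i-weighted sum) or per-clone areas with ``fractions``, together with
    ``K`` and ``P`` per derived clone.
    """
    if n < 3:
        raise ValueError("n must be >= 3 for a non-trivial spectrum")
    if hierarchy is not None:
        p = hierarchy.clone_fractions()
        A_i = n * hierarchy.theta / hierarchy.r
        A_total = float(np.sum(p * A_i))
        K_arr = hierarchy.ancestral_mutation_counts()
        P_arr = hierarchy.hump_centroids()
    else:
        if A is None:
            raise ValueError("direct mode needs the neutral area A")
        A_vec = np.atleast_1d(np.asarray(A, dtype=float))
        if A_vec.size == 1:
            A_total = float(A_vec[0])
        else:
            if fractions is None:
                raise ValueError("per-clone areas need clone fractions")
            frac = np.asarray(fractions, dtype=float)
            if frac.shape != A_vec.shape:
                raise ValueError("fractions and A must align")
            if abs(frac.sum() - 1.0) > 1e-9:
                raise ValueError("clone fractions must sum to 1")
            A_total = float(np.sum(frac * A_vec))
        K_arr = np.asarray([] if K is None else K, dtype=float)
        P_arr = np.asarray([] if P is None else P, dtype=float)
    if K_arr.shape != P_arr.shape:
        raise ValueError("K and P must have one entry per derived clone")
    if np.any(K_arr < 0):
        raise ValueError("ancestral mutation counts must be >= 0")
    if K_arr.size and not np.all((P_arr > 0) & (P_arr < 1)):
        raise ValueError("hump centroids must lie in (0, 1)")

    k = np.arange(2, n)
    Q = A_total / (k * (k - 1.0))
    for Ki, Pi in zip(K_arr, P_arr):
        log_hump = (
            _log_binom(n, k) + (n - k) * np.log1p(-Pi) + k * np.log(Pi)
        )
        Q = Q + Ki * np.exp(log_hump)
    return HumpSFS(n=n, A_total=A_total, K=K_arr, P=P_arr, Q=Q)


def power_law_tail(
    c: float,
    lambda0: float,
    lambda1: float,
    grid: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law SFS density ``c*f**-alpha`` and its analytic cumulative tail.

    ``alpha = lambda0 / lambda1`` where lambda0 < lambda1 are the net
    growth rates of the ancestral and the fitter derived type of a two-type
    birth-death process; the advantageous mutations founding the derived
    type shape the spectrum into this power law.

    Returns ``(density, tail)`` on the grid, with
    tail(x) = integral_x^1 c*f**-alpha df = c*(1 - x**(1-alpha))/(1-alpha).
    """
    if not 0 < lambda0 < lambda1:
        raise ValueError("rates must satisfy 0 < lambda0 < lambda1")
    if c <= 0:
        raise ValueError("scale c must be positive")
    alpha = lambda0 / lambda1
    x = np.asarray(grid, dtype=float)
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("grid must lie in (0, 1]")
    density = c * x ** (-alpha)
    tail = c * (1.0 - x ** (1.0 - alpha)) / (1.0 - alpha)
    return density, tail


def coalescent_ET_exponential(
    n: int,
    r: float,
    N_pop: float,
    n_reps: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Monte-Carlo expected coalescence times under exponential growth.

    For a population of present size ``N_pop`` that grew as N*exp(r*t)
    (t < 0 in the past), the coalescent rate while j lineages remain is
    j*(j-1)/(2*N(t)) with backwards time N(t) = N_pop*exp(-r*t).  Each
    inter-coalescence interval can be drawn exactly by inverting the
    cumulative hazard, so no discretisation error is involved; only
    Monte-Carlo error remains.  Returns (E[T_2], ..., E[T_n]).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ET = np.zeros(n - 1)
    for _ in range(n_reps):
        t = 0.0
        for j in range(n, 1, -1):
            rate0 = j * (j - 1) / (2.0 * N_pop)  # hazard at current time
            E = rng.exponential()
            # cumulative hazard from t to t+w is rate0*exp(r*t)*(exp(r*w)-1)/r
            w = np.log1p(r * E / (rate0 * np.exp(r * t))) / r
            ET[j - 2] += w
            t += w
    return ET / n_reps
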