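"""Canned simulation-study workflows over ensembles of runs.

These functions bundle the recurring study designs -- martingale checks
with a mutation-free heterogeneous start, clone-count ensembles at the
driver/passenger equilibrium, neutral ensembles for Ewens-formula testing,
and mean cumulative SFS tails for model comparison -- so that analysis
scripts and tests share one implementation.  All of them are deterministic
given the seed.
"""

from __future__ import annotations

import numpy as np

from .population import ModelParams, carrier_counts
from .simulator import init_exponential_draw, run
from .neutrality import allele_summary
from .spectra import cumulative_tail

__all__ = [
    "spawn_rngs",
    "martingale_ratio",
    "clone_total_ensemble",
    "neutral_allele_ensemble",
    "mean_sfs_tail",
]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def martingale_ratio(
    variant: str = "A",
    n_runs: int = 100,
    N: int = 100,
    s: float = 0.01,
    d: float = 0.01,
    p: float = 0.5,
    t_max: float = 100.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean-final over mean-initial population fitness, with its SE.

    Runs ``n_runs`` mutation-free simulations from the exponential-draw
    heterogeneous start (per-cell driver/passenger counts with means 10p
    and 10(1-p), rounded) and returns the ratio of across-run means of
    population-average fitness at ``t_max`` vs. time 0, plus a
    delta-method standard error.  Under Model A the death-replacement
    process preserves expected fitness, so the ratio is 1 up to Monte-Carlo
    noise; under Model B it exceeds 1.
    """
    init_f, final_f = [], []
    for rng in spawn_rngs(seed, n_runs):
        params = ModelParams(
            N=N, mu=0.0, p=p, s=s, d=d, variant=variant, t_max=t_max
        )
        state = init_exponential_draw(params, rng)
        init_f.append(state.mean_fitness)
        final_f.append(run(params, init=state, rng=rng).final_state.mean_fitness)
    init_f, final_f = np.asarray(init_f), np.asarray(final_f)
    ratio = final_f.mean() / init_f.mean()
    # delta method on the ratio of two (correlated) means
    n = len(init_f)
    cov = np.cov(final_f, init_f)
    var = (
        cov[0, 0] / init_f.mean() ** 2
        + cov[1, 1] * final_f.mean() ** 2 / init_f.mean() ** 4
        - 2 * cov[0, 1] * final_f.mean() / init_f.mean() ** 3
    ) / n
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def clone_total_ensemble(
    variant: str,
    n_runs: int = 50,
    N: int = 100,
    mu: float = 0.1,
    p: float = 0.0909,
    s: float = 0.1,
    d: float = 0.01,
    t_max: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Clone totals (root included) over replicate runs at the given setting.

    The defaults are the driver/passenger equilibrium ``s*p = d*(1-p)``;
    since every mutation event founds one clone, the total is
    1 + Poisson(N*mu*t) regardless of variant.
    """
    totals = []
    for rng in spawn_rngs(seed, n_runs):
        params = ModelParams(
            N=N, mu=mu, p=p, s=s, d=d, variant=variant, t_max=t_max
        )
        totals.append(run(params, rng=rng).clone_total)
    return np.asarray(totals)


def neutral_allele_ensemble(
    variant: str,
    n_runs: int = 200,
    N: int = 100,
    mu: float = 0.1,
    p: float = 0.5,
    t_max: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts k and singleton counts from a strictly neutral ensemble.

    Runs the tug-of-war with ``s = d = 0`` (mutations present but fitness-
    neutral) and summarises each final population under the infinite-allele
    model.  Returns ``(ks, singletons)`` for the two Ewens-formula tests.
    """
    ks, singles = [], []
    for rng in spawn_rngs(seed, n_runs):
        params = ModelParams(
            N=N, mu=mu, p=p, s=0.0, d=0.0, variant=variant, t_max=t_max
        )
        sample = allele_summary(run(params, rng=rng).final_state)
        ks.append(sample.k)
        singles.append(sample.singletons)
    return np.asarray(ks), np.asarray(singles)


def mean_sfs_tail(
    variant: str,
    n_runs: int = 20,
    N: int = 200,
    L: float = 6.0,
    p: float = 0.01,
    s: float = 0.5,
    d: float = 0.0001,
    t_max: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-run mean normalized cumulative SFS tail on the grid k/N.

    Each run's SFS is taken from the final population (extinct and fixed
    mutations dropped); runs with no segregating sites are skipped.  ``L``
    is the population-scaled mutation rate N*mu.
    """
    grid = np.arange(1, N) / N
    tails = []
    for rng in spawn_rngs(seed, n_runs):
        params = ModelParams(
            N=N, mu=L / N, p=p, s=s, d=d, variant=variant, t_max=t_max
        )
        state = run(params, rng=rng).final_state
        freqs = np.array(
            [v / N for v in carrier_counts(state).values() if 0 < v < N]
        )
        if freqs.size == 0:
            continue
        tails.append(cumulative_tail(freqs, grid=grid).T)
    if not tails:
        raise RuntimeError("no run produced segregating sites")
    return grid, np.mean(tails, axis=0)
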