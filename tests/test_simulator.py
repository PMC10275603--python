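"""Event-driven simulation: rates, laws of the event process, recorders."""

import numpy as np
import pytest
from scipy import stats

from tugwar import (
    ModelParams,
    SimulationCapError,
    genealogy_newick,
    genealogy_table,
    init_exponential_draw,
    init_homogeneous,
    run,
    step,
    succession_by_driver,
)


def test_init_homogeneous_sigma():
    for N in (1, 100):
        state = init_homogeneous(ModelParams(N=N, mu=0.1))
        assert state.sigma_P == pytest.approx(N)
        assert state.mean_fitness == pytest.approx(1.0)


def test_init_exponential_draw_means(rng):
    # sample mean of alpha over 10^4 cells ~ 10*p = 5 within MC error
    params = ModelParams(N=10_000, mu=0.0, p=0.5, s=0.0, d=0.0)
    state = init_exponential_draw(params, rng)
    n = state.n_clones
    alpha_mean = float((state.alpha[:n] * state.live[:n]).sum()) / params.N
    beta_mean = float((state.beta[:n] * state.live[:n]).sum()) / params.N
    # mean of round(Exp(mean 5)) is ~5 + O(rounding); se ~ 5/100
    assert alpha_mean == pytest.approx(5.0, abs=0.2)
    assert beta_mean == pytest.approx(5.0, abs=0.2)
    assert int(state.live[:n].sum()) == params.N


def test_init_exponential_draw_merges_identical_pairs(rng):
    params = ModelParams(N=1000, mu=0.0, p=0.5)
    state = init_exponential_draw(params, rng)
    n = state.n_clones
    pairs = {(int(state.alpha[i]), int(state.beta[i])) for i in range(n)}
    assert len(pairs) == n  # one clone per distinct (alpha, beta)
    assert n < params.N  # collisions must have been merged


def test_init_exponential_zero_scale_limit(rng):
    params = ModelParams(N=50, mu=0.0, p=0.5)
    state = init_exponential_draw(params, rng, scale_driver=0.0, scale_passenger=0.0)
    assert state.n_clones == 1
    assert state.mean_fitness == pytest.approx(1.0)


def test_no_mutation_composition_constant(rng):
    # mu = 0, single clone: composition never changes, only self-replacements
    params = ModelParams(N=20, mu=0.0, s=0.3, t_max=5.0)
    state = init_homogeneous(params)
    for _ in range(200):
        step(state, params, rng)
    assert state.n_clones == 1
    assert int(state.live[0]) == 20


def test_interevent_times_exponential_at_total_rate(rng):
    # N=100, all fitness 1, mu=0.1: total rate = 100 + 10 = 110
    params = ModelParams(N=100, mu=0.1, p=0.5, t_max=1e9)
    state = init_homogeneous(params)
    times = []
    prev = 0.0
    for _ in range(4000):
        # keep the population homogeneous so the rate stays 110
        state.live[: state.n_clones] = 0
        state.live[0] = 100
        state.recompute_sigma()
        step(state, params, rng)
        times.append(state.time - prev)
        prev = state.time
    lam_hat = 1.0 / np.mean(times)
    assert lam_hat == pytest.approx(110, rel=0.05)
    # KS against Exp(110)
    p = stats.kstest(times, "expon", args=(0, 1 / 110)).pvalue
    assert p > 0.01


def test_mutation_type_fraction_matches_p(rng):
    params = ModelParams(N=50, mu=1.0, p=0.1, t_max=50.0)
    result = run(params, rng=rng)
    _, drivers, passengers = result.event_counts
    total = drivers + passengers
    assert total > 1000
    assert drivers / total == pytest.approx(0.1, abs=3 * np.sqrt(0.09 / total))


def test_clone_total_accounting(rng):
    params = ModelParams(N=50, mu=0.5, p=0.3, s=0.1, d=0.01, t_max=20.0)
    result = run(params, rng=rng)
    dr, drivers, passengers = result.event_counts
    assert result.clone_total == 1 + drivers + passengers
    assert result.final_state.n_clones == result.clone_total


def test_mutation_count_poisson_law():
    """Mutations over [0, t] are Poisson(N*mu*t): chi-square GOF at 1%."""
    N, mu, t = 20, 0.5, 5.0
    lam = N * mu * t  # 50
    counts = []
    for ss in np.random.SeedSequence(77).spawn(500):
        params = ModelParams(N=N, mu=mu, p=0.5, t_max=t)
        result = run(params, rng=np.random.default_rng(ss))
        counts.append(result.n_mutations)
    counts = np.asarray(counts)
    assert counts.mean() == pytest.approx(lam, rel=0.05)
    # bin the Poisson support so every expected count is >= 5
    edges = stats.poisson.ppf(np.linspace(0.0, 1.0, 11), lam)
    edges[0], edges[-1] = -0.5, np.inf
    obs, _ = np.histogram(counts, bins=edges)
    cdf = stats.poisson.cdf(edges[1:], lam)
    cdf_lo = stats.poisson.cdf(edges[:-1], lam)
    cdf_lo[0] = 0.0
    expected = (cdf - cdf_lo) * len(counts)
    expected[-1] = len(counts) - expected[:-1].sum()
    chi2 = ((obs - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=len(obs) - 1)
    assert p > 0.01


def test_trajectory_trivial_when_neutral_and_mutationless(rng):
    params = ModelParams(N=30, mu=0.0, s=0.0, d=0.0, t_max=10.0)
    result = run(params, rng=rng)
    assert all(f == pytest.approx(1.0) for _, f in result.fitness_trajectory)
    assert result.fitness_trajectory[0][0] == 0.0
    assert result.fitness_trajectory[-1][0] == 10.0


def test_determinism_same_seed():
    params = ModelParams(N=40, mu=0.2, p=0.3, s=0.2, d=0.05, t_max=15.0, seed=123)
    r1 = run(params)
    r2 = run(params)
    assert r1.clone_total == r2.clone_total
    assert r1.event_counts == r2.event_counts
    assert r1.fitness_trajectory == r2.fitness_trajectory
    np.testing.assert_array_equal(
        r1.final_state.live[: r1.final_state.n_clones],
        r2.final_state.live[: r2.final_state.n_clones],
    )


def test_event_cap_raises_with_partial_result(rng):
    params = ModelParams(N=50, mu=0.5, p=0.5, t_max=100.0, max_events=500)
    with pytest.raises(SimulationCapError) as exc:
        run(params, rng=rng)
    partial = exc.value.partial_result
    assert partial is not None and not partial.completed
    assert partial.final_state.n_events == 500


def test_model_a_martingale_under_drift():
    """With mu=0 and heterogeneous start, Model A mean fitness is a martingale."""
    init_means, final_means = [], []
    for ss in np.random.SeedSequence(5).spawn(200):
        rng = np.random.default_rng(ss)
        params = ModelParams(N=100, mu=0.0, p=0.5, s=0.05, d=0.05,
                             variant="A", t_max=20.0)
        state = init_exponential_draw(params, rng)
        init_means.append(state.mean_fitness)
        result = run(params, init=state, rng=rng)
        final_means.append(result.final_state.mean_fitness)
    diff = np.asarray(final_means) - np.asarray(init_means)
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * se + 1e-12


def test_model_b_drift_increases_fitness():
    """With mu=0 and heterogeneous start, Model B mean fitness drifts upward."""
    init_means, final_means = [], []
    for ss in np.random.SeedSequence(6).spawn(200):
        rng = np.random.default_rng(ss)
        params = ModelParams(N=100, mu=0.0, p=0.5, s=0.05, d=0.05,
                             variant="B", t_max=20.0)
        state = init_exponential_draw(params, rng)
        init_means.append(state.mean_fitness)
        result = run(params, init=state, rng=rng)
        final_means.append(result.final_state.mean_fitness)
    assert np.mean(final_means) > np.mean(init_means)


def test_equilibrium_no_fitness_trend():
    """sp = d(1-p): Model A fitness trend has slope 0 within MC error."""
    finals = []
    for ss in np.random.SeedSequence(8).spawn(100):
        params = ModelParams(N=100, mu=0.1, p=0.0909, s=0.1, d=0.01,
                             variant="A", t_max=30.0)
        result = run(params, rng=np.random.default_rng(ss))
        finals.append(result.final_state.mean_fitness)
    finals = np.asarray(finals)
    se = finals.std(ddof=1) / np.sqrt(len(finals))
    assert abs(finals.mean() - 1.0) < 3 * se


class TestSuccession:
    def test_no_drivers_single_group(self, rng):
        params = ModelParams(N=30, mu=0.2, p=1e-9, d=0.1, t_max=10.0)
        result = run(params, rng=rng, record_snapshots=True)
        groups = succession_by_driver(result)
        for _, entry in groups:
            assert list(entry) == [-1]
            frac, _ = entry[-1]
            assert frac == pytest.approx(1.0)

    def test_driver_clade_fractions_and_weighted_fitness(self):
        from conftest import build_state
        from tugwar.simulator import RunResult

        # two driver clades of 30/70 cells; the 70-clade has two equally
        # sized passenger subclones with fitnesses 1.1*0.99 and 1.1*0.99^2
        s, d = 0.1, 0.01
        state = build_state(
            100,
            [
                (None, 0, 0, "root", 1.0, 0),
                (0, 1, 0, "driver", 1.1, 30),
                (0, 1, 0, "driver", 1.1, 0),
                (2, 1, 1, "passenger", 1.1 * 0.99, 35),
                (3, 1, 2, "passenger", 1.1 * 0.99**2, 35),
            ],
        )
        result = RunResult(
            params=ModelParams(N=100, mu=0.1, s=s, d=d),
            final_state=state,
            fitness_trajectory=[],
            succession_snapshots=[(0.0, state.live_counts())],
            clone_total=5,
            event_counts=(0, 2, 2),
        )
        (_, entry), = succession_by_driver(result)
        assert entry[1][0] == pytest.approx(0.3)
        assert entry[2][0] == pytest.approx(0.7)
        assert entry[2][1] == pytest.approx(1.1 * 0.99 * (1 + 0.99) / 2)
        assert sum(frac for frac, _ in entry.values()) == pytest.approx(1.0)


def test_genealogy_exports(rng):
    params = ModelParams(N=20, mu=0.3, p=0.3, s=0.1, d=0.01, t_max=10.0)
    result = run(params, rng=rng)
    state = result.final_state
    table = genealogy_table(state)
    assert len(table) == state.n_clones
    assert int(table["live_cells_at_end"].sum()) == 20
    nwk = genealogy_newick(state)
    assert nwk.endswith(";")
    # round-trip through a standard parser: every clone id appears once
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    labels = {c.name for c in tree.find_clades() if c.name is not None}
    assert str(state.n_clones - 1) in labels
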