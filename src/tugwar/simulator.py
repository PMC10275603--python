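"""Event-driven simulation of the tug-of-war Moran models.

Both model variants are time-continuous Markov chains over a constant
population of N cells.  Two event types compete:

* **death-replacement**, at total rate ``sigma_P`` (the summed fitness of
  all live cells): one cell dies and is replaced by a copy of another
  (possibly the same) cell.  Model A draws the dying cell proportionally to
  fitness, Model B uniformly; both draw the replacing cell proportionally
  to fitness.
* **mutation**, at total rate ``N * mu``: a uniformly chosen cell acquires
  one new mutation -- a driver with probability ``p``, else a passenger --
  and founds a new clone.

The competing exponential clocks are realised as a single exponential draw
at the total rate ``sigma_P + N*mu`` followed by a categorical choice of
event type, which is distributionally identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .population import (
    SIGMA_RECOMPUTE_EVERY,
    ModelParams,
    ModelVariant,
    OriginKind,
    PopulationState,
)

__all__ = [
    "RunResult",
    "SimulationCapError",
    "init_homogeneous",
    "init_exponential_draw",
    "step",
    "run",
    "succession_by_driver",
    "genealogy_table",
    "genealogy_newick",
]


class SimulationCapError(RuntimeError):
    """Raised when a run exceeds ``max_events`` (memory/time guard).

    The partially completed result is attached as ``partial_result``.
    """

    def __init__(self, message: str, partial_result: "RunResult | None" = None):
        super().__init__(message)
        self.partial_result = partial_result


@dataclass
class RunResult:
    """Everything recorded from one simulation run."""

    params: ModelParams
    final_state: PopulationState
    #: (time, population-average fitness) sampled on the recording grid
    fitness_trajectory: list[tuple[float, float]]
    #: (time, live cell count per clone id) on the recording grid
    succession_snapshots: list[tuple[float, np.ndarray]]
    #: clones ever created, root(s) included
    clone_total: int
    #: (death_replacement, mutation_driver, mutation_passenger)
    event_counts: tuple[int, int, int]
    completed: bool = True

    @property
    def n_mutations(self) -> int:
        return self.event_counts[1] + self.event_counts[2]


def init_homogeneous(params: ModelParams, *, log_events: bool = False) -> PopulationState:
    """All N cells in one founding clone with no mutations (fitness 1)."""
    state = PopulationState(params.N, log_events=log_events)
    state.add_clone(None, 0, 0, OriginKind.ROOT, 1.0, params.N, birth_time=0.0)
    return state


def init_exponential_draw(
    params: ModelParams,
    rng: np.random.Generator,
    scale_driver: float | None = None,
    scale_passenger: float | None = None,
    *,
    rate_parametrization: bool = False,
    log_events: bool = False,
) -> PopulationState:
    """Heterogeneous start: standing driver/passenger counts per cell.

    Each of the N cells independently draws ``alpha`` and ``beta`` from
    exponential distributions with means ``10*p`` and ``10*(1-p)`` (the
    defaults), rounded half-up to the nearest integer.  Cells with identical
    (alpha, beta) are merged into one founding clone.  With
    ``rate_parametrization=True`` the scales are instead interpreted as
    rates (means ``1/scale``).

    The founding clones all have origin kind ``root``: their standing
    mutations predate the genealogy and are not tracked as sites.
    """
    if scale_driver is None:
        scale_driver = 10.0 * params.p
    if scale_passenger is None:
        scale_passenger = 10.0 * (1.0 - params.p)
    if scale_driver < 0 or scale_passenger < 0:
        raise ValueError("exponential scales must be non-negative")
    if rate_parametrization:
        scale_driver = 1.0 / scale_driver if scale_driver > 0 else 0.0
        scale_passenger = 1.0 / scale_passenger if scale_passenger > 0 else 0.0

    def _draw(scale: float) -> np.ndarray:
        if scale == 0:
            return np.zeros(params.N, dtype=np.int64)
        # round half-up: floor(x + 0.5)
        return np.floor(rng.exponential(scale, size=params.N) + 0.5).astype(np.int64)

    alphas = _draw(scale_driver)
    betas = _draw(scale_passenger)
    state = PopulationState(params.N, log_events=log_events)
    pairs, counts = np.unique(np.column_stack([alphas, betas]), axis=0, return_counts=True)
    for (a, b), c in zip(pairs, counts):
        fit = (1.0 + params.s) ** a * (1.0 - params.d) ** b
        state.add_clone(None, int(a), int(b), OriginKind.ROOT, fit, int(c), birth_time=0.0)
    return state


def _sample_index(cumw: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportionally to the weights whose cumsum is given."""
    x = rng.random() * cumw[-1]
    i = int(np.searchsorted(cumw, x, side="right"))
    return min(i, len(cumw) - 1)


def step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    counts: list[int] | None = None,
    t_max: float | None = None,
) -> PopulationState:
    """Advance the population by exactly one event, in place.

    Time advances by an Exp(sigma_P + N*mu) draw; with probability
    ``sigma_P / (sigma_P + N*mu)`` a death-replacement is applied, otherwise
    a mutation founds a new clone.  ``counts``, when given, is a 3-slot
    accumulator [death_replacement, driver, passenger].

    When ``t_max`` is given and the drawn waiting time crosses it, the event
    is censored: time is set to ``t_max`` and the composition is left
    untouched (by memorylessness this realises the process exactly on
    [0, t_max]).
    """
    n = state.n_clones
    sigma = state.sigma_P
    if sigma <= 0:
        raise ValueError("total fitness must be positive")
    mut_rate = params.N * params.mu
    total_rate = sigma + mut_rate

    new_time = state.time + rng.exponential(1.0 / total_rate)
    if t_max is not None and new_time > t_max:
        state.time = t_max
        return state
    state.time = new_time
    state.n_events += 1
    if state.n_events % SIGMA_RECOMPUTE_EVERY == 0:
        sigma = state.recompute_sigma()

    if rng.random() * total_rate < sigma:
        # death-replacement
        cum_w = np.cumsum(state._w[:n])
        if params.variant is ModelVariant.A:
            dying = _sample_index(cum_w, rng)
        else:
            cum_live = np.cumsum(state.live[:n])
            dying = _sample_index(cum_live, rng)
        replacing = _sample_index(cum_w, rng)
        state._move_cell(dying, replacing)
        if counts is not None:
            counts[0] += 1
        state.log("death_replacement", dying, replacing)
    else:
        # mutation of a uniformly chosen cell
        cum_live = np.cumsum(state.live[:n])
        parent = _sample_index(cum_live, rng)
        if rng.random() < params.p:
            kind = OriginKind.DRIVER
            a, b = state.alpha[parent] + 1, state.beta[parent]
            fit = state.fitness[parent] * (1.0 + params.s)
            if counts is not None:
                counts[1] += 1
        else:
            kind = OriginKind.PASSENGER
            a, b = state.alpha[parent], state.beta[parent] + 1
            fit = state.fitness[parent] * (1.0 - params.d)
            if counts is not None:
                counts[2] += 1
        state.live[parent] -= 1
        state._w[parent] -= state.fitness[parent]
        state._sigma -= state.fitness[parent]
        child = state.add_clone(parent, int(a), int(b), kind, float(fit), 1)
        state.log("mutation", parent, child)
    return state


def run(
    params: ModelParams,
    init: PopulationState | str = "homogeneous",
    record_grid: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    *,
    record_snapshots: bool = False,
) -> RunResult:
    """Simulate until ``time >= t_max`` and collect recorders.

    Parameters
    ----------
    init
        A prepared :class:`PopulationState`, or ``"homogeneous"`` /
        ``"expdraw"`` to build one (the latter needs the run's rng, so the
        draw is part of the seeded stream).
    record_grid
        Times at which the population-average fitness (and, optionally,
        clone-composition snapshots) are recorded by carrying the last
        state forward; defaults to integer times ``0..t_max``.
    rng
        Source of randomness; defaults to ``default_rng(params.seed)``.

    Raises
    ------
    SimulationCapError
        If more than ``params.max_events`` events occur; the partial result
        is attached to the exception.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if isinstance(init, str):
        if init == "homogeneous":
            state = init_homogeneous(params)
        elif init == "expdraw":
            state = init_exponential_draw(params, rng)
        else:
            raise ValueError(f"unknown init spec {init!r}")
    else:
        state = init
    if record_grid is None:
        record_grid = np.arange(0.0, params.t_max + 0.5)
    grid = np.asarray(record_grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > params.t_max):
        raise ValueError("record_grid must lie within [0, t_max]")

    counts = [0, 0, 0]
    trajectory: list[tuple[float, float]] = []
    snapshots: list[tuple[float, np.ndarray]] = []
    gi = 0

    def _record_until(t: float) -> None:
        nonlocal gi
        while gi < grid.size and grid[gi] <= t:
            trajectory.append((float(grid[gi]), state.mean_fitness))
            if record_snapshots:
                snapshots.append((float(grid[gi]), state.live_counts()))
            gi += 1

    _record_until(state.time)
    while state.time < params.t_max:
        if state.n_events >= params.max_events:
            partial = RunResult(
                params, state, trajectory, snapshots,
                state.n_clones, tuple(counts), completed=False,
            )
            raise SimulationCapError(
                f"event cap {params.max_events} exceeded at t={state.time:.3f}",
                partial,
            )
        step(state, params, rng, counts, t_max=params.t_max)
        _record_until(state.time)
    state.recompute_sigma()
    return RunResult(
        params, state, trajectory, snapshots, state.n_clones, tuple(counts)
    )


def _driver_group(state: PopulationState) -> np.ndarray:
    """Most recent driver-origin ancestor (inclusive) of each clone.

    Driver sets along a root path are nested, so the nearest driver ancestor
    identifies the full driver haplotype.  Clones with no driver ancestor
    map to -1 (the ancestral, driver-free group).
    """
    n = state.n_clones
    group = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if state.origin[i] == OriginKind.DRIVER:
            group[i] = i
        elif state.parent[i] >= 0:
            group[i] = group[state.parent[i]]
    return group


def succession_by_driver(
    result: RunResult,
) -> list[tuple[float, dict[int, tuple[float, float]]]]:
    """Group clone-composition snapshots by driver haplotype.

    For every recorded snapshot, clones are grouped by the set of driver
    mutations on their root path (keyed by the id of the most recent
    driver-origin ancestor; -1 for the driver-free group).  Each group maps
    to ``(cell fraction, mean fitness)`` where the mean is cell-weighted
    across the passenger subclones sharing that driver haplotype.
    Fractions sum to 1 in every snapshot.
    """
    if not result.succession_snapshots:
        raise ValueError("run() was not asked to record snapshots")
    state = result.final_state
    group = _driver_group(state)
    fitness = state.fitness[: state.n_clones]
    out: list[tuple[float, dict[int, tuple[float, float]]]] = []
    for t, live in result.succession_snapshots:
        m = len(live)
        g = group[:m]
        alive = live > 0
        keys = np.unique(g[alive])
        entry: dict[int, tuple[float, float]] = {}
        for key in keys:
            sel = alive & (g == key)
            cells = int(live[sel].sum())
            meanfit = float((live[sel] * fitness[:m][sel]).sum() / cells)
            entry[int(key)] = (cells / state.N, meanfit)
        out.append((t, entry))
    return out


def genealogy_table(state: PopulationState):
    """Edge-list of the clone genealogy as a pandas DataFrame.

    Columns: child_id, parent_id (-1 for roots), origin_kind, alpha, beta,
    birth_time, live_cells_at_end.
    """
    import pandas as pd

    n = state.n_clones
    return pd.DataFrame(
        {
            "child_id": np.arange(n),
            "parent_id": state.parent[:n],
            "origin_kind": [state.origin[i].value for i in range(n)],
            "alpha": state.alpha[:n],
            "beta": state.beta[:n],
            "birth_time": state.birth_time[:n],
            "live_cells_at_end": state.live[:n],
        }
    )


def genealogy_newick(state: PopulationState) -> str:
    """Newick string of the clone genealogy with clone ids as labels.

    Branch lengths are differences of birth times.  Multiple founding
    clones are attached to a virtual root labelled ``-1``.
    """
    n = state.n_clones
    children: dict[int, list[int]] = {}
    roots: list[int] = []
    for i in range(n):
        p = int(state.parent[i])
        if p < 0:
            roots.append(i)
        else:
            children.setdefault(p, []).append(i)

    def _fmt(i: int) -> str:
        kids = children.get(i, [])
        t0 = float(state.birth_time[i])
        label = str(i)
        if not kids:
            return label
        inner = ",".join(
            f"{_fmt(k)}:{float(state.birth_time[k]) - t0:.6g}" for k in kids
        )
        return f"({inner}){label}"

    if len(roots) == 1:
        return _fmt(roots[0]) + ";"
    inner = ",".join(f"{_fmt(r)}:0" for r in roots)
    return f"({inner})-1;"
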