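"""Population state, clone genealogy and fitness bookkeeping.

The population is a constant-size (N cells) multiset over *clones*: a clone
is the set of cells sharing an identical mutation history.  Under the
infinite-allele / infinite-site convention every mutation event founds a new
clone, so non-root clones correspond 1:1 to mutations and the clones form a
rooted genealogy.  Cells are never stored individually.

A cell carrying ``alpha`` driver and ``beta`` passenger mutations has
multiplicative fitness ``(1 + s)**alpha * (1 - d)**beta`` where ``s`` is the
selective advantage per driver and ``d`` the disadvantage per passenger.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ModelVariant",
    "OriginKind",
    "ModelParams",
    "Clone",
    "PopulationState",
    "compute_fitness",
    "expected_fitness_increment",
    "death_replacement_pmfs",
    "carrier_counts",
]

#: relative tolerance to which the cached total fitness is maintained
SIGMA_RTOL = 1e-9
#: number of events between exact recomputations of the cached total fitness
SIGMA_RECOMPUTE_EVERY = 10_000


class ModelVariant(str, enum.Enum):
    """Which death-replacement rule is in force.

    ``A``: the dying cell is drawn with probability proportional to its
    fitness (fast-living cells are also fast-dying); expected fitness is a
    martingale under death-replacement alone.

    ``B``: the dying cell is drawn uniformly; death-replacement is biased
    toward fitness increase.

    In both variants the replacing cell is drawn proportionally to fitness,
    and the replacing cell may coincide with the dying cell (a no-op that
    still consumes an event).
    """

    A = "A"
    B = "B"


class OriginKind(str, enum.Enum):
    ROOT = "root"
    DRIVER = "driver"
    PASSENGER = "passenger"


def compute_fitness(alpha: int, beta: int, s: float, d: float) -> float:
    """Multiplicative fitness ``(1+s)**alpha * (1-d)**beta`` of a cell.

    Parameters
    ----------
    alpha, beta
        Non-negative driver and passenger mutation counts.
    s
        Selective advantage per driver, ``s >= 0``.
    d
        Selective disadvantage per passenger, ``0 <= d < 1``.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("mutation counts must be non-negative")
    if s < 0:
        raise ValueError(f"driver coefficient s must be >= 0, got {s}")
    if not 0 <= d < 1:
        raise ValueError(f"passenger coefficient d must be in [0, 1), got {d}")
    return (1.0 + s) ** alpha * (1.0 - d) ** beta


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a tug-of-war simulation run.

    Attributes
    ----------
    N
        Constant population size (number of cells).
    mu
        Mutation rate per cell per model time unit.
    p
        Probability that a mutation is a driver (otherwise passenger).
    s
        Driver selection coefficient; each driver multiplies fitness by 1+s.
    d
        Passenger selection coefficient; each passenger multiplies fitness
        by 1-d.
    variant
        Death-replacement rule, Model ``A`` or ``B``.
    t_max
        Simulation horizon in model time units.
    seed
        RNG seed; identical seeds give bit-identical runs.
    max_events
        Safety cap on the total number of events (the total event rate grows
        with population fitness and can explode when drivers dominate).
    """

    N: int
    mu: float
    p: float = 0.5
    s: float = 0.0
    d: float = 0.0
    variant: ModelVariant = ModelVariant.A
    t_max: float = 100.0
    seed: int | None = None
    max_events: int = 5_000_000

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.mu > 0 and not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1) when mu > 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 <= self.d < 1:
            raise ValueError("d must be in [0, 1)")
        # normalise string variants
        object.__setattr__(self, "variant", ModelVariant(self.variant))


@dataclass
class Clone:
    """One node of the clone genealogy (a read-only view of the state)."""

    id: int
    parent_id: int | None
    alpha: int
    beta: int
    origin_kind: OriginKind
    fitness: float
    live_cells: int
    birth_time: float


class PopulationState:
    """Mutable population of ``N`` cells partitioned into clones.

    Clone attributes live in parallel numpy arrays indexed by clone id (ids
    are assigned in birth order, so a child's id always exceeds its
    parent's).  The total fitness ``sigma_P`` of the N live cells -- the
    overall death-replacement rate -- is maintained incrementally and
    recomputed exactly every :data:`SIGMA_RECOMPUTE_EVERY` events.
    """

    __slots__ = (
        "N", "time", "n_clones", "n_events",
        "parent", "alpha", "beta", "origin", "birth_time",
        "fitness", "live", "_w", "_sigma", "event_log",
    )

    def __init__(self, N: int, *, capacity: int = 64, log_events: bool = False):
        if N < 1:
            raise ValueError("N must be >= 1")
        self.N = int(N)
        self.time = 0.0
        self.n_clones = 0
        self.n_events = 0
        cap = max(capacity, 4)
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.alpha = np.zeros(cap, dtype=np.int64)
        self.beta = np.zeros(cap, dtype=np.int64)
        self.origin = np.empty(cap, dtype=object)
        self.birth_time = np.zeros(cap, dtype=np.float64)
        self.fitness = np.zeros(cap, dtype=np.float64)
        self.live = np.zeros(cap, dtype=np.int64)
        self._w = np.zeros(cap, dtype=np.float64)  # live * fitness
        self._sigma = 0.0
        self.event_log: list[tuple[float, str, tuple[int, ...]]] | None = (
            [] if log_events else None
        )

    # -- construction -----------------------------------------------------

    def add_clone(
        self,
        parent_id: int | None,
        alpha: int,
        beta: int,
        origin_kind: OriginKind,
        fitness: float,
        live_cells: int,
        birth_time: float | None = None,
    ) -> int:
        """Append a clone and return its id; updates the cached total fitness."""
        i = self.n_clones
        if i == len(self.live):
            self._grow()
        self.parent[i] = -1 if parent_id is None else parent_id
        self.alpha[i] = alpha
        self.beta[i] = beta
        self.origin[i] = OriginKind(origin_kind)
        self.birth_time[i] = self.time if birth_time is None else birth_time
        self.fitness[i] = fitness
        self.live[i] = live_cells
        self._w[i] = live_cells * fitness
        self._sigma += self._w[i]
        self.n_clones += 1
        return i

    def _grow(self) -> None:
        for name in ("parent", "alpha", "beta", "origin", "birth_time",
                     "fitness", "live", "_w"):
            arr = getattr(self, name)
            new = np.empty(2 * len(arr), dtype=arr.dtype)
            new[: len(arr)] = arr
            setattr(self, name, new)

    # -- views ------------------------------------------------------------

    @property
    def sigma_P(self) -> float:
        """Total fitness of the N live cells (total death-replacement rate)."""
        return self._sigma

    def recompute_sigma(self) -> float:
        """Exact recomputation of sigma_P; bounds floating-point drift."""
        n = self.n_clones
        np.multiply(self.live[:n], self.fitness[:n], out=self._w[:n])
        self._sigma = float(self._w[:n].sum())
        return self._sigma

    @property
    def mean_fitness(self) -> float:
        """Population-average fitness, sigma_P / N."""
        return self._sigma / self.N

    def live_counts(self) -> np.ndarray:
        return self.live[: self.n_clones].copy()

    def clones(self) -> Iterator[Clone]:
        for i in range(self.n_clones):
            pid = int(self.parent[i])
            yield Clone(
                id=i,
                parent_id=None if pid < 0 else pid,
                alpha=int(self.alpha[i]),
                beta=int(self.beta[i]),
                origin_kind=self.origin[i],
                fitness=float(self.fitness[i]),
                live_cells=int(self.live[i]),
                birth_time=float(self.birth_time[i]),
            )

    def check_invariants(self) -> None:
        n = self.n_clones
        total = int(self.live[:n].sum())
        if total != self.N:
            raise AssertionError(f"live cells sum to {total}, expected N={self.N}")
        exact = float((self.live[:n] * self.fitness[:n]).sum())
        if abs(self._sigma - exact) > SIGMA_RTOL * max(exact, 1.0):
            raise AssertionError("cached sigma_P drifted beyond tolerance")

    # -- event primitives (used by the simulator) -------------------------

    def _move_cell(self, src: int, dst: int) -> None:
        """Kill one cell of clone ``src`` and add one cell to clone ``dst``."""
        if src == dst:
            return
        self.live[src] -= 1
        self.live[dst] += 1
        self._w[src] -= self.fitness[src]
        self._w[dst] += self.fitness[dst]
        self._sigma += self.fitness[dst] - self.fitness[src]

    def log(self, kind: str, *ids: int) -> None:
        if self.event_log is not None:
            self.event_log.append((self.time, kind, ids))


def expected_fitness_increment(
    fitnesses: Sequence[float], variant: ModelVariant | str
) -> float:
    """Exact expected fitness change of one death-replacement event.

    Enumerates all ordered (dying cell i, replacing cell j) pairs with the
    model's sampling probabilities.  The replacing cell is drawn
    proportionally to fitness in both models; the dying cell is drawn
    proportionally to fitness in Model A and uniformly in Model B.

    Model A is antisymmetric under i <-> j so the expectation is exactly 0.
    Model B reduces to ``sum(f^2)/sum(f) - mean(f)`` which is >= 0 with
    equality iff all fitnesses are equal (it is Var(f) / mean(f) up to the
    population-size factor).
    """
    f = np.asarray(list(fitnesses), dtype=float)
    if f.size == 0:
        raise ValueError("fitness sequence must be non-empty")
    if np.any(f <= 0):
        raise ValueError("all fitnesses must be strictly positive")
    variant = ModelVariant(variant)
    total = f.sum()
    n = f.size
    if variant is ModelVariant.A:
        # P(i dies) = f_i / total, P(j replaces) = f_j / total
        p_die = f / total
    else:
        p_die = np.full(n, 1.0 / n)
    p_rep = f / total
    # E[f_j - f_i] over independent draws
    return float(p_rep @ f - p_die @ f)


def death_replacement_pmfs(
    state: PopulationState, variant: ModelVariant | str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-clone sampling distributions for one death-replacement event.

    Returns ``(dying, replacing)`` pmfs over clone ids ``0..n_clones-1``.
    The dying pmf is proportional to ``live_cells * fitness`` in Model A and
    to ``live_cells`` in Model B; the replacing pmf is proportional to
    ``live_cells * fitness`` in both.
    """
    variant = ModelVariant(variant)
    n = state.n_clones
    if state.sigma_P <= 0:
        raise ValueError("total fitness must be positive")
    w = state.live[:n] * state.fitness[:n]
    replacing = w / w.sum()
    if variant is ModelVariant.A:
        dying = replacing.copy()
    else:
        dying = state.live[:n] / state.live[:n].sum()
    return dying, replacing


def carrier_counts(state: PopulationState) -> dict[int, int]:
    """Number of live cells carrying each mutation.

    Each non-root clone corresponds to exactly one mutation; its carrier
    count is the number of live cells in the clone's subtree (the clone and
    all its descendants), since descendants inherit the mutation.

    Returns a mapping clone id -> carrier count for all non-root clones.
    Extinct mutations (count 0) are included; filtering happens downstream.
    """
    n = state.n_clones
    parent = state.parent[:n]
    # validate the tree: each parent link must point to an earlier clone
    order = np.arange(n)
    bad = (parent >= order) | (parent < -1)
    if np.any(bad):
        # distinguish an out-of-order (but acyclic) tree from a true cycle
        _check_acyclic(parent)
        order = _topological_order(parent)
    subtree = state.live[:n].astype(np.int64).copy()
    for i in order[::-1]:
        if parent[i] >= 0:
            subtree[parent[i]] += subtree[i]
    return {
        int(i): int(subtree[i])
        for i in range(n)
        if parent[i] >= 0 or state.origin[i] != OriginKind.ROOT
    }


def _check_acyclic(parent: np.ndarray) -> None:
    n = len(parent)
    for start in range(n):
        seen = set()
        i = start
        while i >= 0:
            if i in seen:
                raise ValueError(f"cycle in clone genealogy through clone {i}")
            seen.add(i)
            i = int(parent[i])


def _topological_order(parent: np.ndarray) -> np.ndarray:
    """Parents-before-children order for trees with arbitrary id layout."""
    n = len(parent)
    depth = np.zeros(n, dtype=np.int64)
    for i in range(n):
        d, j = 0, i
        while parent[j] >= 0:
            d += 1
            j = int(parent[j])
            if d > n:
                raise ValueError("cycle in clone genealogy")
        depth[i] = d
    return np.argsort(depth, kind="stable")
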