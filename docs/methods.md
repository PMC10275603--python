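# Methods

## Model and state representation

Both tug-of-war variants are time-continuous Markov chains over a constant
population of `N` cells. The simulator never stores individual cells:
because mutations map one-to-one onto clones (infinite-allele/infinite-site
convention) and `N` is constant, the state is a multiset over clones —
parallel arrays of parent id, driver/passenger counts `(α, β)`, origin kind,
birth time, fitness `(1+s)^α(1−d)^β`, and live-cell count. Clone ids are
assigned in birth order, so every parent precedes its children; carrier
counts of all mutations are then a single reverse sweep of subtree sums.

The two competing exponential clocks (death–replacement at rate
`Σ𝒫 = Σ live_i·f_i`, mutation at rate `Nμ`) are realised as one exponential
draw at the total rate followed by a categorical choice of event type; this
is distributionally identical to simulating the clocks separately and keeps
the state minimal. The dying and replacing cells are drawn independently
from the pre-event population, so the replacing cell may equal the dying
cell — a no-op that still consumes an event and advances time. An event
whose waiting time crosses the horizon `t_max` is censored (time is set to
`t_max`, nothing is applied); by memorylessness this realises the process
exactly on `[0, t_max]`, and it makes the mutation count over a run exactly
Poisson(`Nμt`).

`Σ𝒫` is maintained incrementally (two fitness updates per event) and
recomputed exactly every 10,000 events to bound floating-point drift; the
cached value is asserted against an exact recompute at a relative tolerance
of 1e−9.

## Parameters

| parameter | meaning | default / study value |
|---|---|---|
| `N` | population size (cells) | 100–400 in the simulation studies; 100 unless noted |
| `μ` | mutations per cell per time unit | 0.1 (often expressed as `L = Nμ`) |
| `p` | driver probability per mutation | 0.5 neutral studies; 0.0909 at equilibrium; 0.01 tail studies |
| `s` | fitness gain per driver | 0 (neutral) … 0.5 |
| `d` | fitness loss per passenger | 0 … 0.5 |
| `t_max` | horizon in model time units | 100 (one unit ≈ one cell generation at fitness 1) |
| `max_events` | safety cap | 5×10⁶ — the total event rate grows with `Σ𝒫` and can explode when drivers dominate (`sp ≫ d(1−p)`); exceeding the cap raises with the partial result attached |

The driver/passenger equilibrium is `s·p = d·(1−p)`; e.g. `s=0.1, d=0.01,
p=0.0909`. At that setting Model A shows no fitness trend while Model B
still drifts upward.

Two initial conditions are provided. `init_homogeneous` starts all cells
in one mutation-free clone of fitness 1. `init_exponential_draw` gives each
cell independent standing driver and passenger counts drawn from
exponential distributions and rounded half-up to the nearest integer; the
distribution parameters `10p` and `10(1−p)` are interpreted as **means**
(with `p = 0.5` each cell starts with ~5 drivers and ~5 passengers, which
is the heterogeneity the scenario needs), with a flag to switch to the
rate interpretation. Standing mutations are not tracked as sites — the
founding clones are all roots of the genealogy.

## Spectra and tails

The observed SFS is computed from the final population only; mutations
extinct by then are dropped, as are fixed (truncal) ones unless requested.
The cumulative tail uses the weak inequality `T(x) = #{f ≥ x}`, normalized
by default so all curves are inscribed in the unit square; the default
evaluation grid is the set of distinct observed frequencies. Singletons are
included by default (a minimum-carrier filter is available, since
low-frequency variants are often pruned from real call sets as suspected
sequencing errors).

Model-vs-data tail comparison is quantified — rather than judged visually —
by the sup distance of `log10 T` over the overlap of the two grids, with
the area between the log-curves as tie-breaker. Tail values are floored at
1e−12 before logs.

## Theoretical spectra

* **Coalescent form**: `ES_n(k) = θ Σ_j j·p_nj(k)·E[T_j]` with hypergeometric
  weights evaluated in log space. The coalescence-time expectations for
  exponential growth are obtained by Monte-Carlo inversion of the cumulative
  hazard (exact per draw, seeded), cross-checked in the test suite against
  msprime.
* **Growth approximation**: `ES_n(k) = θn/(r·k(k−1))` for `k ≥ 2`, singleton
  `θn·ln(rN)/r` only when the present population size is supplied. This is a
  fixed-`k`, large-`N` asymptotic: the gap to the coalescent form grows
  roughly like `k/(3n)` toward `k = n−1` (≈25% at the top of the spectrum),
  so agreement is only asserted on the low-frequency range where the
  approximation is meant to operate.
* **Multiclone humps**: `Q_nk = Σ p_i A_i/(k(k−1)) + Σ K_i C(n,k)(1−P_i)^{n−k}P_i^k`.
  In hierarchy mode the clone fractions come from exponential clade sizes at
  diagnosis, `K_i = θ_{j_i}(t_i − t_{j_i})` is kept real-valued (an expected
  count, not rounded to integer mutations), and the hump centroid `P_i` is
  taken as the cell fraction of clone `i`'s whole clade (the marker
  mutations are carried by every descendant of clone `i`) — the relation
  between centroid and clone fraction is otherwise under-determined, and
  callers can pass `P_i` directly. The denominator of the clone-fraction
  formula uses each clone's own growth rate (the total cell count at
  diagnosis), not a shared one.
* **Power law**: density `c·f^(−α)` with `α = λ0/λ1 ∈ (0,1)`; the cumulative
  tail is the closed-form integral. The two-type birth-death model behind it
  is represented only by this curve; no birth-death simulation is attempted.

## Neutrality testing

Unsigned Stirling numbers of the first kind are built by the triangular
recurrence entirely in log space (log-sum-exp), exact to machine precision
against integer arithmetic for `n ≤ 20` and stable far beyond. The ESF
distribution of the allele count `K` and the conditional mean spectrum
`E(A_j | k, n)` follow in log space; the latter is validated against
exhaustive enumeration of the Ewens distribution over integer partitions
for `n ≤ 8`.

The scaled mutation rate is `θ = Nμ/λ`, where `λ` is an allele-fitness
correction (cell generation length is inversely proportional to fitness);
`λ = 1` in the neutral case, and for non-neutral ensembles the recommended
choice is the ensemble mean of final population-average fitness (the
authors' exact per-scenario choice is not documented, so `λ` is an explicit
argument everywhere).

Two ensemble tests are provided. (1) The observed allele counts are
compared with the ESF distribution of `K` by a one-sample
Kolmogorov–Smirnov test. Because both distribution functions are
right-continuous steps on `1..n`, the statistic is computed as the sup
distance over that support (scipy's generic one-sample KS assumes a
continuous null and grossly inflates the statistic on tied integer data);
the p-value uses the standard one-sample KS distribution, which is
conservative for discrete nulls, so a seeded parametric-bootstrap p-value
is available as a companion. (2) Observed singleton counts are compared
with the semi-empirical null sample `{E(A_1 | k_i, n)}` — the conditional
expectations kept un-rounded — by a two-sample two-sided Wilcoxon rank-sum
test. The allele count `k` is taken from clones alive at `t_max`
("observed" sample semantics), not clones ever created.

## Variant tables and coverage equalization

TSV is the canonical interchange format (`site`, `total_reads`,
`variant_reads`); VCF reading uses per-sample allelic depths (AD) only,
splitting multiallelic records one row per alternate allele. The total-read
histogram equalization follows four steps — common-bin-width histograms of
both samples, per-bin target = the lower count, variants partitioned into
bins by total reads, larger subset pruned by uniform choice without
replacement — so the output histograms agree exactly bin by bin, retained
rows pass through verbatim, and the procedure is idempotent. The bin width
is not prescribed by the procedure itself; the default is the
Freedman–Diaconis width on the pooled total-read counts, overridable. The
total-read column is used as given (no distinction between raw and
post-filter depth).

## Synthetic paired tables

The generator that stands in for controlled-access patient sequencing data
draws per-site depth from a negative binomial (default mean 100, matching
the ~100× exome coverage typical of such experiments; shape 5 for visible
overdispersion) and variant reads from Binomial(depth, f), with a
configurable fraction of sites shared between the pair at identical
underlying frequency and depths drawn independently per sample — exactly
the coverage imbalance the equalization corrects. It emulates depth
variation and binomial read sampling only: no tumor purity, contamination,
copy-number change, or FFPE artifacts. Tests passing on these tables
therefore demonstrate the mechanics of VAF estimation and equalization,
not robustness to those real-data effects.

## Study problem sizes

The packaged reproduction workflows use 100 runs for the martingale check
(`N=100`, `t=100`), 50 seeds per model for clone-total ensembles, ensembles
of 200 runs (3 replicates) for the neutrality tests, and 20 runs per model
for the mean-tail comparison at `N=200, L=6` — sizes chosen so each
experiment's Monte-Carlo error is well below the effect it measures while a
full reproduction stays in the minutes range on a single core.

## Known limitations

* Constant population size only; no branching-process (growing-population)
  variant, no spatial or age structure, haploid genetics.
* `α` and `β` are unbounded non-negative integers.
* Expected-SFS fitting to data is by overlay and distance ranking; no
  maximum-likelihood estimation of hump parameters.
* The KS allele-count p-value is conservative on the discrete null (use the
  bootstrap companion when near the significance boundary).
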