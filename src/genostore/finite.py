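"""Finite-population Wright-Fisher engines with drift and recurrent mutation.

Two engines, mathematically equivalent where their domains overlap:

* an 8-haplotype multinomial engine (:func:`wf_multinomial_step`): the
  deterministic selection + recombination update followed by one
  multinomial draw of size N — usable whenever only two recombination-rate
  alleles segregate;
* an individual-based engine (:func:`individual_based_generation`,
  :func:`run_stationary_distribution`) that carries a continuum of
  recombination-rate alleles in [0, 0.5].  Parents are sampled with
  replacement and retained by rejection against the maximum fitness in the
  population; each accepted pair recombines (modifier-to-sequence rate R,
  plasticity-target rate equal to the parental allele average) and
  contributes one of its two reciprocal products, chosen by a fair coin,
  until N offspring are assembled.

Mutation introduces diversity with chance Nmu per locus per generation
(one uniformly chosen individual mutates: the recombination locus redraws
its rate from U[0, 0.5]; the plasticity and target loci flip alleles).  A
per-individual per-copy variant (rate Nmu/N per copy) is available behind
``per_individual=True`` since the event-level description is one of two
natural readings.

The stationary distribution of recombination rates is recorded at 0.01
resolution: every generation of the recording window, every individual
contributes its current rate allele (rounded to two decimals) to the
histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import EnvironmentalRegime, HaplotypeDistribution, fitness_vector, seasonal_effect
from .recombination import RecombinationScheme, recombination_tensor

__all__ = [
    "PopulationParams",
    "Individual",
    "Population",
    "StationaryDistribution",
    "wf_multinomial_step",
    "run_wf_multinomial",
    "individual_based_generation",
    "mutate_population",
    "run_stationary_distribution",
    "RATE_BINS",
]

#: Histogram bin centres for rates recorded to two-decimal precision.
RATE_BINS = np.round(np.arange(0.0, 0.5001, 0.01), 2)


@dataclass(frozen=True)
class PopulationParams:
    """Size, mutation intensity and window lengths of a finite-population run.

    ``mutation_intensity`` is the expected number of mutation events per
    locus per generation (the compound parameter N*mu); burn-in and
    recording windows default to 100*N generations each.
    """

    N: int
    mutation_intensity: float = 0.1
    burn_in_generations: int | None = None
    record_generations: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size must be at least 2")
        if not 0.0 <= self.mutation_intensity <= 1.0:
            raise ValueError("mutation_intensity must be in [0, 1]")
        for name in ("burn_in_generations", "record_generations"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def burn_in(self) -> int:
        return self.burn_in_generations if self.burn_in_generations is not None else 100 * self.N

    @property
    def record(self) -> int:
        return self.record_generations if self.record_generations is not None else 100 * self.N


@dataclass
class Individual:
    """One haploid genome of the individual-based engine."""

    rec_rate_allele: float
    plasticity_allele: str  # "m" or "M"
    target_alleles: tuple  # of "a"/"d"

    def __post_init__(self):
        if not 0.0 <= self.rec_rate_allele <= 0.5:
            raise ValueError("rec_rate_allele must lie in [0, 0.5]")


@dataclass
class Population:
    """Array-of-individuals state: rates (float), plasticity and target codes."""

    rec: np.ndarray  # (N,) float in [0, 0.5]
    plasticity: np.ndarray  # (N,) int8, 0=m 1=M
    target: np.ndarray  # (N,) int8, 0=a 1=d

    def __post_init__(self):
        self.rec = np.ascontiguousarray(self.rec, dtype=np.float64)
        self.plasticity = np.ascontiguousarray(self.plasticity, dtype=np.int8)
        self.target = np.ascontiguousarray(self.target, dtype=np.int8)
        n = self.rec.shape[0]
        if self.plasticity.shape[0] != n or self.target.shape[0] != n:
            raise ValueError("population arrays must share a common length")

    @property
    def size(self) -> int:
        return self.rec.shape[0]

    @classmethod
    def monomorphic(cls, N: int, rec: float = 0.0) -> "Population":
        """The reference starting state: non-recombining, all-m, all-a."""
        return cls(np.full(N, rec), np.zeros(N, np.int8), np.zeros(N, np.int8))

    @classmethod
    def from_individuals(cls, individuals) -> "Population":
        return cls(
            np.array([ind.rec_rate_allele for ind in individuals]),
            np.array([ind.plasticity_allele == "M" for ind in individuals], np.int8),
            np.array([ind.target_alleles[0] == "d" for ind in individuals], np.int8),
        )

    def to_individuals(self) -> list:
        return [
            Individual(
                float(self.rec[i]),
                "M" if self.plasticity[i] else "m",
                ("d" if self.target[i] else "a",),
            )
            for i in range(self.size)
        ]


@dataclass
class StationaryDistribution:
    """Aggregated stationary histogram of recombination-rate alleles."""

    bin_edges: np.ndarray  # (51,) bin centres 0.00 .. 0.50
    mass: np.ndarray  # (51,) probabilities, sums to 1
    replicate_count: int
    detail: dict = field(default_factory=dict)

    @property
    def mode(self) -> float:
        return float(self.bin_edges[int(np.argmax(self.mass))])

    @property
    def mean(self) -> float:
        return float(self.bin_edges @ self.mass)

    def mass_below(self, rate: float) -> float:
        return float(self.mass[self.bin_edges < rate].sum())


# ---------------------------------------------------------------------------
# 8-haplotype multinomial engine
# ---------------------------------------------------------------------------


def wf_multinomial_step(
    x: HaplotypeDistribution,
    scheme: RecombinationScheme,
    regime: EnvironmentalRegime,
    N: int | None,
    rng: np.random.Generator,
    tensor: np.ndarray | None = None,
) -> HaplotypeDistribution:
    """One Wright-Fisher generation on haplotype frequencies.

    Deterministic selection and recombination followed by a multinomial
    draw of size N; ``N=None`` skips the draw (the infinite-population
    limit).  The generation label advances by one.
    """
    from .model import _check_normalized, select

    _check_normalized(x.freqs)
    T = recombination_tensor(scheme) if tensor is None else tensor
    s_t = seasonal_effect(x.generation, regime)
    xs = select(x.freqs, fitness_vector(s_t, regime.p))
    xr = np.einsum("gij,i,j->g", T, xs, xs)
    xr = xr / xr.sum()
    if N is not None:
        xr = rng.multinomial(N, xr) / N
    return HaplotypeDistribution(xr, x.generation + 1)


def run_wf_multinomial(
    x0: HaplotypeDistribution,
    scheme: RecombinationScheme,
    regime: EnvironmentalRegime,
    N: int,
    n_generations: int,
    rng: np.random.Generator,
) -> HaplotypeDistribution:
    """Iterate :func:`wf_multinomial_step` for a fixed number of generations."""
    T = recombination_tensor(scheme)
    x = x0
    for _ in range(n_generations):
        x = wf_multinomial_step(x, scheme, regime, N, rng, tensor=T)
    return x


# ---------------------------------------------------------------------------
# Individual-based engine (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fitness_3locus(pl, tg, s_t, p):
    N = pl.shape[0]
    w = np.empty(N)
    for i in range(N):
        eff = s_t * (1.0 - p) if pl[i] == 1 else s_t
        w[i] = 1.0 + eff if tg[i] == 1 else 1.0 - eff
    return w


@njit(cache=True)
def _ib_generation_kernel(rec, pl, tg, w, R):
    """Assemble N offspring by fitness-rejection parent sampling."""
    N = rec.shape[0]
    wmax = w[0]
    for i in range(1, N):
        if w[i] > wmax:
            wmax = w[i]
    new_rec = np.empty(N)
    new_pl = np.empty(N, np.int8)
    new_tg = np.empty(N, np.int8)
    for n in range(N):
        while True:
            i = np.random.randint(N)
            if np.random.random() * wmax <= w[i]:
                break
        while True:
            j = np.random.randint(N)
            if np.random.random() * wmax <= w[j]:
                break
        if np.random.random() < 0.5:  # fair coin between reciprocal products
            i, j = j, i
        c1 = np.random.random() < R
        r = 0.5 * (rec[i] + rec[j])
        c2 = np.random.random() < r
        new_rec[n] = rec[i]
        new_pl[n] = pl[j] if c1 else pl[i]
        new_tg[n] = tg[j] if (c1 != c2) else tg[i]
    return new_rec, new_pl, new_tg


@njit(cache=True)
def _mutate_kernel(rec, pl, tg, nmu, per_individual):
    N = rec.shape[0]
    if per_individual:
        mu = nmu / N
        for i in range(N):
            if np.random.random() < mu:
                rec[i] = np.random.random() * 0.5
            if np.random.random() < mu:
                pl[i] = 1 - pl[i]
            if np.random.random() < mu:
                tg[i] = 1 - tg[i]
    else:
        if np.random.random() < nmu:
            rec[np.random.randint(N)] = np.random.random() * 0.5
        if np.random.random() < nmu:
            i = np.random.randint(N)
            pl[i] = 1 - pl[i]
        if np.random.random() < nmu:
            i = np.random.randint(N)
            tg[i] = 1 - tg[i]


@njit(cache=True)
def _run_stationary_kernel(
    rec, pl, tg, seed, C, s_max, p, R, nmu, burn_in, record, per_individual
):
    """Mutation -> reproduction each generation; histogram over the window."""
    np.random.seed(seed)
    hist = np.zeros(51, np.int64)
    total = burn_in + record
    for t in range(total):
        s_t = s_max * math.sin(2.0 * math.pi * t / C)
        _mutate_kernel(rec, pl, tg, nmu, per_individual)
        w = _fitness_3locus(pl, tg, s_t, p)
        rec, pl, tg = _ib_generation_kernel(rec, pl, tg, w, R)
        if t >= burn_in:
            for i in range(rec.shape[0]):
                hist[int(rec[i] * 100.0 + 0.5)] += 1
    return hist, rec, pl, tg


def individual_based_generation(
    pop: Population,
    regime: EnvironmentalRegime,
    R: float,
    t: int,
    rng: np.random.Generator,
) -> Population:
    """One generation of the individual-based engine at seasonal time t.

    Selection happens inside parent sampling (rejection against the maximum
    fitness), recombination uses the parental rate average for the
    plasticity-target interval and R for the modifier-to-sequence interval.
    """
    s_t = seasonal_effect(t, regime)
    w = _fitness_3locus(pop.plasticity, pop.target, s_t, regime.p)
    np.random.seed(int(rng.integers(2**31)))
    rec, pl, tg = _ib_generation_kernel(
        pop.rec.copy(), pop.plasticity.copy(), pop.target.copy(), w, R
    )
    return Population(rec, pl, tg)


def mutate_population(
    pop: Population,
    mutation_intensity: float,
    rng: np.random.Generator,
    per_individual: bool = False,
) -> Population:
    """Mutation step: with chance Nmu per locus, one random individual mutates.

    Returns a new Population; the input is not modified.  With
    ``per_individual=True`` every copy mutates independently at rate Nmu/N
    per locus instead.
    """
    rec = pop.rec.copy()
    pl = pop.plasticity.copy()
    tg = pop.target.copy()
    np.random.seed(int(rng.integers(2**31)))
    _mutate_kernel(rec, pl, tg, mutation_intensity, per_individual)
    return Population(rec, pl, tg)


def run_stationary_distribution(
    params: PopulationParams,
    regime: EnvironmentalRegime,
    R: float = 0.5,
    protocol: str = "monomorphic",
    replicates: int = 1,
    per_individual: bool = False,
    initial_population: Population | None = None,
) -> StationaryDistribution:
    """Stationary distribution of plasticity-target recombination rates.

    Each replicate starts per ``protocol`` ('monomorphic': no recombination,
    all-m, all-a; 'custom': ``initial_population``), runs mutation ->
    reproduction for the burn-in window, then accumulates every
    individual's rate allele (two-decimal bins) over the recording window.
    Histograms aggregate across replicates; per-replicate counts are kept
    in ``detail`` so no replicate is silently dropped.
    """
    if protocol not in ("monomorphic", "custom"):
        raise ValueError(f"unknown protocol {protocol!r}")
    seeds = np.random.SeedSequence(params.seed).generate_state(replicates) % (2**31)
    hist = np.zeros(51, np.int64)
    per_rep = []
    for k in range(replicates):
        if protocol == "custom":
            if initial_population is None:
                raise ValueError("protocol 'custom' needs initial_population")
            pop = Population(
                initial_population.rec.copy(),
                initial_population.plasticity.copy(),
                initial_population.target.copy(),
            )
        else:
            pop = Population.monomorphic(params.N)
        h, rec, pl, tg = _run_stationary_kernel(
            pop.rec, pop.plasticity, pop.target,
            int(seeds[k]), regime.period, regime.s_max, regime.p, R,
            params.mutation_intensity, params.burn_in, params.record,
            per_individual,
        )
        hist += h
        per_rep.append(int(h.sum()))
    mass = hist / hist.sum()
    return StationaryDistribution(
        bin_edges=RATE_BINS.copy(),
        mass=mass,
        replicate_count=replicates,
        detail={"per_replicate_counts": per_rep, "seeds": [int(s) for s in seeds]},
    )
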