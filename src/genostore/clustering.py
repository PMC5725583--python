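"""Clustering of multiple co-modulated target loci; supergene growth.

Extends the finite-population engine to k >= 2 target loci whose seasonal
effects are all buffered by the single plasticity locus, with no epistasis
among the targets (per-locus fitness factors multiply).  Each adjacent
interval of the selected sequence (plasticity -- target_1 -- ... --
target_k) carries its own recombination rate, either fixed or controlled
by an evolvable modifier locus; modifiers recombine with the selected
sequence at their own linkage rate (0.5 = unlinked, the default).

Protocols:

* ``run_two_target_protocol`` — the two-target experiments: 'sequential'
  (a population equilibrated at the plasticity--target distance ``r_pt``
  receives a second polymorphic target at a random initial distance) and
  'simultaneous' (both intervals evolve from random monomorphic rates).
* ``run_supergene_growth`` — repeated sequential introduction: after each
  cluster stage equilibrates, a new polymorphic target is appended at a
  random distance drawn from U[0, 0.5], growing an n-locus supergene.

Under genomic storage the distance between co-modulated targets collapses
towards zero (clustering): balancing selection keeps the high-variance
all-ancestral / all-derived haplotypes, drift removes mismatched ones, and
the resulting positive LD disfavours recombination between targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .finite import PopulationParams, RATE_BINS, StationaryDistribution
from .model import EnvironmentalRegime

__all__ = [
    "MultiLocusConfig",
    "MultiPopulation",
    "multilocus_fitness",
    "cosegregation_fraction",
    "target_ld",
    "run_two_target_protocol",
    "run_supergene_growth",
]


@dataclass(frozen=True)
class MultiLocusConfig:
    """Arrangement of k target loci and their interval modifiers.

    ``interval_rates``: initial rate per interval (length k: interval 0 is
    plasticity--target_1, interval l is target_l--target_{l+1});
    ``evolvable``: which intervals are modifier-controlled (mutating);
    ``modifier_linkage``: recombination rate of each modifier locus with
    the selected sequence (0.5 = unlinked); ``per_locus_s_max``: seasonal
    effect applied at every target locus; ``fitness_mode``: 'multiplicative'
    (no epistasis: per-locus factors multiply) or 'additive'
    (1 + sum of per-locus effects), the latter for sensitivity analysis.
    """

    k: int
    interval_rates: tuple
    evolvable: tuple
    modifier_linkage: tuple
    per_locus_s_max: float
    fitness_mode: str = "multiplicative"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("need at least one target locus")
        for name in ("interval_rates", "evolvable", "modifier_linkage"):
            if len(getattr(self, name)) != self.k:
                raise ValueError(f"{name} must have one entry per interval (k={self.k})")
        if self.fitness_mode not in ("multiplicative", "additive"):
            raise ValueError("fitness_mode must be 'multiplicative' or 'additive'")


@dataclass
class MultiPopulation:
    """State of the k-target engine."""

    plasticity: np.ndarray  # (N,) int8
    target: np.ndarray  # (N, k) int8
    rho: np.ndarray  # (N, k) float rate alleles per interval

    def __post_init__(self):
        self.plasticity = np.ascontiguousarray(self.plasticity, np.int8)
        self.target = np.ascontiguousarray(self.target, np.int8)
        self.rho = np.ascontiguousarray(self.rho, np.float64)

    @property
    def size(self) -> int:
        return self.plasticity.shape[0]

    @property
    def k(self) -> int:
        return self.target.shape[1]


def multilocus_fitness(
    plasticity_allele: int | str,
    target_alleles,
    s_t: float,
    p: float,
    mode: str = "multiplicative",
) -> float:
    """Fitness of one genome with k target loci, shared plasticity allele.

    Each target locus contributes the familiar factor (1 - eff) for the
    ancestral allele or (1 + eff) for the derived allele, with
    eff = s_t (1 - p) for plasticity carriers and s_t otherwise.  With
    ``mode='multiplicative'`` the factors multiply (no epistasis); with
    k = 1 this reduces exactly to the three-locus haplotype fitness.
    """
    is_M = plasticity_allele in (1, "M")
    eff = s_t * (1.0 - p) if is_M else s_t
    codes = [a in (1, "d") for a in target_alleles]
    if mode == "multiplicative":
        w = 1.0
        for derived in codes:
            w *= (1.0 + eff) if derived else (1.0 - eff)
    elif mode == "additive":
        w = 1.0 + sum(eff if derived else -eff for derived in codes)
    else:
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    return w


def cosegregation_fraction(pop: MultiPopulation | np.ndarray) -> float:
    """Fraction of chromosomes whose target alleles are all-a or all-d."""
    tg = pop.target if isinstance(pop, MultiPopulation) else np.asarray(pop)
    if tg.ndim != 2:
        raise ValueError("expected an (N, k) target-allele array")
    s = tg.sum(axis=1)
    k = tg.shape[1]
    return float(np.mean((s == 0) | (s == k)))


def target_ld(pop: MultiPopulation, i: int = 0, j: int = 1) -> float:
    """Pairwise D between two target loci: freq(d_i d_j) - freq(d_i) freq(d_j)."""
    ti = pop.target[:, i].astype(float)
    tj = pop.target[:, j].astype(float)
    return float(np.mean(ti * tj) - np.mean(ti) * np.mean(tj))


# ---------------------------------------------------------------------------
# numba engine
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fitness_multi(pl, tg, s_t, p, additive):
    N, k = tg.shape
    w = np.empty(N)
    for i in range(N):
        eff = s_t * (1.0 - p) if pl[i] == 1 else s_t
        if additive:
            acc = 1.0
            for l in range(k):
                acc += eff if tg[i, l] == 1 else -eff
        else:
            acc = 1.0
            for l in range(k):
                acc *= (1.0 + eff) if tg[i, l] == 1 else (1.0 - eff)
        w[i] = acc
    return w


@njit(cache=True)
def _multi_generation_kernel(pl, tg, rho, w, mod_linkage):
    """One generation: rejection-sampled parents, chained crossovers."""
    N, k = tg.shape
    wmax = w[0]
    for i in range(1, N):
        if w[i] > wmax:
            wmax = w[i]
    new_pl = np.empty(N, np.int8)
    new_tg = np.empty((N, k), np.int8)
    new_rho = np.empty((N, k))
    for n in range(N):
        while True:
            i = np.random.randint(N)
            if np.random.random() * wmax <= w[i]:
                break
        while True:
            j = np.random.randint(N)
            if np.random.random() * wmax <= w[j]:
                break
        if np.random.random() < 0.5:
            i, j = j, i
        # selected sequence: plasticity head, then the k targets in order
        new_pl[n] = pl[i]
        src_is_j = False
        for l in range(k):
            r = 0.5 * (rho[i, l] + rho[j, l])
            if np.random.random() < r:
                src_is_j = not src_is_j
            new_tg[n, l] = tg[j, l] if src_is_j else tg[i, l]
        # modifier loci: linked to the sequence head at their own rate
        for l in range(k):
            if np.random.random() < mod_linkage[l]:
                new_rho[n, l] = rho[j, l]
            else:
                new_rho[n, l] = rho[i, l]
    return new_pl, new_tg, new_rho


@njit(cache=True)
def _mutate_multi_kernel(pl, tg, rho, nmu, evolvable):
    N, k = tg.shape
    if np.random.random() < nmu:
        i = np.random.randint(N)
        pl[i] = 1 - pl[i]
    for l in range(k):
        if np.random.random() < nmu:
            i = np.random.randint(N)
            tg[i, l] = 1 - tg[i, l]
        if evolvable[l] and np.random.random() < nmu:
            rho[np.random.randint(N), l] = np.random.random() * 0.5
    return


@njit(cache=True)
def _run_multi_kernel(
    pl, tg, rho, seed, C, s_max, p, nmu,
    mod_linkage, evolvable, additive, burn_in, record,
):
    """Burn-in then recording; per-interval rate histograms + summaries.

    Returns (hists, coseg_sum, ld_sum, amp, pl, tg, rho) where hists is
    (k, 51), coseg_sum and ld_sum accumulate per recorded generation, and
    amp is the mean within-cycle amplitude (per-cycle max minus min,
    averaged over recorded cycles) of the first target locus'
    derived-allele frequency — the seasonal oscillation magnitude, kept
    separate from slow drift excursions.
    """
    np.random.seed(seed)
    N, k = tg.shape
    hists = np.zeros((k, 51), np.int64)
    coseg_sum = 0.0
    ld_sum = 0.0
    amp_sum = 0.0
    n_cycles = 0
    cyc_min = 1.0
    cyc_max = 0.0
    total = burn_in + record
    for t in range(total):
        s_t = s_max * math.sin(2.0 * math.pi * t / C)
        _mutate_multi_kernel(pl, tg, rho, nmu, evolvable)
        w = _fitness_multi(pl, tg, s_t, p, additive)
        pl, tg, rho = _multi_generation_kernel(pl, tg, rho, w, mod_linkage)
        if t >= burn_in:
            for l in range(k):
                for i in range(N):
                    hists[l, int(rho[i, l] * 100.0 + 0.5)] += 1
            nco = 0
            for i in range(N):
                s = 0
                for l in range(k):
                    s += tg[i, l]
                if s == 0 or s == k:
                    nco += 1
            coseg_sum += nco / N
            f1 = 0.0
            for i in range(N):
                f1 += tg[i, 0]
            f1 /= N
            if f1 < cyc_min:
                cyc_min = f1
            if f1 > cyc_max:
                cyc_max = f1
            if (t - burn_in) % C == C - 1:
                amp_sum += cyc_max - cyc_min
                n_cycles += 1
                cyc_min = 1.0
                cyc_max = 0.0
            if k >= 2:
                fa = 0.0
                fb = 0.0
                fab = 0.0
                for i in range(N):
                    fa += tg[i, 0]
                    fb += tg[i, 1]
                    fab += tg[i, 0] * tg[i, 1]
                ld_sum += fab / N - (fa / N) * (fb / N)
    amp = amp_sum / n_cycles if n_cycles > 0 else 0.0
    return hists, coseg_sum, ld_sum, amp, pl, tg, rho


def _run_stage(
    pop: MultiPopulation,
    config: MultiLocusConfig,
    regime: EnvironmentalRegime,
    nmu: float,
    burn_in: int,
    record: int,
    seed: int,
) -> tuple[dict, MultiPopulation]:
    hists, coseg_sum, ld_sum, amplitude, pl, tg, rho = _run_multi_kernel(
        pop.plasticity.copy(), pop.target.copy(), pop.rho.copy(),
        int(seed), regime.period, config.per_locus_s_max, regime.p, nmu,
        np.asarray(config.modifier_linkage, np.float64),
        np.asarray(config.evolvable, np.bool_),
        config.fitness_mode == "additive",
        int(burn_in), int(record),
    )
    n_rec = max(record, 1)
    result = {
        "hists": hists,
        "cosegregation": coseg_sum / n_rec,
        "mean_target_ld": ld_sum / n_rec,
        "oscillation_amplitude": float(amplitude),
        "seed": int(seed),
    }
    return result, MultiPopulation(pl, tg, rho)


def _distribution_from_hist(hist: np.ndarray, replicate_count: int, detail: dict):
    mass = hist / hist.sum()
    return StationaryDistribution(RATE_BINS.copy(), mass, replicate_count, detail)


def run_two_target_protocol(
    mode: str,
    params: PopulationParams,
    regime: EnvironmentalRegime,
    r_pt: float = 0.35,
    replicates: int = 1,
    pre_burn_in: int | None = None,
    modifier_linkage: tuple = (0.5, 0.5),
    fitness_mode: str = "multiplicative",
    r_prime_init: float | None = None,
) -> StationaryDistribution:
    """Stationary distribution of the inter-target rate r' with two targets.

    'sequential': the plasticity--target_1 interval is held at the
    equilibrated distance ``r_pt`` while the population runs a
    ``pre_burn_in`` window (default 10N) to reach the storage equilibrium;
    a second polymorphic target is then appended downstream at a random
    monomorphic distance ~ U[0, 0.5] (or at ``r_prime_init`` when given)
    whose modifier then evolves.
    'simultaneous': both intervals start at independent random monomorphic
    rates and both evolve from the outset.  Seasonal amplitude per target
    locus is ``regime.s_max``.  Returns the aggregated r' distribution;
    per-replicate summaries (co-segregation, target LD, oscillation
    amplitude) are kept in ``detail``.
    """
    if mode not in ("sequential", "simultaneous"):
        raise ValueError("mode must be 'sequential' or 'simultaneous'")
    seeds = np.random.SeedSequence(params.seed).generate_state(2 * replicates) % (2**31)
    rng = np.random.default_rng(params.seed)
    hist = np.zeros(51, np.int64)
    per_rep = []
    for rep in range(replicates):
        if mode == "sequential":
            cfg1 = MultiLocusConfig(
                1, (r_pt,), (False,), (modifier_linkage[0],),
                regime.s_max, fitness_mode,
            )
            # the storage equilibrium is polymorphic at both selected loci;
            # start there and let the pre-burn relax to the stationary state
            pop = MultiPopulation(
                (rng.random(params.N) < 0.5).astype(np.int8),
                (rng.random((params.N, 1)) < 0.5).astype(np.int8),
                np.full((params.N, 1), r_pt),
            )
            pre = pre_burn_in if pre_burn_in is not None else 10 * params.N
            _, pop = _run_stage(
                pop, cfg1, regime, params.mutation_intensity,
                pre, 1, int(seeds[2 * rep]),
            )
            r_init = rng.uniform(0.0, 0.5) if r_prime_init is None else r_prime_init
            new_target = (rng.random(params.N) < 0.5).astype(np.int8)
            pop = MultiPopulation(
                pop.plasticity,
                np.column_stack([pop.target[:, 0], new_target]),
                np.column_stack([pop.rho[:, 0], np.full(params.N, r_init)]),
            )
            cfg2 = MultiLocusConfig(
                2, (r_pt, r_init), (False, True), tuple(modifier_linkage),
                regime.s_max, fitness_mode,
            )
        else:
            r0 = rng.uniform(0.0, 0.5)
            r_init = rng.uniform(0.0, 0.5) if r_prime_init is None else r_prime_init
            pop = MultiPopulation(
                (rng.random(params.N) < 0.5).astype(np.int8),
                (rng.random((params.N, 2)) < 0.5).astype(np.int8),
                np.column_stack(
                    [np.full(params.N, r0), np.full(params.N, r_init)]
                ),
            )
            cfg2 = MultiLocusConfig(
                2, (r0, r_init), (True, True), tuple(modifier_linkage),
                regime.s_max, fitness_mode,
            )
        result, pop = _run_stage(
            pop, cfg2, regime, params.mutation_intensity,
            params.burn_in, params.record, int(seeds[2 * rep + 1]),
        )
        hist += result["hists"][1]
        fd = pop.target.mean(axis=0)
        per_rep.append(
            {
                "cosegregation": result["cosegregation"],
                "mean_target_ld": result["mean_target_ld"],
                "oscillation_amplitude": result["oscillation_amplitude"],
                "final_target_freqs": [float(f) for f in fd],
                "polymorphism_retained": bool(np.all((fd > 0.01) & (fd < 0.99))),
                "r_prime_initial": float(r_init),
            }
        )
    return _distribution_from_hist(hist, replicates, {"replicates": per_rep, "mode": mode})


def run_supergene_growth(
    n_max: int,
    params: PopulationParams,
    regime: EnvironmentalRegime,
    r_pt: float = 0.15,
    pre_burn_in: int | None = None,
    stage_record: int = 10_000,
    clustering_threshold: float = 0.1,
    fitness_mode: str = "multiplicative",
) -> list[dict]:
    """Grow a supergene by sequential introduction of polymorphic targets.

    Starting from the equilibrated single-target system (plasticity--target
    distance ``r_pt``), targets 2..n_max are introduced one at a time at a
    random distance ~ U[0, 0.5] from the extant cluster; after each
    introduction the population runs ``params.burn_in`` generations and is
    then recorded for ``stage_record`` generations.  Per stage, reports the
    newest-interval rate distribution, whether the stage clustered (the
    majority of recorded mass below ``clustering_threshold``), the
    co-segregation fraction (chromosomes carrying all-ancestral or
    all-derived target alleles), and mean inter-target LD.  Failure to
    cluster at a stage is reported, not raised; the sequence continues.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    seeds = np.random.SeedSequence(params.seed).generate_state(n_max + 1) % (2**31)
    rng = np.random.default_rng(params.seed)
    # start from the polymorphic storage state the growth model presumes
    pop = MultiPopulation(
        (rng.random(params.N) < 0.5).astype(np.int8),
        (rng.random((params.N, 1)) < 0.5).astype(np.int8),
        np.full((params.N, 1), r_pt),
    )
    cfg = MultiLocusConfig(
        1, (r_pt,), (False,), (0.5,), regime.s_max, fitness_mode
    )
    pre = pre_burn_in if pre_burn_in is not None else 10 * params.N
    _, pop = _run_stage(
        pop, cfg, regime, params.mutation_intensity, pre, 1, int(seeds[0])
    )
    stages = []
    for n in range(2, n_max + 1):
        r_init = rng.uniform(0.0, 0.5)
        new_target = (rng.random(params.N) < 0.5).astype(np.int8)
        pop = MultiPopulation(
            pop.plasticity,
            np.column_stack([pop.target, new_target]),
            np.column_stack([pop.rho, np.full(params.N, r_init)]),
        )
        cfg = MultiLocusConfig(
            n,
            tuple(pop.rho[0]),
            (False,) + (True,) * (n - 1),
            (0.5,) * n,
            regime.s_max,
            fitness_mode,
        )
        result, pop = _run_stage(
            pop, cfg, regime, params.mutation_intensity,
            params.burn_in, stage_record, int(seeds[n - 1]),
        )
        newest = result["hists"][n - 1]
        mass = newest / newest.sum()
        below = float(mass[RATE_BINS < clustering_threshold].sum())
        fd = pop.target.mean(axis=0)
        stages.append(
            {
                "n_targets": n,
                "r_prime_initial": float(r_init),
                "distribution": _distribution_from_hist(
                    newest, 1, {"stage": n}
                ),
                "mass_below_threshold": below,
                "clustered": below > 0.5,
                "cosegregation": result["cosegregation"],
                "mean_target_ld": result["mean_target_ld"],
                "final_target_freqs": [float(f) for f in fd],
                "polymorphism_retained": bool(np.all((fd > 0.01) & (fd < 0.99))),
            }
        )
    return stages
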