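"""Wright-Fisher engines: multinomial sampling, mutation, reproduction."""

import numpy as np
import pytest

from genostore.finite import (
    Individual,
    Population,
    PopulationParams,
    individual_based_generation,
    mutate_population,
    run_stationary_distribution,
    run_wf_multinomial,
    wf_multinomial_step,
)
from genostore.model import (
    EnvironmentalRegime,
    HaplotypeDistribution,
    apply_selection,
)
from genostore.recombination import RecombinationScheme, apply_recombination


class TestMultinomialEngine:
    def test_infinite_population_limit_is_deterministic_step(self, regime_c10, rng):
        scheme = RecombinationScheme(0.1, 0.4, 0.5)
        x = HaplotypeDistribution(rng.dirichlet(np.ones(8)), generation=3)
        out = wf_multinomial_step(x, scheme, regime_c10, None, rng)
        expected = apply_recombination(apply_selection(x, regime_c10), scheme)
        assert np.allclose(out.freqs, expected.freqs, atol=1e-12)
        assert out.generation == 4

    def test_monomorphic_state_is_absorbing(self, regime_c10, rng):
        x = np.zeros(8)
        x[5] = 1.0
        out = wf_multinomial_step(
            HaplotypeDistribution(x, 1), RecombinationScheme(0.2, 0.3, 0.5),
            regime_c10, 100, rng,
        )
        assert np.array_equal(out.freqs, x)

    def test_sampling_is_unbiased(self, regime_c10, rng):
        """The mean over replicate draws of one Wright-Fisher step matches
        the deterministic update within binomial standard error."""
        scheme = RecombinationScheme(0.1, 0.4, 0.5)
        x = HaplotypeDistribution(rng.dirichlet(np.ones(8)), generation=2)
        N, reps = 100, 10_000
        expected = apply_recombination(apply_selection(x, regime_c10), scheme).freqs
        draws = rng.multinomial(N, expected, size=reps) / N
        se = np.sqrt(expected * (1 - expected) / (N * reps))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 4 * se + 1e-12)

    def test_drift_shrinks_with_population_size(self, regime_c10):
        """Mutation-free finite trajectories track the deterministic orbit,
        the more closely the larger N."""
        scheme = RecombinationScheme(0.25, 0.35, 0.5)
        x0 = HaplotypeDistribution.from_marginals(0.5, 0.5, 0.5)
        det = x0
        for _ in range(10):
            det = wf_multinomial_step(
                det, scheme, regime_c10, None, np.random.default_rng(0)
            )
        devs = {}
        for N in (1_000, 100_000):
            acc = 0.0
            for rep in range(20):
                r = np.random.default_rng(1000 * N + rep)
                xf = run_wf_multinomial(x0, scheme, regime_c10, N, 10, r)
                acc += np.abs(xf.freqs - det.freqs).max()
            devs[N] = acc / 20
        assert devs[100_000] < devs[1_000]


class TestMutation:
    def test_zero_intensity_is_identity(self, rng):
        pop = Population.monomorphic(50, rec=0.2)
        out = mutate_population(pop, 0.0, rng)
        assert np.array_equal(out.rec, pop.rec)
        assert np.array_equal(out.plasticity, pop.plasticity)
        assert np.array_equal(out.target, pop.target)

    def test_unit_intensity_mutates_one_copy_per_locus(self, rng):
        pop = Population.monomorphic(200)
        out = mutate_population(pop, 1.0, rng)
        assert out.plasticity.sum() == 1  # exactly one flip
        assert out.target.sum() == 1
        assert np.count_nonzero(out.rec != 0.0) <= 1  # U[0,0.5) draw

    def test_event_count_matches_intensity(self, rng):
        """Over G generations the expected number of plasticity-flip events
        is G * Nmu; a long neutral run must land in the binomial range."""
        nmu, G = 0.1, 3000
        pop = Population.monomorphic(100)
        flips = 0
        prev = pop
        for _ in range(G):
            cur = mutate_population(prev, nmu, rng)
            flips += int(np.any(cur.plasticity != prev.plasticity))
            prev = cur
        se = np.sqrt(G * nmu * (1 - nmu))
        assert abs(flips - G * nmu) < 4 * se

    def test_rates_stay_in_bounds(self, rng):
        pop = Population.monomorphic(50)
        for _ in range(200):
            pop = mutate_population(pop, 1.0, rng)
        assert np.all((pop.rec >= 0.0) & (pop.rec <= 0.5))


class TestIndividualBasedEngine:
    def test_identical_parents_identical_offspring(self, regime_c10, rng):
        pop = Population(
            np.full(100, 0.3), np.ones(100, np.int8), np.ones(100, np.int8)
        )
        out = individual_based_generation(pop, regime_c10, 0.5, t=2, rng=rng)
        assert np.all(out.rec == 0.3)
        assert np.all(out.plasticity == 1)
        assert np.all(out.target == 1)

    def test_neutral_reproduction_conserves_frequencies(self, rng):
        """At a season boundary (s_t = 0) reproduction is pure resampling:
        allele frequencies move only by drift, of order 1/sqrt(N)."""
        regime = EnvironmentalRegime(s_max=0.5, period=10, p=1.0)
        N = 4000
        pop = Population(
            np.where(np.arange(N) < N // 2, 0.0, 0.4),
            (np.arange(N) % 2).astype(np.int8),
            (np.arange(N) < N // 4).astype(np.int8),
        )
        out = individual_based_generation(pop, regime, 0.5, t=0, rng=rng)
        se = np.sqrt(0.25 / N)
        assert abs(out.plasticity.mean() - 0.5) < 5 * se
        assert abs(out.target.mean() - 0.25) < 5 * np.sqrt(0.25 * 0.75 / N)
        assert abs((out.rec > 0.2).mean() - 0.5) < 5 * se

    def test_individual_roundtrip(self):
        inds = [
            Individual(0.1, "m", ("a",)),
            Individual(0.4, "M", ("d",)),
        ]
        pop = Population.from_individuals(inds)
        back = pop.to_individuals()
        assert back[0] == inds[0] and back[1] == inds[1]

    def test_rate_allele_bounds_enforced(self):
        with pytest.raises(ValueError):
            Individual(0.7, "m", ("a",))


class TestStationaryDistribution:
    def test_histogram_mass_is_complete(self):
        """Two-decimal recording loses no mass and aggregates replicates."""
        regime = EnvironmentalRegime(s_max=0.5, period=10, p=1.0)
        params = PopulationParams(
            N=200, mutation_intensity=0.1,
            burn_in_generations=500, record_generations=500, seed=7,
        )
        sd = run_stationary_distribution(params, regime, replicates=2)
        assert sd.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert sd.replicate_count == 2
        assert len(sd.detail["per_replicate_counts"]) == 2
        assert all(c == 200 * 500 for c in sd.detail["per_replicate_counts"])

    def test_runs_are_reproducible_by_seed(self):
        regime = EnvironmentalRegime(s_max=0.5, period=10, p=1.0)
        params = PopulationParams(
            N=100, mutation_intensity=0.1,
            burn_in_generations=300, record_generations=300, seed=11,
        )
        a = run_stationary_distribution(params, regime)
        b = run_stationary_distribution(params, regime)
        assert np.array_equal(a.mass, b.mass)
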