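# Methods

## The model

`genostore` implements a haploid Wright–Fisher model of the *genomic
storage effect*: the maintenance of seasonally selected diversity by
recombination between a selected **target locus** and a **plasticity
modifier** that buffers selection at the target, and the consequences of
that effect for the evolution of recombination rates themselves.

Three loci are tracked in the core model, physically arranged
recombination-modifier – plasticity – target:

* **target locus** (alleles *a*/*d*): the ancestral allele *a* is favoured
  for one half of the environmental cycle, the derived allele *d* for the
  other half;
* **plasticity modifier** (*m*/*M*): carriers of *M* feel the seasonal
  effect reduced by the factor (1 − p); with p = 1 they are fitness-neutral
  at the target locus in every season;
* **recombination modifier** (*r1*/*r2*): selectively inert in itself, its
  alleles set the recombination rate between the plasticity and target
  loci.  Heterozygous parental pairings recombine at the additive mean
  rate r_c = (r1 + r2)/2; the modifier itself recombines with the selected
  pair at a fixed rate R (R = 0.5 means an unlinked modifier).

Fitness of the eight haplotypes at generation t:

    w(·ma) = 1 − s_t          w(·Ma) = 1 − s_t (1 − p)
    w(·md) = 1 + s_t          w(·Md) = 1 + s_t (1 − p)

with the sinusoidal seasonal effect s_t = s_max · sin(2πt / C) over a
period of C discrete generations.  One generation is selection
(x_g ∝ x_g w_g) followed by recombination; in finite populations the next
generation is then formed by sampling.

### Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| s_max | peak seasonal effect (dimensionless) | 0.1 deterministic / 0.5 finite C=10 | must lie in (0, 1) |
| C | environmental period (generations) | 10 | even values make the two seasons exact mirrors |
| p | plasticity effect in [0, 1] | 1 | p = 0 switches the plasticity locus off |
| R | modifier-to-sequence recombination rate | 0.5 | 0.5 = unlinked; a conservative lower bound for the evolved rate |
| r1, r2, r | plasticity–target recombination rates | — | all rates live on [0, 0.5] |
| N | haploid population size | 2000 (scaled runs) | see “Problem sizes” |
| Nµ | expected mutation events per locus per generation | 0.1 | compound mutation intensity |

The starting seasonal phase is a convention the model itself does not fix;
runs start at a season boundary (s_0 = 0) and an explicit phase offset is
available on `EnvironmentalRegime`.

## Why recombination is selected at all

The modifier never appears in the fitnesses; all selection on it is
indirect.  Within a season, epistasis between the plasticity and target
loci (E = −2 p s_t on the multiplicative scale) favours coupling of the
currently good target allele with *m* and the bad one with *M*; linkage
disequilibrium D (measured on the (M, d) coupling) follows with a lag.
When the season flips, E changes sign instantly and D does not: during the
window with E·D < 0 the population is enriched for currently unfit
combinations, a higher-rate modifier allele breaks them up faster, ends up
associated with fitter backgrounds, and hitchhikes upward.  Once D catches
up, further recombination is disfavoured.  The balance of the two windows
sets the evolutionarily stable (ES) rate r*.  The cycle diagnostics
(`genostore diagnose`) expose exactly this signature: D changes sign
within the cycle and E·D < 0 holds at the start of each season.

## Deterministic analysis

### Periodic orbits

For a population monomorphic at rate r, `resident_orbit` iterates the
8-dimensional map from a factorial grid of plasticity/target starting
frequencies until the state sequence repeats over two consecutive cycles
(tolerance 1e−8 per coordinate, the orbit comparison metric being the
maximum absolute same-phase difference), or an allele at the plasticity or
target locus fixes (frequency < 1e−4).  An orbit counts as polymorphic
when the minor allele frequency at both selected loci stays ≥ 0.01
throughout the cycle.  Under the reference regime (C = 10, s_max = 0.1,
p = 1, R = 0.5) polymorphic orbits exist exactly for r ≥ 0.20: below that,
the plasticity allele sweeps (with p = 1 the swept state is selectively
inert) and storage dies.  This threshold is what makes a non-recombining
resident displaceable by any rate in the fixation band.

### Invasion protocol

`classify_pair(r1, r2)` gives each rate the chance to arise as a rare
invader (frequency 0.01, carrying the resident's plasticity–target
composition — recombination cannot create modifier variation, so the
invader must appear in situ) on the other rate's orbit.  Outcomes are read
off the endpoint: the invader is *lost* (rec-locus minor frequency < 1e−4,
or a converged cycle on which it stays below 0.01), the *resident is
lost*, or an *interior* periodic attractor retains both alleles at minor
frequency ≥ 0.01 (“coexistence at intermediate frequencies”).  Pairs where
no attractor sustains the selected-locus polymorphism are classified
`no_polymorphism`.  Direct iteration is the primary criterion because it
is robust exactly where eigenvalues are least informative (|λ| near 1);
the cycle-Jacobian eigenvalue of the invader block is kept as an
independent cross-check and agrees in direction on every tested pair.

Numerical choices: the generation cap is 2×10⁶ (near-threshold
competitions resolve in ~5×10⁵ generations; hitting the cap flags the
result, never silently); the plasticity/target initialization grid
defaults to {0.05, 0.5, 0.95}² — the attractors found are the same as with
the full 0.05–0.95 step-0.1 factorial grid at a tenth of the cost.

### ES rate

`find_es_rate` classifies all grid pairs and returns every rate that no
alternative displaces.  Near r* neighbouring grid rates mutually coexist,
so the result is a contiguous *band* plus a point estimate (band median).
At s_max = 0.1, R = 0.5, grid step 0.05 the bands are {0.30–0.40} for
C = 10, {0.10–0.15} for C = 20, and {0–0.05} for C = 40 and 80:
non-increasing in C, and nearly unmoved by halving s_max.

### Cycle Jacobian

The monodromy matrix is the product over one period of per-generation
Jacobians of the composed selection+recombination map evaluated along the
orbit.  Selection is scale-invariant, so its Jacobian maps onto the
sum-zero tangent space, where the renormalization of the quadratic
recombination map contributes nothing; the analytic product agrees with a
central finite-difference Jacobian (step 1e−6, simplex-projected
perturbations) to better than 1e−7 relative on stored orbits.

## Recombination operators

The mechanistic operator averages the two-interval crossover algebra
(independent Bernoulli crossovers; no interference, as the coefficient
structure of the recursion implies) over all ordered parent pairs drawn
with replacement from the post-selection distribution.  It conserves
single-locus allele frequencies to machine precision and is the identity
on linkage-equilibrium states; restricted to a monomorphic modifier it
reduces to the classical two-locus decay D′ = (1 − r)D.

A literal transcription of the printed eight-equation recursion is kept
solely as a cross-validation fixture.  Symbolic comparison shows the
transcribed equations for r1ma and r1Ma agree with the mechanistic
operator exactly, while the remaining six carry typographical slips
(sign-flipped “(Rr_c − R − r_c)” terms, one “(R + r_c − Rr_c)” where the
algebra gives (R + r_c − 2Rr_c), a missing R·x_{r2ma}·x_{r2Ma} cross term,
and one malformed subscript).  `printed_recursion_discrepancies` documents
the differences; nothing in the package “corrects” the transcription,
and the mechanistic operator is the source of truth throughout.

## Finite populations

The multinomial engine applies the deterministic update and draws N
haplotypes; the individual-based engine carries a continuum of rate
alleles, samples parents with replacement by rejection against the maximum
fitness, recombines each accepted pair (rate R for the modifier interval,
parental average for the selected interval) and keeps one of the two
reciprocal products by fair coin until N offspring exist.  Restricted to
two rate alleles the engines are distributionally equivalent; the test
suite checks this with two-sample KS tests on terminal allele-frequency
distributions over 1000 replicates.

Mutation follows the event-level reading of the compound intensity: per
locus and generation, with probability Nµ one uniformly chosen individual
mutates (modifier: rate redrawn from U[0, 0.5]; other loci: allele flip).
A per-copy variant (rate Nµ/N per individual) is available behind
`per_individual=True` because the event-level description is one of two
natural readings of a compound parameter.  Stationary distributions record
every individual's rate allele each recorded generation at two-decimal
resolution (the histogram is exhaustive: recording loses no mass).

## Multiple targets and supergenes

With k targets co-modulated by the one plasticity locus, per-locus factors
multiply (no epistasis).  An additive variant (1 + Σ effects) exists
behind `fitness_mode="additive"` for sensitivity analysis only.  Each
adjacent interval of the selected sequence carries its own rate, fixed or
governed by an evolvable modifier; modifiers are unlinked (0.5) by
default, with linked variants available.  The sequential protocols start
from the polymorphic storage state they presume (plasticity and first
target near 0.5, relaxed by a pre-burn window) rather than waiting for
mutation to establish the polymorphism from a monomorphic start — at long
periods that establishment is the bottleneck, not the phenomenon under
study.  Each new polymorphic target is introduced at a random (or pinned)
distance from the equilibrated cluster; per stage the package records the
newest-interval rate histogram, the co-segregation fraction (chromosomes
all-*a* or all-*d* across targets), mean inter-target LD, and the mean
within-cycle amplitude of allele-frequency oscillation.
“Downstream” introduction appends the new locus after the existing
targets; placement between the plasticity locus and the first target is
available through the same configuration.

## What the simulations emulate — and what they do not

All inputs are internally generated: the model *is* the data-generating
process, so the synthetic runs emulate exactly the idealized populations
the theory describes — discrete non-overlapping generations, constant N,
strictly sinusoidal and perfectly periodic seasonality, no stochastic
environmental perturbation, no dominance (haploidy), no interference among
crossovers, and mutation at a fixed compound intensity.  Real seasonal
populations violate most of these (overlapping generations, noisy
seasons, diploidy with dominance, linked background selection), so
passing tests demonstrate the internal consistency and the claimed
qualitative phenomena of the model, not quantitative predictions for any
natural population.

## Problem sizes

The reference experiments at N = 25,000 with 100N-generation windows
(≈ 5×10⁶ generations per replicate, thousands of replicates) are a
documented long-running mode, not something the default suite executes.
The package's own standard problem sizes, chosen once as the smallest
scale at which each phenomenon is cleanly expressed:

* deterministic invasion grid: exact protocol, full 0.01 grid (seconds per
  column);
* stationary rate distribution: N = 2000, Nµ = 0.1, C = 10, s_max = 0.5,
  burn-in and recording 100N each, one replicate (the mode is stable
  across seeds at this size);
* two-target clustering: N = 2000, C = 10, s_max = 0.5 per locus, burn-in
  100,000 and recording 50,000 generations, the new target introduced at
  distance 0.25 (a deliberately unclustered start);
* supergene growth: C = 20 with N = 4000 and s_max = 0.35 per locus,
  burn-in 80,000 and recording 10,000 generations per stage, growth to
  three targets.  Storage weakens with the period, so desk-scale C = 20
  runs compensate the smaller population with stronger per-locus
  selection: N = 2000 does not sustain the target polymorphism at C = 20
  for s_max ≤ 0.25, while N = 4000 at s_max = 0.35 clusters decisively
  with the balanced polymorphism intact — the same qualitative regime,
  reached at ~1/6 of the reference population size.

## Known limitations

* The deterministic classifier resolves competitions, not transient
  timescales; near band edges competitions take ~10⁵–10⁶ generations and
  the 1e−8 cycle criterion can trigger while a doomed allele is still at
  ~10⁻⁴ — the 0.01 rec-locus polymorphism criterion is what separates such
  slow losses from genuine coexistence.
* ES “rates” are bands at finite grid resolution; the point estimate is a
  convention (band median).
* Finite-population results at desk scale are single- or few-replicate;
  they reproduce modes and majority-mass statements, not full histogram
  shapes.
* The supergene protocol treats each stage's start as an equilibrated
  cluster; it does not model the waiting time for new polymorphic targets
  to arise.  At desk scale the growth sequence frequently loses the
  balanced polymorphism beyond two or three targets: small populations
  need strong per-locus selection for storage, and strong selection on a
  growing all-ancestral/all-derived cluster is exactly what pushes its
  alleles to the boundary.  Stage-level failure is reported, never
  papered over; large supergenes are a large-N phenomenon.
* No diploid genotypes, dominance, inversion mechanics, epistasis among
  targets, or stochastic environments.
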