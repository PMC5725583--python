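"""Recombination among the three loci, and its n-locus generalization.

The physical arrangement is recombination-modifier -- plasticity -- target.
A crossover occurs in the modifier--plasticity interval with probability R,
and in the plasticity--target interval with a probability set by the
parental modifier alleles: r1 if both carry r1, r2 if both carry r2, and
the additive heterozygous rate r_c = (r1 + r2) / 2 for mixed pairings.
Crossovers in the two intervals are independent (no interference), which is
what the coefficient structure of the published recursion (terms like
R*r_c and (1-R)*r_c) implies.

Two deterministic operators are provided:

* :func:`apply_recombination` -- the mechanistic operator, derived from
  first principles by averaging the crossover algebra over all ordered
  parent pairs.  This is the source of truth used by every other module.
* :func:`apply_recombination_printed` -- a literal transcription of the
  eight displayed recursion equations, retained purely to cross-validate
  the mechanistic operator.  The transcription preserves the original's
  apparent typographical slips (see :func:`printed_recursion_discrepancies`,
  which documents exactly where and by how much the two disagree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    N_HAPLOTYPES,
    PLASTICITY_ALLELE,
    REC_ALLELE,
    TARGET_ALLELE,
    Haplotype,
    HaplotypeDistribution,
    _check_normalized,
    haplotype_index,
)

__all__ = [
    "RecombinationScheme",
    "recombination_tensor",
    "apply_recombination",
    "apply_recombination_printed",
    "recombine_pair",
    "multilocus_recombine",
    "printed_recursion_discrepancies",
]

DEFAULT_LOCUS_ORDER = ("recombination", "plasticity", "target")


@dataclass(frozen=True)
class RecombinationScheme:
    """Recombination rates of the three-locus system.

    ``r1``/``r2``: plasticity--target rates encoded by the two modifier
    alleles; ``R``: rate between the modifier and the plasticity--target
    sequence.  Heterozygous modifier pairings recombine at the additive
    mean ``r_c``.
    """

    r1: float
    r2: float
    R: float
    locus_order: tuple = field(default=DEFAULT_LOCUS_ORDER)

    def __post_init__(self):
        for name in ("r1", "r2", "R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if tuple(self.locus_order) != DEFAULT_LOCUS_ORDER:
            raise ValueError(
                "three-locus scheme supports only the arrangement "
                f"{DEFAULT_LOCUS_ORDER}; use multilocus_recombine for others"
            )

    @property
    def r_c(self) -> float:
        """Plasticity--target rate for heterozygous modifier pairings."""
        return 0.5 * (self.r1 + self.r2)

    def pair_rate(self, rec_i: int, rec_j: int) -> float:
        """Plasticity--target crossover rate for parental modifier codes."""
        if rec_i == rec_j:
            return self.r2 if rec_i else self.r1
        return self.r_c


def _offspring_indices(i: int, j: int, c1: int, c2: int) -> tuple[int, int]:
    """The reciprocal products of parents i, j under crossover pattern (c1, c2).

    c1 = crossover in the modifier--plasticity interval, c2 = crossover in
    the plasticity--target interval.  Offspring 1 keeps parent i's modifier
    allele; the source chromosome flips at each realized crossover.
    """
    src_plast = j if c1 else i
    src_target = j if (c1 ^ c2) else i
    o1 = haplotype_index(
        REC_ALLELE[i],
        PLASTICITY_ALLELE[src_plast],
        TARGET_ALLELE[src_target],
    )
    src_plast2 = i if c1 else j
    src_target2 = i if (c1 ^ c2) else j
    o2 = haplotype_index(
        REC_ALLELE[j],
        PLASTICITY_ALLELE[src_plast2],
        TARGET_ALLELE[src_target2],
    )
    return int(o1), int(o2)


def recombination_tensor(scheme: RecombinationScheme) -> np.ndarray:
    """(8, 8, 8) tensor T with T[g, i, j] = P(first product is g | parents i, j).

    The deterministic recombination map is the quadratic form
    x''_g = sum_ij T[g, i, j] x_i x_j; because each ordered pair is counted
    both ways, taking the first product only is equivalent to averaging the
    two reciprocal products.
    """
    T = np.zeros((N_HAPLOTYPES, N_HAPLOTYPES, N_HAPLOTYPES))
    R = scheme.R
    for i in range(N_HAPLOTYPES):
        for j in range(N_HAPLOTYPES):
            r = scheme.pair_rate(int(REC_ALLELE[i]), int(REC_ALLELE[j]))
            for c1 in (0, 1):
                p1 = R if c1 else 1.0 - R
                for c2 in (0, 1):
                    p2 = r if c2 else 1.0 - r
                    g, _ = _offspring_indices(i, j, c1, c2)
                    T[g, i, j] += p1 * p2
    return T


def apply_recombination(
    x: HaplotypeDistribution,
    scheme: RecombinationScheme,
    tensor: np.ndarray | None = None,
) -> HaplotypeDistribution:
    """Mechanistic deterministic recombination: expectation over random mating.

    Parents are drawn independently (with replacement) from ``x``; each pair
    recombines per the crossover algebra; the output is the expected
    frequency vector of the products.  Conserves single-locus allele
    frequencies exactly.
    """
    _check_normalized(x.freqs)
    T = recombination_tensor(scheme) if tensor is None else tensor
    out = np.einsum("gij,i,j->g", T, x.freqs, x.freqs)
    return HaplotypeDistribution(out / out.sum(), x.generation)


def recombine_pair(
    parent1: Haplotype,
    parent2: Haplotype,
    scheme: RecombinationScheme,
    rng_draws: tuple[float, float],
) -> tuple[Haplotype, Haplotype]:
    """Stochastic recombination of one parent pair.

    ``rng_draws`` are two uniform variates deciding the crossovers in the
    modifier--plasticity interval (threshold R) and plasticity--target
    interval (threshold r1, r2 or r_c depending on the parental modifier
    alleles).  Returns the two reciprocal products.
    """
    i, j = parent1.index, parent2.index
    u1, u2 = rng_draws
    c1 = int(u1 < scheme.R)
    r = scheme.pair_rate(int(REC_ALLELE[i]), int(REC_ALLELE[j]))
    c2 = int(u2 < r)
    o1, o2 = _offspring_indices(i, j, c1, c2)
    return Haplotype.from_index(o1), Haplotype.from_index(o2)


def multilocus_recombine(
    parent1: np.ndarray,
    parent2: np.ndarray,
    interval_rates: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent crossover per interval on haploid genomes of equal length.

    ``parent1``/``parent2`` are allele arrays over a shared locus order;
    ``interval_rates`` holds one crossover probability per adjacent-locus
    interval (length = n_loci - 1).  Intervals whose rate is under modifier
    control must already carry the pairing-resolved (additive) rate.
    Returns the two reciprocal products.
    """
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError("parental genomes must have identical locus counts")
    rates = np.asarray(interval_rates, dtype=float)
    if rates.shape != (p1.shape[0] - 1,):
        raise ValueError("need exactly one rate per adjacent-locus interval")
    if np.any(rates < 0.0) or np.any(rates > 0.5):
        raise ValueError("interval rates must lie in [0, 0.5]")
    crossovers = rng.random(rates.shape) < rates
    # source[k] = which parent contributes locus k to offspring 1
    source = np.concatenate([[0], np.cumsum(crossovers) % 2])
    o1 = np.where(source == 0, p1, p2)
    o2 = np.where(source == 0, p2, p1)
    return o1, o2


# ---------------------------------------------------------------------------
# Literal transcription of the published eight-equation recursion.
# ---------------------------------------------------------------------------


def _printed_raw(freqs: np.ndarray, scheme: RecombinationScheme) -> np.ndarray:
    """Unnormalized output of the transcribed recursion (see below)."""
    a, b, c, d, e, f, g, h = freqs  # r1ma, r1Ma, r1md, r1Md, r2ma, r2Ma, r2md, r2Md
    r1, r2, R, rc = scheme.r1, scheme.r2, scheme.R, scheme.r_c

    out = np.empty(N_HAPLOTYPES)
    out[0] = (
        a * (1 - g - h - r1 * d - R * f
             + (1 - R - rc + 2 * R * rc) * g + (1 - rc) * (1 - R) * h)
        + b * (r1 * c + R * e + R * rc * g)
        + c * ((R + rc - 2 * R * rc) * e + (1 - R) * rc * f)
        + R * (1 - rc) * d * e
    )
    out[1] = (
        b * (1 - g - h - r1 * c - R * e
             + (1 - R) * (1 - rc) * g + (1 - R - rc + 2 * R * rc) * h)
        + a * (r1 * d + R * f + R * rc * h)
        + R * (1 - rc) * c * f
        + d * ((1 - R) * rc * e + (R + rc - 2 * R * rc) * f)
    )
    out[2] = (
        c * (1 - R * h - e + (R * rc - R - rc) * f
             + (1 - R - rc - 2 * R * rc) * e - r1 * b)
        + a * (r1 * d + (R + rc - 2 * R * rc) * g + (1 - R) * rc * h)
        + R * (1 - rc) * b * g
        + R * d * (rc * e + g)
    )
    out[3] = (
        d * (1 - r1 * a - (R * rc - R - rc) * e
             - (2 * R * rc - R - rc) * f - R * g)
        + R * (1 - rc) * a * h
        + b * (r1 * c + (1 - R) * rc * g + (R + rc - 2 * R * rc) * h)
        + R * c * (rc * f + h)
    )
    out[4] = (
        e * (1 - R * f - (R + rc - R * rc) * d - r2 * h
             - (2 * R * rc - R - rc) * c)
        + a * (R * f + (R + rc - 2 * R * rc) * g + R * (1 - rc) * h)
        + (1 - R) * rc * b * g
        + R * rc * c * f
        + r2 * f * g
    )
    out[5] = (
        f * (1 - R * a - (R * rc - R - rc) * c
             - (2 * R * rc - R - rc) * d - r2 * g)
        + (1 - R) * rc * a * h
        + b * (R * e + R * (1 - rc) * g + (R + rc - 2 * R * rc) * h)
        + e * (R * rc * d + r2 * h)
    )
    out[6] = (
        g * (1 - (2 * R * rc - R - rc) * a - (R * rc - R - rc) * b
             - R * d - r2 * f)
        + R * rc * a * h
        + c * ((R + rc - 2 * R * rc) * e + R * (1 - rc) * f + R * h)
        + e * ((1 - R) * rc * d + r2 * h)
    )
    out[7] = (
        h * (1 - (R * rc - R - rc) * a - (R * rc - R - rc) * b
             - R * c - r2 * e)
        + d * (R * (1 - rc) * e + (R + rc - 2 * R * rc) * f + R * g)
        + g * (r2 * f + R * rc * b)
        + (1 - R) * rc * c * f  # subscript printed as "r1mcd"; read as r1md
    )
    return out


def apply_recombination_printed(
    x: HaplotypeDistribution, scheme: RecombinationScheme
) -> HaplotypeDistribution:
    """Verbatim transcription of the published recombination recursion.

    Kept only as a cross-validation fixture for :func:`apply_recombination`.
    The transcription is faithful to the displayed equations, including
    their apparent typographical slips: an inconsistent sign on a 2*R*r_c
    term in two of the equations, a (R + r_c - R*r_c) coefficient where the
    crossover algebra gives (R + r_c - 2*R*r_c), and one malformed haplotype
    subscript (read here as r1md, the only three-locus haplotype it can
    plausibly denote).  Because of those slips the raw output need not sum
    to one; it is renormalized here.  Use
    :func:`printed_recursion_discrepancies` for the full difference report.
    """
    _check_normalized(x.freqs)
    out = _printed_raw(x.freqs, scheme)
    return HaplotypeDistribution(out / out.sum(), x.generation)


def printed_recursion_discrepancies(
    scheme: RecombinationScheme,
    n_states: int = 1000,
    seed: int = 0,
):
    """Compare the transcribed recursion against the mechanistic operator.

    Evaluates both operators (before renormalization) on ``n_states`` random
    frequency vectors and returns a DataFrame with, per haplotype, the
    maximum and mean absolute difference.  Haplotypes whose printed equation
    is internally consistent with the crossover algebra show differences at
    machine precision; haplotypes affected by the typographical slips show
    O(rate^2) differences.
    """
    import pandas as pd

    from .model import HAPLOTYPES

    rng = np.random.default_rng(seed)
    T = recombination_tensor(scheme)
    diffs = np.zeros((n_states, N_HAPLOTYPES))
    for k in range(n_states):
        x = rng.dirichlet(np.ones(N_HAPLOTYPES))
        mech = np.einsum("gij,i,j->g", T, x, x)
        printed = _printed_raw(x, scheme)
        diffs[k] = np.abs(mech - printed)
    return pd.DataFrame(
        {
            "haplotype": HAPLOTYPES,
            "max_abs_diff": diffs.max(axis=0),
            "mean_abs_diff": diffs.mean(axis=0),
            "matches_mechanistic": diffs.max(axis=0) < 1e-12,
        }
    )
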