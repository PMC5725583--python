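"""Genetic state space and seasonal selection for the genomic storage model.

The model tracks a haploid population at three loci: a recombination
modifier (alleles ``r1``/``r2``, each encoding a recombination rate between
the two selected loci), a plasticity modifier (``m``/``M``), and a target
locus under seasonally oscillating selection (``a``/``d``).  The plasticity
allele ``M`` buffers the seasonal fitness effect at the target locus by a
factor ``1 - p``, which is what allows seasonally disfavoured target alleles
to be "stored" on the plastic background until conditions reverse.

Haplotype fitnesses are

    w(r*, m, a) = 1 - s_t          w(r*, M, a) = 1 - s_t (1 - p)
    w(r*, m, d) = 1 + s_t          w(r*, M, d) = 1 + s_t (1 - p)

with the seasonal effect s_t = s_max * sin(2 pi t / C).  Fitness never
depends on the recombination allele itself; selection on the modifier is
purely indirect, through the haplotypes it becomes associated with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HAPLOTYPES",
    "N_HAPLOTYPES",
    "REC_ALLELE",
    "PLASTICITY_ALLELE",
    "TARGET_ALLELE",
    "EnvironmentalRegime",
    "Haplotype",
    "HaplotypeDistribution",
    "haplotype_index",
    "seasonal_effect",
    "haplotype_fitness",
    "fitness_vector",
    "apply_selection",
    "mean_fitness",
    "rec_allele_frequency",
    "plasticity_allele_frequency",
    "target_allele_frequency",
]

#: Canonical haplotype ordering, fixed project-wide.  All frequency vectors,
#: recombination tensors and Jacobians index haplotypes in this order.
HAPLOTYPES = ("r1ma", "r1Ma", "r1md", "r1Md", "r2ma", "r2Ma", "r2md", "r2Md")
N_HAPLOTYPES = 8

# Per-index allele codes (0/1) in canonical order.
REC_ALLELE = np.array([i >> 2 for i in range(8)], dtype=np.int8)  # 0=r1, 1=r2
TARGET_ALLELE = np.array([(i >> 1) & 1 for i in range(8)], dtype=np.int8)  # 0=a, 1=d
PLASTICITY_ALLELE = np.array([i & 1 for i in range(8)], dtype=np.int8)  # 0=m, 1=M

_NORM_TOL = 1e-9


def haplotype_index(rec: int, plasticity: int, target: int) -> int:
    """Canonical index of the haplotype with the given allele codes.

    ``rec``: 0 for r1, 1 for r2; ``plasticity``: 0 for m, 1 for M;
    ``target``: 0 for a, 1 for d.
    """
    return 4 * rec + 2 * target + plasticity


@dataclass(frozen=True)
class Haplotype:
    """One of the eight three-locus haplotypes."""

    rec_allele: str  # "r1" or "r2"
    plasticity_allele: str  # "m" or "M"
    target_allele: str  # "a" or "d"

    def __post_init__(self):
        if self.rec_allele not in ("r1", "r2"):
            raise ValueError(f"rec_allele must be 'r1' or 'r2', got {self.rec_allele!r}")
        if self.plasticity_allele not in ("m", "M"):
            raise ValueError(
                f"plasticity_allele must be 'm' or 'M', got {self.plasticity_allele!r}"
            )
        if self.target_allele not in ("a", "d"):
            raise ValueError(f"target_allele must be 'a' or 'd', got {self.target_allele!r}")

    @property
    def index(self) -> int:
        return haplotype_index(
            int(self.rec_allele == "r2"),
            int(self.plasticity_allele == "M"),
            int(self.target_allele == "d"),
        )

    @property
    def label(self) -> str:
        return HAPLOTYPES[self.index]

    @classmethod
    def from_index(cls, i: int) -> "Haplotype":
        return cls(
            rec_allele="r2" if REC_ALLELE[i] else "r1",
            plasticity_allele="M" if PLASTICITY_ALLELE[i] else "m",
            target_allele="d" if TARGET_ALLELE[i] else "a",
        )


@dataclass(frozen=True)
class EnvironmentalRegime:
    """Seasonal forcing: maximum effect ``s_max``, period ``C`` (generations),
    plasticity effect ``p`` and an optional phase offset (generations).

    ``phase`` shifts the seasonal clock: the effect at generation ``t`` is
    ``s_max * sin(2 pi (t + phase) / C)``.  The default phase 0 starts runs
    at a season boundary (s_0 = 0); the offset is exposed because the
    starting phase is otherwise an arbitrary convention.
    """

    s_max: float
    period: int
    p: float = 1.0
    phase: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.s_max < 1.0:
            raise ValueError(f"s_max must be in (0, 1), got {self.s_max}")
        if not (isinstance(self.period, (int, np.integer)) and self.period >= 1):
            raise ValueError(f"period must be a positive integer, got {self.period}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"plasticity effect p must be in [0, 1], got {self.p}")

    def seasonal_effect(self, t: float) -> float:
        return seasonal_effect(t, self)

    def fitness_by_phase(self) -> np.ndarray:
        """(C, 8) fitness table: one fitness vector per phase of the cycle."""
        return np.array(
            [fitness_vector(seasonal_effect(t, self), self.p) for t in range(self.period)]
        )


def seasonal_effect(t: float, regime: EnvironmentalRegime) -> float:
    """Signed seasonal selection coefficient s_t = s_max sin(2 pi t / C)."""
    return regime.s_max * math.sin(2.0 * math.pi * (t + regime.phase) / regime.period)


def fitness_vector(s_t: float, p: float) -> np.ndarray:
    """Fitness of the 8 canonical haplotypes at seasonal effect ``s_t``.

    The pattern (1-s, 1-s(1-p), 1+s, 1+s(1-p)) repeats across the two
    recombination-allele classes because fitness ignores the modifier.
    """
    quad = np.array([1.0 - s_t, 1.0 - s_t * (1.0 - p), 1.0 + s_t, 1.0 + s_t * (1.0 - p)])
    return np.concatenate([quad, quad])


def haplotype_fitness(h: Haplotype, s_t: float, p: float) -> float:
    """Fitness of one haplotype; independent of its recombination allele."""
    if abs(s_t) >= 1.0:
        raise ValueError(f"|s_t| must be < 1, got {s_t}")
    return float(fitness_vector(s_t, p)[h.index])


@dataclass
class HaplotypeDistribution:
    """Frequency vector over the 8 haplotypes plus a generation label."""

    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_HAPLOTYPES,):
            raise ValueError(f"freqs must have shape (8,), got {self.freqs.shape}")
        if np.any(self.freqs < -1e-15) or np.any(self.freqs > 1.0 + 1e-12):
            raise ValueError("haplotype frequencies must lie in [0, 1]")
        if abs(self.freqs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"haplotype frequencies must sum to 1 (got {self.freqs.sum():.12g})"
            )

    @classmethod
    def uniform(cls, generation: int = 0) -> "HaplotypeDistribution":
        return cls(np.full(N_HAPLOTYPES, 1.0 / N_HAPLOTYPES), generation)

    @classmethod
    def from_marginals(
        cls,
        freq_r2: float,
        freq_M: float,
        freq_d: float,
        generation: int = 0,
    ) -> "HaplotypeDistribution":
        """Linkage-equilibrium distribution with the given allele frequencies."""
        x = np.empty(N_HAPLOTYPES)
        for i in range(N_HAPLOTYPES):
            x[i] = (
                (freq_r2 if REC_ALLELE[i] else 1.0 - freq_r2)
                * (freq_M if PLASTICITY_ALLELE[i] else 1.0 - freq_M)
                * (freq_d if TARGET_ALLELE[i] else 1.0 - freq_d)
            )
        return cls(x, generation)


def _check_normalized(x: np.ndarray) -> None:
    if abs(float(np.sum(x)) - 1.0) > _NORM_TOL:
        raise ValueError(f"frequency vector not normalized (sum={np.sum(x):.12g})")


def mean_fitness(x: np.ndarray, w: np.ndarray) -> float:
    """Population mean fitness, the normalizer of the selection step."""
    return float(np.dot(x, w))


def apply_selection(
    x: HaplotypeDistribution, regime: EnvironmentalRegime
) -> HaplotypeDistribution:
    """One round of haploid viability selection at the distribution's generation.

    Each frequency is multiplied by its fitness and renormalized by the
    population mean fitness; the generation label is unchanged (selection and
    recombination together make up one generation).
    """
    _check_normalized(x.freqs)
    s_t = seasonal_effect(x.generation, regime)
    w = fitness_vector(s_t, regime.p)
    return HaplotypeDistribution(select(x.freqs, w), x.generation)


def select(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Raw selection update x_g' = x_g w_g / mean(w) on a frequency array."""
    wbar = np.dot(x, w)
    return x * w / wbar


def rec_allele_frequency(x: np.ndarray) -> float:
    """Frequency of the r2 allele (haplotypes 4..7)."""
    return float(np.sum(np.asarray(x)[4:]))


def plasticity_allele_frequency(x: np.ndarray) -> float:
    """Frequency of the plasticity allele M."""
    return float(np.sum(np.asarray(x)[PLASTICITY_ALLELE == 1]))


def target_allele_frequency(x: np.ndarray) -> float:
    """Frequency of the derived target allele d."""
    return float(np.sum(np.asarray(x)[TARGET_ALLELE == 1]))
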