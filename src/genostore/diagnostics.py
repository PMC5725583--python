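"""Cycle diagnostics: linkage disequilibrium, epistasis sign, relative fitness.

The engine of indirect selection on the recombination modifier is the
interplay of epistasis E between the plasticity and target loci (whose sign
flips with the season) and linkage disequilibrium D (which lags behind).
While E*D < 0 the population carries an excess of currently unfit
plasticity-target combinations, and a modifier allele that recombines more
breaks them up faster and hitchhikes upward; once D catches up (E*D > 0)
higher recombination is disfavoured.  These diagnostics make that mechanism
measurable on any trajectory or periodic orbit.

Sign conventions: D is measured on the (M, d) coupling, so an excess of
``Md`` (and hence ``ma``) haplotypes gives D > 0.  Epistasis is measured
multiplicatively, E = w_Md * w_ma - w_Ma * w_md (fitnesses are
multiplicative factors, so a multiplicative interaction scale is natural).
"""

from __future__ import annotations

import numpy as np

from .model import (
    EnvironmentalRegime,
    HaplotypeDistribution,
    PLASTICITY_ALLELE,
    REC_ALLELE,
    TARGET_ALLELE,
    fitness_vector,
    seasonal_effect,
)

__all__ = [
    "linkage_disequilibrium",
    "epistasis",
    "epistasis_sign",
    "relative_fitness_ratio",
    "cycle_diagnostics",
]

_LOCUS_CODES = {
    "rec": REC_ALLELE,
    "plasticity": PLASTICITY_ALLELE,
    "target": TARGET_ALLELE,
}


def linkage_disequilibrium(
    x: HaplotypeDistribution | np.ndarray,
    locus_pair: tuple[str, str] = ("plasticity", "target"),
) -> float:
    """D between two loci: joint derived-allele frequency minus the product
    of marginals.  For the default pair, positive D means an excess of M-d
    (and m-a) combinations; bounded by +/- 0.25.
    """
    freqs = x.freqs if isinstance(x, HaplotypeDistribution) else np.asarray(x)
    c1 = _LOCUS_CODES[locus_pair[0]]
    c2 = _LOCUS_CODES[locus_pair[1]]
    joint = float(freqs[(c1 == 1) & (c2 == 1)].sum())
    return joint - float(freqs[c1 == 1].sum()) * float(freqs[c2 == 1].sum())


def epistasis(s_t: float, p: float) -> float:
    """Multiplicative epistasis between plasticity and target classes.

    E = w_Md * w_ma - w_Ma * w_md = (1 + s(1-p))(1 - s) - (1 - s(1-p))(1 + s),
    which collapses to -2 p s_t: opposite in sign to the seasonal effect,
    vanishing at season boundaries and for p = 0.
    """
    w = fitness_vector(s_t, p)
    # indices: ma=0, Ma=1, md=2, Md=3 within either rec class
    return float(w[3] * w[0] - w[1] * w[2])


def epistasis_sign(
    x: HaplotypeDistribution | None,
    regime: EnvironmentalRegime,
    t: int,
) -> int:
    """Sign of the plasticity-target epistasis at generation t (state-free)."""
    e = epistasis(seasonal_effect(t, regime), regime.p)
    if abs(e) < 1e-15:
        return 0
    return 1 if e > 0 else -1


def relative_fitness_ratio(
    trajectory: np.ndarray,
    regime: EnvironmentalRegime,
    t_start: int = 0,
) -> float:
    """Geometric-mean relative fitness of the r2 class over one full period.

    For a trajectory segment of C+1 consecutive states (rows of an
    (C+1, 8) array; row k is the state at generation t_start + k), returns

        prod_t [ sum_g x_{r2 g, t} w_{g,t} / f_{r2,t} ]
             / [ sum_g x_{r1 g, t} w_{g,t} / f_{r1,t} ]

    i.e. the product over the cycle of the ratio of class mean fitnesses.
    Because recombination conserves the rec-allele marginal, this product
    telescopes to the relative change of f_{r2}/f_{r1} over the cycle:
    > 1 predicts the r2 allele gains on r1, = 1 at a periodic equilibrium.
    Raises if either allele class is absent at any generation.
    """
    traj = np.asarray(trajectory)
    C = regime.period
    if traj.shape[0] < C + 1 or traj.shape[1] != 8:
        raise ValueError(f"need a (C+1, 8) trajectory segment, got {traj.shape}")
    ratio = 1.0
    for k in range(C):
        x = traj[k]
        w = fitness_vector(seasonal_effect(t_start + k, regime), regime.p)
        f1 = float(x[:4].sum())
        f2 = float(x[4:].sum())
        if f1 <= 0.0 or f2 <= 0.0:
            raise ValueError(
                f"recombination allele absent at generation {t_start + k}"
            )
        ratio *= (float(x[4:] @ w[4:]) / f2) / (float(x[:4] @ w[:4]) / f1)
    return ratio


def cycle_diagnostics(trajectory: np.ndarray, regime: EnvironmentalRegime, t_start: int = 0):
    """Per-generation diagnostic series along a trajectory (DataFrame).

    Columns: generation, s_t, D (plasticity-target LD), E (epistasis),
    E_sign, ED_sign, allele frequencies at the three loci, and mean fitness.
    """
    import pandas as pd

    rows = []
    for k, x in enumerate(np.asarray(trajectory)):
        t = t_start + k
        s_t = seasonal_effect(t, regime)
        w = fitness_vector(s_t, regime.p)
        D = linkage_disequilibrium(x)
        E = epistasis(s_t, regime.p)
        ed = E * D
        rows.append(
            {
                "generation": t,
                "s_t": s_t,
                "D": D,
                "E": E,
                "E_sign": int(np.sign(E)) if abs(E) > 1e-15 else 0,
                "ED_sign": int(np.sign(ed)) if abs(ed) > 1e-18 else 0,
                "freq_r2": float(x[4:].sum()),
                "freq_M": float(x[PLASTICITY_ALLELE == 1].sum()),
                "freq_d": float(x[TARGET_ALLELE == 1].sum()),
                "mean_fitness": float(x @ w),
            }
        )
    return pd.DataFrame(rows)
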