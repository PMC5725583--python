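"""Crossover algebra: mechanistic operator, printed recursion, n-locus form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genostore.model import (
    HAPLOTYPES,
    PLASTICITY_ALLELE,
    REC_ALLELE,
    TARGET_ALLELE,
    Haplotype,
    HaplotypeDistribution,
)
from genostore.recombination import (
    RecombinationScheme,
    apply_recombination,
    apply_recombination_printed,
    multilocus_recombine,
    printed_recursion_discrepancies,
    recombination_tensor,
    recombine_pair,
)


def _h(label):
    return Haplotype.from_index(HAPLOTYPES.index(label))


rates = st.floats(0.0, 0.5, allow_nan=False)


class TestDeterministicOperator:
    def test_zero_rates_identity(self, rng):
        scheme = RecombinationScheme(0.0, 0.0, 0.0)
        x = HaplotypeDistribution(rng.dirichlet(np.ones(8)))
        out = apply_recombination(x, scheme)
        assert np.allclose(out.freqs, x.freqs, atol=1e-15)

    @given(r1=rates, r2=rates, R=rates, seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_conserves_single_locus_allele_frequencies(self, r1, r2, R, seed):
        scheme = RecombinationScheme(r1, r2, R)
        x = HaplotypeDistribution(np.random.default_rng(seed).dirichlet(np.ones(8)))
        out = apply_recombination(x, scheme)
        for codes in (REC_ALLELE, PLASTICITY_ALLELE, TARGET_ALLELE):
            assert out.freqs[codes == 1].sum() == pytest.approx(
                x.freqs[codes == 1].sum(), abs=1e-14
            )

    @given(r1=rates, r2=rates, R=rates,
           fr=st.floats(0.01, 0.99), fM=st.floats(0.01, 0.99), fd=st.floats(0.01, 0.99))
    @settings(max_examples=150, deadline=None)
    def test_identity_on_linkage_equilibrium(self, r1, r2, R, fr, fM, fd):
        scheme = RecombinationScheme(r1, r2, R)
        x = HaplotypeDistribution.from_marginals(fr, fM, fd)
        out = apply_recombination(x, scheme)
        assert np.allclose(out.freqs, x.freqs, atol=1e-12)

    @pytest.mark.parametrize("r1", [0.0, 0.1, 0.37, 0.5])
    @pytest.mark.parametrize("R", [0.0, 0.5])
    def test_two_locus_ld_decay_oracle(self, r1, R, rng):
        """Monomorphic rec locus: D between plasticity and target decays by
        exactly (1 - r) per round, the classical two-locus recursion."""
        scheme = RecombinationScheme(r1, r1, R)
        marg = rng.dirichlet(np.ones(4))
        fM = marg[1] + marg[3]
        fd = marg[2] + marg[3]
        x4 = np.array(
            [(1 - fM) * (1 - fd), fM * (1 - fd), (1 - fM) * fd, fM * fd]
        )
        D0 = 0.11 * min(fM * (1 - fd), (1 - fM) * fd)
        x4 = x4 + D0 * np.array([1.0, -1.0, -1.0, 1.0])  # couple m-a with M-d
        x = HaplotypeDistribution(np.concatenate([x4, np.zeros(4)]))
        out = apply_recombination(x, scheme)
        D1 = out.freqs[3] - (out.freqs[1] + out.freqs[3]) * (out.freqs[2] + out.freqs[3])
        assert D1 == pytest.approx((1.0 - r1) * D0, abs=1e-14)

    def test_tensor_rows_are_distributions(self):
        T = recombination_tensor(RecombinationScheme(0.2, 0.4, 0.3))
        assert np.allclose(T.sum(axis=0), 1.0)
        assert np.all(T >= 0)


class TestRecombinePair:
    def test_identical_parents_unchanged(self):
        scheme = RecombinationScheme(0.3, 0.4, 0.5)
        h = _h("r2Md")
        for draws in [(0.0, 0.0), (0.99, 0.0), (0.0, 0.99), (0.99, 0.99)]:
            o1, o2 = recombine_pair(h, h, scheme, draws)
            assert o1 == h and o2 == h

    def test_forced_plasticity_target_crossover(self):
        # u1 >= R blocks the first interval; u2 < r1 forces the second
        scheme = RecombinationScheme(0.3, 0.3, 0.5)
        o1, o2 = recombine_pair(_h("r1ma"), _h("r1Md"), scheme, (0.9, 0.0))
        assert {o1.label, o2.label} == {"r1md", "r1Ma"}

    def test_forced_double_crossover_heterozygous_pair(self):
        # both intervals cross over: plasticity swaps, target swaps back
        scheme = RecombinationScheme(0.2, 0.4, 0.5)
        o1, o2 = recombine_pair(_h("r1ma"), _h("r2Md"), scheme, (0.0, 0.0))
        assert (o1.label, o2.label) == ("r1Ma", "r2md")

    def test_all_four_crossover_configurations(self):
        """Hand enumeration for r1ma x r2Md against the operator.

        The modifier allele never leaves its chromosome; the plasticity
        segment swaps on a first-interval crossover; the target segment
        swaps when exactly one of the two intervals crosses over.
        """
        scheme = RecombinationScheme(0.2, 0.4, 0.5)
        expected = {
            (False, False): ("r1ma", "r2Md"),
            (True, False): ("r1Md", "r2ma"),  # whole tail swaps
            (False, True): ("r1md", "r2Ma"),  # target segment only
            (True, True): ("r1Ma", "r2md"),  # target returns to its own side
        }
        for (c1, c2), (e1, e2) in expected.items():
            u1 = 0.1 if c1 else 0.9
            u2 = 0.1 if c2 else 0.9
            o1, o2 = recombine_pair(_h("r1ma"), _h("r2Md"), scheme, (u1, u2))
            assert (o1.label, o2.label) == (e1, e2)

    def test_monte_carlo_matches_deterministic_operator(self, rng):
        """Averaging the stochastic pair operator over many draws reproduces
        the deterministic expectation on a two-haplotype state."""
        scheme = RecombinationScheme(0.1, 0.4, 0.3)
        x = np.zeros(8)
        ia, ib = HAPLOTYPES.index("r1ma"), HAPLOTYPES.index("r2Md")
        x[ia] = 0.6
        x[ib] = 0.4
        n = 200_000
        parents = rng.choice([ia, ib], size=(n, 2), p=[0.6, 0.4])
        draws = rng.random((n, 2))
        counts = np.zeros(8)
        for (i, j), (u1, u2) in zip(parents, draws):
            o1, o2 = recombine_pair(
                Haplotype.from_index(i), Haplotype.from_index(j), scheme, (u1, u2)
            )
            counts[o1.index] += 0.5
            counts[o2.index] += 0.5
        emp = counts / n
        exact = apply_recombination(HaplotypeDistribution(x), scheme).freqs
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n)
        assert np.all(np.abs(emp - exact) < 5 * se + 1e-9)


class TestPrintedRecursion:
    def test_matches_mechanistic_at_zero_rates(self, rng):
        scheme = RecombinationScheme(0.0, 0.0, 0.0)
        for _ in range(20):
            x = HaplotypeDistribution(rng.dirichlet(np.ones(8)))
            a = apply_recombination(x, scheme).freqs
            b = apply_recombination_printed(x, scheme).freqs
            assert np.allclose(a, b, atol=1e-14)

    def test_discrepancy_report_flags_known_typos(self):
        """The transcribed equations for r1ma and r1Ma are internally
        consistent with the crossover algebra; the remaining six carry
        typographical slips and must be flagged, not silently patched."""
        report = printed_recursion_discrepancies(
            RecombinationScheme(0.13, 0.37, 0.29), n_states=1000, seed=1
        )
        matches = dict(zip(report["haplotype"], report["matches_mechanistic"]))
        assert matches["r1ma"] and matches["r1Ma"]
        assert not any(
            matches[h] for h in ("r1md", "r1Md", "r2ma", "r2Ma", "r2md", "r2Md")
        )

    def test_monomorphic_r1_class_agrees(self, rng):
        """With only r1-carrying haplotypes the slips (all in cross-class
        terms) are inert for the r1ma/r1Ma rows, and both operators reduce
        to the two-locus recursion."""
        scheme = RecombinationScheme(0.25, 0.4, 0.35)
        x4 = rng.dirichlet(np.ones(4))
        x = HaplotypeDistribution(np.concatenate([x4, np.zeros(4)]))
        a = apply_recombination(x, scheme).freqs
        b = apply_recombination_printed(x, scheme).freqs
        assert np.allclose(a[:2], b[:2], atol=1e-14)
        D0 = x4[3] - (x4[1] + x4[3]) * (x4[2] + x4[3])
        D1 = a[3] - (a[1] + a[3]) * (a[2] + a[3])
        assert D1 == pytest.approx(0.75 * D0, abs=1e-14)


class _FakeRng:
    """Deterministic stand-in for a Generator: yields preset uniforms."""

    def __init__(self, values):
        self._values = np.asarray(values, dtype=float)

    def random(self, shape):
        assert self._values.shape == shape
        return self._values


class TestMultilocusRecombine:
    def test_zero_rates_identity(self, rng):
        p1 = np.array([0, 1, 1, 0], dtype=np.int8)
        p2 = np.array([1, 0, 0, 1], dtype=np.int8)
        o1, o2 = multilocus_recombine(p1, p2, np.zeros(3), rng)
        assert np.array_equal(o1, p1) and np.array_equal(o2, p2)

    def test_forced_single_crossover_exchanges_suffix(self):
        p1 = np.array([0, 0, 0, 0])
        p2 = np.array([1, 1, 1, 1])
        fake = _FakeRng([0.9, 0.1, 0.9])  # only interval 1 crosses over
        o1, o2 = multilocus_recombine(p1, p2, np.array([0.5, 0.5, 0.5]), fake)
        assert np.array_equal(o1, [0, 0, 1, 1])
        assert np.array_equal(o2, [1, 1, 0, 0])

    def test_marginal_recombinant_fraction(self, rng):
        """Two loci at rate r: recombinant products appear with frequency r."""
        p1 = np.array([0, 0])
        p2 = np.array([1, 1])
        r = 0.3
        n = 20_000
        recombinant = 0
        for _ in range(n):
            o1, _ = multilocus_recombine(p1, p2, np.array([r]), rng)
            recombinant += o1[0] != o1[1]
        se = np.sqrt(r * (1 - r) / n)
        assert abs(recombinant / n - r) < 4 * se

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            multilocus_recombine(np.zeros(3), np.zeros(4), np.zeros(2), rng)

    def test_reciprocal_products_conserve_alleles(self, rng):
        p1 = rng.integers(0, 2, size=6)
        p2 = rng.integers(0, 2, size=6)
        o1, o2 = multilocus_recombine(p1, p2, np.full(5, 0.5), rng)
        assert np.array_equal(np.sort([*o1, *o2]), np.sort([*p1, *p2]))
        for k in range(6):
            assert {o1[k], o2[k]} == {p1[k], p2[k]}
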