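"""Rank correlation, length reconciliation, and the paralog-pair comparison."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nucdup.genome_model import GeneModel
from nucdup.occupancy import FragmentSet
from nucdup.profile_similarity import (
    RESAMPLE_MIN,
    TRUNCATE_MIN,
    compare_paralog_pair,
    fractional_ranks,
    resample_to_length,
    spearman_rho,
)


def d2_closed_form_exact(x, y):
    """No-ties Spearman via 1 - 6*sum(d^2)/(n(n^2-1)), in exact rationals."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return Fraction(1) - Fraction(6 * d2, n * (n * n - 1))


class TestFractionalRanks:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 9], [1.5, 1.5, 3]),
            ([7, 7, 7], [2, 2, 2]),
        ],
    )
    def test_tie_averaging(self, values, expected):
        assert fractional_ranks(values).tolist() == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fractional_ranks([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=30))
    def test_rank_sum_is_triangular(self, values):
        n = len(values)
        assert fractional_ranks(values).sum() == pytest.approx(n * (n + 1) / 2)


class TestSpearmanRho:
    def test_identity_is_one(self):
        x = [3, 1, 4, 1, 5]
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_worked_example(self):
        # Pearson-of-ranks on ranks (1,2,3) vs (3,1,2)
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_constant_input_is_undefined(self):
        assert spearman_rho([1, 2, 3], [7, 7, 7]) is None
        assert spearman_rho([4, 4, 4], [1, 2, 3]) is None

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 2"):
            spearman_rho([1], [2])

    def test_matches_exact_closed_form_without_ties(self):
        for n in (3, 4, 5):
            x = list(range(1, n + 1))
            for perm in itertools.permutations(x):
                expected = d2_closed_form_exact(x, list(perm))
                assert spearman_rho(x, list(perm)) == pytest.approx(
                    float(expected), abs=1e-12
                )

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 5, n)
            y = rng.integers(0, 5, n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            ref = scipy.stats.spearmanr(x, y).statistic
            assert spearman_rho(x, y) == pytest.approx(ref, abs=1e-12)


vectors = st.lists(st.integers(0, 20), min_size=2, max_size=40).filter(
    lambda v: len(set(v)) > 1
)


class TestSpearmanProperties:
    @settings(derandomize=True, max_examples=150)
    @given(vectors, vectors)
    def test_symmetry(self, x, y):
        if len(x) != len(y):
            x, y = x[: min(len(x), len(y))], y[: min(len(x), len(y))]
            if len(set(x)) < 2 or len(set(y)) < 2 or len(x) < 2:
                return
        assert spearman_rho(x, y) == pytest.approx(spearman_rho(y, x), abs=1e-15)

    @settings(derandomize=True, max_examples=150)
    @given(vectors)
    def test_monotone_transform_invariance_and_antisymmetry(self, x):
        """rho depends on ranks only, so strictly increasing transforms leave it
        unchanged; negation of distinct values gives exactly -1 against itself."""
        y = list(reversed(x))
        if len(set(y)) < 2:
            return
        base = spearman_rho(x, y)
        fx = [v**3 + 2 * v for v in x]  # strictly increasing on ints
        assert spearman_rho(fx, y) == pytest.approx(base, abs=1e-12)
        if len(set(x)) == len(x):
            assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)


class TestResample:
    @pytest.mark.parametrize(
        "counts, target, expected",
        [
            ([0, 2, 4], 3, [0, 2, 4]),
            ([0, 4], 3, [0, 2, 4]),
            ([1, 1, 1, 1], 7, [1] * 7),
        ],
    )
    def test_linear_interpolation(self, counts, target, expected):
        assert resample_to_length(counts, target).tolist() == pytest.approx(expected)

    def test_target_too_small(self):
        with pytest.raises(ValueError):
            resample_to_length([1, 2, 3], 1)


def _translated_copy_fixture(shift=10_000, strand_b="+"):
    """Gene B's locus is an exact translated copy of gene A's landscape."""
    gene_a = GeneModel("A", "c", "+", 2000, 3000)
    frags_a = [("c", s, s + 147) for s in range(900, 2900, 100)]
    if strand_b == "+":
        gene_b = GeneModel("B", "c", "+", 2000 + shift, 3000 + shift)
        frags_b = [("c", s + shift, e + shift) for c, s, e in frags_a]
    else:
        # reflect A's landscape onto B's locus: pivot - A.end == B.start
        pivot = 3000 + (2000 + shift)
        gene_b = GeneModel("B", "c", "-", 2000 + shift, 3000 + shift)
        frags_b = [("c", pivot - e, pivot - s) for c, s, e in frags_a]
    return gene_a, gene_b, FragmentSet(frags_a + frags_b)


class TestComparePair:
    @pytest.mark.parametrize("strand_b", ["+", "-"])
    def test_translated_copy_gives_perfect_correlation(self, strand_b):
        gene_a, gene_b, frags = _translated_copy_fixture(strand_b=strand_b)
        pair = compare_paralog_pair(gene_a, gene_b, frags)
        assert pair.promoter_rho == pytest.approx(1.0)
        assert pair.coding_rho == pytest.approx(1.0)
        assert pair.resampled is False
        assert (pair.promoter_n, pair.coding_n) == (1000, 1000)

    def test_zero_fragments_at_one_locus_is_undefined(self):
        gene_a = GeneModel("A", "c", "+", 2000, 3000)
        gene_b = GeneModel("B", "c", "+", 20000, 21000)
        frags = FragmentSet([("c", s, s + 147) for s in range(900, 2900, 120)])
        pair = compare_paralog_pair(gene_a, gene_b, frags)
        assert pair.promoter_rho is None and pair.coding_rho is None
        assert pair.promoter_reason == "constant profile"
        assert pair.coding_reason == "constant profile"

    @pytest.mark.parametrize("policy", [RESAMPLE_MIN, TRUNCATE_MIN])
    def test_unequal_coding_lengths_are_reconciled(self, policy):
        gene_a = GeneModel("A", "c", "+", 2000, 3000)
        gene_b = GeneModel("B", "c", "+", 20000, 21500)  # 1500 bp coding
        frags = FragmentSet(
            [("c", s, s + 147) for s in range(900, 2950, 90)]
            + [("c", s, s + 147) for s in range(18900, 21450, 90)]
        )
        pair = compare_paralog_pair(gene_a, gene_b, frags, length_policy=policy)
        assert pair.resampled is True
        assert pair.coding_n == 1000  # min of the two coding lengths
        assert pair.coding_rho is not None
        assert pair.length_policy == policy
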