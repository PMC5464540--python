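"""Rank statistics and partial redundancy analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from viroprod.series import DuplicateSummary
from viroprod.stats import (
    kruskal_wallis,
    mann_whitney,
    range_overlap_difference,
    rda_variation_partition,
    resolve_below_detection,
    spearman,
)


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)

    def test_below_detection_resolves_to_zero(self):
        r0, _ = spearman([1, 2, 3, None], [4, 3, 2, 0.0])
        r1, _ = spearman([1, 2, 3, 0.0], [4, 3, 2, 0.0])
        assert r0 == pytest.approx(r1)

    def test_exact_enumeration_agrees_with_t_approximation(self):
        """At n=5 the exact permutation p and the t-approximation must agree
        in the rejection decision at alpha = 0.05."""
        cases = [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]),
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]),
            ([1, 2, 3, 4, 5], [3, 1, 4, 2, 5]),
        ]
        for x, y in cases:
            _, p_exact = spearman(x, y, exact=True)
            _, p_approx = spearman(x, y)
            assert (p_exact <= 0.05) == (p_approx <= 0.05), (x, y, p_exact, p_approx)

    def test_exact_p_for_perfect_rank_agreement(self):
        # 2/120 orderings reach |r| = 1 at n = 5
        _, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], exact=True)
        assert p == pytest.approx(2 / 120)

    @given(
        hst.lists(
            hst.tuples(
                hst.integers(min_value=0, max_value=50),
                hst.integers(min_value=0, max_value=50),
            ),
            min_size=4, max_size=12,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_monotone_invariance(self, pairs):
        x = [float(a) for a, _ in pairs]
        y = [float(b) for _, b in pairs]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r_xy, _ = spearman(x, y)
        r_yx, _ = spearman(y, x)
        assert r_xy == pytest.approx(r_yx)
        r_t, _ = spearman([np.exp(v / 10) for v in x], y)
        assert r_t == pytest.approx(r_xy)

    def test_input_contract(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            resolve_below_detection([1.0], nd_policy="interpolate")


class TestMannWhitney:
    def test_identical_samples_not_rejected(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9

    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0

    @given(
        hst.lists(hst.floats(min_value=0, max_value=1), min_size=2, max_size=8,
                  unique=True),
    )
    @settings(deadline=None, max_examples=50)
    def test_u_statistics_sum_without_ties(self, values):
        k = len(values) // 2
        a, b = values[:k], values[k:]
        if not a or not b:
            return
        ra = np.asarray(a)[:, None] > np.asarray(b)[None, :]
        u_a = ra.sum()  # brute-force count of winning pairs
        res = mann_whitney(a, b)
        assert res.U == min(u_a, len(a) * len(b) - u_a)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-9)

    def test_h_matches_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        # direct formula on ranks 1..6, no ties
        n = 6
        rank_sums = [1 + 2, 3 + 4, 5 + 6]
        h = 12 / (n * (n + 1)) * sum(
            rs**2 / 2 for rs in rank_sums
        ) - 3 * (n + 1)
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(h)
        assert len(res.posthoc) == 3  # all pairs get a U test

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])


class TestRangeOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1.5, 1, 2), (3.5, 3, 4), True),
            ((2.0, 1, 3), (3.0, 2, 4), False),
            ((1.5, 1, 2), (2.5, 2, 3), False),  # touching endpoints overlap
        ],
    )
    def test_relevant_difference_rule(self, a, b, expected):
        assert (
            range_overlap_difference(DuplicateSummary(*a), DuplicateSummary(*b))
            is expected
        )


class TestVariationPartitioning:
    def test_exact_linear_response_fully_explained(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        Y = X @ rng.normal(size=(2, 3))
        part = rda_variation_partition(Y, X, n_perm=99, seed=0)
        assert part.total_explained == pytest.approx(1.0)
        assert part.residual == pytest.approx(0.0, abs=1e-10)
        assert part.p_total <= 0.05

    def test_null_noise_not_significant(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(50, 2))
        X = rng.normal(size=(50, 3))
        part = rda_variation_partition(Y, X, n_perm=499, seed=1)
        assert part.total_explained < 0.25
        assert part.p_total > 0.05

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(20, 2))
        X = 0.5 * Z @ rng.normal(size=(2, 3)) + rng.normal(size=(20, 3))
        Y = (
            X @ rng.normal(size=(3, 2))
            + Z @ rng.normal(size=(2, 2))
            + rng.normal(size=(20, 2)) * 2
        )
        part = rda_variation_partition(Y, X, Z, n_perm=99, seed=0)
        assert part.fractions_sum() == pytest.approx(1.0)

    def test_matches_vegan_reference_partition(self):
        """Frozen cross-check against vegan::rda/RsquareAdj on the same
        seeded fixture (r-base 4.3, vegan 2.7)."""
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(20, 2))
        X = 0.5 * Z @ rng.normal(size=(2, 3)) + rng.normal(size=(20, 3))
        Y = (
            X @ rng.normal(size=(3, 2))
            + Z @ rng.normal(size=(2, 2))
            + rng.normal(size=(20, 2)) * 2
        )
        part = rda_variation_partition(Y, X, Z, n_perm=9, seed=0)
        assert part.total_explained == pytest.approx(0.6950559, abs=1e-6)
        assert part.unique_explanatory == pytest.approx(0.06563123, abs=1e-6)
        assert part.conditional == pytest.approx(0.202238, abs=1e-6)
        assert part.shared == pytest.approx(0.4271866, abs=1e-6)

    def test_permutation_p_reproducible_and_seed_sensitive(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(30, 2))
        X = rng.normal(size=(30, 2))
        p1 = rda_variation_partition(Y, X, n_perm=199, seed=5).p_total
        p2 = rda_variation_partition(Y, X, n_perm=199, seed=5).p_total
        assert p1 == p2
        part_b = rda_variation_partition(Y, X, n_perm=199, seed=5, bootstrap=True)
        assert 0 < part_b.p_total <= 1

    def test_rank_deficiency_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 1))
        X = np.hstack([X, X])  # duplicated column
        Y = rng.normal(size=(10, 2))
        part = rda_variation_partition(Y, X, n_perm=19, seed=0)
        assert part.rank_deficient
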