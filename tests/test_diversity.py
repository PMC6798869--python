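"""Diversity indices and individual-based floral rarefaction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from leafcensus import pielou, rank_abundance, rarefy_species, richness, shannon
from oracles import expected_richness, species_memberships, variance_richness


class TestIndices:
    def test_richness_counts_positive_entries(self):
        assert richness([0, 0, 3]) == 1
        assert richness([]) == 0

    def test_richness_rejects_negative(self):
        with pytest.raises(ValueError):
            richness([1, -1])

    def test_shannon_closed_forms(self):
        assert shannon([7]) == 0.0
        assert shannon([3] * 10) == pytest.approx(math.log(10))
        assert shannon([5, 3, 2]) == pytest.approx(1.029653, abs=1e-6)

    def test_shannon_all_zero_is_error(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_pielou_closed_forms(self):
        assert pielou([4, 4, 4]) == pytest.approx(1.0)
        assert pielou([5, 3, 2]) == pytest.approx(1.029653 / math.log(3),
                                                  abs=1e-6)

    def test_pielou_published_identity(self):
        """J = H/ln S reproduces a published 2-decimal evenness value."""
        h, s = 1.72, 17  # pooled level with 17 species
        assert round(h / math.log(s), 2) == 0.61

    def test_pielou_single_species_undefined(self):
        with pytest.raises(ValueError):
            pielou([9])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2,
                    max_size=12))
    def test_shannon_bounded_by_log_richness(self, counts):
        h = shannon(counts)
        assert h <= math.log(richness(counts)) + 1e-12
        if len(set(counts)) == 1:
            assert h == pytest.approx(math.log(len(counts)))


class TestRankAbundance:
    def test_descending_proportions(self):
        ranked = rank_abundance({"a": 20, "b": 50, "c": 30})
        assert [r[0] for r in ranked] == ["b", "c", "a"]
        assert [r[1] for r in ranked] == pytest.approx([0.5, 0.3, 0.2])

    def test_single_species(self):
        assert rank_abundance({"x": 8}) == [("x", 1.0)]

    def test_dominant_species_share(self):
        """A strongly dominated sample: 128 of 229 leaves -> 0.559."""
        ranked = rank_abundance({"dominant": 128, "other": 101})
        assert ranked[0][1] == pytest.approx(128 / 229, abs=1e-9)
        assert round(ranked[0][1], 3) == 0.559

    def test_ties_broken_lexicographically(self):
        ranked = rank_abundance({"b": 5, "a": 5, "c": 1})
        assert [r[0] for r in ranked] == ["a", "b", "c"]

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            rank_abundance({"a": 0})


class TestRarefySpecies:
    def test_full_sample_is_exact(self):
        counts = [4, 3, 1]
        curve = rarefy_species(counts, sizes=[8], n_resamples=200, seed=0)
        assert curve.mean_richness[0] == 3
        assert curve.lower95[0] == curve.upper95[0] == 3

    def test_single_individual_mean_one(self):
        curve = rarefy_species([5, 2, 9], sizes=[1], n_resamples=100, seed=1)
        assert curve.mean_richness[0] == 1

    def test_two_of_three_enumeration(self):
        """counts [2,1] at m=2: 3 equally likely pairs -> E[S] = 5/3."""
        n_resamples = 4000
        curve = rarefy_species([2, 1], sizes=[2], n_resamples=n_resamples,
                               seed=3)
        se = math.sqrt((2 / 9) / n_resamples)  # Var(S) = 2/9 by enumeration
        assert abs(curve.mean_richness[0] - 5 / 3) < 3 * se

    def test_size_above_total_is_error(self):
        with pytest.raises(ValueError):
            rarefy_species([2, 1], sizes=[4])

    def test_monte_carlo_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            counts = rng.integers(0, 8, size=rng.integers(2, 6))
            if counts.sum() < 2:
                continue
            total = int(counts.sum())
            sizes = sorted({1, max(total // 2, 1), total})
            n_res = 1000
            curve = rarefy_species(counts, sizes=sizes, n_resamples=n_res,
                                   seed=int(rng.integers(2**31)))
            members = species_memberships(counts)
            for j, m in enumerate(sizes):
                exp = expected_richness(members, total, m)
                var = variance_richness(members, total, m)
                if var == 0:
                    assert curve.mean_richness[j] == pytest.approx(exp)
                else:
                    se = math.sqrt(var / n_res)
                    assert abs(curve.mean_richness[j] - exp) < 3 * se

    def test_permutation_invariance(self):
        a = rarefy_species([5, 1, 3], sizes=[2, 5, 9], n_resamples=500, seed=4)
        b = rarefy_species([3, 5, 1], sizes=[2, 5, 9], n_resamples=500, seed=4)
        np.testing.assert_allclose(a.mean_richness, b.mean_richness)

    def test_curve_invariants(self):
        curve = rarefy_species([10, 6, 3, 1], n_resamples=300, seed=5)
        assert np.all(curve.lower95 <= curve.mean_richness)
        assert np.all(curve.mean_richness <= curve.upper95)
        assert np.all(np.diff(curve.mean_richness) >= -1e-12)
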