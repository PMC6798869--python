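"""Damage frequency, specialization ratio, and damage-type rarefaction."""

import math

import numpy as np
import pytest

from leafcensus import (
    damage_frequency,
    damage_summary,
    per_host_curves,
    rarefy_dts,
    spec_gen_ratio,
)
from leafcensus.io import DTInfo

from conftest import make_census, make_record
from oracles import expected_richness, variance_richness

GEN = {"DT1": DTInfo("DT1", "hole feeding", "generalized"),
       "DT2": DTInfo("DT2", "skeletonization", "generalized"),
       "DT5": DTInfo("DT5", "mining", "specialized"),
       "DT6": DTInfo("DT6", "galling", "specialized")}


def leaves_with(dt_sets, tally=None):
    return [make_record(specimen=f"s{i}", dts=d,
                        tally=(tally[i] if tally else 1))
            for i, d in enumerate(dt_sets)]


class TestDamageFrequency:
    def test_undamaged_census_is_zero_everywhere(self):
        leaves = leaves_with([set(), set(), set()])
        for cat in ("total", "specialized", "generalized"):
            assert damage_frequency(leaves, GEN, cat) == 0.0

    def test_simple_proportion(self):
        leaves = leaves_with([{"DT1"}, {"DT5"}] + [set()] * 6)
        assert damage_frequency(leaves, GEN, "total") == pytest.approx(0.25)

    def test_leaf_counts_once_per_category(self):
        leaves = leaves_with([{"DT1", "DT2"}, set()])
        assert damage_frequency(leaves, GEN, "generalized") == pytest.approx(0.5)

    def test_tally_batches_enter_denominator(self):
        leaves = leaves_with([{"DT1"}]) + [make_record(specimen="t", tally=3)]
        assert damage_frequency(leaves, GEN, "total") == pytest.approx(0.25)

    def test_tally_split_invariance(self):
        batched = leaves_with([{"DT1"}]) + [make_record(specimen="t", tally=5)]
        split = leaves_with([{"DT1"}]) + [
            make_record(specimen=f"t{i}") for i in range(5)]
        for cat in ("total", "specialized", "generalized"):
            assert (damage_frequency(batched, GEN, cat)
                    == damage_frequency(split, GEN, cat))

    def test_empty_unit_is_error(self):
        with pytest.raises(ValueError):
            damage_frequency([], GEN, "total")

    def test_unregistered_dt_is_mapping_error(self):
        leaves = leaves_with([{"DT99"}])
        with pytest.raises(KeyError):
            damage_frequency(leaves, GEN, "total")

    def test_category_inequalities_on_mixed_unit(self):
        leaves = leaves_with([{"DT1"}, {"DT5"}, {"DT1", "DT6"}, set(), set()])
        tot = damage_frequency(leaves, GEN, "total")
        spec = damage_frequency(leaves, GEN, "specialized")
        gen = damage_frequency(leaves, GEN, "generalized")
        assert spec <= tot <= spec + gen
        assert gen <= tot


class TestSpecGenRatio:
    def test_simple_ratio(self):
        leaves = leaves_with([{"DT5"}] * 3 + [{"DT1"}] * 6 + [set()])
        assert spec_gen_ratio(leaves, GEN) == pytest.approx(0.5)

    def test_zero_specialized(self):
        leaves = leaves_with([{"DT1"}, set()])
        assert spec_gen_ratio(leaves, GEN) == 0.0

    def test_no_generalized_is_undefined_flag(self):
        leaves = leaves_with([{"DT5"}, set()])
        assert spec_gen_ratio(leaves, GEN) is None


class TestRarefyDTs:
    def test_all_undamaged_curve_is_zero(self):
        leaves = leaves_with([set()] * 6)
        curve = rarefy_dts(leaves, GEN, sizes=[1, 3, 6], n_resamples=100,
                           seed=0)
        assert np.all(curve.mean_richness == 0)
        assert np.all(curve.upper95 == 0)

    def test_three_leaf_enumeration(self):
        """{DT1,DT2}, {DT1}, {} at m=2: pairs give richness 2,2,1 -> 5/3."""
        leaves = leaves_with([{"DT1", "DT2"}, {"DT1"}, set()])
        n_res = 4000
        curve = rarefy_dts(leaves, GEN, sizes=[2], n_resamples=n_res, seed=1)
        se = math.sqrt((2 / 9) / n_res)  # Var by the same enumeration
        assert abs(curve.mean_richness[0] - 5 / 3) < 3 * se

    def test_full_draw_is_exact_and_zero_width(self):
        leaves = leaves_with([{"DT1", "DT5"}, {"DT2"}, set(), set()])
        curve = rarefy_dts(leaves, GEN, sizes=[4], n_resamples=50, seed=2)
        assert curve.mean_richness[0] == 3
        assert curve.lower95[0] == curve.upper95[0] == 3

    def test_size_above_leaf_count_is_error(self):
        with pytest.raises(ValueError):
            rarefy_dts(leaves_with([set()]), GEN, sizes=[2])

    def test_specialized_never_exceeds_all(self):
        rng = np.random.default_rng(3)
        dts = list(GEN)
        sets = [set(rng.choice(dts, size=rng.integers(0, 3), replace=False))
                for _ in range(12)]
        leaves = leaves_with(sets)
        sizes = [2, 6, 12]
        a = rarefy_dts(leaves, GEN, "all", sizes, n_resamples=400, seed=7)
        s = rarefy_dts(leaves, GEN, "specialized", sizes, n_resamples=400,
                       seed=7)
        assert np.all(s.mean_richness <= a.mean_richness + 1e-12)

    def test_monte_carlo_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(11)
        dts = list(GEN)
        for _ in range(8):
            n = int(rng.integers(4, 12))
            sets = [set(rng.choice(dts, size=rng.integers(0, 3),
                                   replace=False)) for _ in range(n)]
            leaves = leaves_with(sets)
            observed = sorted({d for s in sets for d in s})
            members = [{i for i, s in enumerate(sets) if d in s}
                       for d in observed]
            m = int(rng.integers(1, n + 1))
            n_res = 1000
            curve = rarefy_dts(leaves, GEN, sizes=[m], n_resamples=n_res,
                               seed=int(rng.integers(2**31)))
            exp = expected_richness(members, n, m)
            var = variance_richness(members, n, m)
            if var == 0:
                assert curve.mean_richness[0] == pytest.approx(exp)
            else:
                assert abs(curve.mean_richness[0] - exp) < 3 * math.sqrt(
                    var / n_res)


class TestPerHostCurves:
    def _census(self, n_a, n_b):
        recs = ([make_record(specimen=f"a{i}", species="hostA",
                             dts={"DT1"} if i % 4 == 0 else set())
                 for i in range(n_a)]
                + [make_record(specimen=f"b{i}", species="hostB")
                   for i in range(n_b)])
        return make_census(recs)

    def test_threshold_excludes_19_includes_20(self):
        census = self._census(20, 19)
        curves = per_host_curves(census, "L1", min_leaves=20,
                                 n_resamples=50, seed=0)
        assert set(curves) == {"hostA"}

    def test_tally_counts_reach_threshold(self):
        recs = [make_record(specimen="t", species="hostA", tally=20)]
        curves = per_host_curves(make_census(recs), "L1", min_leaves=20,
                                 n_resamples=50, seed=0)
        assert set(curves) == {"hostA"}

    def test_shared_host_yields_comparable_curves_in_two_units(self):
        recs = ([make_record(specimen=f"c{i}", quarry="C", level="C",
                             species="shared",
                             dts={"DT1"} if i % 3 == 0 else set())
                 for i in range(25)]
                + [make_record(specimen=f"e{i}", quarry="E", level="E",
                               species="shared") for i in range(22)])
        census = make_census(recs)
        curves_c = per_host_curves(census, "C", n_resamples=50, seed=0)
        curves_e = per_host_curves(census, "E", n_resamples=50, seed=0)
        assert "shared" in curves_c and "shared" in curves_e


def test_damage_summary_consistency():
    leaves = leaves_with([{"DT1"}, {"DT5"}, {"DT1", "DT6"}, set(), set()])
    s = damage_summary("U", leaves, GEN)
    assert s.n_leaves == 5
    assert s.freq_total == damage_frequency(leaves, GEN, "total")
    assert s.dt_richness_total == 3
    assert s.dt_richness_specialized == 2
    assert s.freq_specialized <= s.freq_total <= (s.freq_specialized
                                                  + s.freq_generalized)
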