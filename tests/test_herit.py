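"""Heritability estimators: midparent slope, variance components, H²(h²)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pupastat.herit import (broad_sense_h2, expected_H2_additive,
                            midparent_regression, single_parent_regression)
from pupastat.synth import (GeneticArchitecture, TrioTable,
                            simulate_trio_cohort)


def trio_table(mother, father, offspring_by_cross):
    n = len(mother)
    crosses = pd.DataFrame({
        "cross_id": np.arange(n),
        "mother_len_mm": mother,
        "father_len_mm": father,
        "vial_id": [f"V{i}" for i in range(n)],
        "vial_density": 60,
    })
    rows = [(i, v) for i, offs in enumerate(offspring_by_cross) for v in offs]
    offspring = pd.DataFrame(rows, columns=["cross_id", "offspring_len_mm"])
    return TrioTable(crosses, offspring)


class TestMidparentRegression:
    def test_offspring_identical_to_midparent_slope_one(self):
        rng = np.random.default_rng(0)
        mother = rng.normal(3.4, 0.2, 40)
        father = rng.normal(3.4, 0.2, 40)
        trios = trio_table(mother, father, [[v] for v in (mother + father) / 2])
        est = midparent_regression(trios)
        assert est.slope == pytest.approx(1.0, abs=1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_offspring_slope_near_zero(self):
        rng = np.random.default_rng(1)
        trios = trio_table(rng.normal(3.4, 0.2, 200),
                           rng.normal(3.4, 0.2, 200),
                           [[v] for v in rng.normal(3.4, 0.2, 200)])
        assert abs(midparent_regression(trios).slope) < 0.15

    def test_individual_and_vial_mean_modes_agree(self):
        arch = GeneticArchitecture.polygenic(h2=0.44)
        cohort = simulate_trio_cohort(arch, 300, seed=21)
        vm = midparent_regression(cohort.trios, "vial_mean")
        ind = midparent_regression(cohort.trios, "individual")
        assert vm.slope == pytest.approx(ind.slope, abs=0.05)

    def test_study_scale_cohort_matches_reported_precision(self):
        # 363 crosses at h2 = 0.44: slope lands near truth with R² ~ 0.3
        arch = GeneticArchitecture.polygenic(h2=0.44)
        cohort = simulate_trio_cohort(arch, 363, seed=2)
        est = midparent_regression(cohort.trios)
        assert est.slope == pytest.approx(0.44, abs=0.10)
        assert 0.15 <= est.r2 <= 0.50
        assert est.se == pytest.approx(0.04, abs=0.02)

    def test_too_few_trios_rejected(self):
        trios = trio_table([3.3, 3.5], [3.4, 3.6], [[3.4], [3.5]])
        with pytest.raises(ValueError):
            midparent_regression(trios)

    def test_zero_midparent_variance_rejected(self):
        trios = trio_table([3.4] * 5, [3.4] * 5, [[3.3]] * 5)
        with pytest.raises(ValueError):
            midparent_regression(trios)


class TestSingleParentRegression:
    def test_offspring_copy_mother(self):
        rng = np.random.default_rng(3)
        mother = rng.normal(3.4, 0.2, 50)
        trios = trio_table(mother, rng.normal(3.4, 0.2, 50),
                           [[v] for v in mother])
        est = single_parent_regression(trios, "mother")
        assert est.slope == pytest.approx(1.0, abs=1e-9)

    def test_additive_cohort_gives_half_h2_for_each_parent(self):
        arch = GeneticArchitecture.polygenic(h2=0.5)
        slopes_m, slopes_f = [], []
        for seed in range(8):
            cohort = simulate_trio_cohort(arch, 400, seed=seed)
            slopes_m.append(single_parent_regression(cohort.trios, "mother").slope)
            slopes_f.append(single_parent_regression(cohort.trios, "father").slope)
        assert np.mean(slopes_m) == pytest.approx(0.25, abs=0.05)
        assert np.mean(slopes_f) == pytest.approx(0.25, abs=0.05)

    def test_maternal_effect_detected_as_asymmetry(self):
        rng = np.random.default_rng(4)
        mother = rng.normal(3.4, 0.2, 300)
        father = rng.normal(3.4, 0.2, 300)
        offspring = 3.4 + 0.6 * (mother - 3.4) + rng.normal(0, 0.1, 300)
        trios = trio_table(mother, father, [[v] for v in offspring])
        m = single_parent_regression(trios, "mother").slope
        f = single_parent_regression(trios, "father").slope
        assert m > f + 0.3

    def test_unknown_parent_rejected(self):
        trios = trio_table([3.3, 3.4, 3.5], [3.4, 3.5, 3.6],
                           [[3.4], [3.5], [3.6]])
        with pytest.raises(ValueError):
            single_parent_regression(trios, "uncle")


class TestBroadSenseH2:
    # hand-worked one-way ANOVA oracle, frozen before implementation:
    # lines A=[3.0,3.1,3.2,3.3], B=[3.5,3.6,3.7,3.8], C=[3.2,3.2,3.4,3.4]
    # SS_between = 0.5266667, MS_between = 0.2633333, MS_within = 0.0155556
    # n0 = 4, sigma2_between = 0.0619444, H2 = 0.7992825, F = 16.9285714
    TOY = pd.DataFrame({
        "ril_id": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        "vial_id": [f"v{i}" for i in range(12)],
        "vial_mean_mm": [3.0, 3.1, 3.2, 3.3, 3.5, 3.6, 3.7, 3.8,
                         3.2, 3.2, 3.4, 3.4],
    })

    def test_matches_hand_computed_anova(self):
        vc = broad_sense_h2(self.TOY, min_reps=3)
        assert vc.SS_between == pytest.approx(0.5266667, abs=1e-6)
        assert vc.MS_between == pytest.approx(0.2633333, abs=1e-6)
        assert vc.sigma2_within == pytest.approx(0.0155556, abs=1e-6)
        assert vc.n0 == pytest.approx(4.0)
        assert vc.sigma2_between == pytest.approx(0.0619444, abs=1e-6)
        assert vc.H2 == pytest.approx(0.7992825, abs=1e-6)
        assert vc.F == pytest.approx(16.9285714, abs=1e-6)
        assert (vc.df_between, vc.df_within) == (2, 9)

    def test_F_and_p_agree_with_independent_oneway(self):
        groups = [g["vial_mean_mm"].to_numpy()
                  for _, g in self.TOY.groupby("ril_id")]
        ref = stats.f_oneway(*groups)
        vc = broad_sense_h2(self.TOY, min_reps=3)
        assert vc.F == pytest.approx(ref.statistic)
        assert vc.p_value == pytest.approx(ref.pvalue)

    def test_equal_line_means_truncate_to_zero(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "ril_id": np.repeat([f"R{i}" for i in range(10)], 4),
            "vial_mean_mm": 3.4 + rng.normal(0, 0.05, 40),
        })
        vc = broad_sense_h2(df)
        assert vc.H2 < 0.3
        if vc.sigma2_between == 0:
            assert vc.truncated

    def test_zero_within_variance_gives_H2_one(self):
        df = pd.DataFrame({
            "ril_id": ["A"] * 3 + ["B"] * 3,
            "vial_mean_mm": [3.2] * 3 + [3.6] * 3,
        })
        vc = broad_sense_h2(df)
        assert vc.H2 == 1.0

    def test_min_reps_filter_applied(self):
        extra = pd.DataFrame({"ril_id": ["D", "D"], "vial_id": ["x", "y"],
                              "vial_mean_mm": [9.0, 9.1]})
        vc = broad_sense_h2(pd.concat([self.TOY, extra]), min_reps=3)
        assert vc.n_lines == 3  # D has only 2 replicates

    def test_unbalanced_design_n0(self):
        df = pd.DataFrame({
            "ril_id": ["A"] * 3 + ["B"] * 5,
            "vial_mean_mm": [3.1, 3.2, 3.3, 3.5, 3.6, 3.7, 3.8, 3.6],
        })
        vc = broad_sense_h2(df)
        # n0 = (N - sum(n_i^2)/N) / (k-1) = (8 - 34/8) / 1
        assert vc.n0 == pytest.approx(8 - 34 / 8)

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            broad_sense_h2(self.TOY[self.TOY["ril_id"] == "A"])


class TestExpectedH2Additive:
    @pytest.mark.parametrize("h2,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundary_values(self, h2, expected):
        assert expected_H2_additive(h2) == expected

    def test_table_value_at_0_44(self):
        assert round(expected_H2_additive(0.44), 2) == 0.61

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(h2=st.floats(0.01, 0.99))
    def test_monotone_and_at_least_h2(self, h2):
        assert expected_H2_additive(h2) >= h2
        assert expected_H2_additive(min(1.0, h2 + 0.01)) > expected_H2_additive(h2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_H2_additive(1.2)
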