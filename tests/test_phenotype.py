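"""Trait summaries, t-tests, ANOVA/Tukey, dosage trend and qPCR."""

import math

import numpy as np
import pandas as pd
import pytest

from triadkit import phenotype, simulate
from triadkit.phenotype import (
    anova_tukey,
    dosage_trend,
    group_summary,
    percent_change,
    plant_trait_means,
    qpcr_relative_expression,
    students_t_test,
)


class TestPlantTraitMeans:
    def test_mean_over_spikes(self):
        df = pd.DataFrame(
            {
                "plant_id": ["p1"] * 3,
                "genotype": ["AABBDD"] * 3,
                "spike": [1, 2, 3],
                "width": [3.6, 3.7, 3.8],
                "length": [6.0, 6.1, 6.2],
                "area": [16.0, 16.1, 16.2],
                "tgw": [40.0, 41.0, 42.0],
            }
        )
        means = plant_trait_means(df)
        assert means.loc[0, "width"] == pytest.approx(3.7)
        assert means.loc[0, "tgw"] == pytest.approx(41.0)

    def test_single_spike_identity(self):
        df = pd.DataFrame(
            {
                "plant_id": ["p1"],
                "genotype": ["AABBDD"],
                "spike": [1],
                "width": [3.5],
                "length": [6.0],
                "area": [16.0],
                "tgw": [40.0],
            }
        )
        assert plant_trait_means(df).loc[0, "width"] == 3.5

    def test_missing_value_excluded_per_trait(self):
        df = pd.DataFrame(
            {
                "plant_id": ["p1"] * 2,
                "genotype": ["AABBDD"] * 2,
                "spike": [1, 2],
                "width": [3.5, np.nan],
                "length": [6.0, 6.2],
                "area": [16.0, 16.2],
                "tgw": [40.0, 41.0],
            }
        )
        means = plant_trait_means(df)
        assert means.loc[0, "width"] == 3.5
        assert means.loc[0, "length"] == pytest.approx(6.1)

    def test_recovers_generator_plant_means(self):
        cfg = simulate.SimConfig(
            seed=1, n_plants=10,
            spike_sd={t: 0.0 for t in simulate.TRAITS},
        )
        sim = simulate.gen_phenotype_table(cfg)
        means = plant_trait_means(sim.table)
        # zero spike noise: plant means equal every spike value
        merged = sim.table.merge(means, on=["plant_id", "genotype"], suffixes=("", "_m"))
        assert np.allclose(merged.width, merged.width_m)


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled variance 1, t = -1/sqrt(2/3)
        res = students_t_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.2879, abs=1e-4)

    def test_degenerate_zero_variance(self):
        equal = students_t_test([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0 and equal.degenerate
        unequal = students_t_test([2.0, 2.0], [3.0, 3.0])
        assert unequal.p == 0.0 and unequal.degenerate

    def test_null_rejection_rate_nominal(self):
        """Type I error of the t-test on generator nulls stays near alpha."""
        effects = {g: {t: 0.0 for t in simulate.TRAITS} for g in "ABD"}
        rejections = 0
        n_reps = 1000
        rng = np.random.default_rng(42)
        for _ in range(n_reps):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            if students_t_test(x, y).p < 0.05:
                rejections += 1
        assert abs(rejections / n_reps - 0.05) < 0.02


class TestGroupSummary:
    def _plant_means(self):
        rng = np.random.default_rng(0)
        rows = []
        for code, base in (("AABBDD", 3.62), ("AAbbDD", 3.70)):
            for i in range(12):
                rows.append(
                    {
                        "plant_id": f"{code}-{i}",
                        "genotype": code,
                        "width": base + rng.normal(0, 0.02),
                        "length": 6.2,
                        "area": 16.0,
                        "tgw": 40.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_reference_group_zero_pct_change(self):
        summ = group_summary(self._plant_means(), "AABBDD")
        ref = summ[(summ.genotype == "AABBDD") & (summ.trait == "width")]
        assert ref["pct_change"].iloc[0] == 0.0

    def test_percent_change_from_printed_means(self):
        assert round(percent_change(3.70, 3.62), 2) == 2.21
        assert round(percent_change(6.12, 6.27), 2) == -2.39

    def test_se_is_sd_over_sqrt_n(self):
        summ = group_summary(self._plant_means(), "AABBDD")
        row = summ[(summ.genotype == "AAbbDD") & (summ.trait == "width")].iloc[0]
        grp = self._plant_means()
        vals = grp[grp.genotype == "AAbbDD"].width
        assert row.se == pytest.approx(vals.std(ddof=1) / math.sqrt(len(vals)))

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            group_summary(self._plant_means(), "aabbdd")


class TestAnovaTukey:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=9)
        res = anova_tukey({"x": x, "y": y})
        t = students_t_test(x, y)
        assert res.f == pytest.approx(t.t**2, rel=1e-10)

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, size=6) for i in range(4)}
        res = anova_tukey(groups)
        # independent oracle: explicit SS decomposition
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f = (ss_between / 3) / (ss_within / (len(allv) - 4))
        assert res.f == pytest.approx(f, abs=1e-10)

    def test_null_gives_large_p(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(0, 1, size=30) for i in range(3)}
        res = anova_tukey(groups)
        assert res.p > 0.01

    def test_all_identical_flagged_degenerate(self):
        res = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.degenerate and math.isnan(res.f)

    def test_tukey_table_has_all_pairs(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(size=5) for i in range(4)}
        res = anova_tukey(groups)
        assert len(res.tukey) == 6


class TestDosageTrend:
    def test_signs_follow_programmed_effects(self):
        cfg = simulate.SimConfig(seed=6, n_plants=400)
        sim = simulate.gen_phenotype_table(cfg)
        means = plant_trait_means(sim.table)
        summaries, trend = dosage_trend(means)
        # more functional copies -> narrower, longer grain, lower TGW
        t = trend.set_index("trait")
        assert t.loc["width", "direction"] == -1
        assert t.loc["length", "direction"] == 1
        assert t.loc["tgw", "direction"] == -1

    def test_single_genotype_single_group(self):
        cfg = simulate.SimConfig(seed=7, n_plants=10)
        sim = simulate.gen_phenotype_table(cfg, ["AAbbdd"] * 10)
        means = plant_trait_means(sim.table)
        summaries, trend = dosage_trend(means)
        assert set(summaries.functional_copies) == {2}
        assert trend.direction.eq(0).all()

    def test_null_effects_no_significant_trend(self):
        effects = {g: {t: 0.0 for t in simulate.TRAITS} for g in "ABD"}
        sig = 0
        for rep in range(20):
            cfg = simulate.SimConfig(seed=100 + rep, n_plants=60, effect_sizes=effects)
            sim = simulate.gen_phenotype_table(cfg)
            _, trend = dosage_trend(plant_trait_means(sim.table))
            sig += int((trend.p_value < 0.05).any())
        assert sig <= 8  # 4 traits at alpha 0.05 over 20 null replicates


class TestQpcr:
    def test_calibrated_fold_change(self):
        assert qpcr_relative_expression(10, 5, calibrator=(11, 5)) == pytest.approx(2.0)

    def test_sample_equal_calibrator_is_one(self):
        assert qpcr_relative_expression(9, 4, calibrator=(9, 4)) == pytest.approx(1.0)

    def test_ddct_three_gives_eighth(self):
        assert qpcr_relative_expression(10, 5, calibrator=(7, 5)) == pytest.approx(0.125)

    def test_uncalibrated_reports_dct_only(self):
        assert qpcr_relative_expression(8, 5) == pytest.approx(2.0**-3)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            qpcr_relative_expression(float("nan"), 5)
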