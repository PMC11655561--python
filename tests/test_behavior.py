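"""Freezing inclusion rule, mixed ANOVA, Tukey HSD and power analysis."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from engramap.behavior import (
    FreezingRecord,
    PowerSpec,
    endpoint_anova,
    exclusion_filter,
    records_to_frame,
    rm_anova,
    rm_anova_power,
    rm_anova_sample_size,
    tukey_hsd,
    tukey_posthoc_groups,
)

from .conftest import make_freezing_frame
from .oracles import brute_anova_f


def _records(rows):
    return records_to_frame(
        [FreezingRecord(a, g, p, v) for a, g, p, v in rows]
    )


class TestExclusionFilter:
    def test_threshold_is_strict(self):
        df = _records(
            [
                ("a1", "g", "reactivation", 37.0),
                ("a2", "g", "reactivation", 37.1),
                ("a3", "g", "reactivation", 80.0),
            ]
        )
        res = exclusion_filter(df, threshold=37.0)
        assert res.excluded == ["a1"]
        assert res.retained == ["a2", "a3"]

    def test_empty_cohort(self):
        res = exclusion_filter(pd.DataFrame(columns=["animal_id", "group", "phase", "percent_freezing"]))
        assert res.retained == [] and res.excluded == []

    def test_missing_reactivation_record_names_animal(self):
        df = _records([("a1", "g", "test", 50.0), ("a2", "g", "reactivation", 50.0)])
        with pytest.raises(ValueError, match="a1"):
            exclusion_filter(df)

    def test_record_value_range_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            FreezingRecord("a", "g", "test", 101.0)


class TestRmAnova:
    def test_pure_group_effect_toy_table(self):
        """2 groups x 2 subjects x 2 days, G1 all 10, G2 all 20."""
        rows = []
        for a, g, v in [("s1", "g1", 10), ("s2", "g1", 10), ("s3", "g2", 20), ("s4", "g2", 20)]:
            rows += [(a, g, "reactivation", v), (a, g, "test", v)]
        res = rm_anova(_records(rows))
        assert res.effects["group"].ss == pytest.approx(200.0)
        assert res.effects["phase"].ss == pytest.approx(0.0)
        assert res.effects["interaction"].ss == pytest.approx(0.0)
        # zero error with a nonzero effect -> the stated degenerate convention
        assert res.effects["group"].p == 0.0
        assert res.effects["phase"].F == 0.0 and res.effects["phase"].p == 1.0

    def test_all_equal_observations(self):
        rows = [(f"s{i}", f"g{i % 2}", p, 42.0) for i in range(4) for p in ("reactivation", "test")]
        res = rm_anova(_records(rows))
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        df = make_freezing_frame(
            ["g1", "g2", "g3"], 5,
            {g: {"training-post": 30, "reactivation": 60, "test": 50} for g in ["g1", "g2", "g3"]},
            sd=8.0, rng=rng,
        )
        shifted = df.copy()
        shifted["percent_freezing"] = shifted["percent_freezing"] * 0.3 + 10  # stay in range
        base = df.copy()
        base["percent_freezing"] = base["percent_freezing"] * 0.3
        r1, r2 = rm_anova(base), rm_anova(shifted)
        for name in ("group", "phase", "interaction"):
            assert r1.effects[name].F == pytest.approx(r2.effects[name].F, rel=1e-9)

    def test_unbalanced_phases_list_offenders(self):
        rows = [("s1", "g1", "reactivation", 10), ("s1", "g1", "test", 12),
                ("s2", "g2", "reactivation", 11)]
        with pytest.raises(ValueError, match="s2"):
            rm_anova(_records(rows))

    def test_ss_decomposition_closes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k, n, m = rng.integers(2, 5), rng.integers(2, 6), rng.integers(2, 5)
            df = make_freezing_frame(
                [f"g{i}" for i in range(k)], int(n),
                {f"g{i}": {p: rng.uniform(20, 80) for p in ("a", "b", "c", "d")[:m]} for i in range(k)},
                sd=10.0, rng=rng, phases=("a", "b", "c", "d")[:m],
            )
            res = rm_anova(df)
            t = res.ss_table.set_index("source")["ss"]
            parts = (
                t["group"] + t["subjects-within-groups"] + t["phase"]
                + t["group:phase"] + t["phase-by-subjects-within-groups"]
            )
            assert parts == pytest.approx(t["total"], rel=1e-9)

    def test_group_f_equals_one_way_on_subject_means(self):
        rng = np.random.default_rng(4)
        df = make_freezing_frame(
            ["g1", "g2", "g3"], 6,
            {"g1": {"reactivation": 40, "test": 50}, "g2": {"reactivation": 55, "test": 60},
             "g3": {"reactivation": 45, "test": 52}},
            sd=9.0, rng=rng, phases=("reactivation", "test"),
        )
        res = rm_anova(df)
        subj = df.groupby(["animal_id", "group"])["percent_freezing"].mean().reset_index()
        groups = [sub["percent_freezing"].to_numpy() for _, sub in subj.groupby("group")]
        F_oracle, _, _ = brute_anova_f(groups)
        assert res.effects["group"].F == pytest.approx(F_oracle, rel=1e-9)

    def test_matches_pingouin_mixed_anova(self):
        rng = np.random.default_rng(5)
        df = make_freezing_frame(
            ["g1", "g2"], 6,
            {"g1": {"training-post": 30, "reactivation": 60, "test": 55},
             "g2": {"training-post": 32, "reactivation": 62, "test": 35}},
            sd=7.0, rng=rng,
        )
        res = rm_anova(df)
        aov = pg.mixed_anova(
            data=df, dv="percent_freezing", within="phase", between="group", subject="animal_id"
        ).set_index("Source")
        assert res.effects["group"].F == pytest.approx(aov.loc["group", "F"], rel=1e-6)
        assert res.effects["phase"].F == pytest.approx(aov.loc["phase", "F"], rel=1e-6)
        assert res.effects["interaction"].F == pytest.approx(aov.loc["Interaction", "F"], rel=1e-6)
        assert res.effects["group"].p == pytest.approx(aov.loc["group", "p_unc"], rel=1e-6)


class TestTukeyHsd:
    def test_identical_means_give_p_one(self):
        groups = {"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0], "c": [5.0, 5.0, 5.0]}
        res = tukey_hsd(groups, error_mean_square=2.0, error_df=6)
        assert np.allclose(res["p_adj"], 1.0)

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        mse = (np.var(a, ddof=1) * 5 + np.var(b, ddof=1) * 5) / 10
        res = tukey_hsd({"a": a, "b": b}, error_mean_square=mse, error_df=10)
        _, p_t = stats.ttest_ind(a, b)
        assert res["p_adj"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_three_groups_match_monte_carlo_studentized_range(self):
        """Adjusted p agrees with a 1e5-draw studentized-range simulation."""
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(mu, 2.0, 6) for g, mu in [("a", 0.0), ("b", 1.5), ("c", 3.0)]}
        arr = list(groups.values())
        mse = np.mean([np.var(x, ddof=1) for x in arr])
        df_err = 15
        res = tukey_hsd(groups, error_mean_square=mse, error_df=df_err).set_index(["group_1", "group_2"])
        z = rng.standard_normal((100_000, 3))
        s = np.sqrt(rng.chisquare(df_err, 100_000) / df_err)
        q_null = (z.max(axis=1) - z.min(axis=1)) / s
        for (ga, gb), row in res.iterrows():
            p_mc = float(np.mean(q_null > row["q_stat"]))
            assert row["p_adj"] == pytest.approx(p_mc, abs=0.01)

    def test_zero_error_term_conventions(self):
        res = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]}, error_mean_square=0.0, error_df=2)
        assert res["p_adj"].iloc[0] == 0.0
        res = tukey_hsd({"a": [1.0, 1.0], "b": [1.0, 1.0]}, error_mean_square=0.0, error_df=2)
        assert res["p_adj"].iloc[0] == 1.0

    def test_posthoc_wrapper_uses_subject_means(self):
        rng = np.random.default_rng(3)
        df = make_freezing_frame(
            ["g1", "g2", "g3"], 6,
            {"g1": {"reactivation": 40, "test": 42}, "g2": {"reactivation": 60, "test": 62},
             "g3": {"reactivation": 41, "test": 43}},
            sd=5.0, rng=rng, phases=("reactivation", "test"),
        )
        res = tukey_posthoc_groups(df)
        assert len(res) == 3
        strong = res[(res.group_1 == "g1") & (res.group_2 == "g2")]["p_adj"].iloc[0]
        weak = res[(res.group_1 == "g1") & (res.group_2 == "g3")]["p_adj"].iloc[0]
        assert strong < 0.05 < weak


class TestPower:
    def test_null_effect_limit_recovers_alpha(self):
        spec = PowerSpec(f=1e-9, alpha=0.05, k=6, m=3, rho=0.5)
        assert rm_anova_power(spec, 36) == pytest.approx(0.05, abs=1e-4)

    def test_power_increases_with_n_and_f(self):
        spec = PowerSpec(f=0.4, k=4, m=3, rho=0.5)
        powers = [rm_anova_power(spec, N) for N in range(8, 80, 4)]
        assert np.all(np.diff(powers) > 0)
        powers_f = [rm_anova_power(PowerSpec(f=f, k=4, m=3, rho=0.5), 40) for f in (0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(powers_f) > 0)

    def test_sample_size_monotone_nonincreasing_in_f(self):
        sizes = [
            rm_anova_sample_size(PowerSpec(f=f, k=6, m=3, rho=0.5)) for f in (0.3, 0.58, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_achieved_power_at_returned_n_meets_target(self):
        spec = PowerSpec(f=0.58, alpha=0.05, power=0.8, k=6, m=3, rho=0.5)
        N = rm_anova_sample_size(spec)
        assert rm_anova_power(spec, N) >= 0.8
        assert rm_anova_power(spec, N - spec.k) < 0.8  # minimality

    def test_huge_effect_hits_degrees_of_freedom_floor(self):
        # smallest multiple of k with df2 = N - k >= 1 is 2k
        spec = PowerSpec(f=10.0, k=6, m=3, rho=0.5)
        assert rm_anova_sample_size(spec) == 12

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            PowerSpec(f=0.0)
        with pytest.raises(ValueError):
            PowerSpec(f=0.5, alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(f=0.5, rho=1.0)
        with pytest.raises(ValueError):
            PowerSpec(f=0.5, k=1)
        with pytest.raises(ValueError):
            rm_anova_sample_size(PowerSpec(f=0.5), group_multiple=5)


class TestEndpointAnova:
    def test_identical_groups(self):
        res = endpoint_anova({"a": [3, 3, 3], "b": [3, 3, 3]})
        assert res.F == 0.0

    def test_hand_example(self):
        res = endpoint_anova({"a": (2, 3, 7), "b": (6, 8, 10)})
        assert res.F == pytest.approx(24 / (22 / 4))

    def test_type_i_error_calibrated_under_null(self):
        """Three null groups, 500 cohorts: rejection rate ~ alpha."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_cohorts = 500
        for _ in range(n_cohorts):
            groups = {g: rng.normal(50, 10, 8) for g in "abc"}
            rejections += endpoint_anova(groups).p < 0.05
        assert rejections / n_cohorts == pytest.approx(0.05, abs=0.02)
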