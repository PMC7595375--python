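import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posturelab.anova import (
    UnbalancedDesignError,
    normalize_outcomes,
    rm_anova_1way,
    rm_anova_2way,
    simple_contrasts,
    single_level_posthoc,
)

from oracles import brute_force_rm1, brute_force_rm2, long_table


def random_table(n, a, b, seed=0, effects=True):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=(n, a, b))
    if effects:
        y += rng.normal(scale=1.0, size=(1, a, 1))
        y += rng.normal(scale=0.5, size=(1, 1, b))
        y += rng.normal(scale=0.8, size=(n, 1, 1))
    return y


class TestRmAnova2Way:
    @pytest.mark.parametrize("n,a,b,seed", [(3, 2, 2, 1), (5, 3, 4, 2), (9, 4, 4, 3)])
    def test_matches_brute_force_oracle(self, n, a, b, seed):
        y = random_table(n, a, b, seed)
        res = rm_anova_2way(long_table(y))
        oracle = brute_force_rm2(y)
        for effect, key in [("visual", "A"), ("platform", "B"), ("visual * platform", "AB")]:
            row = res.row(effect)
            err = res.row(f"Residual ({effect})")
            assert row["ss"] == pytest.approx(oracle[key]["ss"], rel=1e-9)
            assert row["df"] == oracle[key]["df"]
            assert err["ss"] == pytest.approx(oracle[key]["ss_err"], rel=1e-9)
            assert err["df"] == oracle[key]["df_err"]
            assert row["F"] == pytest.approx(oracle[key]["F"], rel=1e-9)
            assert row["p"] == pytest.approx(oracle[key]["p"], rel=1e-9)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        y = random_table(6, 3, 4, seed=9)
        df = long_table(y)
        res = rm_anova_2way(df)
        sm = AnovaRM(
            df, depvar="value", subject="subject", within=["visual", "platform"]
        ).fit()
        tbl = sm.anova_table
        assert res.row("visual")["F"] == pytest.approx(
            tbl.loc["visual", "F Value"], rel=1e-8
        )
        assert res.row("platform")["F"] == pytest.approx(
            tbl.loc["platform", "F Value"], rel=1e-8
        )
        assert res.row("visual * platform")["F"] == pytest.approx(
            tbl.loc["visual:platform", "F Value"], rel=1e-8
        )

    def test_table1_df_structure_9_subjects_4x4(self):
        y = random_table(9, 4, 4, seed=4)
        res = rm_anova_2way(long_table(y))
        assert res.row("visual")["df"] == 3
        assert res.row("Residual (visual)")["df"] == 24
        assert res.row("platform")["df"] == 3
        assert res.row("Residual (platform)")["df"] == 24
        assert res.row("visual * platform")["df"] == 9
        assert res.row("Residual (visual * platform)")["df"] == 72

    def test_identical_outcomes_zero_effect_ss(self):
        y = np.full((4, 3, 3), 2.5)
        res = rm_anova_2way(long_table(y))
        for effect in ("visual", "platform", "visual * platform"):
            assert res.row(effect)["ss"] == pytest.approx(0.0, abs=1e-12)
            assert np.isnan(res.row(effect)["F"])

    def test_ss_decomposition_exact(self):
        y = random_table(7, 3, 2, seed=5)
        res = rm_anova_2way(long_table(y))
        total = float(np.sum((y - y.mean()) ** 2))
        parts = res.table["ss"].sum()
        assert parts == pytest.approx(total, rel=1e-9)

    def test_f_invariant_to_affine_outcome_transform(self):
        y = random_table(5, 3, 3, seed=6)
        f0 = rm_anova_2way(long_table(y)).row("visual")["F"]
        f1 = rm_anova_2way(long_table(3.7 * y + 11.0)).row("visual")["F"]
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_eta_squared_is_ss_over_total(self):
        y = random_table(6, 4, 4, seed=8)
        res = rm_anova_2way(long_table(y))
        total = res.table["ss"].sum()
        row = res.row("platform")
        assert row["eta_sq"] == pytest.approx(row["ss"] / total, rel=1e-9)

    def test_missing_cell_rejected(self):
        df = long_table(random_table(4, 2, 2, seed=1)).iloc[:-1]
        with pytest.raises(UnbalancedDesignError, match="balanced"):
            rm_anova_2way(df)

    def test_duplicate_cell_rejected(self):
        df = long_table(random_table(4, 2, 2, seed=1))
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(UnbalancedDesignError):
            rm_anova_2way(df)

    def test_single_subject_rejected(self):
        df = long_table(random_table(1, 2, 2, seed=1))
        with pytest.raises(UnbalancedDesignError, match="2 subjects"):
            rm_anova_2way(df)

    def test_greenhouse_geisser_epsilon_range(self):
        y = random_table(8, 4, 3, seed=10)
        res = rm_anova_2way(long_table(y), greenhouse_geisser=True)
        for effect, k in [("visual", 4), ("platform", 3)]:
            eps = res.gg_epsilon[effect]
            assert 1.0 / (k - 1) - 1e-9 <= eps <= 1.0 + 1e-9
            # GG-corrected p can only grow
            assert res.row(effect)["p"] >= rm_anova_2way(long_table(y)).row(effect)["p"]


class TestRmAnova1Way:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(9, 4)) + rng.normal(scale=1.0, size=(1, 4))
        df = pd.DataFrame(
            [
                {"subject": f"S{s}", "visual": f"A{i}", "value": y[s, i]}
                for s in range(9)
                for i in range(4)
            ]
        )
        res = rm_anova_1way(df, within="visual")
        oracle = brute_force_rm1(y)
        assert res.row("visual")["ss"] == pytest.approx(oracle["ss"], rel=1e-9)
        assert res.row("visual")["F"] == pytest.approx(oracle["F"], rel=1e-9)
        assert res.row("visual")["df"] == 3
        assert res.row("Residual (visual)")["df"] == 24

    def test_two_levels_equals_paired_t(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(12, 2))
        df = pd.DataFrame(
            [
                {"subject": f"S{s}", "visual": f"A{i}", "value": y[s, i]}
                for s in range(12)
                for i in range(2)
            ]
        )
        res = rm_anova_1way(df, within="visual")
        t = stats.ttest_rel(y[:, 0], y[:, 1])
        assert res.row("visual")["F"] == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.row("visual")["p"] == pytest.approx(t.pvalue, rel=1e-9)


class TestSimpleContrasts:
    def test_identical_levels_zero_estimate(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        df = pd.DataFrame(
            [
                {"subject": f"S{s}", "visual": lvl, "value": base[s] + (0.5 if lvl == "C" else 0.0)}
                for s in range(8)
                for lvl in ("EO", "B", "C")
            ]
        )
        row = simple_contrasts(df, factor="visual", reference="EO").row("B")
        assert row["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert row["t"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(4)
        delta = 0.42
        rows = []
        for s in range(10):
            base = rng.normal()
            for b in ("P1", "P2"):
                noise = rng.normal(scale=0.05)
                rows.append({"subject": f"S{s}", "visual": "EO", "platform": b,
                             "value": base + noise})
                rows.append({"subject": f"S{s}", "visual": "X", "platform": b,
                             "value": base + noise + delta})
        df = pd.DataFrame(rows)
        res = simple_contrasts(df, factor="visual", reference="EO", other="platform")
        assert res.row("X")["estimate"] == pytest.approx(delta, abs=1e-9)

    def test_antisymmetry(self):
        y = random_table(6, 3, 1, seed=7)[:, :, 0]
        df = pd.DataFrame(
            [
                {"subject": f"S{s}", "visual": f"A{i}", "value": y[s, i]}
                for s in range(6)
                for i in range(3)
            ]
        )
        fwd = simple_contrasts(df, factor="visual", reference="A0").row("A1")
        rev = simple_contrasts(df, factor="visual", reference="A1").row("A0")
        assert fwd["estimate"] == pytest.approx(-rev["estimate"], rel=1e-12)

    def test_two_level_contrast_matches_paired_t_se(self):
        # with one other-factor level and a 2-level factor the stratum SE
        # reduces to the paired-t SE
        rng = np.random.default_rng(6)
        y = rng.normal(size=(10, 2))
        df = pd.DataFrame(
            [
                {"subject": f"S{s}", "visual": lvl, "value": y[s, i]}
                for s in range(10)
                for i, lvl in enumerate(("EO", "EC"))
            ]
        )
        row = simple_contrasts(df, factor="visual", reference="EO").row("EC")
        d = y[:, 1] - y[:, 0]
        se_t = d.std(ddof=1) / np.sqrt(10)
        t = stats.ttest_rel(y[:, 1], y[:, 0])
        assert row["se"] == pytest.approx(se_t, rel=1e-9)
        assert row["t"] == pytest.approx(t.statistic, rel=1e-9)
        assert row["p"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_unknown_reference_rejected(self):
        df = long_table(random_table(3, 2, 2, seed=1))
        with pytest.raises(ValueError, match="reference"):
            simple_contrasts(df, factor="visual", reference="NOPE", other="platform")

    def test_se_uses_factor_error_stratum(self):
        y = random_table(9, 4, 4, seed=11)
        df = long_table(y)
        res2 = rm_anova_2way(df)
        con = simple_contrasts(df, factor="visual", reference="A0", other="platform")
        ms = res2.row("Residual (visual)")["ms"]
        assert con.error_ms == pytest.approx(ms, rel=1e-12)
        assert con.row("A1")["se"] == pytest.approx(
            np.sqrt(2 * ms / (9 * 4)), rel=1e-12
        )
        assert con.row("A1")["df"] == 24


class TestSingleLevelPosthoc:
    def test_restriction_with_identical_values_zero_ss(self):
        y = random_table(5, 3, 2, seed=3)
        y[:, :, 0] = 1.0
        res, _ = single_level_posthoc(long_table(y), "B0", reference="A0")
        assert res.row("visual")["ss"] == pytest.approx(0.0, abs=1e-12)

    def test_equals_one_way_on_restricted_table(self):
        y = random_table(6, 4, 3, seed=12)
        df = long_table(y)
        res, con = single_level_posthoc(df, "B1", reference="A0")
        direct = rm_anova_1way(df[df["platform"] == "B1"], within="visual")
        assert res.row("visual")["F"] == pytest.approx(
            direct.row("visual")["F"], rel=1e-12
        )

    def test_df_formula_9_subjects_4_levels(self):
        y = random_table(9, 4, 2, seed=13)
        res, _ = single_level_posthoc(long_table(y), "B0", reference="A0")
        assert res.row("visual")["df"] == 3
        assert res.row("Residual (visual)")["df"] == 24

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="platform level"):
            single_level_posthoc(long_table(random_table(3, 2, 2, seed=1)), "ZZ")


class TestNormalizeOutcomes:
    def test_zscore_per_platform_column(self):
        df = long_table(random_table(6, 3, 4, seed=14))
        out = normalize_outcomes(df, by="platform", method="zscore")
        for _, grp in out.groupby("platform"):
            assert grp["value"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["value"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_raw_passthrough(self):
        df = long_table(random_table(3, 2, 2, seed=1))
        out = normalize_outcomes(df, method="raw")
        assert np.allclose(out["value"], df["value"])

    def test_log_requires_positive(self):
        df = long_table(random_table(3, 2, 2, seed=1))
        with pytest.raises(ValueError, match="positive"):
            normalize_outcomes(df, method="log")

    def test_log_transform(self):
        df = long_table(np.abs(random_table(3, 2, 2, seed=1)) + 1.0)
        out = normalize_outcomes(df, method="log")
        assert np.allclose(out["value"], np.log(df["value"]))

    def test_unknown_method_rejected(self):
        df = long_table(random_table(3, 2, 2, seed=1))
        with pytest.raises(ValueError, match="unknown"):
            normalize_outcomes(df, method="rank")
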