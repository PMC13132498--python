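"""Acuity conversion, descriptives, mixed models, permutation and Holm."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from ssvepkit.stats import (
    acuity_to_logmar,
    cohort_descriptives,
    fit_association_lmm,
    fit_group_lmm,
    holm_adjust,
    monte_carlo_perm_test,
    pairwise_emmeans,
    pearson_corr,
)


class TestAcuityConversion:
    @pytest.mark.parametrize(
        "raw, expected, converted",
        [("HM", 2.3, True), ("PL", 2.7, True), ("hm", 2.3, True), (0.32, 0.32, False), ("0.5", 0.5, False)],
    )
    def test_scalar_conversion(self, raw, expected, converted):
        value, flag = acuity_to_logmar(raw)
        assert value == pytest.approx(expected)
        assert flag is converted

    def test_missing_propagates(self):
        value, flag = acuity_to_logmar(np.nan)
        assert np.isnan(value) and not flag

    def test_unknown_category_error_names_it(self):
        with pytest.raises(ValueError, match="NLP"):
            acuity_to_logmar("NLP")

    def test_vector_conversion_flags_categorical_entries(self):
        s = pd.Series([0.1, "HM", "PL", 1.4])
        values, converted = acuity_to_logmar(s)
        assert list(values) == pytest.approx([0.1, 2.3, 2.7, 1.4])
        assert list(converted) == [False, True, True, False]


class TestDescriptives:
    def test_eye_level_acuity_and_participant_level_age(self):
        cohort = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "group": ["G1"] * 4,
                "eye": ["OS", "OD"] * 2,
                "acuity_logmar": [0.1, 0.3, 1.1, 1.3],
                "age": [30.0, 30.0, 50.0, 50.0],
            }
        )
        out = cohort_descriptives(cohort, extra_participant_cols=("age",))
        assert out.loc["G1", "acuity_mean"] == pytest.approx(0.7)
        assert out.loc["G1", "acuity_sd"] == pytest.approx(np.std([0.1, 0.3, 1.1, 1.3], ddof=1))
        # age must average over participants (30, 50), not over the 4 eye rows
        assert out.loc["G1", "age_mean"] == pytest.approx(40.0)
        assert out.loc["G1", "age_sd"] == pytest.approx(np.std([30.0, 50.0], ddof=1))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_descriptives(pd.DataFrame(columns=["participant_id", "group", "acuity_logmar"]))


def two_eye_cohort(means, n_per_group, participant_sd, noise_sd, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in means.items():
        for p in range(n_per_group):
            u = rng.normal(0, participant_sd)
            for eye in ("OS", "OD"):
                rows.append(
                    {"participant_id": f"{g}{p}", "group": g, "eye": eye, "auc": mu + u + rng.normal(0, noise_sd)}
                )
    return pd.DataFrame(rows)


class TestGroupLmm:
    def test_reduces_to_one_way_anova_with_one_eye_per_participant(self):
        rng = np.random.default_rng(0)
        rows = [
            {"participant_id": f"{g}{i}", "group": g, "auc": rng.normal(m, 1.0)}
            for g, m in [("A", 0.0), ("B", 0.3), ("C", 0.8)]
            for i in range(8)
        ]
        df = pd.DataFrame(rows)
        res = fit_group_lmm(df)
        groups = [df[df.group == g].auc.to_numpy() for g in "ABC"]
        f_ref = sstats.f_oneway(*groups)
        assert res.singular  # no replication within participant -> tau^2 = 0
        assert res.F == pytest.approx(f_ref.statistic, abs=1e-6)
        assert res.df_den == pytest.approx(21)
        assert res.p == pytest.approx(f_ref.pvalue, rel=1e-6)

    def test_variance_components_match_statsmodels_mixedlm(self):
        df = two_eye_cohort({"Control": 120, "MD": 60, "GRD": 10}, 10, 25.0, 15.0, seed=1)
        res = fit_group_lmm(df)
        sm = smf.mixedlm("auc ~ group", df, groups=df["participant_id"]).fit(reml=True)
        assert res.tau2 == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=1e-4)
        assert res.sigma2 == pytest.approx(sm.scale, rel=1e-4)
        ours = res._model.fit_.beta
        assert ours[0] == pytest.approx(sm.params["Intercept"], rel=1e-6)

    def test_partial_eta_squared_consistent_with_f_and_dfs(self):
        df = two_eye_cohort({"A": 0, "B": 5}, 8, 1.0, 1.0, seed=2)
        res = fit_group_lmm(df)
        assert res.partial_eta_sq == pytest.approx(
            res.F * res.df_num / (res.F * res.df_num + res.df_den)
        )

    def test_emmeans_equal_raw_means_in_balanced_designs(self):
        df = two_eye_cohort({"A": 1.0, "B": 4.0, "C": 9.0}, 6, 2.0, 1.0, seed=3)
        res = fit_group_lmm(df)
        raw = df.groupby("group")["auc"].mean()
        for g in "ABC":
            assert res.emmeans[g] == pytest.approx(raw[g], abs=1e-9)

    def test_strongly_ordered_means_all_contrasts_significant(self):
        df = two_eye_cohort({"low": 0.0, "mid": 30.0, "high": 60.0}, 8, 3.0, 3.0, seed=4)
        res = fit_group_lmm(df)
        table = pairwise_emmeans(res)
        assert len(table) == 3
        assert (table["p_adjusted"] < 0.05).all()
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()

    def test_single_group_rejected(self):
        df = two_eye_cohort({"A": 0.0}, 4, 1.0, 1.0, seed=5)
        with pytest.raises(ValueError):
            fit_group_lmm(df)


class TestMonteCarloPermutation:
    def test_copied_group_composition_is_null(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 8)
        values = np.concatenate([base, base])
        labels = np.array(["A"] * 8 + ["B"] * 8)
        pids = np.array([f"a{i//2}" for i in range(8)] + [f"b{i//2}" for i in range(8)])
        res = monte_carlo_perm_test(values, labels, pids, reps=2000, seed=0)
        assert res.p > 0.5

    def test_matches_exhaustive_enumeration_on_tiny_design(self):
        values = np.array([1.0, 1.2, 3.0, 2.8, 0.5, 0.6, 2.0, 2.2])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        pids = np.array(["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"])
        sums = {"p1": 2.2, "p2": 5.8, "p3": 1.1, "p4": 4.2}
        obs = (sums["p1"] + sums["p2"]) / 4 - (sums["p3"] + sums["p4"]) / 4
        null = []
        for combo in itertools.combinations(sums, 2):
            sa = sum(sums[p] for p in combo)
            null.append(sa / 4 - (sum(sums.values()) - sa) / 4)
        exact = sum(abs(v) >= abs(obs) - 1e-9 for v in null) / len(null)
        res = monte_carlo_perm_test(values, labels, pids, reps=50_000, seed=1)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_perm_test(np.ones(4), np.array(["A"] * 4), np.array(list("abcd")))


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_applied_step_down_rule(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones_stay_capped(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPearson:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        assert pearson_corr(x, x)[0] == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.arange(10.0)
        assert pearson_corr(x, -2 * x + 5)[0] == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_corr(x, y)[0] == pytest.approx(num / den)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestAssociation:
    def test_noiseless_linear_relation_recovers_slope_exactly(self):
        x = np.linspace(0, 100, 24)
        df = pd.DataFrame(
            {"participant_id": [f"p{i//2}" for i in range(24)], "auc": x, "acuity_logmar": 1.5 - 0.002 * x}
        )
        res = fit_association_lmm(df, response_col="acuity_logmar", predictor_col="auc")
        assert res.slope == pytest.approx(-0.002, abs=1e-10)

    def test_recovers_simulated_slope_at_cohort_scale(self):
        rng = np.random.default_rng(7)
        rows = []
        for p in range(36):
            u = rng.normal(0, 0.15)
            for eye in ("OS", "OD"):
                auc = rng.uniform(-20, 150)
                rows.append(
                    {
                        "participant_id": f"p{p}",
                        "auc": auc,
                        "acuity_logmar": 1.2 - 0.002 * auc + u + rng.normal(0, 0.1),
                    }
                )
        res = fit_association_lmm(pd.DataFrame(rows), response_col="acuity_logmar", predictor_col="auc")
        assert res.slope == pytest.approx(-0.002, abs=2 * res.se)
        assert res.p < 0.05

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"participant_id": list("aabb"), "y": [1.0, 2, 3, 4], "x": [1.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            fit_association_lmm(df, response_col="y", predictor_col="x")
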