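import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import abmtrial as ab
from abmtrial.inference import MODEL_FORMULAS, likelihood_ratio_test


def summarise(groups, labels=None):
    labels = labels or [f"g{i}" for i in range(len(groups))]
    return pd.DataFrame(
        {
            "group": labels,
            "n": [len(g) for g in groups],
            "mean": [np.mean(g) for g in groups],
            "sd": [np.std(g, ddof=1) for g in groups],
        }
    )


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert ab.pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert ab.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_covariance_oracle(self):
        x, y = [1, 2, 3], [2, 1, 3]
        # cov = 0.5, sd_x = sd_y = 1 -> r = 0.5
        r, _ = ab.pearson_correlation(x, y)
        assert r == pytest.approx(0.5)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1, p1 = ab.pearson_correlation(x, y)
        perm = rng.permutation(30)
        r2, p2 = ab.pearson_correlation(x[perm], y[perm])
        assert (r1, p1) == pytest.approx((r2, p2))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ab.pearson_correlation([1, 2], [3, 4])


class TestSummaryAnova:
    def test_matches_raw_data_oracle_to_1e9(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc, 2.0, size=n) for loc, n in ((0, 12), (0.5, 15), (1.2, 9))]
        ours = ab.oneway_anova_from_summary(summarise(groups))
        F, p = stats.f_oneway(*groups)
        assert ours["F"] == pytest.approx(F, abs=1e-9)
        assert ours["p"] == pytest.approx(p, abs=1e-9)

    def test_equal_means_give_zero_F(self):
        s = pd.DataFrame({"group": list("ab"), "n": [10, 10], "mean": [5.0, 5.0], "sd": [1.0, 2.0]})
        assert ab.oneway_anova_from_summary(s)["F"] == 0.0

    def test_zero_within_variance_flagged_infinite(self):
        s = pd.DataFrame({"group": list("ab"), "n": [5, 5], "mean": [1.0, 2.0], "sd": [0.0, 0.0]})
        assert np.isinf(ab.oneway_anova_from_summary(s)["F"])


class TestWelchAnova:
    def test_matches_pingouin_on_raw_data(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, s, size=n) for s, n in ((1, 12), (3, 20), (5, 8))]
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(list("abc"), [12, 20, 8])}
        )
        theirs = pg.welch_anova(data=df, dv="y", between="g")
        ours = ab.welch_anova_from_summary(summarise(groups))
        assert ours["F"] == pytest.approx(theirs["F"].item(), abs=1e-9)
        assert ours["df2"] == pytest.approx(theirs["ddof2"].item(), abs=1e-9)
        assert ours["p"] == pytest.approx(theirs["p_unc"].item(), abs=1e-9)

    def test_equal_means_give_zero_F(self):
        s = pd.DataFrame({"group": list("ab"), "n": [10, 12], "mean": [5.0, 5.0], "sd": [1.0, 2.0]})
        assert ab.welch_anova_from_summary(s)["F"] == 0.0

    def test_zero_variance_rejected(self):
        s = pd.DataFrame({"group": list("ab"), "n": [10, 12], "mean": [5.0, 6.0], "sd": [0.0, 2.0]})
        with pytest.raises(ValueError):
            ab.welch_anova_from_summary(s)


class TestChiSquare:
    @given(
        st.lists(st.lists(st.integers(1, 40), min_size=4, max_size=4), min_size=2, max_size=2)
    )
    def test_brute_force_formula(self, rows):
        obs = np.array(rows, dtype=float)
        res = ab.chisq_independence(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(chi2, abs=1e-9)
        assert res["df"] == (obs.shape[0] - 1) * (obs.shape[1] - 1)

    def test_expected_table_gives_zero(self):
        obs = np.outer([10, 20], [3, 7]) / 10.0
        assert ab.chisq_independence(obs)["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            ab.chisq_independence([[0, 0], [1, 2]])


class TestTukeyKramer:
    def test_identical_groups_yield_empty_set(self):
        s = pd.DataFrame({"group": list("abc"), "n": [8, 8, 8], "mean": [5.0] * 3, "sd": [1.0] * 3})
        out = ab.tukey_kramer_from_summary(s)
        assert not out["significant"].any()

    def test_two_group_case_agrees_with_pooled_t_test(self):
        # with k=2 the studentized range q = t*sqrt(2), so decisions coincide
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 14), rng.normal(0.9, 1, 11)
        out = ab.tukey_kramer_from_summary(summarise([a, b]))
        t, p = stats.ttest_ind(a, b)
        assert out["p"].item() == pytest.approx(p, abs=1e-9)
        assert out["q"].item() == pytest.approx(abs(t) * np.sqrt(2), abs=1e-9)


class TestLevene:
    def test_identical_spread_not_significant(self):
        g = [np.array([1.0, 2, 3, 4, 5]) + m for m in (0, 10, 20)]
        res = ab.levene_test(g)
        assert res["W"] == pytest.approx(0.0, abs=1e-12)

    def test_detects_tenfold_scale_difference(self):
        rng = np.random.default_rng(4)
        g = [rng.normal(0, 1, 200), rng.normal(0, 10, 200)]
        assert ab.levene_test(g)["p"] < 0.05

    def test_center_choice_matters_on_skewed_data(self):
        rng = np.random.default_rng(5)
        g = [rng.exponential(1, 60), rng.exponential(1.5, 60)]
        assert ab.levene_test(g, "mean") != ab.levene_test(g, "median")


def glm_mixed_anova_oracle(df):
    """Brute-force sums-of-squares mixed ANOVA (between group, within time)."""
    wide = df.pivot_table(index=["participant_id", "group"], columns="timepoint",
                          values="bias_index").reset_index()
    y = wide[["pre", "post"]].to_numpy()
    groups = wide["group"].to_numpy()
    n, k_t = y.shape
    grand = y.mean()
    subj_mean = y.mean(1)
    time_mean = y.mean(0)
    ss_subj = k_t * ((subj_mean - grand) ** 2).sum()
    ss_time = n * ((time_mean - grand) ** 2).sum()
    labels = np.unique(groups)
    ss_group = sum(k_t * (groups == g).sum() * (subj_mean[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_cells = sum(
        (groups == g).sum() * (y[groups == g, t].mean() - grand) ** 2
        for g in labels for t in range(k_t)
    )
    ss_int = ss_cells - ss_group - ss_time
    ss_total = ((y - grand) ** 2).sum()
    ss_subj_within = ss_subj - ss_group
    ss_resid = ss_total - ss_subj - ss_time - ss_int
    k_g = len(labels)
    F_group = (ss_group / (k_g - 1)) / (ss_subj_within / (n - k_g))
    F_time = (ss_time / (k_t - 1)) / (ss_resid / ((n - k_g) * (k_t - 1)))
    F_int = (ss_int / ((k_g - 1) * (k_t - 1))) / (ss_resid / ((n - k_g) * (k_t - 1)))
    return F_group, F_time, F_int


@pytest.fixture(scope="module")
def bias_data():
    alloc = ab.allocate_blocks(40, seed=6)
    trials = ab.generate_trials(alloc, ab.RtGenModel(), seed=7)
    cleaned, rep = ab.clean_trials(trials)
    return ab.bias_table(cleaned, exclude=rep.excluded_participants), alloc


class TestRmAnova:
    def test_no_change_gives_zero_time_and_interaction_F(self, bias_data):
        bias, alloc = bias_data
        mirrored = bias.copy()
        pre = mirrored[mirrored["timepoint"] == "pre"].set_index("participant_id")["bias_index"]
        mirrored["bias_index"] = mirrored["participant_id"].map(pre)
        table = ab.rm_anova_2x4(mirrored, alloc)
        f_time = table.loc[table["Source"] == "timepoint", "F"].item()
        f_int = table.loc[table["Source"] == "Interaction", "F"].item()
        assert f_time == pytest.approx(0.0, abs=1e-9)
        assert f_int == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_glm_oracle(self, bias_data):
        bias, alloc = bias_data
        table = ab.rm_anova_2x4(bias, alloc)
        df = bias.merge(alloc, on="participant_id")
        df["group"] = df["stimuli"].astype(str) + ":" + df["condition"].astype(str)
        counts = df.dropna(subset=["bias_index"]).groupby("participant_id")["timepoint"].nunique()
        df = df[df["participant_id"].isin(counts[counts == 2].index)]
        F_group, F_time, F_int = glm_mixed_anova_oracle(df)
        assert table.loc[table["Source"] == "group", "F"].item() == pytest.approx(F_group, rel=1e-6)
        assert table.loc[table["Source"] == "timepoint", "F"].item() == pytest.approx(F_time, rel=1e-6)
        assert table.loc[table["Source"] == "Interaction", "F"].item() == pytest.approx(F_int, rel=1e-6)

    def test_incomplete_pairs_dropped(self, bias_data, caplog):
        bias, alloc = bias_data
        broken = bias[~((bias["participant_id"] == bias["participant_id"].iloc[0])
                        & (bias["timepoint"] == "post"))]
        with caplog.at_level("WARNING", logger="abmtrial"):
            ab.rm_anova_2x4(broken, alloc)
        assert any("incomplete" in r.message for r in caplog.records)


class TestLmm:
    def test_noise_free_limit_recovers_generating_coefficients(self, alloc100):
        model = ab.ScoreGenModel(tau0=0, tau1=0, sigma_eps=0,
                                 p_missing_fu1=0, p_missing_fu2=0,
                                 gamma0=60, gamma_time=-4, gamma_cond=-2, gamma_stim=1,
                                 gamma_time_cond=0.5, gamma_time_stim=-0.5,
                                 gamma_cond_stim=2, gamma_time_cond_stim=0.25)
        scores = ab.generate_scores(alloc100, model, seed=1)
        fit = ab.fit_lmm(scores, alloc100, model="full")
        est = fit.fixed_effects["estimate"]
        # integer rounding of totals perturbs the surface slightly
        assert est["Intercept"] == pytest.approx(60, abs=0.3)
        assert est["time"] == pytest.approx(-4, abs=0.3)
        assert est["condition"] == pytest.approx(-2, abs=0.5)
        assert est["time:condition:stimuli"] == pytest.approx(0.25, abs=0.5)

    def test_zero_random_variance_matches_ols(self, alloc100):
        import statsmodels.formula.api as smf

        model = ab.ScoreGenModel(tau0=0.0, tau1=0.0, sigma_eps=6.0,
                                 p_missing_fu1=0, p_missing_fu2=0)
        scores = ab.generate_scores(alloc100, model, seed=2)
        fit = ab.fit_lmm(scores, alloc100, model="full")
        df = scores.merge(alloc100, on="participant_id").rename(columns={"assessment": "time"})
        ols = smf.ols(MODEL_FORMULAS["full"], df).fit()
        for term in fit.fixed_effects.index:
            assert fit.fixed_effects.loc[term, "estimate"] == pytest.approx(
                ols.params[term], abs=0.05
            )

    def test_containment_df_split(self, small_cohort):
        fit = ab.fit_lmm(small_cohort["scores"], small_cohort["alloc"], model="full")
        fe = fit.fixed_effects
        within = [t for t in fe.index if "time" in t]
        between = [t for t in fe.index if "time" not in t]
        assert (fe.loc[within, "df"] == fit.n_obs - fit.n_groups - len(within)).all()
        assert (fe.loc[between, "df"] == fit.n_groups - len(between)).all()

    def test_aic_identity_and_comparison(self, small_cohort):
        fits = {m: ab.fit_lmm(small_cohort["scores"], small_cohort["alloc"], model=m)
                for m in ("full", "time_only")}
        for f in fits.values():
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k_params)
        table = ab.aic_compare(fits)
        assert list(table["aic"]) == sorted(table["aic"])
        lrt = likelihood_ratio_test(fits["full"], fits["time_only"])
        assert lrt["df"] == 6
        assert 0 <= lrt["p"] <= 1

    def test_mixed_estimators_not_comparable(self, small_cohort):
        a = ab.fit_lmm(small_cohort["scores"], small_cohort["alloc"], model="time_only")
        b = ab.fit_lmm(small_cohort["scores"], small_cohort["alloc"], model="full", method="reml")
        with pytest.raises(ValueError, match="REML"):
            ab.aic_compare({"a": a, "b": b})


class TestPseudoR2:
    def _result(self, loglik, n_obs=100):
        from abmtrial.inference import LmmResult

        return LmmResult("m", pd.DataFrame(), {}, loglik, 3, n_obs, 25, "ml", True)

    def test_full_equals_null_gives_zero(self):
        assert ab.nagelkerke_pseudo_r2(self._result(-100.0), self._result(-100.0)) == 0.0

    def test_matches_logistic_regression_oracle(self):
        # same likelihood-ratio formula as for a GLM: cross-check against
        # statsmodels' Cox-Snell ingredients on a textbook logistic fit
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        y = rng.random(200) < 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
        full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((200, 1))).fit(disp=0)
        ours = ab.nagelkerke_pseudo_r2(self._result(full.llf, 200), self._result(null.llf, 200))
        r2_cs = 1 - np.exp(2 * (null.llf - full.llf) / 200)
        expected = r2_cs / (1 - np.exp(2 * null.llf / 200))
        assert ours == pytest.approx(expected, abs=1e-12)
        assert 0 < ours < 1

    def test_monotone_in_full_likelihood(self):
        null = self._result(-120.0)
        vals = [ab.nagelkerke_pseudo_r2(self._result(l), null) for l in (-119, -110, -100)]
        assert vals == sorted(vals)

    def test_worse_than_null_warns_and_clamps(self):
        with pytest.warns(UserWarning):
            assert ab.nagelkerke_pseudo_r2(self._result(-130.0), self._result(-120.0)) == 0.0
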