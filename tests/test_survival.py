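"""Survival battery: product-limit curves, generalized Wilcoxon,
Cox hazard ratios, ROC AUC, and the marker-ranking design."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from eldltg import cox_fit, km_estimate, marker_battery, roc_auc, wilcoxon_chisq


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        s = km.set_index("time")["survival"]
        assert s.loc[0.0] == 1.0
        np.testing.assert_allclose(s.loc[[1.0, 2.0, 3.0, 4.0, 5.0]],
                                   [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_all_censored_flat_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_subject(self):
        km = km_estimate([2.0], [1]).set_index("time")["survival"]
        assert km.loc[0.0] == 1.0 and km.loc[2.0] == 0.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(5.0, 300)
        km = km_estimate(t, np.ones(300)).set_index("time")["survival"]
        for u in np.quantile(t, [0.1, 0.5, 0.9]):
            empirical = np.mean(t > u)
            step = km[km.index <= u].iloc[-1]
            assert step == pytest.approx(empirical, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            km_estimate([1.0, -1.0], [1, 1])
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [1])


class TestWilcoxon:
    def test_identical_strata_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.repeat([0, 1], 5)
        res = wilcoxon_chisq(t, e, g)
        assert res.chisq == pytest.approx(0.0, abs=1e-9)
        assert res.df == 1

    def test_power_under_hazard_ratio_three(self):
        """Two exponential strata with a threefold hazard: the test is
        significant at alpha = 0.001 in every desk-scale replicate."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            t = np.concatenate([rng.exponential(1.0, 500), rng.exponential(1 / 3, 500)])
            t = np.minimum(t, 3.0)
            e = t < 3.0
            res = wilcoxon_chisq(t, e, np.repeat([0, 1], 500))
            hits += res.p_value < 0.001
        assert hits >= 9

    def test_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_chisq([1.0, 2.0], [1, 1], [0, 0])  # single stratum

    def test_type_one_error_near_nominal(self):
        """Two-sample null rejection rate at alpha = 0.05 stays within
        (0.03, 0.07) over 1,000 simulations."""
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(1000):
            t = np.minimum(rng.exponential(10.0, 200), 14.0)
            res = wilcoxon_chisq(t, t < 14.0, np.repeat([0, 1], 100))
            rejections += res.p_value < 0.05
        assert 0.03 < rejections / 1000 < 0.07


class TestCox:
    def test_binary_covariate_direction_matches_km_ordering(self, survival_cohort):
        df = survival_cohort.copy()
        df["high"] = (df["eldl_tg"] > df["eldl_tg"].median()).astype(float)
        res = cox_fit(df, covariates=["high"])
        assert res.loc["high", "hr"] > 1.0
        # the high-marker stratum's survival curve lies below
        km_lo = km_estimate(df.loc[df["high"] == 0, "follow_up"],
                            df.loc[df["high"] == 0, "event"])
        km_hi = km_estimate(df.loc[df["high"] == 1, "follow_up"],
                            df.loc[df["high"] == 1, "event"])
        assert km_hi["survival"].iloc[-1] < km_lo["survival"].iloc[-1]

    def test_null_covariate_ci_covers_one(self, survival_cohort):
        df = survival_cohort.copy()
        rng = np.random.default_rng(31)
        df["noise"] = rng.normal(size=len(df))
        res = cox_fit(df, covariates=["noise"], standardize=["noise"])
        assert res.loc["noise", "ci_lower"] < 1.0 < res.loc["noise", "ci_upper"]

    def test_per_sd_scaling(self, survival_cohort):
        """Standardizing rescales the log-HR by the covariate SD."""
        raw = cox_fit(survival_cohort, covariates=["eldl_tg"])
        std = cox_fit(survival_cohort, covariates=["eldl_tg"], standardize=["eldl_tg"])
        sd = survival_cohort["eldl_tg"].std(ddof=1)
        assert std.loc["eldl_tg", "coef"] == pytest.approx(
            raw.loc["eldl_tg", "coef"] * sd, rel=1e-6
        )

    def test_adjusted_model_keeps_marker_effect(self, survival_cohort):
        res = cox_fit(
            survival_cohort,
            covariates=["eldl_tg", "age", "sex", "sbp", "diabetes", "smoker"],
            standardize=["eldl_tg"],
        )
        # demographics are generated independently of the hazard here,
        # so adjustment must not remove the marker's effect
        assert res.loc["eldl_tg", "ci_lower"] > 1.0

    def test_few_events_warns(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame(
            {
                "follow_up": rng.exponential(50.0, 60).clip(max=14.0),
                "event": np.r_[np.ones(5), np.zeros(55)],
                "x": rng.normal(size=60),
            }
        )
        with pytest.warns(UserWarning, match="events"):
            cox_fit(df, covariates=["x"])


class TestAUC:
    @pytest.mark.parametrize(
        "marker, outcome, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),            # perfect separation
            ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),            # ties count half
            ([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1], 6 / 9),  # pairwise count
        ],
    )
    def test_known_values(self, marker, outcome, expected):
        assert roc_auc(marker, outcome) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_equals_mann_whitney_concordance(self):
        """ROC-integration AUC == U/(n1*n0) to 1e-12, ties included."""
        rng = np.random.default_rng(41)
        marker = np.round(rng.normal(size=500), 1)  # rounding forces ties
        outcome = rng.uniform(size=500) < 0.3
        u = mannwhitneyu(marker[outcome], marker[~outcome]).statistic
        concordance = u / (outcome.sum() * (~outcome).sum())
        assert roc_auc(marker, outcome) == pytest.approx(concordance, abs=1e-12)

    def test_logistic_fit_preserves_auc(self):
        """A single-marker logistic model is a monotone transform, so
        its predicted-probability AUC equals the raw-marker AUC."""
        rng = np.random.default_rng(42)
        marker = rng.normal(size=400)
        outcome = rng.uniform(size=400) < 1 / (1 + np.exp(-marker))
        lr = LogisticRegression().fit(marker.reshape(-1, 1), outcome)
        p = lr.predict_proba(marker.reshape(-1, 1))[:, 1]
        assert roc_auc(marker, outcome) == pytest.approx(
            roc_auc_score(outcome, p), abs=1e-12
        )


class TestMarkerBattery:
    def test_causal_marker_ranks_first(self, survival_cohort):
        table = marker_battery(
            survival_cohort, ["eldl_tg", "ldl_c_sampson", "nonhdl_c", "rem_c", "sdldl_c"]
        )
        assert table.index[0] == "eldl_tg"
        assert table["wilcoxon_chisq"].is_monotonic_decreasing

    def test_null_hazard_all_auc_near_half(self):
        from eldltg import CohortSpec, HazardSpec, generate_cohort

        coh = generate_cohort(
            CohortSpec(n=4000, seed=51, hazard=HazardSpec(hr_per_sd=1.0))
        )
        table = marker_battery(coh, ["eldl_tg", "ldl_c_sampson", "rem_c"])
        assert (table["auc"] - 0.5).abs().max() < 0.03

    def test_per_marker_failure_does_not_abort(self, survival_cohort):
        df = survival_cohort.copy()
        df["constant"] = 1.0
        table = marker_battery(df, ["eldl_tg", "constant"])
        assert np.isnan(table.loc["constant", "wilcoxon_chisq"])
        assert np.isfinite(table.loc["eldl_tg", "wilcoxon_chisq"])
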