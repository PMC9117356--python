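"""Kaplan-Meier, log-rank, Cox fitting and backward selection."""

import numpy as np
import pandas as pd
import pytest

import adctex as at
from adctex.survival import (
    backward_select_cox,
    backward_select_linear,
    compare_aic,
    fit_cox,
    kaplan_meier,
    log_rank,
    score_design,
    validate_clinical,
)
from oracles import cox_mle_1d, cox_partial_loglik, logrank_two_group


def clinical_frame(times, events, dsgpa=None, rpa=None):
    n = len(times)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "os_months": times,
            "event": events,
            "dsgpa_group": dsgpa if dsgpa is not None else ["II"] * n,
            "rpa_class": rpa if rpa is not None else ["II"] * n,
        }
    )


class TestKaplanMeier:
    def test_no_censoring_staircase_and_median(self):
        tab = clinical_frame([1, 2, 3, 4, 5], [1] * 5)
        km = kaplan_meier(tab)["all"]
        steps = km.survival[np.isin(km.times, [1, 2, 3, 4, 5])]
        assert np.allclose(steps, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3.0

    def test_all_censored_flat_curve(self):
        tab = clinical_frame([2, 4, 6], [0, 0, 0])
        with pytest.warns(UserWarning, match="no events"):
            km = kaplan_meier(tab)["all"]
        assert np.all(km.survival == 1.0)
        assert np.isnan(km.median)

    def test_mixed_censoring_matches_hand_computed_product_limit(self):
        # times 1, 2+, 3, 4, 4+, 6 -> S = 5/6, 5/8, 5/12, 0
        tab = clinical_frame([1, 2, 3, 4, 4, 6], [1, 0, 1, 1, 0, 1])
        km = kaplan_meier(tab)["all"]
        s = dict(zip(km.times, km.survival))
        assert s[1.0] == pytest.approx(5 / 6)
        assert s[3.0] == pytest.approx(5 / 8)
        assert s[4.0] == pytest.approx(5 / 12)
        assert s[6.0] == pytest.approx(0.0)

    def test_grouped_curves(self):
        tab = clinical_frame([1, 2, 3, 4], [1, 1, 1, 1], dsgpa=["I", "I", "III", "III"])
        km = kaplan_meier(tab, group="dsgpa_group")
        assert set(km) == {"I", "III"}
        assert km["I"].n == 2


class TestLogRank:
    def test_identical_event_time_multisets_give_zero(self):
        tab = clinical_frame([1, 2, 3, 1, 2, 3], [1] * 6,
                             dsgpa=["I"] * 3 + ["III"] * 3)
        stat, p = log_rank(tab, "dsgpa_group")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_statistic_matches_hand_formula(self):
        times = [1, 3, 5, 2, 4, 6]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["I", "I", "I", "III", "III", "III"]
        tab = clinical_frame(times, events, dsgpa=groups)
        stat, _ = log_rank(tab, "dsgpa_group")
        assert stat == pytest.approx(
            logrank_two_group(times, events, groups), rel=1e-9
        )

    def test_label_swap_invariance(self):
        tab = clinical_frame([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1],
                             dsgpa=["I", "III", "I", "III", "I", "III"])
        swapped = tab.copy()
        swapped["dsgpa_group"] = swapped["dsgpa_group"].map({"I": "III", "III": "I"})
        assert log_rank(tab, "dsgpa_group")[0] == pytest.approx(
            log_rank(swapped, "dsgpa_group")[0]
        )

    def test_null_permutation_calibration(self, rng):
        n = 40
        times = rng.exponential(12.0, n)
        events = (rng.random(n) < 0.8).astype(int)
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            labels = np.where(rng.random(n) < 0.5, "I", "III")
            if len(set(labels)) < 2:
                continue
            tab = clinical_frame(times, events, dsgpa=labels)
            _, p = log_rank(tab, "dsgpa_group")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_perm <= 0.07


class TestCoxFit:
    def test_beta_matches_partial_likelihood_oracle_on_tiny_data(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 7))
            times = rng.exponential(10, n)
            while len(np.unique(times)) < n:  # oracle assumes no ties
                times = rng.exponential(10, n)
            x = rng.standard_normal(n)
            events = (rng.random(n) < 0.8).astype(int)
            if events.sum() < 2:
                continue
            tab = clinical_frame(times, events)
            cov = pd.DataFrame({"x": x}, index=tab.index)
            try:
                fit = fit_cox(tab, cov)
            except ValueError:
                continue  # separation on a tiny draw: correctly refused
            beta_ref = cox_mle_1d(times, x, events)
            if abs(beta_ref) > 8:
                continue
            assert fit.coef[0] == pytest.approx(beta_ref, abs=1e-6)
            assert fit.loglik == pytest.approx(
                cox_partial_loglik(fit.coef[0], times, x, events), abs=1e-8
            )

    def test_aic_identity_and_ci_brackets_hr(self, rng):
        feats, clin = at.simulate_feature_cohort(120, {"a": 0.4}, seed=3)
        fit = fit_cox(clin.set_index("subject_id", drop=False),
                      feats.rename_axis(None))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        assert (fit.ci_lower <= fit.hr).all() and (fit.hr <= fit.ci_upper).all()

    def test_constant_covariate_rejected_by_name(self):
        tab = clinical_frame([1, 2, 3, 4], [1, 1, 1, 1])
        cov = pd.DataFrame({"flat": [1.0] * 4}, index=tab.index)
        with pytest.raises(ValueError, match="flat"):
            fit_cox(tab, cov)

    def test_breslow_and_efron_agree_without_ties(self, rng):
        feats, clin = at.simulate_feature_cohort(80, {"a": 0.5}, seed=11)
        tab = clin.set_index("subject_id", drop=False)
        f1 = fit_cox(tab, feats.rename_axis(None), ties="efron")
        f2 = fit_cox(tab, feats.rename_axis(None), ties="breslow")
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)


class TestBackwardSelection:
    def test_single_significant_candidate_survives_with_empty_trace(self):
        feats, clin = at.simulate_feature_cohort(150, {"a": 1.0},
                                                 censoring_target=0.0, seed=4)
        clin = clin.set_index("subject_id", drop=False)
        trace = backward_select_linear(feats.rename_axis(None), clin)
        assert trace.surviving == ["a"]
        assert trace.steps == []

    def test_exact_linear_predictor_always_survives(self, rng):
        feats, clin = at.simulate_feature_cohort(100, {}, noise_features=4, seed=5,
                                                 censoring_target=0.0)
        clin = clin.set_index("subject_id", drop=False)
        feats = feats.rename_axis(None)
        feats["signal"] = np.log(clin["os_months"])  # exact predictor
        trace = backward_select_linear(feats, clin)
        assert "signal" in trace.surviving

    def test_each_step_removes_exactly_one_and_surviving_is_subset(self):
        feats, clin = at.simulate_feature_cohort(80, {}, noise_features=6, seed=6)
        clin = clin.set_index("subject_id", drop=False)
        trace = backward_select_linear(feats.rename_axis(None), clin)
        assert len(trace.steps) + len(trace.surviving) == 6
        assert set(trace.surviving) <= set(feats.columns)
        assert len(set(trace.removed())) == len(trace.steps)

    def test_cox_stage_keeps_clinical_score_protected(self):
        feats, clin = at.simulate_feature_cohort(200, {}, noise_features=5, seed=7)
        clin = clin.set_index("subject_id", drop=False)
        fit, trace = backward_select_cox(clin, "dsgpa_group",
                                         feats.rename_axis(None))
        assert {"dsgpa_group_I", "dsgpa_group_II"} <= set(fit.names)
        assert set(trace.surviving) <= set(feats.columns)

    def test_empty_candidate_list_returns_score_only_fit(self):
        feats, clin = at.simulate_feature_cohort(60, {}, seed=8)
        clin = clin.set_index("subject_id", drop=False)
        empty = pd.DataFrame(index=clin.index)
        fit, trace = backward_select_cox(clin, "rpa_class", empty)
        ref = fit_cox(clin, score_design(clin, "rpa_class"))
        assert fit.aic == pytest.approx(ref.aic)
        assert trace.surviving == [] and trace.steps == []


class TestAicComparison:
    def test_formula_on_known_values(self):
        feats, clin = at.simulate_feature_cohort(50, {"a": 0.5}, seed=9)
        fit = fit_cox(clin.set_index("subject_id", drop=False),
                      feats.rename_axis(None))
        assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.k

    def test_comparison_table_flags_minimum(self):
        feats, clin = at.simulate_feature_cohort(150, {"a": 0.8}, seed=10)
        tab = clin.set_index("subject_id", drop=False)
        feats = feats.rename_axis(None)
        with_f = fit_cox(tab, pd.concat([score_design(tab, "dsgpa_group"), feats],
                                        axis=1))
        without = fit_cox(tab, score_design(tab, "dsgpa_group"))
        df = compare_aic({"augmented": with_f, "score_only": without})
        assert df["dAIC"].min() == 0.0
        assert df.loc[df["best"]].index[0] == df["AIC"].idxmin()

    def test_different_subject_sets_refused(self):
        feats, clin = at.simulate_feature_cohort(60, {"a": 0.5}, seed=12)
        tab = clin.set_index("subject_id", drop=False)
        feats = feats.rename_axis(None)
        f1 = fit_cox(tab, feats)
        f2 = fit_cox(tab.iloc[:50], feats.iloc[:50])
        with pytest.raises(ValueError, match="identical subject"):
            compare_aic({"full": f1, "subset": f2})


class TestValidation:
    def test_contract_violations_rejected(self):
        bad = clinical_frame([1, -2], [1, 0])
        with pytest.raises(ValueError, match="positive"):
            validate_clinical(bad)
        bad2 = clinical_frame([1, 2], [1, 2])
        with pytest.raises(ValueError, match="event"):
            validate_clinical(bad2)
        bad3 = clinical_frame([1, 2], [1, 0], dsgpa=["IV", "I"])
        with pytest.raises(ValueError, match="dsgpa"):
            validate_clinical(bad3)
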