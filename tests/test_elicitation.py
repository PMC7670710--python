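"""Indirect elicitation: oracle identities, recovery, bootstrap, counterfactuals."""

import numpy as np
import pandas as pd
import pytest

from harmdw import ConditionSpec, SimulationConfig, simulate_population
from harmdw.elicitation import (
    DisabilityWeightEstimator,
    bootstrap_ci,
    counterfactual_hsv,
    elicit_category_dws,
    extract_dw,
    fit_additive_interactions,
    fit_loglinear,
    naive_dw,
)


def _case_frame(persons, category="PG"):
    sub = persons[persons["pgsi_category"].isin([category, "NP"])].reset_index(
        drop=True
    )
    return sub.assign(case=(sub["pgsi_category"] == category).astype(int))


class TestLoglinearOracle:
    def test_noiseless_recovery_is_exact(self, noiseless_single_condition):
        """Without noise the log-linear fit inverts the multiplicative
        model algebraically: coefficients equal log(1 - DW) to ~1e-10."""
        persons, cfg = noiseless_single_condition
        sub = _case_frame(persons)
        fit = fit_loglinear(
            sub, np.ones(len(sub)), ["alcohol_abuse"], censor_ceiling=False
        )
        assert fit.coef_["case"] == pytest.approx(np.log(0.54), abs=1e-10)
        assert fit.coef_["alcohol_abuse"] == pytest.approx(np.log(0.765), abs=1e-10)
        assert fit.intercept_ == pytest.approx(0.0, abs=1e-10)
        assert fit.dw_estimates_[0].dw == pytest.approx(0.46, abs=1e-10)

    def test_intercept_zero_without_conditions_or_gambling(self):
        cfg = SimulationConfig(
            n=1_000, seed=2, noise_sigma=0.0,
            category_dws={"LR": 0.0, "MR": 0.0, "PG": 0.0}, conditions=[],
        )
        persons, _ = simulate_population(cfg)
        sub = _case_frame(persons)
        fit = fit_loglinear(sub, np.ones(len(sub)), [], censor_ceiling=False)
        assert fit.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert fit.dw_estimates_[0].dw == pytest.approx(0.0, abs=1e-12)

    def test_rejects_collinear_indicators(self, noiseless_single_condition):
        persons, _ = noiseless_single_condition
        sub = _case_frame(persons)
        sub["twin"] = sub["alcohol_abuse"]
        est = DisabilityWeightEstimator(
            category_terms=["case"], condition_terms=["alcohol_abuse", "twin"]
        )
        with pytest.raises(ValueError, match="collinear.*twin"):
            est.fit(sub[["case", "alcohol_abuse", "twin"]], sub["hsv"])

    def test_fixed_condition_weights_offset_the_outcome(
        self, noiseless_single_condition
    ):
        persons, _ = noiseless_single_condition
        sub = _case_frame(persons)
        fit = fit_loglinear(
            sub, np.ones(len(sub)), ["alcohol_abuse"], censor_ceiling=False,
            fixed_condition_dws={"alcohol_abuse": 0.235},
        )
        assert "alcohol_abuse" not in fit.coef_
        assert fit.coef_["case"] == pytest.approx(np.log(0.54), abs=1e-10)


class TestAdditiveOracle:
    def test_interaction_equals_product_of_weights(self, noiseless_single_condition):
        """(1-a)(1-b) = 1 - a - b + ab: the comorbidity discount appears
        as a positive interaction coefficient a*b."""
        persons, _ = noiseless_single_condition
        sub = _case_frame(persons)
        fit = fit_additive_interactions(
            sub, np.ones(len(sub)), ["alcohol_abuse"], censor_ceiling=False
        )
        assert fit.coef_["case"] == pytest.approx(-0.46, abs=1e-10)
        assert fit.coef_["alcohol_abuse"] == pytest.approx(-0.235, abs=1e-10)
        assert fit.coef_["case:alcohol_abuse"] == pytest.approx(
            0.46 * 0.235, abs=1e-10
        )
        assert fit.dw_estimates_[0].dw == pytest.approx(0.46, abs=1e-10)

    def test_interactions_vanish_without_comorbidity(self):
        cfg = SimulationConfig(n=4_000, seed=3, noise_sigma=0.05, conditions=[])
        persons, _ = simulate_population(cfg)
        sub = _case_frame(persons)
        sub["phantom"] = 0  # present in both arms but unrelated to HSV
        sub.loc[sub[sub["case"] == 1].index[:20], "phantom"] = 1
        sub.loc[sub[sub["case"] == 0].index[:60], "phantom"] = 1
        fit = fit_additive_interactions(
            sub, np.ones(len(sub)), ["phantom"], censor_ceiling=False
        )
        assert abs(fit.coef_["case:phantom"]) < 0.05

    def test_additive_and_loglinear_agree_on_noisy_data(self):
        """Both estimators target the same weights; the additive error
        model is misspecified under multiplicative noise, so agreement is
        to ~0.05 (the simulation oracle gives mean |diff| ~0.03)."""
        diffs = []
        for seed in (1, 2, 3):
            persons, _ = simulate_population(SimulationConfig(n=20_000, seed=seed))
            ll = elicit_category_dws(persons, categories=["PG"], seed=seed)[0]
            ad = elicit_category_dws(
                persons, categories=["PG"], seed=seed, estimator="additive"
            )[0]
            diffs.append(abs(ll.dw_unclipped - ad.dw_unclipped))
            assert ll.dw_unclipped == pytest.approx(0.46, abs=0.05)
            assert ad.dw_unclipped == pytest.approx(0.46, abs=0.07)
        assert np.mean(diffs) < 0.05


class TestExtractDW:
    def _fitted(self, beta):
        est = DisabilityWeightEstimator()
        est.category_terms_ = ["PG"]
        est.condition_terms_ = []
        est.fixed_condition_dws_ = {}
        est.coef_ = {"PG": beta}
        est.intercept_ = 0.0
        est.n_effective_ = 100.0
        return est

    def test_zero_coefficient_means_zero_weight(self):
        assert self._fitted(0.0)._extract()[0].dw == 0.0

    def test_log_half_recovers_046(self):
        est = self._fitted(np.log(0.54))._extract()[0]
        assert est.dw == pytest.approx(0.46, abs=1e-12)

    def test_protective_estimate_clipped_and_flagged(self):
        est = self._fitted(+0.01)._extract()[0]
        assert est.dw == 0.0 and est.clipped
        assert est.dw_unclipped == pytest.approx(1 - np.exp(0.01))


#: compact covariate set keeping small resampled logistic fits well-posed
BOOT_COVARIATES = ("impulsivity", "male", "age_z", "unemployed")


class TestBootstrap:
    def test_degenerate_constant_hsv_gives_zero_width_interval(self):
        cfg = SimulationConfig(
            n=6_000, seed=4, noise_sigma=0.0,
            category_dws={"LR": 0.0, "MR": 0.0, "PG": 0.0}, conditions=[],
        )
        persons, _ = simulate_population(cfg)
        est = bootstrap_ci(
            persons, "PG", [], covariates=BOOT_COVARIATES, b=100, seed=1
        )
        assert est.dw == 0.0
        assert est.ci_low == 0.0 and est.ci_high == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism_and_truth_coverage(self):
        persons, _ = simulate_population(SimulationConfig(n=12_000, seed=9))
        conds = None_or_default(persons)
        a = bootstrap_ci(
            persons, "PG", conds, covariates=BOOT_COVARIATES, b=100, seed=42
        )
        b = bootstrap_ci(
            persons, "PG", conds, covariates=BOOT_COVARIATES, b=100, seed=42
        )
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.b_boot >= 95
        assert a.ci_low < a.dw_unclipped < a.ci_high
        assert a.ci_low < 0.46 < a.ci_high  # truth covered at this scale

    def test_requires_minimum_replicates(self):
        persons, _ = simulate_population(SimulationConfig(n=2_000, seed=5))
        with pytest.raises(ValueError, match="b >= 100"):
            bootstrap_ci(persons, "PG", [], b=10, seed=0)


def None_or_default(persons):
    from harmdw.population import default_conditions

    return [s.column for s in default_conditions() if s.column in persons.columns]


class TestCounterfactual:
    def test_null_effect_leaves_hsv_unchanged(self):
        cfg = SimulationConfig(
            n=8_000, seed=6, category_dws={"LR": 0.0, "MR": 0.0, "PG": 0.0}
        )
        persons, _ = simulate_population(cfg)
        sub = _case_frame(persons)
        fit = fit_loglinear(sub, np.ones(len(sub)), None_or_default(sub))
        out = counterfactual_hsv(sub, fit)
        assert out["uplift"] == pytest.approx(0.0, abs=0.02)

    def test_noiseless_uplift_is_dwcat_times_condition_complement(
        self, noiseless_single_condition
    ):
        persons, _ = noiseless_single_condition
        sub = _case_frame(persons)
        fit = fit_loglinear(
            sub, np.ones(len(sub)), ["alcohol_abuse"], censor_ceiling=False
        )
        with_cond = sub[(sub["case"] == 1) & (sub["alcohol_abuse"] == 1)]
        out = counterfactual_hsv(with_cond, fit)
        assert out["uplift"] == pytest.approx(0.46 * (1 - 0.235), abs=1e-10)

    def test_removing_problem_gambling_raises_mean_hsv(self, default_population):
        persons, _ = default_population
        sub = _case_frame(persons)
        fit = fit_loglinear(sub, np.ones(len(sub)), None_or_default(sub))
        out = counterfactual_hsv(sub, fit)
        assert out["counterfactual_mean"] > out["observed_mean"]


class TestConfounding:
    def test_pipeline_beats_naive_under_confounding(self):
        """Impulsivity drives both gambling category and conditions; the
        unadjusted group difference over-attributes comorbidity to
        gambling, while matching + condition terms remove most of it."""
        naive_biases, adj_biases = [], []
        for seed in (11, 12, 13, 14, 15):
            persons, _ = simulate_population(SimulationConfig(n=20_000, seed=seed))
            naive_biases.append(naive_dw(persons, "PG") - 0.46)
            adj = elicit_category_dws(persons, categories=["PG"], seed=seed)[0]
            adj_biases.append(adj.dw_unclipped - 0.46)
        naive_bias = np.mean(naive_biases)
        adj_bias = np.mean(adj_biases)
        assert naive_bias > 0.02  # upward-biased
        assert abs(adj_bias) <= 0.5 * abs(naive_bias)
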