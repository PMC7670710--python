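"""Synthetic-population generator: determinism, calibration, HSV model."""

import numpy as np
import pandas as pd
import pytest

from harmdw import ConditionSpec, SimulationConfig, simulate_population
from harmdw.population import (
    CATEGORIES,
    ConfigurationError,
    assign_gambling_category,
    generate_hsv,
    sample_comorbidities,
    sample_risk_factors,
    write_population,
)


class TestRiskFactors:
    def test_seeded_determinism(self):
        a = sample_risk_factors(1000, seed=7)
        b = sample_risk_factors(1000, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_impulsivity_is_standardized(self):
        profiles = sample_risk_factors(10_000, seed=3)
        assert abs(profiles["impulsivity"].mean()) < 4 / np.sqrt(10_000)

    def test_single_profile_is_complete_and_valid(self):
        p = sample_risk_factors(1, seed=0)
        assert len(p) == 1 and not p.isna().any().any()
        assert p["age"].iloc[0] >= 18
        assert p["venue_distance"].iloc[0] >= 0

    def test_rejects_empty_population(self):
        with pytest.raises(ConfigurationError):
            sample_risk_factors(0, seed=1)


class TestCategoryAssignment:
    def test_null_propensity_matches_target_prevalence(self):
        n = 20_000
        cfg = SimulationConfig(
            n=n, seed=2, propensity_coefficients={}, conditions=[]
        )
        profiles = sample_risk_factors(n, seed=2)
        cats = assign_gambling_category(profiles, cfg, np.random.default_rng(2))
        for cat, target in cfg.category_prevalence.items():
            freq = np.mean(cats == cat)
            tol = 4 * np.sqrt(target * (1 - target) / n)
            assert abs(freq - target) < tol, (cat, freq, target)

    def test_impulsivity_increases_with_severity(self):
        """Higher severity categories carry higher mean impulsivity.

        With fourteen covariates sharing the linear predictor, the MR->PG
        conditional-mean gap (~0.03 SD) is below sampling noise for the
        rare PG group, so the top-category check uses the wider PG-vs-LR
        contrast instead of a strict full ordering.
        """
        persons, _ = simulate_population(
            SimulationConfig(n=100_000, seed=4, conditions=[])
        )
        means = {
            c: persons.loc[persons["pgsi_category"] == c, "impulsivity"].mean()
            for c in CATEGORIES
        }
        assert means["NP"] < means["LR"] < means["MR"]
        assert means["PG"] > means["LR"]

    def test_marginals_stay_on_target_with_nonzero_coefficients(
        self, default_population
    ):
        _, manifest = default_population
        for cat, target in DEFAULTS.items():
            realized = manifest["realized_category_prevalence"][cat]
            tol = 4 * np.sqrt(target * (1 - target) / manifest["n"])
            assert abs(realized - target) < tol

    def test_missing_covariate_is_a_configuration_error(self):
        cfg = SimulationConfig(
            n=100, seed=0, propensity_coefficients={"no_such_factor": 1.0}
        )
        profiles = sample_risk_factors(100, seed=0)
        with pytest.raises(ConfigurationError, match="no_such_factor"):
            assign_gambling_category(profiles, cfg, np.random.default_rng(0))


DEFAULTS = {"NP": 0.90, "LR": 0.06, "MR": 0.03, "PG": 0.01}


class TestComorbiditySampling:
    def test_problem_gambler_prevalence_hits_rr_times_community(self):
        # alcohol abuse: RR 3.9 on community 4.7% -> 18.33% among PG
        spec = ConditionSpec("Alcohol abuse", 0.047, 3.9, 0.235)
        cfg = SimulationConfig(n=200_000, seed=6, conditions=[spec])
        persons, manifest = simulate_population(cfg)
        realized = manifest["realized_conditions"]["Alcohol abuse"]
        assert realized["realized_p_pg"] == pytest.approx(0.1833, abs=0.02)

    def test_unit_rr_means_category_independence(self):
        spec = ConditionSpec("Flat condition", 0.10, 1.0, 0.2)
        cfg = SimulationConfig(
            n=100_000, seed=8, conditions=[spec], confounding_strength=0.0
        )
        persons, _ = simulate_population(cfg)
        by_cat = persons.groupby("pgsi_category")["flat_condition"].mean()
        for cat in CATEGORIES:
            assert by_cat[cat] == pytest.approx(0.10, abs=0.02)

    def test_marginals_conserved_and_rrs_recovered(self):
        """Population marginals match community prevalence by construction,
        and realized PG relative risks land near their targets, for every
        condition whose calibration needed no clipping."""
        persons, manifest = simulate_population(SimulationConfig(n=100_000, seed=9))
        warned = {w.split(":")[0] for w in manifest["calibration_warnings"]}
        checked = 0
        for name, info in manifest["realized_conditions"].items():
            if name in warned:
                continue
            p = info["community_prevalence"]
            n = manifest["n"]
            assert abs(info["realized_marginal"] - p) < 5 * np.sqrt(p * (1 - p) / n)
            assert info["realized_rr"] == pytest.approx(info["target_rr"], rel=0.15)
            checked += 1
        assert checked >= 6

    def test_infeasible_targets_are_clipped_with_warning(self):
        _, manifest = simulate_population(SimulationConfig(n=5_000, seed=1))
        assert any(
            "Adjustment disorder" in w for w in manifest["calibration_warnings"]
        )

    def test_confounding_recentering_preserves_conditional_means(self):
        spec = ConditionSpec("Some condition", 0.10, 3.0, 0.2)
        base = dict(n=150_000, seed=12, conditions=[spec])
        p0, _ = simulate_population(
            SimulationConfig(**base, confounding_strength=0.0)
        )
        p1, _ = simulate_population(
            SimulationConfig(**base, confounding_strength=1.0)
        )
        for pop in (p0, p1):
            pg = pop[pop["pgsi_category"] == "PG"]
            assert pg["some_condition"].mean() == pytest.approx(0.30, abs=0.03)
        # but the tilt induces within-category association with impulsivity
        pg1 = p1[p1["pgsi_category"] == "NP"]
        assert (
            pg1.loc[pg1["some_condition"] == 1, "impulsivity"].mean()
            > pg1.loc[pg1["some_condition"] == 0, "impulsivity"].mean() + 0.1
        )


class TestHSVGeneration:
    def test_full_health_without_conditions_or_gambling(self):
        cfg = SimulationConfig(
            n=2_000, seed=5, noise_sigma=0.0,
            category_dws={"LR": 0.0, "MR": 0.0, "PG": 0.0}, conditions=[],
        )
        persons, _ = simulate_population(cfg)
        assert np.all(persons["hsv"] == 1.0)

    def test_problem_gambler_with_severe_alcohol_disorder(self):
        # noiseless: HSV = (1 - 0.46)(1 - 0.57) = 0.2322
        spec = ConditionSpec("Severe AUD", 0.047, 3.9, 0.57)
        cfg = SimulationConfig(n=30_000, seed=7, noise_sigma=0.0, conditions=[spec])
        persons, _ = simulate_population(cfg)
        both = persons[(persons["pgsi_category"] == "PG") & (persons["severe_aud"] == 1)]
        assert len(both) > 10
        assert np.allclose(both["hsv"], 0.2322)
        assert np.allclose(both["true_dw_total"], 0.7678)

    def test_noise_is_mean_one_before_clipping(self):
        # a latent low enough that the ceiling never binds
        cfg = SimulationConfig(
            n=100_000, seed=13,
            category_prevalence={"NP": 0.0, "LR": 0.0, "MR": 0.0, "PG": 1.0},
            category_dws={"LR": 0.14, "MR": 0.29, "PG": 0.46},
            conditions=[], propensity_coefficients={},
        )
        persons, _ = simulate_population(cfg)
        assert persons["hsv"].mean() == pytest.approx(0.54, rel=0.01)

    def test_hsv_bounded(self, default_population):
        persons, _ = default_population
        assert persons["hsv"].between(0.0, 1.0).all()


class TestSimulatePopulation:
    def test_byte_identical_outputs_across_runs(self, tmp_path):
        cfg = SimulationConfig(n=500, seed=21)
        for sub in ("a", "b"):
            persons, manifest = simulate_population(cfg)
            write_population(persons, manifest, tmp_path / sub)
        assert (tmp_path / "a" / "population.csv").read_bytes() == (
            tmp_path / "b" / "population.csv"
        ).read_bytes()
        assert (tmp_path / "a" / "manifest.json").read_bytes() == (
            tmp_path / "b" / "manifest.json"
        ).read_bytes()

    def test_rejects_empty_population(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=0)

    def test_rejects_unknown_config_keys_and_bad_prevalence(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            SimulationConfig.from_dict({"n": 10, "nonsense": 1})
        with pytest.raises(ConfigurationError, match="sum to 1"):
            SimulationConfig(
                n=10, category_prevalence={"NP": 0.5, "LR": 0.1, "MR": 0.1, "PG": 0.1}
            )

    def test_manifest_records_conditions_and_hash(self, default_population):
        persons, manifest = default_population
        assert manifest["config_hash"]
        assert set(manifest["realized_conditions"]) == {
            s["name"] for s in manifest["config"]["conditions"] or []
        } or len(manifest["realized_conditions"]) == 8
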