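"""Seeded synthetic populations with the structure the framework assumes.

The generator produces person-level records with

* risk factors for gambling problems drawn from the five families the
  field recognises (childhood/family, cultural, demographic, geographic,
  personal), including trait impulsivity as the key personal factor;
* a PGSI gambling category (non-problem NP, low-risk LR, moderate-risk MR,
  problem gambler PG) assigned by an ordered-logit propensity model whose
  cutpoints are calibrated so marginal category frequencies match the
  configured prevalences;
* comorbid psychiatric conditions whose prevalence among problem gamblers
  is calibrated to the registry relative risks, with the non-gambler
  prevalence solved so the population marginal equals the community
  prevalence, plus an impulsivity tilt (recentred on the log-odds scale so
  conditional means are preserved) that creates genuine confounding;
* a latent health-state valuation built from the multiplicative
  disability-weight model over the person's gambling category and
  conditions, observed with mean-one multiplicative lognormal noise and
  clipped to ``[hsv_floor, 1]``.

Everything flows from a single seeded ``numpy`` generator: the same
config and seed reproduce the same population exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .registry import ConditionRecord, compute_rr, load_registry

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionSpec",
    "SimulationConfig",
    "ConfigurationError",
    "CATEGORIES",
    "PROPENSITY_COVARIATES",
    "DEFAULT_PROPENSITY_COEFFICIENTS",
    "default_conditions",
    "sample_risk_factors",
    "encode_covariates",
    "assign_gambling_category",
    "sample_comorbidities",
    "generate_hsv",
    "simulate_population",
    "write_population",
]

#: PGSI categories in increasing severity order
CATEGORIES = ("NP", "LR", "MR", "PG")


class ConfigurationError(ValueError):
    """Raised when a simulation / run configuration is invalid."""


def _slug(name: str) -> str:
    out = "".join(ch if ch.isalnum() else "_" for ch in name.lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


@dataclass(frozen=True)
class ConditionSpec:
    """One modelled comorbid condition.

    ``rr_pg`` is the target relative risk of the condition for problem
    gamblers versus the general population; ``dw`` is the scalar
    disability weight the simulator applies when the condition is present.
    """

    name: str
    community_prevalence: float
    rr_pg: float
    dw: float

    @property
    def column(self) -> str:
        return _slug(self.name)


# Simulation weights for registry conditions that publish no severity level;
# chosen to sit beside the closest published analogues (see docs/methods.md).
_FALLBACK_SIM_DW = {
    "Alcohol abuse": 0.235,
    "Alcohol dependence": 0.373,
    "Adjustment disorder": 0.15,
    "Paranoid personality disorder": 0.193,
}

#: default modelled condition set: the registry rows whose published RR is
#: reproducible from the tabulated prevalences, plus cannabis use disorder
_DEFAULT_CONDITION_NAMES = (
    "Alcohol abuse",
    "Alcohol dependence",
    "Dysthymic disorder",
    "Panic disorder",
    "Psychotic disorder",
    "Adjustment disorder",
    "Paranoid personality disorder",
    "Cannabis use disorder",
)


def default_conditions(
    registry: Optional[Sequence[ConditionRecord]] = None,
) -> list[ConditionSpec]:
    """Default condition specs, calibrated to the packaged registry.

    Relative-risk targets are the exact prevalence ratios recomputed from
    the registry; disability weights use the mean of published severity
    midpoints, falling back to package defaults where the registry prints
    none.
    """
    registry = load_registry() if registry is None else registry
    by_name = {rec.name: rec for rec in registry}
    specs = []
    for name in _DEFAULT_CONDITION_NAMES:
        rec = by_name[name]
        est = compute_rr(rec)
        dw = rec.scalar_dw()
        if dw is None:
            dw = _FALLBACK_SIM_DW[name]
        specs.append(
            ConditionSpec(
                name=name,
                community_prevalence=rec.community.mean,
                rr_pg=est.rr,
                dw=dw,
            )
        )
    return specs


#: encoded covariate columns used by both the generative and the fitted
#: propensity models
PROPENSITY_COVARIATES = [
    "age_z",
    "male",
    "unemployed",
    "not_in_labour_force",
    "income_c",
    "education_c",
    "single",
    "divorced",
    "impulsivity",
    "childhood_exposure",
    "venue_proximity",
    "metro",
    "rural",
    "minority_language",
]

# Package defaults; the source literature reports directions, not effect
# sizes, so magnitudes are package choices (documented in docs/methods.md).
DEFAULT_PROPENSITY_COEFFICIENTS = {
    "age_z": -0.4,
    "male": 0.5,
    "unemployed": 0.6,
    "not_in_labour_force": 0.1,
    "income_c": -0.15,
    "education_c": -0.2,
    "single": 0.25,
    "divorced": 0.35,
    "impulsivity": 0.6,
    "childhood_exposure": 0.5,
    "venue_proximity": 0.4,
    "metro": 0.15,
    "rural": -0.1,
    "minority_language": 0.25,
}

DEFAULT_CATEGORY_PREVALENCE = {"NP": 0.90, "LR": 0.06, "MR": 0.03, "PG": 0.01}
DEFAULT_CATEGORY_DWS = {"LR": 0.14, "MR": 0.29, "PG": 0.46}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic population.

    Defaults encode the reference scenario: published Australian category
    disability weights (LR 0.14, MR 0.29, PG 0.46), registry-calibrated
    comorbidity, multiplicative lognormal noise with sigma 0.2, and
    impulsivity-driven confounding of strength 0.5 log-odds per SD.
    """

    n: int = 20_000
    seed: int = 0
    category_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PREVALENCE)
    )
    category_dws: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_DWS))
    benefit_uplift: float = 0.0
    noise_sigma: float = 0.2
    noise_kind: str = "lognormal"  # or "additive" (truncated-normal robustness option)
    confounding_strength: float = 0.5
    rr_fraction_lr: float = 0.25
    rr_fraction_mr: float = 0.5
    np_participation: float = 0.6  # share of non-problem individuals who gamble
    hsv_floor: float = 1e-6
    propensity_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY_COEFFICIENTS)
    )
    conditions: Optional[list[ConditionSpec]] = None  # None -> registry defaults

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"population size must be >= 1, got {self.n}")
        total = sum(self.category_prevalence.get(c, 0.0) for c in CATEGORIES)
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(
                f"category_prevalence must sum to 1, got {total:.6f}"
            )
        if set(self.category_prevalence) - set(CATEGORIES):
            raise ConfigurationError(
                f"unknown categories {set(self.category_prevalence) - set(CATEGORIES)}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.noise_kind not in {"lognormal", "additive"}:
            raise ConfigurationError(f"unknown noise_kind {self.noise_kind!r}")
        if self.benefit_uplift < 0:
            raise ConfigurationError("benefit_uplift must be >= 0")
        for cat, dw in self.category_dws.items():
            if cat not in ("LR", "MR", "PG") or not 0.0 <= dw <= 1.0:
                raise ConfigurationError(f"invalid category DW {cat}={dw}")

    def resolved_conditions(self) -> list[ConditionSpec]:
        return default_conditions() if self.conditions is None else list(self.conditions)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["conditions"] is not None:
            d["conditions"] = [asdict(c) for c in self.conditions]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if data.get("conditions") is not None:
            data["conditions"] = [
                c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
                for c in data["conditions"]
            ]
        return cls(**data)


def sample_risk_factors(n: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw *n* risk-factor profiles, reproducibly for a fixed seed.

    Marginals (documented defaults): age truncated normal (mean 46, sd 17,
    min 18, max 95); gender balanced; employment 62/5/33 employed /
    unemployed / not-in-labour-force; income quintiles uniform; education
    ordinal 1-4 (25/35/25/15); marital 30/50/10/10 single / married /
    divorced / other; impulsivity standard normal; childhood gambling
    exposure 15%; venue distance exponential (mean 8 km); urbanicity
    70/20/10 metro / regional / rural; minority home language 20%.
    Factors are drawn independently.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    age = np.clip(rng.normal(46.0, 17.0, size=n), 18.0, 95.0)
    return pd.DataFrame(
        {
            "age": age,
            "gender": rng.choice(["male", "female"], size=n),
            "employment": rng.choice(
                ["employed", "unemployed", "not_in_labour_force"],
                size=n,
                p=[0.62, 0.05, 0.33],
            ),
            "income": rng.integers(1, 6, size=n),
            "education": rng.choice([1, 2, 3, 4], size=n, p=[0.25, 0.35, 0.25, 0.15]),
            "marital": rng.choice(
                ["single", "married", "divorced", "other"],
                size=n,
                p=[0.30, 0.50, 0.10, 0.10],
            ),
            "impulsivity": rng.normal(0.0, 1.0, size=n),
            "childhood_exposure": rng.random(n) < 0.15,
            "venue_distance": rng.exponential(8.0, size=n),
            "urbanicity": rng.choice(
                ["metro", "regional", "rural"], size=n, p=[0.70, 0.20, 0.10]
            ),
            "minority_language": rng.random(n) < 0.20,
        }
    )


def encode_covariates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix over the standard risk-factor encoding.

    Used identically by the generative propensity model and by the fitted
    one, so simulation studies exercise a correctly-specified matcher.
    """
    return pd.DataFrame(
        {
            "age_z": (profiles["age"] - 45.0) / 15.0,
            "male": (profiles["gender"] == "male").astype(float),
            "unemployed": (profiles["employment"] == "unemployed").astype(float),
            "not_in_labour_force": (
                profiles["employment"] == "not_in_labour_force"
            ).astype(float),
            "income_c": profiles["income"].astype(float) - 3.0,
            "education_c": profiles["education"].astype(float) - 2.5,
            "single": (profiles["marital"] == "single").astype(float),
            "divorced": (profiles["marital"] == "divorced").astype(float),
            "impulsivity": profiles["impulsivity"].astype(float),
            "childhood_exposure": profiles["childhood_exposure"].astype(float),
            "venue_proximity": np.exp(-profiles["venue_distance"] / 10.0),
            "metro": (profiles["urbanicity"] == "metro").astype(float),
            "rural": (profiles["urbanicity"] == "rural").astype(float),
            "minority_language": profiles["minority_language"].astype(float),
        },
        index=profiles.index,
    )


def _linear_predictor(profiles: pd.DataFrame, coefficients: dict) -> np.ndarray:
    design = encode_covariates(profiles)
    unknown = set(coefficients) - set(design.columns)
    if unknown:
        raise ConfigurationError(
            f"propensity coefficients reference unknown covariates: {sorted(unknown)}"
        )
    eta = np.zeros(len(design))
    for name, coef in coefficients.items():
        eta += coef * design[name].to_numpy()
    return eta


def assign_gambling_category(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign PGSI categories by an ordered-logit propensity model.

    Cumulative category probabilities are ``expit(c_k - eta)`` with the
    cutpoints ``c_k`` solved so the *average* probability of each category
    equals the configured marginal prevalence; higher linear predictors
    shift mass toward more severe categories while the population marginal
    stays on target.
    """
    eta = _linear_predictor(profiles, config.propensity_coefficients)
    cum_targets = np.cumsum([config.category_prevalence[c] for c in CATEGORIES])[:-1]
    cutpoints = []
    for target in cum_targets:
        if target <= 0.0:
            cutpoints.append(-np.inf)
            continue
        if target >= 1.0:
            cutpoints.append(np.inf)
            continue
        f = lambda c: expit(c - eta).mean() - target  # noqa: E731
        lo, hi = float(eta.min()) - 40.0, float(eta.max()) + 40.0
        cutpoints.append(brentq(f, lo, hi, xtol=1e-12))
    cum_probs = expit(np.subtract.outer(np.asarray(cutpoints), eta))  # (3, n)
    u = rng.random(len(eta))
    idx = (u[None, :] > cum_probs).sum(axis=0)
    return np.asarray(CATEGORIES)[idx]


def _category_rr(spec: ConditionSpec, config: SimulationConfig) -> dict:
    """Interpolated relative-risk targets per at-risk category."""
    r = spec.rr_pg
    return {
        "LR": 1.0 + config.rr_fraction_lr * (r - 1.0),
        "MR": 1.0 + config.rr_fraction_mr * (r - 1.0),
        "PG": r,
    }


def sample_comorbidities(
    persons: pd.DataFrame,
    conditions: Sequence[ConditionSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample condition indicators calibrated to relative-risk targets.

    For condition ``c`` with community prevalence ``p`` the conditional
    prevalence is ``min(1, r_cat * p)`` in each at-risk category (with
    interpolated RRs below PG) and is solved for non-problem individuals
    so the realized population marginal equals ``p``.  On top of the
    category-conditional mean, individual risk is tilted by
    ``confounding_strength * impulsivity`` on the log-odds scale, then
    recentred (per category) so conditional means are preserved.
    Infeasible targets are clipped with a logged warning; warnings are
    also returned for the manifest.
    """
    warnings_out: list[str] = []
    categories = persons["pgsi_category"].to_numpy()
    z = persons["impulsivity"].to_numpy()
    shares = {c: float(np.mean(categories == c)) for c in CATEGORIES}
    out = pd.DataFrame(index=persons.index)

    for spec in conditions:
        p = spec.community_prevalence
        rr_by_cat = _category_rr(spec, config)
        cond_prev = {}
        for cat, r in rr_by_cat.items():
            q = r * p
            if q > 1.0:
                warnings_out.append(
                    f"{spec.name}: P(condition | {cat}) = {q:.3f} clipped to 1"
                )
                q = 1.0
            cond_prev[cat] = q
        risk_mass = sum(shares[c] * cond_prev[c] for c in ("LR", "MR", "PG"))
        if shares["NP"] > 0:
            q_np = (p - risk_mass) / shares["NP"]
        else:
            q_np = 0.0
        if q_np < 0.0:
            warnings_out.append(
                f"{spec.name}: implied non-problem prevalence {q_np:.4f} clipped to 0;"
                " population marginal will exceed the community prevalence"
            )
            q_np = 0.0
        cond_prev["NP"] = min(q_np, 1.0)

        prob = np.empty(len(persons))
        for cat in CATEGORIES:
            mask = categories == cat
            if not mask.any():
                continue
            q = cond_prev[cat]
            gamma = config.confounding_strength
            if q <= 0.0 or q >= 1.0 or gamma == 0.0:
                prob[mask] = q
                continue
            base = logit(q) + gamma * z[mask]
            # recentre so the category-conditional mean is exactly preserved
            g = lambda d: expit(base + d).mean() - q  # noqa: E731
            delta = brentq(g, -40.0, 40.0, xtol=1e-12)
            prob[mask] = expit(base + delta)
        out[spec.column] = (rng.random(len(persons)) < prob).astype(int)

    for msg in warnings_out:
        logger.warning(msg)
    return out, warnings_out


def generate_hsv(
    persons: pd.DataFrame,
    conditions: Sequence[ConditionSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latent and observed health-state valuations.

    Latent HSV is the product of health-state valuations over the
    gambling-category weight (for LR/MR/PG) and every present condition's
    weight — the multiplicative comorbidity model applied uniformly.
    Non-problem and low-risk individuals who gamble receive a
    ``(1 + benefit_uplift)`` recreational uplift.  Observed HSV multiplies
    the latent value by mean-one lognormal noise ``exp(eps)``,
    ``eps ~ N(-sigma^2/2, sigma)`` (or adds truncated-normal noise under
    the additive option) and clips to ``[hsv_floor, 1]``.
    """
    n = len(persons)
    latent = np.ones(n)
    categories = persons["pgsi_category"].to_numpy()
    for cat, dw in config.category_dws.items():
        latent[categories == cat] *= 1.0 - dw
    for spec in conditions:
        has = persons[spec.column].to_numpy().astype(bool)
        latent[has] *= 1.0 - spec.dw
    true_dw_total = 1.0 - latent

    uplifted = latent.copy()
    if config.benefit_uplift > 0:
        gambles = persons["gambles"].to_numpy().astype(bool)
        rec = gambles & np.isin(categories, ["NP", "LR"])
        uplifted[rec] *= 1.0 + config.benefit_uplift

    sigma = config.noise_sigma
    if sigma == 0:
        observed = uplifted.copy()
    elif config.noise_kind == "lognormal":
        eps = rng.normal(-0.5 * sigma**2, sigma, size=n)
        observed = uplifted * np.exp(eps)
    else:  # additive truncated-normal robustness option
        observed = uplifted + np.clip(rng.normal(0.0, sigma, size=n), -3 * sigma, 3 * sigma)
    observed = np.clip(observed, config.hsv_floor, 1.0)
    return pd.DataFrame(
        {"hsv": observed, "latent_hsv": uplifted, "true_dw_total": true_dw_total},
        index=persons.index,
    )


def simulate_population(
    config: SimulationConfig,
    registry: Optional[Sequence[ConditionRecord]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a full person table plus a reproducibility manifest.

    Composes risk-factor sampling, category assignment, comorbidity
    sampling and HSV generation under one seeded generator.  The manifest
    records the seed, a config hash, realized category prevalences,
    realized condition marginals and relative risks (problem gamblers vs
    whole population), and any calibration warnings.
    """
    conditions = (
        default_conditions(registry) if config.conditions is None else config.conditions
    )
    rng = np.random.default_rng(config.seed)
    persons = sample_risk_factors(config.n, rng)
    persons.insert(0, "person_id", np.arange(config.n))
    persons["pgsi_category"] = assign_gambling_category(persons, config, rng)
    at_risk = persons["pgsi_category"].isin(["LR", "MR", "PG"]).to_numpy()
    persons["gambles"] = at_risk | (rng.random(config.n) < config.np_participation)
    cond_cols, warnings_out = sample_comorbidities(persons, conditions, config, rng)
    persons = pd.concat([persons, cond_cols], axis=1)
    persons = pd.concat(
        [persons, generate_hsv(persons, conditions, config, rng)], axis=1
    )

    realized_rr = {}
    pg = persons["pgsi_category"] == "PG"
    for spec in conditions:
        marginal = float(persons[spec.column].mean())
        p_pg = float(persons.loc[pg, spec.column].mean()) if pg.any() else float("nan")
        realized_rr[spec.name] = {
            "target_rr": spec.rr_pg,
            "community_prevalence": spec.community_prevalence,
            "realized_marginal": marginal,
            "realized_p_pg": p_pg,
            "realized_rr": p_pg / marginal if marginal > 0 else float("nan"),
        }
    manifest = {
        "seed": config.seed,
        "n": config.n,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "realized_category_prevalence": {
            c: float(np.mean(persons["pgsi_category"] == c)) for c in CATEGORIES
        },
        "realized_conditions": realized_rr,
        "calibration_warnings": warnings_out,
        "columns": list(persons.columns),
    }
    return persons, manifest


def write_population(
    persons: pd.DataFrame, manifest: dict, outdir: str | Path
) -> Path:
    """Write ``population.csv`` and ``manifest.json`` into *outdir*."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        persons.to_csv(outdir / "population.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float) + "\n"
        )
    except OSError as exc:
        raise OSError(f"failed writing population outputs to {outdir}: {exc}") from exc
    return outdir
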