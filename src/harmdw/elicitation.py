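"""Indirect elicitation of disability weights from health-state valuations.

Under the multiplicative comorbidity model, a person's latent HSV is a
product of per-condition complements, so its log is linear in condition
indicators:

    log HSV = sum_j log(1 - DW_j) * I_j

The default ("loglinear") estimator regresses log HSV on a gambling-
category indicator and comorbid-condition indicators and reads each
disability weight off as ``1 - exp(beta)``.  Self-reported valuations are
bounded above at full health, and under the generator's mean-one
multiplicative noise a large share of healthy controls sits exactly at
the ceiling; treating those observations as ordinary data attenuates
every coefficient.  The estimator therefore treats HSV = 1 as
right-censored and maximises a weighted censored-normal (Tobit)
likelihood by default; plain weighted least squares is available via
``censor_ceiling=False`` and is exact on noiseless data.

The alternative ("additive") estimator works on the HSV scale with
category x condition interaction terms: expanding
``(1 - a)(1 - b) = 1 - a - b + ab`` shows the multiplicative discount
appears as a *positive* interaction coefficient ``a * b`` offsetting the
negative main effects, i.e. the comorbidity discount of the verbal
"negative interactions" prescription.  DWs are read as the negative of
the category main effect (the effect at zero conditions).

Uncertainty comes from a nonparametric case-resampling bootstrap that
re-runs matching and fitting inside every replicate, so matching
uncertainty is propagated into the interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .population import PROPENSITY_COVARIATES
from .propensity import PropensityMatcher, case_control_frame

logger = logging.getLogger(__name__)

__all__ = [
    "DisabilityWeightEstimator",
    "DWEstimate",
    "fit_loglinear",
    "fit_additive_interactions",
    "extract_dw",
    "bootstrap_ci",
    "counterfactual_hsv",
    "elicit_category_dws",
    "naive_dw",
]


@dataclass
class DWEstimate:
    """A recovered disability weight for one gambling category."""

    category: str
    dw: float  # clipped to [0, 1]
    dw_unclipped: float  # signed point estimate, for bias accounting
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = "loglinear"
    b_boot: int = 0
    clipped: bool = False
    n_effective: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def _clip_dw(value: float) -> tuple[float, bool]:
    clipped = not 0.0 <= value <= 1.0
    if clipped:
        logger.info("disability-weight estimate %.4f clipped into [0, 1]", value)
    return float(np.clip(value, 0.0, 1.0)), clipped


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def _censored_normal_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    censored: np.ndarray,
    limit: float,
) -> tuple[np.ndarray, float, bool]:
    """Weighted MLE of a linear model right-censored at *limit*.

    Returns ``(beta, sigma, converged)``.  Falls back to plain WLS when
    nothing is censored or the data fit exactly (noiseless case).
    """
    beta0 = _weighted_lstsq(X, y, w)
    resid = y - X @ beta0
    sigma0 = float(np.sqrt(np.average(resid**2, weights=w)))
    if not censored.any() or sigma0 < 1e-10:
        return beta0, sigma0, True

    unc = ~censored
    Xu, yu, wu = X[unc], y[unc], w[unc]
    Xc, wc = X[censored], w[censored]

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        r = (yu - Xu @ beta) / sigma
        c = (Xc @ beta - limit) / sigma
        log_cdf = special.log_ndtr(c)
        nll = np.sum(wu * (log_sigma + 0.5 * r**2)) - np.sum(wc * log_cdf)
        hazard = np.exp(-0.5 * c**2 - 0.5 * np.log(2 * np.pi) - log_cdf)
        g_beta = -(Xu.T @ (wu * r)) / sigma - (Xc.T @ (wc * hazard)) / sigma
        g_logsigma = np.sum(wu * (1.0 - r**2)) + np.sum(wc * c * hazard)
        return float(nll), np.append(g_beta, g_logsigma)

    theta0 = np.append(beta0, np.log(max(sigma0, 1e-6)))
    res = optimize.minimize(
        negloglik, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-9},
    )
    _, grad = negloglik(res.x)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-4 * max(
        1.0, float(np.sum(w))
    )
    return res.x[:-1], float(np.exp(res.x[-1])), converged


class DisabilityWeightEstimator(BaseEstimator):
    """Causal model linking gambling category and comorbidity to HSV.

    Parameters
    ----------
    estimator : {"loglinear", "additive"}
        Link scale.  "loglinear" inverts the multiplicative comorbidity
        model exactly (default); "additive" fits the HSV scale with
        category x condition interactions.
    censor_ceiling : bool
        Treat observations at HSV = 1 as right-censored (Tobit
        likelihood).  Set False for plain (weighted) least squares.
    hsv_floor : float
        Lower clip applied to HSV before the log transform.
    category_terms, condition_terms : column lists, set at fit time if None.
    fixed_condition_dws : optional mapping condition column -> known DW;
        their contribution is moved into an offset instead of being
        re-estimated.

    Fitted attributes: ``coef_`` (term -> coefficient), ``intercept_``,
    ``sigma_``, ``terms_``, ``dropped_terms_``, ``n_effective_``,
    ``dw_estimates_``.
    """

    def __init__(
        self,
        estimator: str = "loglinear",
        censor_ceiling: bool = True,
        hsv_floor: float = 1e-6,
        category_terms: Optional[Sequence[str]] = None,
        condition_terms: Optional[Sequence[str]] = None,
        interactions: bool = True,
        fixed_condition_dws: Optional[dict] = None,
    ):
        self.estimator = estimator
        self.censor_ceiling = censor_ceiling
        self.hsv_floor = hsv_floor
        self.category_terms = category_terms
        self.condition_terms = condition_terms
        self.interactions = interactions
        self.fixed_condition_dws = fixed_condition_dws

    # -- design construction ----------------------------------------------

    def _resolve_terms(self, X: pd.DataFrame) -> tuple[list, list]:
        cats = list(self.category_terms) if self.category_terms is not None else [
            c for c in ("LR", "MR", "PG", "case") if c in X.columns
        ]
        conds = list(self.condition_terms) if self.condition_terms is not None else [
            c for c in X.columns if c not in cats
        ]
        return cats, conds

    def _build_design(
        self, X: pd.DataFrame, cats: list, conds: list
    ) -> tuple[np.ndarray, list]:
        cols, names = [], []
        for c in cats + conds:
            cols.append(X[c].to_numpy(dtype=float))
            names.append(c)
        if self.estimator == "additive" and self.interactions:
            for cat in cats:
                for cond in conds:
                    cols.append(
                        X[cat].to_numpy(dtype=float) * X[cond].to_numpy(dtype=float)
                    )
                    names.append(f"{cat}:{cond}")
        design = np.column_stack([np.ones(len(X))] + cols) if cols else np.ones(
            (len(X), 1)
        )
        return design, names

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "DisabilityWeightEstimator":
        if self.estimator not in {"loglinear", "additive"}:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        X = pd.DataFrame(X)
        hsv = np.asarray(y, dtype=float)
        if np.any(hsv < 0) or np.any(hsv > 1):
            raise ValueError("HSV outcomes must lie in [0, 1]")
        w = (
            np.ones(len(X))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ValueError("sample weights must be finite and non-negative")
        keep = w > 0
        X, hsv, w = X.loc[keep].reset_index(drop=True), hsv[keep], w[keep]

        cats, conds = self._resolve_terms(X)
        fixed = dict(self.fixed_condition_dws or {})
        est_conds = [c for c in conds if c not in fixed]

        # drop indicators with no variation in the analysis sample
        dropped = [
            c
            for c in cats + est_conds
            if float(X[c].var()) < 1e-16
        ]
        if dropped:
            logger.warning("dropping zero-variance terms: %s", dropped)
        cats = [c for c in cats if c not in dropped]
        est_conds = [c for c in est_conds if c not in dropped]

        design, names = self._build_design(X, cats, est_conds)
        design, names, dropped_dependent = self._prune_collinear(
            design, names, w, n_main=len(cats) + len(est_conds)
        )
        if dropped_dependent:
            logger.warning(
                "dropping linearly dependent interaction terms: %s",
                dropped_dependent,
            )
            dropped = dropped + dropped_dependent

        if self.estimator == "loglinear":
            yv = np.log(np.clip(hsv, self.hsv_floor, 1.0))
            offset = np.zeros(len(X))
            for cond, dw in fixed.items():
                offset += np.log1p(-dw) * X[cond].to_numpy(dtype=float)
            yv = yv - offset
            limit = 0.0
            censored = hsv >= 1.0 - 1e-12
        else:
            yv = np.clip(hsv, 0.0, 1.0)
            offset = np.zeros(len(X))
            for cond, dw in fixed.items():
                offset -= dw * X[cond].to_numpy(dtype=float)
            yv = yv - offset
            limit = 1.0
            censored = hsv >= 1.0 - 1e-12

        if self.censor_ceiling:
            beta, sigma, converged = _censored_normal_fit(design, yv, w, censored, limit)
        else:
            beta = _weighted_lstsq(design, yv, w)
            resid = yv - design @ beta
            sigma = float(np.sqrt(np.average(resid**2, weights=w)))
            converged = True
        if not converged:
            raise ValueError("disability-weight model failed to converge")

        self.terms_ = names
        self.category_terms_ = cats
        self.condition_terms_ = est_conds
        self.fixed_condition_dws_ = fixed
        self.dropped_terms_ = dropped
        self.intercept_ = float(beta[0])
        self.coef_ = dict(zip(names, beta[1:]))
        self.sigma_ = sigma
        self.n_effective_ = float(w.sum() ** 2 / np.sum(w**2))
        self.dw_estimates_ = self._extract()
        return self

    @staticmethod
    def _prune_collinear(
        design: np.ndarray, names: list, w: np.ndarray, n_main: int
    ) -> tuple[np.ndarray, list, list]:
        """Drop dependent interaction columns; collinear main terms are fatal.

        A collinear main-effect indicator means the requested contrast is
        unidentifiable and is raised as an error listing the offending
        terms; an interaction that is a linear combination of lower-order
        terms (e.g. a condition present only among cases) is dropped.
        """
        sw = np.sqrt(w)[:, None]
        weighted = design * sw
        if np.linalg.matrix_rank(weighted) == design.shape[1]:
            return design, names, []
        # greedy rank construction, intercept first, spec order after
        kept, collinear_main, dropped_inter = [0], [], []
        for j in range(1, design.shape[1]):
            cand = weighted[:, kept + [j]]
            if np.linalg.matrix_rank(cand) > len(kept):
                kept.append(j)
            elif j - 1 < n_main:
                collinear_main.append(names[j - 1])
            else:
                dropped_inter.append(names[j - 1])
        if collinear_main:
            raise ValueError(f"collinear indicator terms: {collinear_main}")
        keep_names = [names[j - 1] for j in kept[1:]]
        return design[:, kept], keep_names, dropped_inter

    # -- extraction & prediction ------------------------------------------

    def _extract(self) -> list[DWEstimate]:
        out = []
        for cat in self.category_terms_:
            beta = self.coef_[cat]
            raw = 1.0 - float(np.exp(beta)) if self.estimator == "loglinear" else -beta
            dw, was_clipped = _clip_dw(raw)
            out.append(
                DWEstimate(
                    category=cat,
                    dw=dw,
                    dw_unclipped=float(raw),
                    method=self.estimator,
                    clipped=was_clipped,
                    n_effective=self.n_effective_,
                )
            )
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted latent HSV for indicator rows in *X*."""
        if not hasattr(self, "coef_"):
            raise ValueError("estimator is not fitted")
        X = pd.DataFrame(X)
        design, names = self._build_design(
            X, self.category_terms_, self.condition_terms_
        )
        beta = np.array(
            [self.intercept_] + [self.coef_.get(nm, 0.0) for nm in names]
        )
        eta = design @ beta
        for cond, dw in self.fixed_condition_dws_.items():
            if self.estimator == "loglinear":
                eta += np.log1p(-dw) * X[cond].to_numpy(dtype=float)
            else:
                eta -= dw * X[cond].to_numpy(dtype=float)
        return np.exp(eta) if self.estimator == "loglinear" else eta


# -- functional wrappers ---------------------------------------------------


def fit_loglinear(
    persons: pd.DataFrame,
    weights,
    condition_cols: Sequence[str],
    category_col: str = "case",
    **params,
) -> DisabilityWeightEstimator:
    """Weighted log-scale fit of HSV on category + condition indicators."""
    est = DisabilityWeightEstimator(
        estimator="loglinear",
        category_terms=[category_col],
        condition_terms=list(condition_cols),
        **params,
    )
    return est.fit(persons[[category_col, *condition_cols]], persons["hsv"], weights)


def fit_additive_interactions(
    persons: pd.DataFrame,
    weights,
    condition_cols: Sequence[str],
    category_col: str = "case",
    **params,
) -> DisabilityWeightEstimator:
    """Additive HSV-scale fit with category x condition interactions."""
    est = DisabilityWeightEstimator(
        estimator="additive",
        category_terms=[category_col],
        condition_terms=list(condition_cols),
        **params,
    )
    return est.fit(persons[[category_col, *condition_cols]], persons["hsv"], weights)


def extract_dw(fit: DisabilityWeightEstimator) -> list[DWEstimate]:
    """Disability-weight estimates from a fitted causal model."""
    return fit.dw_estimates_


def counterfactual_hsv(
    persons: pd.DataFrame,
    fit: DisabilityWeightEstimator,
    category_col: str = "case",
) -> dict:
    """Mean predicted HSV for cases had the gambling condition been absent.

    Conditions are held fixed; only the category indicator is switched
    off.  Returns the counterfactual mean beside the observed case mean
    and the factual model prediction.
    """
    cases = persons[persons[category_col] == 1]
    cols = [category_col, *fit.condition_terms_, *fit.fixed_condition_dws_.keys()]
    cols = [c for c in dict.fromkeys(cols) if c in persons.columns]
    factual = fit.predict(cases[cols])
    cf_rows = cases[cols].copy()
    cf_rows[category_col] = 0
    counterfactual = fit.predict(cf_rows)
    return {
        "observed_mean": float(cases["hsv"].mean()),
        "factual_predicted_mean": float(np.mean(factual)),
        "counterfactual_mean": float(np.mean(counterfactual)),
        "uplift": float(np.mean(counterfactual) - np.mean(factual)),
    }


def naive_dw(persons: pd.DataFrame, case: str = "PG", scale: str = "log") -> float:
    """Unadjusted group-difference DW estimate (no matching, no conditions).

    ``scale="log"``: ``1 - exp(mean log HSV cases - mean log HSV NP)`` —
    the unadjusted analogue of the default estimator; ``scale="linear"``:
    plain difference of mean HSVs.
    """
    cases = persons.loc[persons["pgsi_category"] == case, "hsv"]
    ctrls = persons.loc[persons["pgsi_category"] == "NP", "hsv"]
    if scale == "log":
        return 1.0 - float(
            np.exp(np.log(cases.clip(lower=1e-6)).mean() - np.log(ctrls.clip(lower=1e-6)).mean())
        )
    return float(ctrls.mean() - cases.mean())


# -- matched pipeline ------------------------------------------------------


def _fit_one_category(
    persons: pd.DataFrame,
    category: str,
    condition_cols: Sequence[str],
    covariates: Sequence[str],
    method: str,
    caliper: float,
    estimator: str,
    censor_ceiling: bool,
    fixed_condition_dws: Optional[dict],
) -> tuple[DWEstimate, DisabilityWeightEstimator, PropensityMatcher]:
    design, y, sub = case_control_frame(persons, category, covariates)
    matcher = PropensityMatcher(method=method, caliper=caliper).fit(design, y)
    sub = sub.assign(case=y)
    est = DisabilityWeightEstimator(
        estimator=estimator,
        censor_ceiling=censor_ceiling,
        category_terms=["case"],
        condition_terms=list(condition_cols),
        fixed_condition_dws=fixed_condition_dws,
    ).fit(sub[["case", *condition_cols]], sub["hsv"], matcher.match_.weights)
    dw = est.dw_estimates_[0]
    dw.category = category
    dw.diagnostics = {
        "n_pairs": matcher.match_.n_pairs,
        "n_unmatched": matcher.match_.n_unmatched,
        "max_smd_after": matcher.balance_.max_smd_after,
    }
    return dw, est, matcher


def bootstrap_ci(
    persons: pd.DataFrame,
    category: str,
    condition_cols: Sequence[str],
    covariates: Sequence[str] = tuple(PROPENSITY_COVARIATES),
    method: str = "nearest",
    caliper: float = 0.2,
    estimator: str = "loglinear",
    censor_ceiling: bool = True,
    b: int = 500,
    seed: int = 0,
    fixed_condition_dws: Optional[dict] = None,
    max_failure_rate: float = 0.05,
) -> DWEstimate:
    """Percentile bootstrap interval for one category's disability weight.

    Resamples people — cases and non-problem controls independently, with
    replacement — and re-runs propensity fitting, matching and the causal
    model in every replicate, so matching uncertainty is propagated.
    """
    if b < 100:
        raise ValueError(f"bootstrap needs b >= 100 replicates, got {b}")
    point, _, _ = _fit_one_category(
        persons, category, condition_cols, covariates, method, caliper,
        estimator, censor_ceiling, fixed_condition_dws,
    )
    cases = persons[persons["pgsi_category"] == category]
    ctrls = persons[persons["pgsi_category"] == "NP"]
    rng = np.random.default_rng(seed)
    draws, failures = [], 0
    for _ in range(b):
        boot = pd.concat(
            [
                cases.sample(n=len(cases), replace=True, random_state=rng),
                ctrls.sample(n=len(ctrls), replace=True, random_state=rng),
            ],
            ignore_index=True,
        )
        try:
            est, _, _ = _fit_one_category(
                boot, category, condition_cols, covariates, method, caliper,
                estimator, censor_ceiling, fixed_condition_dws,
            )
            draws.append(est.dw_unclipped)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_rate * b:
        raise RuntimeError(
            f"{failures}/{b} bootstrap replicates failed; data too sparse for "
            f"category {category!r} (cases={len(cases)}, controls={len(ctrls)})"
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    point.ci_low = float(np.clip(lo, 0.0, 1.0))
    point.ci_high = float(np.clip(hi, 0.0, 1.0))
    point.b_boot = len(draws)
    return point


def elicit_category_dws(
    persons: pd.DataFrame,
    categories: Sequence[str] = ("LR", "MR", "PG"),
    condition_cols: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = tuple(PROPENSITY_COVARIATES),
    method: str = "nearest",
    caliper: float = 0.2,
    estimator: str = "loglinear",
    censor_ceiling: bool = True,
    bootstrap: int = 0,
    seed: int = 0,
    fixed_condition_dws: Optional[dict] = None,
) -> list[DWEstimate]:
    """Full matched elicitation: one DW estimate per at-risk category.

    Each category is contrasted against non-problem controls separately:
    propensity fit on the risk-factor covariates, the requested matching
    or weighting, then the causal model with condition indicators.  With
    ``bootstrap > 0`` percentile intervals are attached.
    """
    if condition_cols is None:
        from .population import default_conditions

        condition_cols = [spec.column for spec in default_conditions()]
        condition_cols = [c for c in condition_cols if c in persons.columns]
    out = []
    for i, category in enumerate(categories):
        if bootstrap:
            out.append(
                bootstrap_ci(
                    persons, category, condition_cols, covariates, method,
                    caliper, estimator, censor_ceiling, b=bootstrap,
                    seed=seed + 104729 * (i + 1),
                    fixed_condition_dws=fixed_condition_dws,
                )
            )
        else:
            dw, _, _ = _fit_one_category(
                persons, category, condition_cols, covariates, method,
                caliper, estimator, censor_ceiling, fixed_condition_dws,
            )
            out.append(dw)
    return out
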