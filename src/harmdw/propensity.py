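"""Propensity-score matching and weighting with balance diagnostics.

Comparisons between gambling-harmed cases and unharmed controls are made
on samples matched or weighted to resemble each other on risk factors.
:class:`PropensityMatcher` is a scikit-learn-style estimator: ``fit(X, y)``
takes a covariate frame and a binary case indicator, fits a logistic
propensity model, constructs the requested adjustment (greedy 1:1
nearest-neighbour matching on the logit score within a caliper, or
ATT inverse-probability weights), and computes standardized-mean-
difference balance diagnostics.

Conventions (configurable): caliper 0.2 SD of the logit propensity score;
cases processed in descending score order; matching without replacement;
ATT control weights ``score / (1 - score)`` truncated at their 99th
percentile.  A maximum absolute SMD below 0.1 after adjustment is the
package's working definition of adequate balance — a reporting
convention, not a hard threshold.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools import sm_exceptions
from scipy.special import logit
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityMatcher",
    "MatchResult",
    "BalanceReport",
    "fit_propensity",
    "match_nearest",
    "ipw_weights",
    "balance_diagnostics",
]


@dataclass
class MatchResult:
    """A case/control pairing or weighting produced by the matcher."""

    method: str  # "nearest_1to1" or "ipw_att"
    weights: np.ndarray  # per-person non-negative weight, aligned with X rows
    pairs: Optional[np.ndarray] = None  # (k, 2) positional (case, control) indices
    caliper: Optional[float] = None  # in SD-of-logit-score units
    caliper_width: Optional[float] = None  # on the logit-score scale
    n_unmatched: int = 0
    n_truncated: int = 0

    @property
    def n_pairs(self) -> int:
        return 0 if self.pairs is None else len(self.pairs)


@dataclass
class BalanceReport:
    """Absolute standardized mean differences before and after adjustment."""

    smd_before: dict
    smd_after: dict
    max_smd_after: float
    zero_variance: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smd_before": pd.Series(self.smd_before),
                "smd_after": pd.Series(self.smd_after),
            }
        )


class PropensityMatcher(BaseEstimator):
    """Logistic propensity model plus matching/weighting and diagnostics.

    Parameters
    ----------
    method : {"nearest", "ipw"}
        Adjustment built during :meth:`fit`: greedy 1:1 nearest-neighbour
        matching without replacement, or ATT inverse-probability weights.
    caliper : float
        Maximum pair distance, in SDs of the logit propensity score.
    replace : bool
        Allow controls to be reused under nearest matching.
    truncate_percentile : float
        Percentile at which ATT control weights are truncated.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : fitted logistic coefficients.
    scores_ : propensity scores in (0, 1).
    match_ : :class:`MatchResult` for the requested method.
    balance_ : :class:`BalanceReport` on the fitting covariates.
    converged_ : bool.
    """

    def __init__(
        self,
        method: str = "nearest",
        caliper: float = 0.2,
        replace: bool = False,
        truncate_percentile: float = 99.0,
    ):
        self.method = method
        self.caliper = caliper
        self.replace = replace
        self.truncate_percentile = truncate_percentile

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "PropensityMatcher":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.isna().any().any():
            raise ValueError("covariates must be complete (no missing values)")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        n_cases, n_controls = int(y.sum()), int((1 - y).sum())
        if n_cases < 2 or n_controls < 2:
            raise ValueError(
                f"need >= 2 cases and >= 2 controls, got {n_cases} / {n_controls}"
            )

        design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter(
                    "error", sm_exceptions.PerfectSeparationWarning
                )
                result = sm.Logit(y, design).fit(disp=False, maxiter=100)
        except (
            sm_exceptions.PerfectSeparationError,
            sm_exceptions.PerfectSeparationWarning,
        ) as exc:
            raise ValueError(
                "perfect separation in the propensity model; review the "
                "covariate set (a covariate fully predicts case status)"
            ) from exc
        if not result.mle_retvals.get("converged", False):
            raise ValueError(
                "propensity model did not converge after "
                f"{result.mle_retvals.get('iterations', '?')} iterations"
            )
        scores = np.clip(result.predict(design), 1e-12, 1 - 1e-12)
        if np.min(scores[y == 1]) > 1 - 1e-9 or np.max(scores[y == 0]) < 1e-9:
            raise ValueError(
                "perfect separation in the propensity model; review the covariates"
            )

        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.coef_ = pd.Series(result.params[1:], index=X.columns)
        self.intercept_ = float(result.params[0])
        self.model_result_ = result
        self.converged_ = True
        self.scores_ = scores
        self.logit_scores_ = logit(scores)
        self.y_ = y.astype(int)
        self._X = X

        if self.method == "nearest":
            self.match_ = self.match_nearest(self.caliper)
            if self.match_.n_pairs == 0:
                raise ValueError(
                    "zero matchable case/control pairs within the caliper "
                    f"({self.caliper} SD on the logit scale)"
                )
        elif self.method == "ipw":
            self.match_ = self.ipw_weights()
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.balance_ = self.balance_diagnostics(X)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "scores_"):
            raise ValueError("matcher is not fitted; call fit(X, y) first")

    # -- adjustments -------------------------------------------------------

    def match_nearest(self, caliper: Optional[float] = None) -> MatchResult:
        """Greedy 1:1 nearest-neighbour matching on the logit score.

        Cases are processed in descending score order; each is paired with
        the nearest remaining control within ``caliper * SD(logit score)``
        (ties broken toward the earlier record).  Unmatched cases are
        counted, never silently dropped from the report.
        """
        self._check_fitted()
        caliper = self.caliper if caliper is None else caliper
        ls = self.logit_scores_
        sd = float(np.std(ls, ddof=1))
        width = caliper * sd
        case_idx = np.flatnonzero(self.y_ == 1)
        control_idx = np.flatnonzero(self.y_ == 0)
        order = np.argsort(-ls[case_idx], kind="stable")
        # controls sorted by logit score; stable sort keeps record order on ties
        c_order = np.argsort(ls[control_idx], kind="stable")
        avail_scores = [float(ls[control_idx[j]]) for j in c_order]
        avail_ids = [int(control_idx[j]) for j in c_order]

        pairs = []
        n_unmatched = 0
        for i in case_idx[order]:
            if not avail_scores:
                n_unmatched += 1
                continue
            s = float(ls[i])
            pos = bisect.bisect_left(avail_scores, s)
            best = None
            for cand in (pos - 1, pos):
                if 0 <= cand < len(avail_scores):
                    d = abs(avail_scores[cand] - s)
                    if best is None or d < best[0]:
                        best = (d, cand)
            if best is None or best[0] > width + 1e-12:
                n_unmatched += 1
                continue
            _, cand = best
            pairs.append((int(i), avail_ids[cand]))
            if not self.replace:
                avail_scores.pop(cand)
                avail_ids.pop(cand)
        weights = np.zeros(len(self.y_))
        pair_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
        np.add.at(weights, pair_arr[:, 0], 1.0)
        np.add.at(weights, pair_arr[:, 1], 1.0)
        return MatchResult(
            method="nearest_1to1",
            weights=weights,
            pairs=pair_arr,
            caliper=caliper,
            caliper_width=width,
            n_unmatched=n_unmatched,
        )

    def ipw_weights(self) -> MatchResult:
        """ATT weights: cases 1, controls ``score / (1 - score)``, truncated."""
        self._check_fitted()
        weights = np.where(
            self.y_ == 1, 1.0, self.scores_ / (1.0 - self.scores_)
        )
        ctrl = self.y_ == 0
        cap = float(np.percentile(weights[ctrl], self.truncate_percentile))
        n_truncated = int(np.sum(weights[ctrl] > cap))
        if n_truncated:
            logger.info(
                "truncated %d ATT control weights at the %.0fth percentile (%.3g)",
                n_truncated, self.truncate_percentile, cap,
            )
        weights = np.where(ctrl, np.minimum(weights, cap), weights)
        return MatchResult(method="ipw_att", weights=weights, n_truncated=n_truncated)

    # -- diagnostics -------------------------------------------------------

    def balance_diagnostics(
        self,
        X: Optional[pd.DataFrame] = None,
        match: Optional[MatchResult] = None,
    ) -> BalanceReport:
        """Absolute SMDs per covariate before and after adjustment.

        The denominator is always the pooled SD of the *unadjusted*
        groups, so before/after values are directly comparable.
        Zero-variance covariates are reported as SMD 0 and flagged.
        """
        self._check_fitted()
        X = self._X if X is None else pd.DataFrame(X)
        match = self.match_ if match is None else match
        y = self.y_
        w = match.weights
        smd_before, smd_after, flagged = {}, {}, []
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            case, ctrl = x[y == 1], x[y == 0]
            pooled = np.sqrt(0.5 * (case.var(ddof=1) + ctrl.var(ddof=1)))
            if pooled < 1e-12:
                flagged.append(col)
                smd_before[col] = 0.0
                smd_after[col] = 0.0
                continue
            smd_before[col] = abs(case.mean() - ctrl.mean()) / pooled
            wc, wk = w[y == 1], w[y == 0]
            m_case = np.average(case, weights=wc) if wc.sum() > 0 else case.mean()
            m_ctrl = np.average(ctrl, weights=wk) if wk.sum() > 0 else ctrl.mean()
            smd_after[col] = abs(m_case - m_ctrl) / pooled
        return BalanceReport(
            smd_before=smd_before,
            smd_after=smd_after,
            max_smd_after=max(smd_after.values()) if smd_after else 0.0,
            zero_variance=flagged,
        )


# -- functional wrappers over the estimator --------------------------------


def fit_propensity(
    X: pd.DataFrame, y, method: str = "nearest", **params
) -> PropensityMatcher:
    """Fit a :class:`PropensityMatcher` on covariates *X* and case labels *y*."""
    return PropensityMatcher(method=method, **params).fit(X, y)


def match_nearest(model: PropensityMatcher, caliper: float = 0.2) -> MatchResult:
    """Greedy 1:1 nearest-neighbour match from a fitted propensity model."""
    return model.match_nearest(caliper)


def ipw_weights(model: PropensityMatcher) -> MatchResult:
    """ATT inverse-probability weights from a fitted propensity model."""
    return model.ipw_weights()


def balance_diagnostics(
    model: PropensityMatcher,
    match: MatchResult,
    covariates: Optional[pd.DataFrame] = None,
) -> BalanceReport:
    """SMD balance report for an adjustment on a fitted model."""
    return model.balance_diagnostics(covariates, match)


def case_control_frame(
    persons: pd.DataFrame,
    case: str,
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Subset a person table to one case/control contrast.

    ``case`` is an at-risk PGSI category (``"LR"``, ``"MR"``, ``"PG"``) or
    ``"any"`` (all at-risk categories pooled); controls are always the
    non-problem (NP) group.  Returns the covariate frame, the binary case
    vector, and the person subset, all row-aligned.
    """
    from .population import encode_covariates

    if case == "any":
        mask = persons["pgsi_category"].isin(["LR", "MR", "PG", "NP"])
        is_case = persons.loc[mask, "pgsi_category"] != "NP"
    elif case in ("LR", "MR", "PG"):
        mask = persons["pgsi_category"].isin([case, "NP"])
        is_case = persons.loc[mask, "pgsi_category"] == case
    else:
        raise ValueError(f"unknown case definition {case!r}")
    sub = persons.loc[mask].reset_index(drop=True)
    design = encode_covariates(sub)[list(covariates)]
    return design, is_case.to_numpy(dtype=int), sub
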