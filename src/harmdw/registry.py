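"""Condition registry: comorbid prevalence, relative risk and error propagation.

The packaged registry encodes, per psychiatric condition, the pooled
prevalence among problem/pathological gamblers (with 95% CI), the
general-population ("community") prevalence (with SE or 95% CI), published
disability-weight severity levels where available, and the published
relative risk with its standard error.

The relative risk of a condition is the ratio ``f = A / B`` of the
prevalence among problem gamblers (A) to the community prevalence (B).
Its standard error is propagated to first order (delta method):

    sigma_f ~= |f| * sqrt((sigma_A/A)^2 + (sigma_B/B)^2 - 2*sigma_AB/(A*B))

with the covariance ``sigma_AB`` taken as zero.  Where an input is
published as a 95% CI rather than an SE, the SE is recovered assuming a
symmetric normal interval (half-width / 1.959964).

``recompute_table`` re-derives RR and SE for every usable record and flags
rows whose published RR cannot be reproduced from the tabulated
prevalences (``rr_unverified`` — these reflect undocumented pooling in the
source table and are excluded from exact-reproduction checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceEstimate",
    "DWLevel",
    "ConditionRecord",
    "RelativeRiskEstimate",
    "RegistryError",
    "se_from_ci",
    "relative_risk",
    "propagate_se",
    "load_registry",
    "default_registry_path",
    "recompute_table",
]

#: two-sided 97.5% normal quantile used for the symmetric-CI <-> SE conversion
Z95 = 1.959964


class RegistryError(ValueError):
    """Raised when a registry file violates the documented schema."""


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a symmetric normal 95% confidence interval.

    ``(ci_high - ci_low) / (2 * 1.959964)``.  Degenerate intervals give 0.
    """
    if ci_high < ci_low:
        raise ValueError(f"ci_high ({ci_high}) < ci_low ({ci_low})")
    return (ci_high - ci_low) / (2.0 * Z95)


def relative_risk(a: float, b: float) -> float:
    """Relative risk ``a / b``: prevalence among cases over community prevalence."""
    if b <= 0:
        raise ValueError(f"community prevalence must be positive, got {b!r}")
    if a < 0:
        raise ValueError(f"comorbid prevalence must be non-negative, got {a!r}")
    return a / b


def propagate_se(
    rr: float,
    a: float,
    b: float,
    sigma_a: float,
    sigma_b: float,
    sigma_ab: float = 0.0,
) -> float:
    """First-order (delta-method) standard error of a ratio ``rr = a / b``.

    ``|rr| * sqrt((sigma_a/a)^2 + (sigma_b/b)^2 - 2*sigma_ab/(a*b))``.
    The covariance defaults to zero (independent numerator and denominator).
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive for error propagation")
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("standard errors must be non-negative")
    radicand = (sigma_a / a) ** 2 + (sigma_b / b) ** 2 - 2.0 * sigma_ab / (a * b)
    if radicand < 0:
        raise ValueError(
            f"negative radicand ({radicand:g}) in delta-method propagation; "
            "covariance too large"
        )
    return abs(rr) * math.sqrt(radicand)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A pooled prevalence (proportion) with its uncertainty.

    Exactly one of ``se`` or the CI pair may be absent for records used in
    relative-risk computation; both absent means the record is unusable
    for propagation and is reported as skipped.
    """

    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    se: Optional[float] = None
    n_estimates: Optional[int] = None
    source_population: Literal["treatment_seeking", "community"] = "community"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise RegistryError(f"prevalence {self.mean!r} outside [0, 1]")
        if (self.ci_low is None) != (self.ci_high is None):
            raise RegistryError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not self.ci_low <= self.mean <= self.ci_high:
                raise RegistryError(
                    f"mean {self.mean} outside CI [{self.ci_low}, {self.ci_high}]"
                )

    @property
    def standard_error(self) -> Optional[float]:
        """SE, taken directly or recovered from a symmetric 95% CI."""
        if self.se is not None:
            return self.se
        if self.ci_low is not None:
            return se_from_ci(self.ci_low, self.ci_high)
        return None


@dataclass(frozen=True)
class DWLevel:
    """One published severity level: a label and a scalar weight or a range."""

    label: str
    low: float
    high: float

    @property
    def is_range(self) -> bool:
        return self.low != self.high

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class ConditionRecord:
    """One registry condition with its prevalences and disability weights."""

    name: str
    group: Literal["substance", "mood", "anxiety", "other", "personality"]
    comorbid: PrevalenceEstimate  # treatment-seeking problem gamblers
    community: PrevalenceEstimate  # general population
    comorbid_community_gamblers: Optional[PrevalenceEstimate] = None  # "b" rows
    dw_levels: tuple[DWLevel, ...] = ()
    source_key: str = "a"
    rr_printed: Optional[float] = None
    se_printed: Optional[float] = None

    def scalar_dw(self) -> Optional[float]:
        """Single representative weight: mean of level midpoints, or None."""
        if not self.dw_levels:
            return None
        return float(np.mean([lv.midpoint for lv in self.dw_levels]))


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """A recomputed relative risk with delta-method standard error."""

    rr: float
    se: float
    a: float
    b: float
    sigma_a: float
    sigma_b: float
    sigma_ab: float = 0.0


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def _parse_dw_levels(cell: str, row_label: str) -> tuple[DWLevel, ...]:
    levels = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise RegistryError(f"{row_label}: malformed dw_levels entry {part!r}")
        label, value = part.rsplit(":", 1)
        if "-" in value:
            lo, hi = (float(v) for v in value.split("-"))
        else:
            lo = hi = float(value)
        if not (0.0 <= lo <= hi <= 1.0):
            raise RegistryError(f"{row_label}: dw level {part!r} outside [0, 1]")
        levels.append(DWLevel(label=label.strip(), low=lo, high=hi))
    return tuple(levels)


def _opt_int(value) -> Optional[int]:
    text = str(value).strip()
    if text in {"", "-", "nan", "None"}:
        return None
    return int(float(text))


def _pct(value, row_label: str, column: str) -> Optional[float]:
    """Parse a percentage cell into a proportion; blanks/dashes -> None."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text in {"", "-", "nan"}:
        return None
    pct = float(text)
    if not 0.0 <= pct <= 100.0:
        raise RegistryError(f"{row_label}: {column} = {pct}% outside [0, 100]")
    return pct / 100.0


_COLUMNS = [
    "name", "group", "n_estimates_a", "comorbid_pct_a", "comorbid_ci_low",
    "comorbid_ci_high", "n_estimates_b", "comorbid_pct_b", "community_pct",
    "community_se", "community_ci_low", "community_ci_high", "dw_levels",
    "source_key",
]


def default_registry_path() -> Path:
    """Location of the packaged condition registry CSV."""
    return Path(resources.files("harmdw").joinpath("data/comorbidity_registry.csv"))


def load_registry(path: str | Path | None = None) -> list[ConditionRecord]:
    """Load and validate a registry CSV into ``ConditionRecord`` objects.

    ``path=None`` loads the packaged registry.  Percentages in the file are
    converted to proportions here, once, at the boundary.  Schema
    violations, duplicate names and out-of-range prevalences raise
    :class:`RegistryError` naming the offending row.
    """
    path = default_registry_path() if path is None else Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryError(f"registry {path} missing columns: {missing}")

    records: list[ConditionRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        label = f"row {idx + 2} ({row.get('name', '?')!r})"
        name = str(row["name"]).strip()
        if not name or name == "nan":
            raise RegistryError(f"{label}: empty condition name")
        if name in seen:
            raise RegistryError(f"{label}: duplicate condition name")
        seen.add(name)
        group = str(row["group"]).strip()
        if group not in {"substance", "mood", "anxiety", "other", "personality"}:
            raise RegistryError(f"{label}: unknown group {group!r}")

        try:
            comorbid = PrevalenceEstimate(
                mean=_pct(row["comorbid_pct_a"], label, "comorbid_pct_a"),
                ci_low=_pct(row["comorbid_ci_low"], label, "comorbid_ci_low"),
                ci_high=_pct(row["comorbid_ci_high"], label, "comorbid_ci_high"),
                n_estimates=_opt_int(row["n_estimates_a"]),
                source_population="treatment_seeking",
            )
            community = PrevalenceEstimate(
                mean=_pct(row["community_pct"], label, "community_pct"),
                ci_low=_pct(row["community_ci_low"], label, "community_ci_low"),
                ci_high=_pct(row["community_ci_high"], label, "community_ci_high"),
                se=_pct(row["community_se"], label, "community_se"),
                source_population="community",
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, RegistryError):
                raise
            raise RegistryError(f"{label}: {exc}") from exc

        b_mean = _pct(row["comorbid_pct_b"], label, "comorbid_pct_b")
        b_est = None
        if b_mean is not None:
            b_n = str(row["n_estimates_b"]).strip()
            b_est = PrevalenceEstimate(
                mean=b_mean,
                n_estimates=int(float(b_n)) if b_n not in {"", "nan"} else None,
                source_population="treatment_seeking",
            )

        dw_cell = row.get("dw_levels")
        dw_levels = ()
        if isinstance(dw_cell, str) and dw_cell.strip():
            dw_levels = _parse_dw_levels(dw_cell, label)

        def _opt_float(col: str) -> Optional[float]:
            v = row.get(col)
            if v is None or str(v).strip() in {"", "nan", "-"}:
                return None
            return float(v)

        records.append(
            ConditionRecord(
                name=name,
                group=group,  # type: ignore[arg-type]
                comorbid=comorbid,
                community=community,
                comorbid_community_gamblers=b_est,
                dw_levels=dw_levels,
                source_key=str(row["source_key"]).strip(),
                rr_printed=_opt_float("rr_printed"),
                se_printed=_opt_float("se_printed"),
            )
        )
    return records


def compute_rr(record: ConditionRecord) -> RelativeRiskEstimate:
    """Relative risk and propagated SE for one condition record.

    Uses the treatment-seeking comorbid prevalence as numerator and the
    community prevalence as denominator, with SEs taken directly or
    recovered from symmetric 95% CIs.

    Raises ``ValueError`` if either prevalence or both uncertainties are
    missing.
    """
    a = record.comorbid.mean
    b = record.community.mean
    sigma_a = record.comorbid.standard_error
    sigma_b = record.community.standard_error
    if a is None or b is None:
        raise ValueError(f"{record.name}: missing prevalence")
    if sigma_a is None or sigma_b is None:
        raise ValueError(f"{record.name}: no usable uncertainty")
    rr = relative_risk(a, b)
    se = propagate_se(rr, a, b, sigma_a, sigma_b)
    return RelativeRiskEstimate(rr=rr, se=se, a=a, b=b, sigma_a=sigma_a, sigma_b=sigma_b)


def recompute_table(registry: Sequence[ConditionRecord]) -> pd.DataFrame:
    """Re-derive RR (1 dp) and SE (2 dp) for every registry condition.

    Returns a frame with exact and display-rounded values, the published
    values where present, and two flags: ``rr_unverified`` (published RR
    does not equal the rounded recomputed ratio, indicating undocumented
    pooling in the source) and ``skipped`` (record lacks the inputs for
    propagation; reported, not fatal).
    """
    rows = []
    for rec in registry:
        entry: dict = {
            "condition": rec.name,
            "group": rec.group,
            "rr": np.nan,
            "se": np.nan,
            "rr_display": np.nan,
            "se_display": np.nan,
            "rr_printed": rec.rr_printed,
            "se_printed": rec.se_printed,
            "rr_unverified": False,
            "skipped": False,
        }
        try:
            est = compute_rr(rec)
        except ValueError:
            entry["skipped"] = True
        else:
            entry["rr"] = est.rr
            entry["se"] = est.se
            entry["rr_display"] = _round_half_up(est.rr, 1)
            entry["se_display"] = _round_half_up(est.se, 2)
            if rec.rr_printed is not None:
                entry["rr_unverified"] = not math.isclose(
                    entry["rr_display"], rec.rr_printed, abs_tol=1e-9
                )
        rows.append(entry)
    return pd.DataFrame(rows)
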