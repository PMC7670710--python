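"""Non-fatal burden: years lived with disability (YLD).

YLD for a condition is ``prevalence x DW x population`` person-years per
year.  Category DWs recovered by the indirect-elicitation pipeline are
already net of comorbidity, so no further comorbidity scaling is applied
here; the Mathers adjustment in :mod:`harmdw.dw_algebra` remains
available for comparison runs with directly elicited weights.  Fatal
burden (YLL) and DALY totals are out of scope; the report schema reserves
the fields, left empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .elicitation import DWEstimate

__all__ = ["BurdenEstimate", "yld", "category_burden"]


@dataclass(frozen=True)
class BurdenEstimate:
    """Per-category non-fatal burden."""

    category: str
    prevalence: float
    dw: float
    population: int
    yld: float  # person-years per year
    yld_per_1000: float
    yll: Optional[float] = None  # reserved; mortality not modelled
    daly: Optional[float] = None  # reserved


def yld(prevalence: float, dw: float, population: float) -> float:
    """Years lived with disability: ``prevalence * dw * population``."""
    if prevalence < 0 or not 0.0 <= dw <= 1.0 or population < 0:
        raise ValueError(
            f"invalid YLD inputs: prevalence={prevalence}, dw={dw}, "
            f"population={population}"
        )
    return prevalence * dw * population


def category_burden(
    dw_estimates: Sequence[DWEstimate] | Mapping[str, float],
    category_prevalences: Mapping[str, float],
    population: int,
) -> tuple[list[BurdenEstimate], dict]:
    """Per-category and total YLD, with the aggregate-harm comparison.

    Returns the burden list plus a summary reporting total YLD and
    whether combined low-risk + moderate-risk YLD exceeds problem-gambler
    YLD (the prevention-paradox pattern: many mildly affected people can
    outweigh the few severely affected).
    """
    if isinstance(dw_estimates, Mapping):
        dws = dict(dw_estimates)
    else:
        dws = {est.category: est.dw for est in dw_estimates}
    if set(dws) != set(category_prevalences):
        raise ValueError(
            f"category mismatch: DWs for {sorted(dws)} vs prevalences for "
            f"{sorted(category_prevalences)}"
        )
    out = []
    for cat in dws:
        prev = category_prevalences[cat]
        y = yld(prev, dws[cat], population)
        out.append(
            BurdenEstimate(
                category=cat,
                prevalence=prev,
                dw=dws[cat],
                population=population,
                yld=y,
                yld_per_1000=prev * dws[cat] * 1000.0,
            )
        )
    total = sum(b.yld for b in out)
    lr_mr = sum(b.yld for b in out if b.category in ("LR", "MR"))
    pg = sum(b.yld for b in out if b.category == "PG")
    summary = {
        "total_yld": total,
        "lr_mr_yld": lr_mr,
        "pg_yld": pg,
        "lr_mr_exceeds_pg": lr_mr > pg,
    }
    return out, summary


def burden_frame(estimates: Sequence[BurdenEstimate]) -> pd.DataFrame:
    """Tabular burden report (reserved YLL/DALY columns left empty)."""
    return pd.DataFrame(
        [
            {
                "category": b.category,
                "prevalence": b.prevalence,
                "dw": b.dw,
                "population": b.population,
                "yld": b.yld,
                "yld_per_1000": b.yld_per_1000,
                "yll": b.yll,
                "daly": b.daly,
            }
            for b in estimates
        ]
    )
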