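"""Arithmetic on disability weights and health-state valuations.

A disability weight (DW) measures the severity of a health state on
``[0, 1]``: 0 means the state carries no health loss, 1 a state equivalent
to death.  Its complement, the health-state valuation (HSV), is the scale
used by quality-adjusted life-year analyses.

When a person lives with several conditions at once, the package follows
the multiplicative comorbidity model: health-state valuations multiply, so
the combined weight for conditions ``1..n`` is

    DW_[1,n] = 1 - prod_j (1 - DW_j)

which is always at least the largest component weight and never exceeds
the (capped) sum of the components.  The classic worked example: a problem
gambler (DW 0.46) with severe alcohol use disorder (DW 0.57) carries a
combined weight of 1 - 0.54 * 0.43 = 0.77, not 1.03.

The module also implements the Mathers-style adjustment used to derive
comorbidity-consistent individual weights: the most severe condition keeps
its weight, and each milder condition is assigned the composite weight
minus the severe weight.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

__all__ = [
    "validate_dw",
    "combine_pair",
    "combine_many",
    "adjust_milder_weight",
    "hsv_from_dw",
    "dw_from_hsv",
]


def validate_dw(value: float, name: str = "disability weight") -> float:
    """Check that *value* is a valid weight on [0, 1] and return it as float.

    Raises ``ValueError`` naming the offending value otherwise.  Both
    endpoints are permitted (0 = no health loss, 1 = equivalent to death).
    """
    v = float(value)
    if math.isnan(v) or not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return v


def combine_pair(dw1: float, dw2: float) -> float:
    """Combined disability weight of two co-occurring conditions.

    Implements the multiplicative model ``1 - (1 - dw1) * (1 - dw2)``.
    Symmetric in its arguments; the result lies in
    ``[max(dw1, dw2), min(1, dw1 + dw2)]``.

    >>> round(combine_pair(0.46, 0.57), 2)
    0.77
    """
    a = validate_dw(dw1, "dw1")
    b = validate_dw(dw2, "dw2")
    return 1.0 - (1.0 - a) * (1.0 - b)


def combine_many(dws: Iterable[float]) -> float:
    """Combined disability weight of any number of co-occurring conditions.

    ``1 - prod_j (1 - dw_j)``; order-invariant.  An empty collection means
    no conditions and maps to 0 (full health); a single weight is returned
    unchanged.
    """
    survival = 1.0  # product of health-state valuations
    for i, dw in enumerate(dws):
        survival *= 1.0 - validate_dw(dw, f"dws[{i}]")
    return 1.0 - survival


def adjust_milder_weight(severe: float, milder: float) -> float:
    """Comorbidity-adjusted weight for the milder of two conditions.

    The more severe condition keeps its weight; the milder one is adjusted
    so the two sum exactly to the multiplicative composite:
    ``combine_pair(severe, milder) - severe``, which equals
    ``milder * (1 - severe)`` and lies in ``[0, milder]``.

    Raises ``ValueError`` if ``severe < milder`` — the caller must order
    the arguments.
    """
    s = validate_dw(severe, "severe")
    m = validate_dw(milder, "milder")
    if s < m:
        raise ValueError(
            f"severe weight ({s}) must be >= milder weight ({m}); "
            "order the arguments by severity"
        )
    # clamp the tiny negative float residue possible when m == 0
    return max(0.0, combine_pair(s, m) - s)


def hsv_from_dw(dw: float) -> float:
    """Health-state valuation paired with a disability weight: ``1 - dw``."""
    return 1.0 - validate_dw(dw, "dw")


def dw_from_hsv(hsv: float) -> float:
    """Disability weight paired with a health-state valuation: ``1 - hsv``."""
    return 1.0 - validate_dw(hsv, "hsv")


def composite_bounds(dws: Sequence[float]) -> tuple[float, float]:
    """Lower/upper bounds that any composite weight must satisfy.

    Returns ``(max(dws), min(1, sum(dws)))``; ``(0.0, 0.0)`` when empty.
    """
    ws = [validate_dw(d, f"dws[{i}]") for i, d in enumerate(dws)]
    if not ws:
        return 0.0, 0.0
    return max(ws), min(1.0, sum(ws))
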