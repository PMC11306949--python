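"""Pearson correlations with one-tailed Fisher-transform intervals.

Companion inference for graph findings: the correlation between an
attribute-membership indicator and disease-group membership (or between two
raw metric series) with a one-sided 95% confidence bound obtained on the
atanh scale (SE = 1/sqrt(n-3)) and the matching one-tailed p-value for the
null of independence.  The tested side defaults to the sign of the point
estimate, so reported intervals are "fully above 0" or "fully below 0"
style bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .attributes import IncidenceMatrix
from .cohort import CohortAssignment

__all__ = [
    "CorrelationResult",
    "pearson_ci",
    "attribute_group_correlation",
    "attribute_group_correlations",
]


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_lower: float
    ci_upper: float
    p_value: float
    side: str  # "greater" or "less"
    degenerate: bool = False
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "side": self.side,
            "degenerate": self.degenerate,
            "undefined": self.undefined,
        }


def pearson_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    side: Optional[str] = None,
) -> CorrelationResult:
    """Pearson r with a one-sided Fisher-transform confidence bound.

    Pairs with a missing value in either series are dropped (pairwise
    deletion).  For ``side="greater"`` the interval is
    [tanh(z - z_level * SE), 1]; for ``side="less"`` it is
    [-1, tanh(z + z_level * SE)].  ``side`` defaults to the sign of r.
    """
    xs = pd.Series(list(x), dtype=float)
    ys = pd.Series(list(y), dtype=float)
    if len(xs) != len(ys):
        raise ValueError("x and y must have equal length")
    mask = xs.notna() & ys.notna()
    xv = xs[mask].to_numpy(dtype=float)
    yv = ys[mask].to_numpy(dtype=float)
    n = int(xv.size)
    if n < 4:
        raise ValueError(f"need >= 4 pairwise-complete observations, got {n}")
    if np.std(xv) == 0.0 or np.std(yv) == 0.0:
        return CorrelationResult(
            r=math.nan, n=n, ci_lower=math.nan, ci_upper=math.nan,
            p_value=math.nan, side=side or "greater", undefined=True,
        )
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:  # collinear up to round-off
        r = math.copysign(1.0, r)
    if side is None:
        side = "less" if r < 0 else "greater"
    if side not in ("greater", "less"):
        raise ValueError(f"side must be 'greater' or 'less', got {side!r}")
    if abs(r) == 1.0:
        return CorrelationResult(
            r=r, n=n, ci_lower=r, ci_upper=r, p_value=0.0, side=side, degenerate=True
        )
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    z_crit = float(sps.norm.ppf(level))
    if side == "greater":
        ci_lower = math.tanh(z - z_crit * se)
        ci_upper = 1.0
        p = float(sps.norm.sf(z / se))
    else:
        ci_lower = -1.0
        ci_upper = math.tanh(z + z_crit * se)
        p = float(sps.norm.cdf(z / se))
    return CorrelationResult(r=r, n=n, ci_lower=ci_lower, ci_upper=ci_upper, p_value=p, side=side)


def attribute_group_correlation(
    incidence: IncidenceMatrix,
    assignment: CohortAssignment,
    attribute_id: str,
    level: float = 0.95,
    side: Optional[str] = None,
) -> CorrelationResult:
    """Correlation of attribute membership with disease membership.

    Both are encoded as 0/1 indicators over the participants with a valid
    value for the attribute's variable (phi / point-biserial style).
    """
    member = incidence.member[attribute_id]
    valid = incidence.valid[attribute_id]
    disease = assignment.disease_mask().reindex(member.index)
    x = member[valid].astype(float)
    y = disease[valid].astype(float)
    return pearson_ci(x, y, level=level, side=side)


def attribute_group_correlations(
    incidence: IncidenceMatrix,
    assignment: CohortAssignment,
    level: float = 0.95,
) -> pd.DataFrame:
    """Table of attribute-vs-group correlations for every attribute."""
    rows = []
    for a in incidence.attributes:
        try:
            res = attribute_group_correlation(incidence, assignment, a.attribute_id, level=level)
        except ValueError:
            continue
        rows.append({"attribute_id": a.attribute_id, **res.as_dict()})
    return pd.DataFrame(rows)
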