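"""Dashboard data preparation: binned distributions and group averages.

Metric values are rounded to the nearest multiple of a bin width chosen
from {0.1, 0.5, 1, 5, 10, 50} by the within-group SD.  Bins holding fewer
than 3 participants or less than 0.5% of the group are summarized: their
participants are pooled into ``summarized_count`` and only qualifying bins
are kept.  A distribution with no qualifying bin is flagged removed.

The SD -> width mapping (largest allowed width <= SD/3) and the pooling
mechanics are our own documented choices; only the retention thresholds
are from the published method.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortAssignment, CohortTable
from .config import DashboardConfig

__all__ = [
    "BIN_WIDTHS",
    "BinnedDistribution",
    "bin_width_for",
    "binned_distribution",
    "normalized_group_averages",
    "conditional_bin_averages",
    "build_dashboard",
]

BIN_WIDTHS: tuple[float, ...] = (0.1, 0.5, 1, 5, 10, 50)

GROUPS = ("disease", "control", "all")


def bin_width_for(
    sd: float,
    widths: Sequence[float] = BIN_WIDTHS,
    sd_divisor: float = 3.0,
) -> float:
    """Largest allowed width <= sd / sd_divisor, floored at the smallest width."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    candidates = [w for w in widths if w <= sd / sd_divisor]
    return max(candidates) if candidates else min(widths)


def _round_to_width(values: np.ndarray, width: float) -> np.ndarray:
    """Round to the nearest multiple of width, halves away from zero."""
    k = np.sign(values) * np.floor(np.abs(values) / width + 0.5)
    return np.round(k * width, 10)


@dataclass
class BinnedDistribution:
    variable: str
    group: str
    bin_width: float
    bins: list[tuple[float, int]] = field(default_factory=list)  # ordered by bin value
    summarized_count: int = 0
    removed: bool = False
    n_valid: int = 0

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.bins) + self.summarized_count


def binned_distribution(
    values: Iterable[float],
    variable: str = "",
    group: str = "all",
    width: Optional[float] = None,
    config: DashboardConfig | None = None,
) -> BinnedDistribution:
    """Bin one group's values of a metric variable and summarize small bins.

    A bin is retained iff it holds >= 3 participants AND >= 0.5% of the
    group's valid values (configurable); everything else is pooled into
    ``summarized_count``.  ``removed`` is set when no bin qualifies.
    """
    cfg = config or DashboardConfig()
    arr = np.asarray(pd.Series(list(values), dtype=float).dropna(), dtype=float)
    n = int(arr.size)
    if width is None:
        sd = float(np.std(arr, ddof=1)) if n >= 2 else 0.0
        width = bin_width_for(sd, widths=cfg.widths, sd_divisor=cfg.sd_divisor)
    dist = BinnedDistribution(variable=variable, group=group, bin_width=float(width), n_valid=n)
    if n == 0:
        dist.removed = True
        return dist
    counts = Counter(_round_to_width(arr, width).tolist())
    retained: list[tuple[float, int]] = []
    summarized = 0
    for bin_value in sorted(counts):
        c = counts[bin_value]
        if c >= cfg.min_bin_count and c / n >= cfg.min_bin_share:
            retained.append((float(bin_value), int(c)))
        else:
            summarized += int(c)
    dist.bins = retained
    dist.summarized_count = summarized
    dist.removed = not retained
    return dist


def _group_values(
    table: CohortTable, assignment: CohortAssignment, variable: str, group: str
) -> pd.Series:
    values = table.values_for(variable)
    if group == "all":
        return values
    if group == "disease":
        return values[assignment.disease_mask()]
    if group == "control":
        return values[~assignment.disease_mask()]
    raise ValueError(f"unknown group {group!r}")


def normalized_group_averages(
    table: CohortTable, assignment: CohortAssignment
) -> pd.DataFrame:
    """Per metric variable: group means divided by the maximum group mean.

    Rows are variables, columns are disease/control/all; the maximum of the
    three means maps to 1.  Groups without valid values stay NaN.
    """
    rows = {}
    for var, meta in table.meta.items():
        if meta.data_kind != "metric":
            continue
        means = {}
        for group in GROUPS:
            vals = _group_values(table, assignment, var, group).dropna()
            means[group] = float(vals.mean()) if len(vals) else np.nan
        finite = [m for m in means.values() if np.isfinite(m)]
        peak = max(finite, default=np.nan)
        rows[var] = {
            g: (m / peak if np.isfinite(m) and peak != 0 else np.nan) for g, m in means.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS))


def conditional_bin_averages(
    v1: str,
    v2: str,
    group: str,
    table: CohortTable,
    assignment: CohortAssignment,
    width: Optional[float] = None,
    config: DashboardConfig | None = None,
) -> list[tuple[float, float]]:
    """Mean of v2 per retained bin of v1, within one participant group.

    Participants missing either variable are excluded pairwise; the binning
    and retention rules match :func:`binned_distribution` applied to the
    pairwise-complete values of v1.
    """
    cfg = config or DashboardConfig()
    x = _group_values(table, assignment, v1, group)
    y = _group_values(table, assignment, v2, group)
    mask = x.notna() & y.notna()
    x, y = x[mask].to_numpy(dtype=float), y[mask].to_numpy(dtype=float)
    dist = binned_distribution(x, variable=v1, group=group, width=width, config=cfg)
    if dist.removed:
        return []
    binned = _round_to_width(x, dist.bin_width)
    out = []
    for bin_value, _count in dist.bins:
        sel = binned == bin_value
        out.append((bin_value, float(np.mean(y[sel]))))
    return out


def build_dashboard(
    table: CohortTable,
    assignment: CohortAssignment,
    pairs: Sequence[tuple[str, str]] | None = None,
    config: DashboardConfig | None = None,
) -> dict:
    """Assemble the dashboard payload (JSON-ready)."""
    cfg = config or DashboardConfig()
    metric_vars = [v for v, m in table.meta.items() if m.data_kind == "metric"]
    distributions = []
    for var in metric_vars:
        for group in GROUPS:
            dist = binned_distribution(
                _group_values(table, assignment, var, group),
                variable=var,
                group=group,
                config=cfg,
            )
            distributions.append(
                {
                    "variable": dist.variable,
                    "group": dist.group,
                    "bin_width": dist.bin_width,
                    "bins": [[v, c] for v, c in dist.bins],
                    "summarized_count": dist.summarized_count,
                    "removed": dist.removed,
                    "n_valid": dist.n_valid,
                }
            )
    averages = normalized_group_averages(table, assignment)
    conditionals = []
    for v1, v2 in pairs or []:
        for group in GROUPS:
            series = conditional_bin_averages(v1, v2, group, table, assignment, config=cfg)
            conditionals.append(
                {
                    "x_variable": v1,
                    "y_variable": v2,
                    "group": group,
                    "series": [[b, m] for b, m in series],
                }
            )
    averages_records = [
        {"variable": var, **{g: (None if pd.isna(row[g]) else float(row[g])) for g in GROUPS}}
        for var, row in averages.iterrows()
    ]
    return {
        "group_sizes": {
            "disease": assignment.g_d,
            "control": assignment.g_c,
            "all": assignment.g_total,
        },
        "distributions": distributions,
        "normalized_averages": averages_records,
        "conditional_averages": conditionals,
    }
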