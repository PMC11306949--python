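"""Run configuration: thresholds, filtering rules, dashboard options."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "NodeThresholds",
    "EdgeThresholds",
    "GraphConfig",
    "FilterConfig",
    "DashboardConfig",
    "RunConfig",
]


class NodeThresholds(BaseModel):
    """Cut points for frequency and distinction labels."""

    freq_high: float = 0.5
    freq_low: float = 0.1
    delta_high: float = 0.2
    gamma_high: float = 2.0
    delta_related: float = 0.1
    gamma_related: float = 1.5


class EdgeThresholds(BaseModel):
    """Cut points for the conditional-difference edge types."""

    delta_high: float = 0.2
    gamma_high: float = 2.0
    delta_medium: float = 0.1
    gamma_medium: float = 1.5


class GraphConfig(BaseModel):
    node: NodeThresholds = Field(default_factory=NodeThresholds)
    edge: EdgeThresholds = Field(default_factory=EdgeThresholds)
    #: How the two groups' edge magnitudes combine into one type decision.
    aggregation: Literal["max", "disease", "control"] = "max"
    #: Include edges between attributes of the same variable (default off:
    #: mutually exclusive bands give degenerate q=0 edges).
    same_variable_edges: bool = False
    #: Type suppressive edges by magnitude (|delta'|, max(gamma', 1/gamma')).
    magnitude: bool = True


class FilterConfig(BaseModel):
    """Graph pruning rules.

    The default values are NOT from the published method (its exact
    filtering procedure is unavailable); they are conservative choices that
    suppress unstable small-count ratios.
    """

    min_abs_count: int = 10
    min_max_share: float = 0.01
    keep_low_edges: bool = False
    min_cooccurrence: int = 10
    node_whitelist: Optional[list[str]] = None
    node_blacklist: list[str] = Field(default_factory=list)

    @field_validator("min_abs_count", "min_cooccurrence")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("counts must be >= 0")
        return v

    @field_validator("min_max_share")
    @classmethod
    def _share(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("shares must lie in [0, 1]")
        return v


class DashboardConfig(BaseModel):
    widths: list[float] = Field(default_factory=lambda: [0.1, 0.5, 1, 5, 10, 50])
    # Invented mapping: bin width is the largest allowed w <= sd / sd_divisor.
    sd_divisor: float = 3.0
    min_bin_count: int = 3
    min_bin_share: float = 0.005


class RunConfig(BaseModel):
    """Top-level configuration consumed by the CLI."""

    graph: GraphConfig = Field(default_factory=GraphConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    dashboard: DashboardConfig = Field(default_factory=DashboardConfig)
    missing_markers: list[str] = Field(default_factory=lambda: ["", "NA", "NaN"])
    seed: Optional[int] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(obj)
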