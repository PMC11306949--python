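"""Node/edge statistics, label assignment, and graph assembly.

Every node carries, per group, the absolute member count, the relative
total share (group-size denominator) and the relative attribute share
(valid-count denominator, i.e. adjusted for missing values), plus the
absolute difference delta and max/min quotient gamma of the two attribute
shares.  Edges carry the co-occurrence count, the relative conditional
share q (fraction of source members also holding the target attribute) and
its signed difference delta' and quotient gamma' against the target's
unconditional attribute share.

Label rules:

* frequency (from the maximum attribute share p):
  p >= 0.5 highly_frequent | 0.1 <= p < 0.5 frequent | p < 0.1 infrequent
* distinction: delta >= 0.2 or gamma >= 2.0 -> highly_related /
  highly_inverse (by direction); else delta >= 0.1 or gamma >= 1.5 ->
  related / inverse; else unrelated.
* edge type: delta' >= 0.2 or gamma' >= 2.0 -> high conditional
  difference; else delta' >= 0.1 or gamma' >= 1.5 -> medium; else low.

Node computation is linear in variables and sample size; edge computation
is quadratic in the number of variables and linear in the sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .attributes import (
    AttributeDef,
    IncidenceMatrix,
    apply_overrides,
    compute_reference_ranges,
    derive_attributes,
)
from .cohort import CohortAssignment, CohortSpec, CohortTable, assign_cohorts
from .config import EdgeThresholds, GraphConfig, NodeThresholds

__all__ = [
    "BuildError",
    "NodeStats",
    "EdgeStats",
    "AAGraph",
    "FREQUENCY_LABELS",
    "DISTINCTION_LABELS",
    "EDGE_TYPES",
    "node_statistics",
    "assign_frequency_label",
    "assign_distinction_label",
    "edge_statistics",
    "assign_edge_type",
    "build_graph",
    "share_comparison",
]

HIGHLY_FREQUENT = "highly_frequent"
FREQUENT = "frequent"
INFREQUENT = "infrequent"
FREQUENCY_LABELS = (HIGHLY_FREQUENT, FREQUENT, INFREQUENT)

HIGHLY_RELATED = "highly_related"
RELATED = "related"
UNRELATED = "unrelated"
INVERSE = "inverse"
HIGHLY_INVERSE = "highly_inverse"
DISTINCTION_LABELS = (HIGHLY_RELATED, RELATED, UNRELATED, INVERSE, HIGHLY_INVERSE)

HIGH_COND_DIFF = "high_cond_diff"
MEDIUM_COND_DIFF = "medium_cond_diff"
LOW_COND_DIFF = "low_cond_diff"
EDGE_TYPES = (HIGH_COND_DIFF, MEDIUM_COND_DIFF, LOW_COND_DIFF)

# Threshold comparisons are made on values rounded to 12 decimals so that a
# difference like 0.5 - 0.3 (binary float 0.19999999999999998) still meets a
# decimal cut point of 0.2.  Stored statistics keep full precision.
_CMP_DECIMALS = 12


def _cmp(value: float) -> float:
    if value is None or math.isinf(value) or math.isnan(value):
        return value
    return round(value, _CMP_DECIMALS)


class BuildError(RuntimeError):
    """Raised when a graph cannot be assembled (e.g. an empty group)."""


@dataclass
class NodeStats:
    """Per-node cohort-comparison statistics and labels."""

    attribute_id: str
    c_d: int
    c_c: int
    g_d: int
    g_c: int
    n_d: int
    n_c: int
    rel_total_d: Optional[float] = None
    rel_total_c: Optional[float] = None
    p_d: Optional[float] = None
    p_c: Optional[float] = None
    delta: Optional[float] = None
    gamma: Optional[float] = None
    direction: Optional[str] = None  # disease_higher / control_higher / equal
    frequency_label: Optional[str] = None
    distinction_label: Optional[str] = None


@dataclass
class EdgeStats:
    """Per-edge conditional statistics and type."""

    source_id: str
    target_id: str
    o_d: int
    o_c: int
    q_d: Optional[float] = None
    q_c: Optional[float] = None
    dprime_d: Optional[float] = None
    dprime_c: Optional[float] = None
    gprime_d: Optional[float] = None
    gprime_c: Optional[float] = None
    edge_type: Optional[str] = None


@dataclass
class AAGraph:
    """Attribute association graph: labelled nodes plus typed edges."""

    nodes: dict[str, NodeStats]
    edges: list[EdgeStats]
    attributes: dict[str, AttributeDef]
    disease_name: str = "disease"
    control_name: str = "control"
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source_id == e.target_id:
                raise ValueError(f"self-edge on {e.source_id!r}")
            if e.source_id not in self.nodes or e.target_id not in self.nodes:
                raise ValueError(
                    f"edge {e.source_id!r}->{e.target_id!r} has a missing endpoint"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def share_comparison(p_d: float, p_c: float) -> tuple[float, float]:
    """Absolute difference and max/min quotient of two attribute shares.

    With both shares zero the quotient is reported as 1 (no distinction);
    with exactly one share zero it is +inf, which exceeds every quotient
    threshold.
    """
    delta = abs(p_d - p_c)
    mn, mx = min(p_d, p_c), max(p_d, p_c)
    if mx == 0.0:
        gamma = 1.0
    elif mn == 0.0:
        gamma = math.inf
    else:
        gamma = mx / mn
    return delta, gamma


def assign_frequency_label(p_max: float, thresholds: NodeThresholds | None = None) -> str:
    """Three-way frequency label from the maximum relative attribute share."""
    t = thresholds or NodeThresholds()
    if not 0.0 <= p_max <= 1.0:
        raise ValueError(f"maximum relative attribute share out of [0,1]: {p_max}")
    if p_max >= t.freq_high:
        return HIGHLY_FREQUENT
    if p_max >= t.freq_low:
        return FREQUENT
    return INFREQUENT


def assign_distinction_label(
    p_d: float, p_c: float, thresholds: NodeThresholds | None = None
) -> str:
    """Five-way distinction label from the two relative attribute shares."""
    t = thresholds or NodeThresholds()
    for name, p in (("p_d", p_d), ("p_c", p_c)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} out of [0,1]: {p}")
    if p_d == p_c:
        return UNRELATED
    delta, gamma = share_comparison(p_d, p_c)
    delta, gamma = _cmp(delta), _cmp(gamma)
    if delta >= t.delta_high or gamma >= t.gamma_high:
        return HIGHLY_RELATED if p_d > p_c else HIGHLY_INVERSE
    if delta >= t.delta_related or gamma >= t.gamma_related:
        return RELATED if p_d > p_c else INVERSE
    return UNRELATED


def _node_from_counts(
    attribute_id: str,
    c_d: int,
    c_c: int,
    g_d: int,
    g_c: int,
    n_d: int,
    n_c: int,
    thresholds: NodeThresholds,
) -> NodeStats:
    stats = NodeStats(
        attribute_id=attribute_id, c_d=c_d, c_c=c_c, g_d=g_d, g_c=g_c, n_d=n_d, n_c=n_c
    )
    stats.rel_total_d = c_d / g_d if g_d > 0 else None
    stats.rel_total_c = c_c / g_c if g_c > 0 else None
    stats.p_d = c_d / n_d if n_d > 0 else None
    stats.p_c = c_c / n_c if n_c > 0 else None
    if stats.p_d is None or stats.p_c is None:
        warnings.warn(
            f"attribute {attribute_id!r}: no valid values in one group; "
            "shares undefined, node excluded from labelling",
            stacklevel=3,
        )
        return stats
    stats.delta, stats.gamma = share_comparison(stats.p_d, stats.p_c)
    if stats.p_d > stats.p_c:
        stats.direction = "disease_higher"
    elif stats.p_d < stats.p_c:
        stats.direction = "control_higher"
    else:
        stats.direction = "equal"
    stats.frequency_label = assign_frequency_label(max(stats.p_d, stats.p_c), thresholds)
    stats.distinction_label = assign_distinction_label(stats.p_d, stats.p_c, thresholds)
    return stats


def node_statistics(
    incidence: IncidenceMatrix,
    assignment: CohortAssignment,
    attribute: AttributeDef,
    thresholds: NodeThresholds | None = None,
) -> NodeStats:
    """All node statistics for one attribute, labels included."""
    t = thresholds or NodeThresholds()
    aid = attribute.attribute_id
    member = incidence.member[aid]
    valid = incidence.valid[aid]
    d = assignment.disease_mask().reindex(member.index)
    return _node_from_counts(
        attribute_id=aid,
        c_d=int((member & d).sum()),
        c_c=int((member & ~d).sum()),
        g_d=assignment.g_d,
        g_c=assignment.g_c,
        n_d=int((valid & d).sum()),
        n_c=int((valid & ~d).sum()),
        thresholds=t,
    )


def _edge_from_counts(
    source_id: str,
    target_id: str,
    o_d: int,
    o_c: int,
    c_d_src: int,
    c_c_src: int,
    target_stats: NodeStats,
    thresholds: EdgeThresholds,
    aggregation: str = "max",
    magnitude: bool = True,
) -> EdgeStats:
    e = EdgeStats(source_id=source_id, target_id=target_id, o_d=o_d, o_c=o_c)
    e.q_d = o_d / c_d_src if c_d_src > 0 else None
    e.q_c = o_c / c_c_src if c_c_src > 0 else None
    for grp, q, p in (("d", e.q_d, target_stats.p_d), ("c", e.q_c, target_stats.p_c)):
        if q is None or p is None:
            continue
        setattr(e, f"dprime_{grp}", q - p)
        if p > 0:
            setattr(e, f"gprime_{grp}", q / p)
    e.edge_type = assign_edge_type(
        e.dprime_d,
        e.dprime_c,
        e.gprime_d,
        e.gprime_c,
        thresholds=thresholds,
        aggregation=aggregation,
        magnitude=magnitude,
    )
    return e


def edge_statistics(
    incidence: IncidenceMatrix,
    assignment: CohortAssignment,
    source: AttributeDef,
    target: AttributeDef,
    target_stats: NodeStats,
    thresholds: EdgeThresholds | None = None,
    aggregation: str = "max",
    magnitude: bool = True,
) -> EdgeStats:
    """Conditional statistics for the directed pair source -> target."""
    if source.attribute_id == target.attribute_id:
        raise ValueError("source and target must differ")
    t = thresholds or EdgeThresholds()
    src = incidence.member[source.attribute_id]
    tgt = incidence.member[target.attribute_id]
    d = assignment.disease_mask().reindex(src.index)
    return _edge_from_counts(
        source_id=source.attribute_id,
        target_id=target.attribute_id,
        o_d=int((src & tgt & d).sum()),
        o_c=int((src & tgt & ~d).sum()),
        c_d_src=int((src & d).sum()),
        c_c_src=int((src & ~d).sum()),
        target_stats=target_stats,
        thresholds=t,
        aggregation=aggregation,
        magnitude=magnitude,
    )


def assign_edge_type(
    dprime_d: Optional[float],
    dprime_c: Optional[float],
    gprime_d: Optional[float],
    gprime_c: Optional[float],
    thresholds: EdgeThresholds | None = None,
    aggregation: str = "max",
    magnitude: bool = True,
) -> Optional[str]:
    """Three-way edge type, or None when every group's pair is undefined.

    With ``magnitude`` (default) suppressive relations are typed by
    |delta'| and max(gamma', 1/gamma'); per group the magnitudes are
    computed and then aggregated across groups by ``aggregation``
    ("max", "disease", or "control").
    """
    t = thresholds or EdgeThresholds()
    pairs = {"disease": (dprime_d, gprime_d), "control": (dprime_c, gprime_c)}
    if aggregation in ("disease", "control"):
        pairs = {aggregation: pairs[aggregation]}
    elif aggregation != "max":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    deltas: list[float] = []
    gammas: list[float] = []
    for dp, gp in pairs.values():
        if dp is not None:
            deltas.append(abs(dp) if magnitude else dp)
        if gp is not None:
            if magnitude:
                gammas.append(math.inf if gp == 0 else max(gp, 1.0 / gp))
            else:
                gammas.append(gp)
    if not deltas and not gammas:
        return None
    dd = _cmp(max(deltas)) if deltas else -math.inf
    gg = _cmp(max(gammas)) if gammas else -math.inf
    if dd >= t.delta_high or gg >= t.gamma_high:
        return HIGH_COND_DIFF
    if dd >= t.delta_medium or gg >= t.gamma_medium:
        return MEDIUM_COND_DIFF
    return LOW_COND_DIFF


def build_graph(
    table: CohortTable,
    spec: CohortSpec,
    config: GraphConfig | None = None,
    overrides: Mapping[str, tuple[float, float]] | None = None,
    provenance: Mapping[str, object] | None = None,
) -> AAGraph:
    """Run the full pipeline: cohorts, ranges, attributes, nodes, edges.

    Produces the unfiltered graph; apply :func:`aagraph.filtering.filter_graph`
    to prune it.
    """
    cfg = config or GraphConfig()
    assignment = assign_cohorts(table, spec)
    if assignment.g_d == 0 or assignment.g_c == 0:
        raise BuildError(
            f"empty group: g_d={assignment.g_d}, g_c={assignment.g_c}; "
            "both cohorts must be non-empty"
        )
    ranges = compute_reference_ranges(table)
    if overrides:
        metric_vars = {
            v for v, m in table.meta.items() if m.data_kind == "metric"
        }
        ranges = apply_overrides(ranges, overrides, known_variables=metric_vars)
    attrs, incidence = derive_attributes(table, ranges)
    return assemble_graph(
        incidence,
        assignment,
        config=cfg,
        provenance=dict(provenance or {}),
    )


def assemble_graph(
    incidence: IncidenceMatrix,
    assignment: CohortAssignment,
    config: GraphConfig | None = None,
    provenance: Mapping[str, object] | None = None,
) -> AAGraph:
    """Vectorised node/edge computation from a derived incidence matrix."""
    cfg = config or GraphConfig()
    attrs = incidence.attributes
    member = incidence.member.to_numpy(dtype=bool)
    valid = incidence.valid.to_numpy(dtype=bool)
    d_mask = assignment.disease_mask().reindex(incidence.member.index).to_numpy(dtype=bool)
    g_d, g_c = assignment.g_d, assignment.g_c

    m_d = member[d_mask]
    m_c = member[~d_mask]
    c_d = m_d.sum(axis=0).astype(int)
    c_c = m_c.sum(axis=0).astype(int)
    n_d = valid[d_mask].sum(axis=0).astype(int)
    n_c = valid[~d_mask].sum(axis=0).astype(int)

    nodes: dict[str, NodeStats] = {}
    for j, a in enumerate(attrs):
        nodes[a.attribute_id] = _node_from_counts(
            attribute_id=a.attribute_id,
            c_d=int(c_d[j]),
            c_c=int(c_c[j]),
            g_d=g_d,
            g_c=g_c,
            n_d=int(n_d[j]),
            n_c=int(n_c[j]),
            thresholds=cfg.node,
        )

    # Quadratic in attributes; co-occurrence counts via boolean matmul.
    o_d = m_d.astype(np.int64).T @ m_d.astype(np.int64)
    o_c = m_c.astype(np.int64).T @ m_c.astype(np.int64)
    edges: list[EdgeStats] = []
    n_dropped = 0
    for j, src in enumerate(attrs):
        for k, tgt in enumerate(attrs):
            if j == k:
                continue
            if not cfg.same_variable_edges and src.variable == tgt.variable:
                continue
            e = _edge_from_counts(
                source_id=src.attribute_id,
                target_id=tgt.attribute_id,
                o_d=int(o_d[j, k]),
                o_c=int(o_c[j, k]),
                c_d_src=int(c_d[j]),
                c_c_src=int(c_c[j]),
                target_stats=nodes[tgt.attribute_id],
                thresholds=cfg.edge,
                aggregation=cfg.aggregation,
                magnitude=cfg.magnitude,
            )
            if e.edge_type is None:
                n_dropped += 1
                continue
            edges.append(e)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} edge(s) with undefined statistics in both groups",
            stacklevel=2,
        )
    prov = dict(provenance or {})
    prov.setdefault("g_d", g_d)
    prov.setdefault("g_c", g_c)
    return AAGraph(
        nodes=nodes,
        edges=edges,
        attributes={a.attribute_id: a for a in attrs},
        disease_name=assignment.disease_name,
        control_name=assignment.control_name,
        config=cfg.model_dump(),
        provenance=prov,
    )
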