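"""Pruning of the full graph to its most relevant nodes and edges.

The published method filters by statistical parameters but its exact
procedure is not public; the rules and default thresholds here are our own
configurable stand-ins (documented as non-authorial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .graph import AAGraph, EdgeStats, LOW_COND_DIFF, NodeStats

__all__ = ["FilterRules", "FilterReport", "filter_graph"]


@dataclass(frozen=True)
class FilterRules:
    """Node/edge retention rules (defaults invented, not from the method)."""

    min_abs_count: int = 10  # node kept if max(c_d, c_c) >= this
    min_max_share: float = 0.01  # node kept if max(p_d, p_c) >= this
    keep_low_edges: bool = False
    min_cooccurrence: int = 10  # edge kept if max(o_d, o_c) >= this
    node_whitelist: Optional[frozenset[str]] = None
    node_blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_abs_count < 0 or self.min_cooccurrence < 0:
            raise ValueError("count rules must be >= 0")
        if not 0.0 <= self.min_max_share <= 1.0:
            raise ValueError("min_max_share must lie in [0, 1]")


@dataclass
class FilterReport:
    """Counts of removed elements per rule."""

    nodes_removed: dict[str, int] = field(default_factory=dict)
    edges_removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes_removed(self) -> int:
        return sum(self.nodes_removed.values())

    @property
    def n_edges_removed(self) -> int:
        return sum(self.edges_removed.values())

    def as_dict(self) -> dict:
        return {
            "nodes_removed": dict(self.nodes_removed),
            "edges_removed": dict(self.edges_removed),
            "n_nodes_removed": self.n_nodes_removed,
            "n_edges_removed": self.n_edges_removed,
        }


def _node_removal_reason(stats: NodeStats, rules: FilterRules) -> Optional[str]:
    if rules.node_whitelist is not None and stats.attribute_id not in rules.node_whitelist:
        return "not_whitelisted"
    if stats.attribute_id in rules.node_blacklist:
        return "blacklisted"
    if max(stats.c_d, stats.c_c) < rules.min_abs_count:
        return "min_abs_count"
    shares = [p for p in (stats.p_d, stats.p_c) if p is not None]
    if not shares or max(shares) < rules.min_max_share:
        return "min_max_share"
    return None


def _edge_removal_reason(
    edge: EdgeStats, kept_nodes: set[str], rules: FilterRules
) -> Optional[str]:
    if edge.source_id not in kept_nodes or edge.target_id not in kept_nodes:
        return "endpoint_removed"
    if not rules.keep_low_edges and edge.edge_type == LOW_COND_DIFF:
        return "low_cond_diff"
    if max(edge.o_d, edge.o_c) < rules.min_cooccurrence:
        return "min_cooccurrence"
    return None


def filter_graph(graph: AAGraph, rules: FilterRules | None = None) -> AAGraph:
    """Return a pruned copy of the graph; statistics are left untouched.

    The filter report is attached under ``provenance["filter_report"]``.
    """
    rules = rules or FilterRules()
    report = FilterReport()
    kept_nodes: dict[str, NodeStats] = {}
    for aid, stats in graph.nodes.items():
        reason = _node_removal_reason(stats, rules)
        if reason is None:
            kept_nodes[aid] = stats
        else:
            report.nodes_removed[reason] = report.nodes_removed.get(reason, 0) + 1
    kept_ids = set(kept_nodes)
    kept_edges: list[EdgeStats] = []
    for edge in graph.edges:
        reason = _edge_removal_reason(edge, kept_ids, rules)
        if reason is None:
            kept_edges.append(edge)
        else:
            report.edges_removed[reason] = report.edges_removed.get(reason, 0) + 1
    provenance = dict(graph.provenance)
    provenance["filter_report"] = report.as_dict()
    provenance["filter_rules"] = {
        "min_abs_count": rules.min_abs_count,
        "min_max_share": rules.min_max_share,
        "keep_low_edges": rules.keep_low_edges,
        "min_cooccurrence": rules.min_cooccurrence,
        "node_whitelist": sorted(rules.node_whitelist) if rules.node_whitelist else None,
        "node_blacklist": sorted(rules.node_blacklist),
    }
    return AAGraph(
        nodes=kept_nodes,
        edges=kept_edges,
        attributes={aid: graph.attributes[aid] for aid in kept_nodes},
        disease_name=graph.disease_name,
        control_name=graph.control_name,
        config=dict(graph.config),
        provenance=provenance,
    )
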