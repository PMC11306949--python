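"""Graph serialization: property-graph CSVs + load script, GraphML, JSON.

List-valued properties are ordered control group first, disease group
second; the disease group is published as ``posGroup``.  Property names
follow the published vocabulary (``groupAbsCounts`` ... ``groupQuotTargets``).
JSON and GraphML exports are lossless: export -> import -> export is
byte-identical (numbers at full precision; the human-readable CSVs round
to 4 significant digits).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree

import networkx as nx

from .attributes import AttributeDef
from .graph import AAGraph, EdgeStats, NodeStats

__all__ = [
    "NODE_COLORS",
    "NODE_SIZE_RANK",
    "EDGE_WIDTH_RANK",
    "visual_encoding",
    "graph_to_dict",
    "graph_from_dict",
    "export_json",
    "import_json",
    "export_graphml",
    "import_graphml",
    "export_property_graph",
]

#: Node colour by distinction label.
NODE_COLORS = {
    "highly_related": "red",
    "related": "orange",
    "unrelated": "vanilla",
    "inverse": "turquoise",
    "highly_inverse": "blue",
}
#: Node size rank (1 = smallest) by frequency label.
NODE_SIZE_RANK = {"highly_frequent": 3, "frequent": 2, "infrequent": 1}
#: Edge width rank (1 = thinnest) by edge type.
EDGE_WIDTH_RANK = {"high_cond_diff": 3, "medium_cond_diff": 2, "low_cond_diff": 1}


def visual_encoding() -> dict:
    return {
        "node_colors": dict(NODE_COLORS),
        "node_size_rank": dict(NODE_SIZE_RANK),
        "edge_width_rank": dict(EDGE_WIDTH_RANK),
    }


def _edge_type_name(edge_type: Optional[str]) -> Optional[str]:
    return None if edge_type is None else edge_type.upper()


def _node_record(graph: AAGraph, stats: NodeStats) -> dict:
    a = graph.attributes[stats.attribute_id]
    return {
        "id": stats.attribute_id,
        "name": a.variable,
        "value": a.value,
        "description": a.description,
        "broadLabels": list(a.broad_labels),
        "refLower": a.ref_lower,
        "refUpper": a.ref_upper,
        "frequencyLabel": stats.frequency_label,
        "distinctionLabel": stats.distinction_label,
        "direction": stats.direction,
        "groupSizes": [stats.g_c, stats.g_d],
        "groupValidCounts": [stats.n_c, stats.n_d],
        "groupAbsCounts": [stats.c_c, stats.c_d],
        "groupRelShareTotals": [stats.rel_total_c, stats.rel_total_d],
        "groupRelShareAttrs": [stats.p_c, stats.p_d],
        "diffRelShareAttr": stats.delta,
        "quotRelShareAttr": stats.gamma,
    }


def _edge_record(edge: EdgeStats) -> dict:
    return {
        "source": edge.source_id,
        "target": edge.target_id,
        "type": _edge_type_name(edge.edge_type),
        "groupAbsCoOccurs": [edge.o_c, edge.o_d],
        "groupRelShareConds": [edge.q_c, edge.q_d],
        "groupDiffTargets": [edge.dprime_c, edge.dprime_d],
        "groupQuotTargets": [edge.gprime_c, edge.gprime_d],
    }


def graph_to_dict(graph: AAGraph) -> dict:
    """Canonical JSON-able representation of a graph."""
    return {
        "format": "aagraph",
        "version": 1,
        "posGroup": graph.disease_name,
        "negGroup": graph.control_name,
        "config": graph.config,
        "provenance": graph.provenance,
        "encoding": visual_encoding(),
        "nodes": [_node_record(graph, graph.nodes[aid]) for aid in graph.nodes],
        "edges": [_edge_record(e) for e in graph.edges],
    }


def graph_from_dict(doc: dict) -> AAGraph:
    """Inverse of :func:`graph_to_dict`."""
    if doc.get("format") != "aagraph":
        raise ValueError("not an aagraph document")
    nodes: dict[str, NodeStats] = {}
    attributes: dict[str, AttributeDef] = {}
    for rec in doc["nodes"]:
        aid = rec["id"]
        attributes[aid] = AttributeDef(
            attribute_id=aid,
            variable=rec["name"],
            value=rec["value"],
            description=rec.get("description", ""),
            broad_labels=tuple(rec.get("broadLabels", [])),
            ref_lower=rec.get("refLower"),
            ref_upper=rec.get("refUpper"),
        )
        g_c, g_d = rec["groupSizes"]
        n_c, n_d = rec["groupValidCounts"]
        c_c, c_d = rec["groupAbsCounts"]
        rt_c, rt_d = rec["groupRelShareTotals"]
        p_c, p_d = rec["groupRelShareAttrs"]
        nodes[aid] = NodeStats(
            attribute_id=aid,
            c_d=c_d,
            c_c=c_c,
            g_d=g_d,
            g_c=g_c,
            n_d=n_d,
            n_c=n_c,
            rel_total_d=rt_d,
            rel_total_c=rt_c,
            p_d=p_d,
            p_c=p_c,
            delta=rec.get("diffRelShareAttr"),
            gamma=rec.get("quotRelShareAttr"),
            direction=rec.get("direction"),
            frequency_label=rec.get("frequencyLabel"),
            distinction_label=rec.get("distinctionLabel"),
        )
    edges: list[EdgeStats] = []
    for rec in doc["edges"]:
        o_c, o_d = rec["groupAbsCoOccurs"]
        q_c, q_d = rec["groupRelShareConds"]
        dp_c, dp_d = rec["groupDiffTargets"]
        gp_c, gp_d = rec["groupQuotTargets"]
        etype = rec.get("type")
        edges.append(
            EdgeStats(
                source_id=rec["source"],
                target_id=rec["target"],
                o_d=o_d,
                o_c=o_c,
                q_d=q_d,
                q_c=q_c,
                dprime_d=dp_d,
                dprime_c=dp_c,
                gprime_d=gp_d,
                gprime_c=gp_c,
                edge_type=None if etype is None else etype.lower(),
            )
        )
    return AAGraph(
        nodes=nodes,
        edges=edges,
        attributes=attributes,
        disease_name=doc["posGroup"],
        control_name=doc["negGroup"],
        config=doc.get("config", {}),
        provenance=doc.get("provenance", {}),
    )


def export_json(graph: AAGraph, path: str | Path | None = None) -> str:
    """Serialize to deterministic JSON text (sorted keys, full precision)."""
    text = json.dumps(graph_to_dict(graph), indent=2, sort_keys=True, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def import_json(source: str | Path) -> AAGraph:
    """Load a graph from JSON text or a file path."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).is_file()):
        source = Path(source).read_text()
    return graph_from_dict(json.loads(source))


# ---------------------------------------------------------------------------
# GraphML

_NODE_SCALARS = (
    "name",
    "value",
    "description",
    "refLower",
    "refUpper",
    "frequencyLabel",
    "distinctionLabel",
    "direction",
    "diffRelShareAttr",
    "quotRelShareAttr",
)
_LIST_NODE_KEYS = (
    "groupSizes",
    "groupValidCounts",
    "groupAbsCounts",
    "groupRelShareTotals",
    "groupRelShareAttrs",
)
_LIST_EDGE_KEYS = (
    "groupAbsCoOccurs",
    "groupRelShareConds",
    "groupDiffTargets",
    "groupQuotTargets",
)


def _to_nx(graph: AAGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.graph["posGroup"] = graph.disease_name
    g.graph["negGroup"] = graph.control_name
    g.graph["config"] = json.dumps(graph.config, sort_keys=True)
    g.graph["provenance"] = json.dumps(graph.provenance, sort_keys=True)
    for rec in (_node_record(graph, graph.nodes[aid]) for aid in graph.nodes):
        attrs: dict[str, object] = {}
        for key in _NODE_SCALARS:
            if rec[key] is not None:
                attrs[key] = rec[key]
        attrs["broadLabels"] = ";".join(rec["broadLabels"])
        for key in _LIST_NODE_KEYS:
            neg, pos = rec[key]
            if neg is not None:
                attrs[f"{key}Neg"] = neg
            if pos is not None:
                attrs[f"{key}Pos"] = pos
        g.add_node(rec["id"], **attrs)
    for rec in map(_edge_record, graph.edges):
        attrs = {}
        if rec["type"] is not None:
            attrs["type"] = rec["type"]
        for key in _LIST_EDGE_KEYS:
            neg, pos = rec[key]
            if neg is not None:
                attrs[f"{key}Neg"] = neg
            if pos is not None:
                attrs[f"{key}Pos"] = pos
        g.add_edge(rec["source"], rec["target"], **attrs)
    return g


def export_graphml(graph: AAGraph, path: str | Path | None = None) -> bytes:
    """Serialize to GraphML (list properties split into Neg/Pos scalars)."""
    g = _to_nx(graph)
    payload = ("\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n").encode("utf-8")
    if path is not None:
        Path(path).write_bytes(payload)
    return payload


def _pair(attrs: dict, key: str) -> list:
    return [attrs.get(f"{key}Neg"), attrs.get(f"{key}Pos")]


def import_graphml(source: bytes | str | Path) -> AAGraph:
    """Load a graph written by :func:`export_graphml`."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        g = nx.read_graphml(source)
    else:
        if isinstance(source, bytes):
            source = source.decode("utf-8")
        g = nx.parse_graphml(source)
    doc = {
        "format": "aagraph",
        "version": 1,
        "posGroup": g.graph["posGroup"],
        "negGroup": g.graph["negGroup"],
        "config": json.loads(g.graph.get("config", "{}")),
        "provenance": json.loads(g.graph.get("provenance", "{}")),
        "nodes": [],
        "edges": [],
    }
    for aid, attrs in g.nodes(data=True):
        labels = attrs.get("broadLabels", "")
        doc["nodes"].append(
            {
                "id": aid,
                "name": attrs.get("name", ""),
                "value": attrs.get("value", ""),
                "description": attrs.get("description", ""),
                "broadLabels": [s for s in labels.split(";") if s],
                "refLower": attrs.get("refLower"),
                "refUpper": attrs.get("refUpper"),
                "frequencyLabel": attrs.get("frequencyLabel"),
                "distinctionLabel": attrs.get("distinctionLabel"),
                "direction": attrs.get("direction"),
                "groupSizes": _pair(attrs, "groupSizes"),
                "groupValidCounts": _pair(attrs, "groupValidCounts"),
                "groupAbsCounts": _pair(attrs, "groupAbsCounts"),
                "groupRelShareTotals": _pair(attrs, "groupRelShareTotals"),
                "groupRelShareAttrs": _pair(attrs, "groupRelShareAttrs"),
                "diffRelShareAttr": attrs.get("diffRelShareAttr"),
                "quotRelShareAttr": attrs.get("quotRelShareAttr"),
            }
        )
    for src, tgt, attrs in g.edges(data=True):
        doc["edges"].append(
            {
                "source": src,
                "target": tgt,
                "type": attrs.get("type"),
                "groupAbsCoOccurs": _pair(attrs, "groupAbsCoOccurs"),
                "groupRelShareConds": _pair(attrs, "groupRelShareConds"),
                "groupDiffTargets": _pair(attrs, "groupDiffTargets"),
                "groupQuotTargets": _pair(attrs, "groupQuotTargets"),
            }
        )
    return graph_from_dict(doc)


# ---------------------------------------------------------------------------
# Property-graph bulk import

def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "Infinity" if value > 0 else "-Infinity"
        return f"{value:.4g}"
    return str(value)


def _fmt_list(values: list) -> str:
    return ";".join(_fmt(v) for v in values)


def _csv_quote(cell: str) -> str:
    if any(ch in cell for ch in ',"\n'):
        return '"' + cell.replace('"', '""') + '"'
    return cell


def export_property_graph(graph: AAGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write bulk-import ``nodes.csv``/``edges.csv``, a Cypher load script,
    and ``style.json`` into ``out_dir``; returns the written paths."""
    if not graph.nodes:
        raise ValueError("cannot export an empty graph to the property-graph format")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    node_header = [
        "attributeId:ID",
        "name",
        "value",
        "description",
        "refLower:double",
        "refUpper:double",
        ":LABEL",
        "posGroup",
        "negGroup",
        "groupSizes:long[]",
        "groupValidCounts:long[]",
        "groupAbsCounts:long[]",
        "groupRelShareTotals:double[]",
        "groupRelShareAttrs:double[]",
        "diffRelShareAttr:double",
        "quotRelShareAttr:double",
    ]
    node_rows = []
    for aid in graph.nodes:
        rec = _node_record(graph, graph.nodes[aid])
        labels = list(rec["broadLabels"])
        for lbl in (rec["frequencyLabel"], rec["distinctionLabel"]):
            if lbl:
                labels.append(lbl)
        node_rows.append(
            [
                rec["id"],
                rec["name"],
                rec["value"],
                rec["description"],
                _fmt(rec["refLower"]),
                _fmt(rec["refUpper"]),
                ";".join(labels),
                graph.disease_name,
                graph.control_name,
                _fmt_list(rec["groupSizes"]),
                _fmt_list(rec["groupValidCounts"]),
                _fmt_list(rec["groupAbsCounts"]),
                _fmt_list(rec["groupRelShareTotals"]),
                _fmt_list(rec["groupRelShareAttrs"]),
                _fmt(rec["diffRelShareAttr"]),
                _fmt(rec["quotRelShareAttr"]),
            ]
        )
    edge_header = [
        ":START_ID",
        ":END_ID",
        ":TYPE",
        "groupAbsCoOccurs:long[]",
        "groupRelShareConds:double[]",
        "groupDiffTargets:double[]",
        "groupQuotTargets:double[]",
    ]
    edge_rows = []
    for e in graph.edges:
        rec = _edge_record(e)
        edge_rows.append(
            [
                rec["source"],
                rec["target"],
                rec["type"] or "",
                _fmt_list(rec["groupAbsCoOccurs"]),
                _fmt_list(rec["groupRelShareConds"]),
                _fmt_list(rec["groupDiffTargets"]),
                _fmt_list(rec["groupQuotTargets"]),
            ]
        )

    def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
        lines = [",".join(map(_csv_quote, header))]
        lines += [",".join(_csv_quote(str(c)) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")

    paths = {
        "nodes": out / "nodes.csv",
        "edges": out / "edges.csv",
        "cypher": out / "load.cypher",
        "style": out / "style.json",
    }
    _write_csv(paths["nodes"], node_header, node_rows)
    _write_csv(paths["edges"], edge_header, edge_rows)
    paths["cypher"].write_text(_cypher_script(graph))
    paths["style"].write_text(json.dumps(visual_encoding(), indent=2, sort_keys=True) + "\n")
    return paths


def _cypher_quote(s: str) -> str:
    return "'" + str(s).replace("\\", "\\\\").replace("'", "\\'") + "'"


def _cypher_value(v: object) -> str:
    if v is None:
        return "null"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isinf(v):
            return "9.0e999" if v > 0 else "-9.0e999"  # parses as +/-Infinity
        return repr(v)
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, list):
        return "[" + ", ".join(_cypher_value(x) for x in v) + "]"
    return _cypher_quote(str(v))


def _cypher_script(graph: AAGraph) -> str:
    """Statement-per-element script reproducing the graph in a Neo4j-style
    database (suitable for small graphs; use the CSVs for bulk import)."""
    lines = [
        "// Load script generated by aagraph.",
        "// For large graphs prefer: neo4j-admin database import full",
        "//   --nodes=nodes.csv --relationships=edges.csv",
        "",
    ]
    for aid in graph.nodes:
        rec = _node_record(graph, graph.nodes[aid])
        labels = ["Attribute"] + [
            lbl.replace(" ", "_")
            for lbl in (*rec["broadLabels"], rec["frequencyLabel"], rec["distinctionLabel"])
            if lbl
        ]
        props = {
            "attributeId": rec["id"],
            "name": rec["name"],
            "value": rec["value"],
            "description": rec["description"],
            "refLower": rec["refLower"],
            "refUpper": rec["refUpper"],
            "posGroup": graph.disease_name,
            "negGroup": graph.control_name,
            "groupSizes": rec["groupSizes"],
            "groupValidCounts": rec["groupValidCounts"],
            "groupAbsCounts": rec["groupAbsCounts"],
            "groupRelShareTotals": rec["groupRelShareTotals"],
            "groupRelShareAttrs": rec["groupRelShareAttrs"],
            "diffRelShareAttr": rec["diffRelShareAttr"],
            "quotRelShareAttr": rec["quotRelShareAttr"],
        }
        prop_text = ", ".join(f"{k}: {_cypher_value(v)}" for k, v in props.items() if v is not None)
        lines.append(f"CREATE (:`{'`:`'.join(labels)}` {{{prop_text}}});")
    lines.append("")
    for e in graph.edges:
        rec = _edge_record(e)
        props = {
            "groupAbsCoOccurs": rec["groupAbsCoOccurs"],
            "groupRelShareConds": rec["groupRelShareConds"],
            "groupDiffTargets": rec["groupDiffTargets"],
            "groupQuotTargets": rec["groupQuotTargets"],
        }
        prop_text = ", ".join(f"{k}: {_cypher_value(v)}" for k, v in props.items())
        lines.append(
            "MATCH (s:Attribute {attributeId: %s}), (t:Attribute {attributeId: %s}) "
            "CREATE (s)-[:`%s` {%s}]->(t);"
            % (_cypher_quote(rec["source"]), _cypher_quote(rec["target"]), rec["type"], prop_text)
        )
    return "\n".join(lines) + "\n"


def validate_graphml(payload: bytes | str) -> bool:
    """Structural GraphML check: namespace, declared keys, resolvable refs."""
    if isinstance(payload, bytes):
        payload = payload.decode("utf-8")
    root = ElementTree.fromstring(payload)
    ns = "{http://graphml.graphdrawing.org/xmlns}"
    if root.tag != f"{ns}graphml":
        return False
    declared = {k.get("id") for k in root.findall(f"{ns}key")}
    for data in root.iter(f"{ns}data"):
        if data.get("key") not in declared:
            return False
    return True
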