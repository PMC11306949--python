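"""Independent brute-force recount of node and edge statistics.

Pure-Python loops over raw rows; deliberately shares no code with the
package's vectorised path.  Shares are plain int/int divisions so exact
(==) comparison against the package is meaningful.
"""

from __future__ import annotations

import math
import statistics


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _round12(x: float) -> float:
    if math.isinf(x) or math.isnan(x):
        return x
    return round(x, 12)


def oracle_reference_ranges(rows: dict, meta: dict) -> dict:
    """variable -> (lower, upper) using mean +/- sample SD over all rows."""
    ranges = {}
    for var, m in meta.items():
        if m.data_kind != "metric":
            continue
        vals = [row[var] for row in rows.values() if not _is_missing(row.get(var))]
        if len(vals) < 2:
            continue
        mean = statistics.fmean(vals)
        sd = statistics.stdev(vals, xbar=mean)
        ranges[var] = (mean - sd, mean + sd)
    return ranges


def oracle_attribute_status(rows: dict, meta: dict, ranges: dict) -> tuple[list, dict]:
    """Catalogue of (attr_id, variable) plus per-attribute member/valid sets."""
    catalogue = []
    members: dict[str, set] = {}
    valids: dict[str, set] = {}
    for var, m in meta.items():
        if m.data_kind == "metric":
            if var not in ranges:
                continue
            lower, upper = ranges[var]
            for band in ("low", "normal", "high"):
                aid = f"{var}={band}"
                catalogue.append((aid, var))
                members[aid] = set()
                valids[aid] = set()
            for pid, row in rows.items():
                v = row.get(var)
                if _is_missing(v):
                    continue
                for band in ("low", "normal", "high"):
                    valids[f"{var}={band}"].add(pid)
                if v < lower:
                    members[f"{var}=low"].add(pid)
                elif v > upper:
                    members[f"{var}=high"].add(pid)
                else:
                    members[f"{var}=normal"].add(pid)
        else:
            if m.categories:
                cats = list(m.categories)
            else:
                observed = {
                    str(row[var])
                    for row in rows.values()
                    if not _is_missing(row.get(var))
                }
                cats = sorted(observed)
            for cat in cats:
                aid = f"{var}={cat}"
                catalogue.append((aid, var))
                members[aid] = set()
                valids[aid] = set()
            for pid, row in rows.items():
                v = row.get(var)
                if _is_missing(v):
                    continue
                for cat in cats:
                    valids[f"{var}={cat}"].add(pid)
                if str(v) in cats:
                    members[f"{var}={str(v)}"].add(pid)
    return catalogue, {"members": members, "valids": valids}


def _freq_label(p: float) -> str:
    if p >= 0.5:
        return "highly_frequent"
    if p >= 0.1:
        return "frequent"
    return "infrequent"


def _delta_gamma(p_d: float, p_c: float) -> tuple[float, float]:
    delta = abs(p_d - p_c)
    lo, hi = min(p_d, p_c), max(p_d, p_c)
    if hi == 0:
        gamma = 1.0
    elif lo == 0:
        gamma = math.inf
    else:
        gamma = hi / lo
    return delta, gamma


def _distinction_label(p_d: float, p_c: float) -> str:
    if p_d == p_c:
        return "unrelated"
    delta, gamma = _delta_gamma(p_d, p_c)
    delta, gamma = _round12(delta), _round12(gamma)
    if delta >= 0.2 or gamma >= 2.0:
        return "highly_related" if p_d > p_c else "highly_inverse"
    if delta >= 0.1 or gamma >= 1.5:
        return "related" if p_d > p_c else "inverse"
    return "unrelated"


def _edge_type(dprimes: list, gprimes: list) -> str | None:
    ds = [abs(d) for d in dprimes if d is not None]
    gs = [math.inf if g == 0 else max(g, 1.0 / g) for g in gprimes if g is not None]
    if not ds and not gs:
        return None
    dd = _round12(max(ds)) if ds else -math.inf
    gg = _round12(max(gs)) if gs else -math.inf
    if dd >= 0.2 or gg >= 2.0:
        return "high_cond_diff"
    if dd >= 0.1 or gg >= 1.5:
        return "medium_cond_diff"
    return "low_cond_diff"


def oracle_graph(rows: dict, meta: dict, disease_ids: set, same_variable_edges: bool = False):
    """Full recount: node stats keyed by attribute id, edge stats by (src, tgt).

    ``rows`` maps participant id -> {variable: value-or-missing}.
    """
    ranges = oracle_reference_ranges(rows, meta)
    catalogue, status = oracle_attribute_status(rows, meta, ranges)
    members, valids = status["members"], status["valids"]
    all_ids = set(rows)
    control_ids = all_ids - disease_ids
    g_d, g_c = len(disease_ids), len(control_ids)

    nodes = {}
    for aid, var in catalogue:
        c_d = len(members[aid] & disease_ids)
        c_c = len(members[aid] & control_ids)
        n_d = len(valids[aid] & disease_ids)
        n_c = len(valids[aid] & control_ids)
        stats = {
            "c_d": c_d, "c_c": c_c, "g_d": g_d, "g_c": g_c, "n_d": n_d, "n_c": n_c,
            "rel_total_d": c_d / g_d if g_d else None,
            "rel_total_c": c_c / g_c if g_c else None,
            "p_d": c_d / n_d if n_d else None,
            "p_c": c_c / n_c if n_c else None,
            "delta": None, "gamma": None, "direction": None,
            "frequency_label": None, "distinction_label": None,
        }
        if stats["p_d"] is not None and stats["p_c"] is not None:
            p_d, p_c = stats["p_d"], stats["p_c"]
            stats["delta"], stats["gamma"] = _delta_gamma(p_d, p_c)
            stats["direction"] = (
                "disease_higher" if p_d > p_c
                else "control_higher" if p_d < p_c else "equal"
            )
            stats["frequency_label"] = _freq_label(max(p_d, p_c))
            stats["distinction_label"] = _distinction_label(p_d, p_c)
        nodes[aid] = stats

    variable_of = dict(catalogue)
    edges = {}
    for src, src_var in catalogue:
        for tgt, tgt_var in catalogue:
            if src == tgt or (not same_variable_edges and src_var == tgt_var):
                continue
            o_d = len(members[src] & members[tgt] & disease_ids)
            o_c = len(members[src] & members[tgt] & control_ids)
            c_d_src = len(members[src] & disease_ids)
            c_c_src = len(members[src] & control_ids)
            q_d = o_d / c_d_src if c_d_src else None
            q_c = o_c / c_c_src if c_c_src else None
            p_d_tgt, p_c_tgt = nodes[tgt]["p_d"], nodes[tgt]["p_c"]
            dprime_d = q_d - p_d_tgt if q_d is not None and p_d_tgt is not None else None
            dprime_c = q_c - p_c_tgt if q_c is not None and p_c_tgt is not None else None
            gprime_d = (
                q_d / p_d_tgt
                if q_d is not None and p_d_tgt is not None and p_d_tgt > 0
                else None
            )
            gprime_c = (
                q_c / p_c_tgt
                if q_c is not None and p_c_tgt is not None and p_c_tgt > 0
                else None
            )
            etype = _edge_type([dprime_d, dprime_c], [gprime_d, gprime_c])
            if etype is None:
                continue
            edges[(src, tgt)] = {
                "o_d": o_d, "o_c": o_c, "q_d": q_d, "q_c": q_c,
                "dprime_d": dprime_d, "dprime_c": dprime_c,
                "gprime_d": gprime_d, "gprime_c": gprime_c,
                "edge_type": etype,
            }
    return nodes, edges
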