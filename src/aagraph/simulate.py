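"""Synthetic cohort generation with analytically known ground truth.

Cohorts are sampled from group-dependent parameters: categorical/binary
variables from per-group category probabilities, metric variables from
per-group normal distributions, with per-variable per-group
missing-completely-at-random (MCAR) masking applied after value
generation.  Group membership is carried by a dedicated indicator variable
referenced by the emitted cohort definition, so the generated artifacts
feed the full pipeline unchanged.

Planted conditionals make a binary target depend on a binary source with a
chosen conditional probability per group while preserving the target's
marginal, so expected edge statistics (q, delta', gamma') are closed-form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .attributes import attribute_id
from .cohort import CohortSpec, CohortTable, Criterion, VariableMeta
from .config import GraphConfig
from .graph import (
    assign_distinction_label,
    assign_edge_type,
    assign_frequency_label,
    share_comparison,
)

__all__ = [
    "SimConfigError",
    "VariableSim",
    "PlantedConditional",
    "SimulationSpec",
    "GroundTruth",
    "simulate_cohort",
    "plant_conditional",
    "load_simulation_spec",
    "write_simulation",
]

_PROB_TOL = 1e-9


class SimConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class VariableSim:
    """Per-group sampling parameters for one variable.

    metric: ``disease={"mean": m, "sd": s}``;
    binary/categorical: ``disease={"probs": {category: probability, ...}}``.
    """

    name: str
    kind: str
    disease: Mapping[str, object]
    control: Mapping[str, object]
    missing_disease: float = 0.0
    missing_control: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("metric", "binary", "categorical"):
            raise SimConfigError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        for miss in (self.missing_disease, self.missing_control):
            if not 0.0 <= miss <= 1.0:
                raise SimConfigError(f"variable {self.name!r}: missingness out of [0,1]")
        for group in (self.disease, self.control):
            if self.kind == "metric":
                if float(group["sd"]) < 0:
                    raise SimConfigError(f"variable {self.name!r}: sd must be >= 0")
            else:
                probs = dict(group["probs"])  # type: ignore[index]
                if not probs:
                    raise SimConfigError(f"variable {self.name!r}: empty probability map")
                if any(not 0.0 <= float(p) <= 1.0 for p in probs.values()):
                    raise SimConfigError(f"variable {self.name!r}: probability out of [0,1]")
                if abs(sum(map(float, probs.values())) - 1.0) > _PROB_TOL:
                    raise SimConfigError(
                        f"variable {self.name!r}: probabilities must sum to 1"
                    )

    def probs(self, group: str) -> dict[str, float]:
        params = self.disease if group == "disease" else self.control
        return {str(k): float(v) for k, v in dict(params["probs"]).items()}  # type: ignore[index]

    def categories(self) -> list[str]:
        cats = list(self.probs("disease"))
        if list(self.probs("control")) != cats:
            raise SimConfigError(
                f"variable {self.name!r}: category sets differ between groups"
            )
        return cats


@dataclass(frozen=True)
class PlantedConditional:
    """Target depends on source: P(target=positive | source=positive) = q_i."""

    source_var: str
    target_var: str
    q_disease: float
    q_control: float


@dataclass(frozen=True)
class SimulationSpec:
    g_d: int
    g_c: int
    variables: tuple[VariableSim, ...]
    seed: int = 0
    disease_name: str = "disease"
    control_name: str = "control"
    indicator_name: str = "cohort_flag"
    conditionals: tuple[PlantedConditional, ...] = ()

    def __post_init__(self) -> None:
        if self.g_d <= 0 or self.g_c <= 0:
            raise SimConfigError("both group sizes must be positive")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SimConfigError("duplicate variable names in simulation spec")
        if self.indicator_name in names:
            raise SimConfigError("indicator variable name collides with a variable")

    def variable(self, name: str) -> VariableSim:
        for v in self.variables:
            if v.name == name:
                return v
        raise SimConfigError(f"unknown variable {name!r}")


@dataclass
class GroundTruth:
    """Expected shares/labels per plantable attribute and planted edge."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[str, dict] = field(default_factory=dict)


def _positive_category(var: VariableSim) -> str:
    return next(iter(var.probs("disease")))


def plant_conditional(
    spec: SimulationSpec,
    source_var: str,
    target_var: str,
    conditional_prob_by_group: Mapping[str, float],
) -> SimulationSpec:
    """Return a spec where ``target_var`` is generated conditional on
    ``source_var`` with the given per-group conditional probabilities.

    The target keeps its specified marginal: with source share p_x and
    target marginal p_y, P(target | not source) = (p_y - q p_x)/(1 - p_x)
    must land in [0, 1] for both groups, otherwise the request is
    inconsistent.
    """
    src = spec.variable(source_var)
    tgt = spec.variable(target_var)
    for var in (src, tgt):
        if var.kind not in ("binary", "categorical") or len(var.categories()) != 2:
            raise SimConfigError(
                f"plant_conditional needs two-category variables, {var.name!r} is not"
            )
    if any(c.target_var == target_var for c in spec.conditionals):
        raise SimConfigError(f"{target_var!r} is already a conditional target")
    if any(c.source_var == target_var for c in spec.conditionals):
        raise SimConfigError(f"{target_var!r} already serves as a conditional source")
    q = {g: float(conditional_prob_by_group[g]) for g in ("disease", "control")}
    for group in ("disease", "control"):
        if not 0.0 <= q[group] <= 1.0:
            raise SimConfigError(f"conditional probability out of [0,1] for {group}")
        p_x = src.probs(group)[_positive_category(src)]
        p_y = tgt.probs(group)[_positive_category(tgt)]
        if p_x >= 1.0:
            raise SimConfigError(f"source share must be < 1 in {group}")
        p_not = (p_y - q[group] * p_x) / (1.0 - p_x)
        if not -_PROB_TOL <= p_not <= 1.0 + _PROB_TOL:
            raise SimConfigError(
                f"inconsistent conditional for {group}: implied "
                f"P(target|not source) = {p_not:.4f} out of [0, 1]"
            )
    cond = PlantedConditional(
        source_var=source_var,
        target_var=target_var,
        q_disease=q["disease"],
        q_control=q["control"],
    )
    return replace(spec, conditionals=spec.conditionals + (cond,))


def _truth(spec: SimulationSpec, config: GraphConfig) -> GroundTruth:
    truth = GroundTruth()
    for var in spec.variables:
        if var.kind == "metric":
            continue  # band shares depend on the empirical pooled range
        p_d_map, p_c_map = var.probs("disease"), var.probs("control")
        for cat in var.categories():
            p_d, p_c = p_d_map.get(cat, 0.0), p_c_map.get(cat, 0.0)
            delta, gamma = share_comparison(p_d, p_c)
            truth.nodes[attribute_id(var.name, cat)] = {
                "p_d": p_d,
                "p_c": p_c,
                "delta": delta,
                "gamma": gamma,
                "frequency_label": assign_frequency_label(max(p_d, p_c), config.node),
                "distinction_label": assign_distinction_label(p_d, p_c, config.node),
            }
    for cond in spec.conditionals:
        src = spec.variable(cond.source_var)
        tgt = spec.variable(cond.target_var)
        src_id = attribute_id(src.name, _positive_category(src))
        tgt_id = attribute_id(tgt.name, _positive_category(tgt))
        p_y = {
            "d": tgt.probs("disease")[_positive_category(tgt)],
            "c": tgt.probs("control")[_positive_category(tgt)],
        }
        q = {"d": cond.q_disease, "c": cond.q_control}
        dprime = {g: q[g] - p_y[g] for g in ("d", "c")}
        gprime = {g: (q[g] / p_y[g] if p_y[g] > 0 else None) for g in ("d", "c")}
        truth.edges[f"{src_id}->{tgt_id}"] = {
            "q_d": q["d"],
            "q_c": q["c"],
            "dprime_d": dprime["d"],
            "dprime_c": dprime["c"],
            "gprime_d": gprime["d"],
            "gprime_c": gprime["c"],
            "edge_type": assign_edge_type(
                dprime["d"],
                dprime["c"],
                gprime["d"],
                gprime["c"],
                thresholds=config.edge,
                aggregation=config.aggregation,
                magnitude=config.magnitude,
            ),
        }
    return truth


def simulate_cohort(
    spec: SimulationSpec,
    seed: Optional[int] = None,
    config: GraphConfig | None = None,
) -> tuple[CohortTable, dict[str, VariableMeta], CohortSpec, GroundTruth]:
    """Sample a cohort table plus metadata, cohort definition, and truth.

    Deterministic for a fixed spec and seed (byte-identical tables).
    """
    cfg = config or GraphConfig()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g_d, g_c = spec.g_d, spec.g_c
    n = g_d + g_c
    ids = pd.Index([f"P{i:06d}" for i in range(1, n + 1)], name="participant_id")
    disease_mask = np.zeros(n, dtype=bool)
    disease_mask[:g_d] = True

    columns: dict[str, pd.Series] = {}
    indicator = np.where(disease_mask, spec.disease_name, spec.control_name)
    columns[spec.indicator_name] = pd.Series(indicator, index=ids, dtype=object)

    targets = {c.target_var: c for c in spec.conditionals}
    plain = [v for v in spec.variables if v.name not in targets]
    ordered = plain + [spec.variable(t) for t in (c.target_var for c in spec.conditionals)]

    raw: dict[str, np.ndarray] = {}
    for var in ordered:
        if var.kind == "metric":
            values = np.empty(n, dtype=float)
            for group, mask in (("disease", disease_mask), ("control", ~disease_mask)):
                params = var.disease if group == "disease" else var.control
                values[mask] = rng.normal(
                    float(params["mean"]), float(params["sd"]), size=int(mask.sum())
                )
            raw[var.name] = values
        elif var.name in targets:
            cond = targets[var.name]
            src = spec.variable(cond.source_var)
            pos_src = _positive_category(src)
            pos_tgt, neg_tgt = var.categories()
            values = np.empty(n, dtype=object)
            src_positive = raw[src.name] == pos_src
            for group, mask in (("disease", disease_mask), ("control", ~disease_mask)):
                q = cond.q_disease if group == "disease" else cond.q_control
                p_x = src.probs(group)[pos_src]
                p_y = var.probs(group)[pos_tgt]
                p_not = (p_y - q * p_x) / (1.0 - p_x)
                p_not = min(1.0, max(0.0, p_not))
                prob = np.where(src_positive[mask], q, p_not)
                draw = rng.random(int(mask.sum())) < prob
                values[mask] = np.where(draw, pos_tgt, neg_tgt)
            raw[var.name] = values
        else:
            values = np.empty(n, dtype=object)
            for group, mask in (("disease", disease_mask), ("control", ~disease_mask)):
                probs = var.probs(group)
                cats = list(probs)
                values[mask] = rng.choice(
                    cats, size=int(mask.sum()), p=[probs[c] for c in cats]
                )
            raw[var.name] = values

    # MCAR masking, after all values exist (so conditionals see full sources).
    for var in spec.variables:
        values = raw[var.name]
        miss = np.zeros(n, dtype=bool)
        for group, mask, p_miss in (
            ("disease", disease_mask, var.missing_disease),
            ("control", ~disease_mask, var.missing_control),
        ):
            if p_miss > 0:
                miss[mask] = rng.random(int(mask.sum())) < p_miss
        if var.kind == "metric":
            col = pd.Series(values, index=ids, dtype=float)
            col[miss] = np.nan
        else:
            col = pd.Series(values, index=ids, dtype=object)
            col[miss] = None
        columns[var.name] = col

    meta: dict[str, VariableMeta] = {
        spec.indicator_name: VariableMeta(
            name=spec.indicator_name,
            data_kind="binary",
            description="simulated group indicator",
            broad_labels=("Synthetic",),
        )
    }
    for var in spec.variables:
        if var.kind == "categorical":
            meta[var.name] = VariableMeta(
                name=var.name,
                data_kind="categorical",
                description=f"simulated categorical variable {var.name}",
                categories=tuple(var.categories()),
                broad_labels=("Synthetic",),
            )
        else:
            meta[var.name] = VariableMeta(
                name=var.name,
                data_kind=var.kind,
                description=f"simulated {var.kind} variable {var.name}",
                broad_labels=("Synthetic",),
            )

    table = CohortTable(data=pd.DataFrame(columns, index=ids), meta=meta)
    cohort_spec = CohortSpec(
        criteria=[
            Criterion(
                variable=spec.indicator_name,
                comparator="equals",
                value=spec.disease_name,
            )
        ],
        disease_name=spec.disease_name,
        control_name=spec.control_name,
    )
    return table, meta, cohort_spec, _truth(spec, cfg)


def load_simulation_spec(path: str | Path) -> SimulationSpec:
    """Read a simulation spec from YAML."""
    obj = yaml.safe_load(Path(path).read_text())
    variables = tuple(
        VariableSim(
            name=str(v["name"]),
            kind=str(v["kind"]),
            disease=v["disease"],
            control=v["control"],
            missing_disease=float(v.get("missing_disease", 0.0)),
            missing_control=float(v.get("missing_control", 0.0)),
        )
        for v in obj["variables"]
    )
    spec = SimulationSpec(
        g_d=int(obj["g_d"]),
        g_c=int(obj["g_c"]),
        variables=variables,
        seed=int(obj.get("seed", 0)),
        disease_name=str(obj.get("disease_name", "disease")),
        control_name=str(obj.get("control_name", "control")),
        indicator_name=str(obj.get("indicator_name", "cohort_flag")),
    )
    for cond in obj.get("conditionals", []):
        spec = plant_conditional(
            spec,
            source_var=str(cond["source_var"]),
            target_var=str(cond["target_var"]),
            conditional_prob_by_group={
                "disease": float(cond["q_disease"]),
                "control": float(cond["q_control"]),
            },
        )
    return spec


def write_simulation(
    out_dir: str | Path,
    table: CohortTable,
    meta: Mapping[str, VariableMeta],
    cohort_spec: CohortSpec,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the four simulation artifacts as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": out / "data.csv",
        "meta": out / "meta.yaml",
        "cohort": out / "cohort.yaml",
        "truth": out / "truth.json",
    }
    table.data.to_csv(paths["data"], na_rep="")
    meta_doc = [
        {
            "name": m.name,
            "data_kind": m.data_kind,
            "description": m.description,
            "categories": list(m.categories),
            "broad_labels": list(m.broad_labels),
            "vocab_code": m.vocab_code,
        }
        for m in meta.values()
    ]
    paths["meta"].write_text(yaml.safe_dump(meta_doc, sort_keys=False))
    cohort_doc = {
        "disease_name": cohort_spec.disease_name,
        "control_name": cohort_spec.control_name,
        "criteria": [
            {"variable": c.variable, "comparator": c.comparator, "value": c.value}
            for c in cohort_spec.criteria
        ],
    }
    paths["cohort"].write_text(yaml.safe_dump(cohort_doc, sort_keys=False))
    paths["truth"].write_text(
        json.dumps({"nodes": truth.nodes, "edges": truth.edges}, indent=2, sort_keys=True)
        + "\n"
    )
    return paths
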