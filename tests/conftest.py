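from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aagraph.cohort import CohortSpec, CohortTable, Criterion, VariableMeta
from aagraph.simulate import SimulationSpec, VariableSim, plant_conditional, simulate_cohort


def make_meta(**kinds) -> dict[str, VariableMeta]:
    """kinds: variable -> 'metric' | 'binary' | ('categorical', [cats])."""
    meta = {}
    for name, kind in kinds.items():
        if isinstance(kind, tuple):
            meta[name] = VariableMeta(name=name, data_kind=kind[0], categories=tuple(kind[1]))
        else:
            meta[name] = VariableMeta(name=name, data_kind=kind)
    return meta


def make_table(columns: dict[str, list], kinds: dict, ids=None) -> CohortTable:
    n = len(next(iter(columns.values())))
    index = pd.Index(ids or [f"p{i}" for i in range(1, n + 1)], name="participant_id")
    data = {}
    meta = make_meta(**kinds)
    for name, values in columns.items():
        if meta[name].data_kind == "metric":
            data[name] = pd.Series(values, index=index, dtype=float)
        else:
            data[name] = pd.Series(
                [None if v is None else str(v) for v in values], index=index, dtype=object
            )
    return CohortTable(data=pd.DataFrame(data, index=index), meta=meta)


@pytest.fixture
def toy_table() -> CohortTable:
    """9 participants, one binary flag variable + one metric variable."""
    return make_table(
        {
            "flag": ["yes", "yes", "no", None, "yes", "no", "no", "no", None],
            "lab": [1.0, 2.0, 3.0, 4.0, 5.0, None, 2.5, 3.5, 1.5],
        },
        {"flag": "binary", "lab": "metric"},
    )


@pytest.fixture
def toy_spec() -> CohortSpec:
    return CohortSpec(criteria=[Criterion("flag", "equals", "yes")])


def small_simulation_spec(seed: int = 0, g_d: int = 200, g_c: int = 300) -> SimulationSpec:
    spec = SimulationSpec(
        g_d=g_d,
        g_c=g_c,
        seed=seed,
        variables=(
            VariableSim(
                "hyp",
                "binary",
                {"probs": {"yes": 0.6, "no": 0.4}},
                {"probs": {"yes": 0.2, "no": 0.8}},
                missing_disease=0.1,
                missing_control=0.05,
            ),
            VariableSim("chol", "metric", {"mean": 180, "sd": 30}, {"mean": 200, "sd": 30}),
            VariableSim(
                "smoke",
                "categorical",
                {"probs": {"never": 0.4, "former": 0.3, "current": 0.3}},
                {"probs": {"never": 0.5, "former": 0.3, "current": 0.2}},
            ),
            VariableSim(
                "tgt",
                "binary",
                {"probs": {"yes": 0.5, "no": 0.5}},
                {"probs": {"yes": 0.5, "no": 0.5}},
            ),
        ),
    )
    return plant_conditional(spec, "hyp", "tgt", {"disease": 0.8, "control": 0.8})


@pytest.fixture
def simulated():
    """(table, meta, cohort_spec, truth) for a small seeded cohort."""
    return simulate_cohort(small_simulation_spec(seed=11))


def table_to_rows(table: CohortTable) -> dict:
    """Raw row dicts for the brute-force oracle."""
    rows = {}
    for pid, row in table.data.iterrows():
        rows[pid] = {
            var: (None if pd.isna(v) else v) for var, v in row.items()
        }
    return rows
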