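"""Cohort tables, variable metadata, and disease/control assignment.

A cohort table is a participant-by-variable matrix with an explicit notion
of missingness.  Participants are split into a disease group and a control
group by a declarative "any-of" criteria list: a participant belongs to the
disease group if at least one criterion evaluates true on a non-missing
value, and to the control group otherwise.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LoadError",
    "SpecError",
    "VariableMeta",
    "CohortTable",
    "Criterion",
    "CohortSpec",
    "CohortAssignment",
    "DEFAULT_MISSING_MARKERS",
    "COMPARATORS",
    "load_metadata",
    "load_cohort_table",
    "load_cohort_spec",
    "validate_spec",
    "assign_cohorts",
]

DATA_KINDS = frozenset({"metric", "binary", "categorical"})
COMPARATORS = frozenset({"equals", "not_equals", "less_than", "greater_than", "in_set"})
#: Markers interpreted as missing when reading delimited text.
DEFAULT_MISSING_MARKERS = frozenset({"", "NA", "NaN"})


class LoadError(ValueError):
    """Structured error raised for malformed input tables or metadata."""


class SpecError(ValueError):
    """Raised when a cohort specification does not match the metadata."""


@dataclass(frozen=True)
class VariableMeta:
    """Description of one variable (column) of the cohort table."""

    name: str
    data_kind: str
    description: str = ""
    categories: tuple[str, ...] = ()
    broad_labels: tuple[str, ...] = ()
    vocab_code: str | None = None

    def __post_init__(self) -> None:
        if self.data_kind not in DATA_KINDS:
            raise LoadError(
                f"variable {self.name!r}: data_kind must be one of "
                f"{sorted(DATA_KINDS)}, got {self.data_kind!r}"
            )
        if self.data_kind == "categorical" and not self.categories:
            raise LoadError(
                f"variable {self.name!r}: categorical variables need a non-empty "
                "category list"
            )
        if self.data_kind != "categorical" and self.categories:
            raise LoadError(
                f"variable {self.name!r}: categories are only allowed for "
                "categorical variables"
            )


def _meta_from_record(rec: Mapping[str, object]) -> VariableMeta:
    def _as_tuple(v: object) -> tuple[str, ...]:
        if v is None:
            return ()
        if isinstance(v, str):
            return tuple(s.strip() for s in v.split(";") if s.strip())
        return tuple(str(s) for s in v)

    vocab = rec.get("vocab_code")
    if vocab is not None:
        vocab = str(vocab).strip() or None
    return VariableMeta(
        name=str(rec["name"]),
        data_kind=str(rec["data_kind"]),
        description=str(rec.get("description") or ""),
        categories=_as_tuple(rec.get("categories")),
        broad_labels=_as_tuple(rec.get("broad_labels")),
        vocab_code=vocab,
    )


def load_metadata(path: str | Path) -> dict[str, VariableMeta]:
    """Read variable metadata from a CSV or YAML file.

    CSV columns: ``name, data_kind, description, categories, broad_labels,
    vocab_code`` with ``;``-separated list cells.  YAML: a list of mappings
    with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        records = yaml.safe_load(path.read_text())
        if not isinstance(records, list):
            raise LoadError(f"{path}: expected a YAML list of variable records")
    else:
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    metas: dict[str, VariableMeta] = {}
    for rec in records:
        meta = _meta_from_record(rec)
        if meta.name in metas:
            raise LoadError(f"duplicate variable metadata for {meta.name!r}")
        metas[meta.name] = meta
    return metas


@dataclass
class CohortTable:
    """Typed participant-by-variable matrix with explicit missing cells.

    ``data`` is indexed by participant id; metric columns are float (NaN =
    missing), categorical/binary columns are object dtype (None/NaN =
    missing).
    """

    data: pd.DataFrame
    meta: dict[str, VariableMeta]
    n_unparseable: int = 0

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate participant ids: {dups}")
        unknown = [c for c in self.data.columns if c not in self.meta]
        if unknown:
            raise LoadError(f"columns without metadata: {unknown}")

    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def g_total(self) -> int:
        return int(len(self.data))

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, variable: str) -> pd.Series:
        return self.data[variable]


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_cohort_table(
    data_path: str | Path,
    meta: Mapping[str, VariableMeta],
    missing_markers: Iterable[str] | None = None,
    id_column: str = "participant_id",
    delimiter: str | None = None,
) -> CohortTable:
    """Load a delimited cohort table and type each column per its metadata.

    Cells equal to a missing marker become missing; metric cells that fail
    to parse as numbers are counted, reported via a warning, and marked
    missing.
    """
    data_path = Path(data_path)
    markers = set(DEFAULT_MISSING_MARKERS if missing_markers is None else missing_markers)
    sep = delimiter or _sniff_delimiter(data_path)
    raw = pd.read_csv(data_path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise LoadError(f"missing participant id column {id_column!r}")
    raw = raw.set_index(id_column)
    if not raw.index.is_unique:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicate participant ids: {dups}")
    unknown = [c for c in raw.columns if c not in meta]
    if unknown:
        raise LoadError(f"columns without metadata: {unknown}")

    n_unparseable = 0
    typed: dict[str, pd.Series] = {}
    for col in raw.columns:
        s = raw[col].astype(object)
        stripped = s.str.strip()
        is_missing = stripped.isin(markers)
        if meta[col].data_kind == "metric":
            num = pd.to_numeric(stripped.where(~is_missing), errors="coerce")
            bad = int((num.isna() & ~is_missing).sum())
            if bad:
                n_unparseable += bad
                warnings.warn(
                    f"column {col!r}: {bad} unparseable metric cell(s) marked missing",
                    stacklevel=2,
                )
            typed[col] = num.astype(float)
        else:
            typed[col] = stripped.where(~is_missing, other=None)
    frame = pd.DataFrame(typed, index=raw.index)
    return CohortTable(data=frame, meta=dict(meta), n_unparseable=n_unparseable)


@dataclass(frozen=True)
class Criterion:
    """One inclusion predicate of an any-of cohort definition."""

    variable: str
    comparator: str
    value: object

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise SpecError(
                f"unknown comparator {self.comparator!r}; "
                f"allowed: {sorted(COMPARATORS)}"
            )


@dataclass
class CohortSpec:
    criteria: list[Criterion]
    disease_name: str = "disease"
    control_name: str = "control"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise SpecError("cohort spec needs at least one criterion")


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort definition from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(obj, Mapping) or "criteria" not in obj:
        raise SpecError(f"{path}: expected a mapping with a 'criteria' list")
    criteria = [
        Criterion(
            variable=str(c["variable"]),
            comparator=str(c["comparator"]),
            value=c.get("value", c.get("values")),
        )
        for c in obj["criteria"]
    ]
    return CohortSpec(
        criteria=criteria,
        disease_name=str(obj.get("disease_name", "disease")),
        control_name=str(obj.get("control_name", "control")),
    )


_ORDER_COMPARATORS = {"less_than", "greater_than"}


def validate_spec(spec: CohortSpec, meta: Mapping[str, VariableMeta]) -> None:
    """Check every criterion against the variable metadata."""
    for crit in spec.criteria:
        if crit.variable not in meta:
            raise SpecError(f"criterion references unknown variable {crit.variable!r}")
        kind = meta[crit.variable].data_kind
        if crit.comparator in _ORDER_COMPARATORS and kind != "metric":
            raise SpecError(
                f"comparator {crit.comparator!r} requires a metric variable, "
                f"but {crit.variable!r} is {kind}"
            )
        if crit.comparator in _ORDER_COMPARATORS:
            try:
                float(crit.value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise SpecError(
                    f"criterion on {crit.variable!r}: value {crit.value!r} is not numeric"
                ) from None
        if crit.comparator == "in_set" and not isinstance(crit.value, (list, tuple, set, frozenset)):
            raise SpecError(
                f"criterion on {crit.variable!r}: in_set needs a list/set value"
            )


@dataclass
class CohortAssignment:
    """Disease/control membership for every participant of a table."""

    membership: pd.Series  # participant id -> disease_name or control_name
    disease_name: str = "disease"
    control_name: str = "control"

    @property
    def g_d(self) -> int:
        return int((self.membership == self.disease_name).sum())

    @property
    def g_c(self) -> int:
        return int((self.membership == self.control_name).sum())

    @property
    def g_total(self) -> int:
        return int(len(self.membership))

    def disease_mask(self) -> pd.Series:
        return self.membership == self.disease_name

    def swapped(self) -> "CohortAssignment":
        """Return the assignment with the two groups' roles exchanged."""
        mapping = {self.disease_name: self.control_name, self.control_name: self.disease_name}
        return CohortAssignment(
            membership=self.membership.map(mapping),
            disease_name=self.control_name,
            control_name=self.disease_name,
        )


def _evaluate_criterion(table: CohortTable, crit: Criterion) -> pd.Series:
    values = table.values_for(crit.variable)
    kind = table.meta[crit.variable].data_kind
    missing = values.isna()
    if crit.comparator == "less_than":
        result = values < float(crit.value)  # type: ignore[arg-type]
    elif crit.comparator == "greater_than":
        result = values > float(crit.value)  # type: ignore[arg-type]
    else:
        if kind == "metric":
            def _coerce(v: object) -> float:
                try:
                    return float(v)  # type: ignore[arg-type]
                except (TypeError, ValueError):
                    raise SpecError(
                        f"criterion on metric variable {crit.variable!r}: "
                        f"value {v!r} is not numeric"
                    ) from None
            if crit.comparator == "in_set":
                ref = {_coerce(v) for v in crit.value}  # type: ignore[union-attr]
                result = values.isin(ref)
            elif crit.comparator == "equals":
                result = values == _coerce(crit.value)
            else:
                result = values != _coerce(crit.value)
        else:
            str_values = values.astype(object)
            if crit.comparator == "in_set":
                ref = {str(v) for v in crit.value}  # type: ignore[union-attr]
                result = str_values.isin(ref)
            elif crit.comparator == "equals":
                result = str_values == str(crit.value)
            else:
                result = str_values != str(crit.value)
    # A missing value never satisfies a criterion.
    return result.fillna(False) & ~missing


def assign_cohorts(table: CohortTable, spec: CohortSpec) -> CohortAssignment:
    """Split participants into disease and control groups.

    A participant is in the disease group iff ANY criterion holds on a
    non-missing value; everyone else (including participants missing all
    criterion variables) is in the control group, so the two groups always
    partition the table.
    """
    validate_spec(spec, table.meta)
    disease = pd.Series(False, index=table.participant_ids)
    for crit in spec.criteria:
        disease |= _evaluate_criterion(table, crit)
    membership = pd.Series(
        np.where(disease, spec.disease_name, spec.control_name),
        index=table.participant_ids,
        dtype=object,
    )
    return CohortAssignment(
        membership=membership,
        disease_name=spec.disease_name,
        control_name=spec.control_name,
    )
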