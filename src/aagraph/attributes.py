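"""Reference ranges and binary attribute derivation.

Metric variables are discretized into low/normal/high bands relative to a
reference range computed over the whole data set (mean +/- one sample SD),
optionally replaced by manual clinical overrides.  Categorical and binary
variables expand into one attribute per category value.  Every participant
is, per attribute, a member, a non-member, or missing; missingness of the
underlying variable propagates to all attributes derived from it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, VariableMeta

__all__ = [
    "DerivationError",
    "ConfigError",
    "ReferenceRange",
    "AttributeDef",
    "IncidenceMatrix",
    "compute_reference_range",
    "compute_reference_ranges",
    "apply_overrides",
    "load_overrides",
    "derive_attributes",
    "attribute_id",
]

BAND_LOW = "low"
BAND_NORMAL = "normal"
BAND_HIGH = "high"
BANDS = (BAND_LOW, BAND_NORMAL, BAND_HIGH)


class DerivationError(ValueError):
    """Raised when a reference range cannot be derived."""


class ConfigError(ValueError):
    """Raised for invalid override or configuration entries."""


@dataclass(frozen=True)
class ReferenceRange:
    variable: str
    lower: float
    upper: float
    source: str = "computed"  # or "manual_override"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigError(f"reference range for {self.variable!r} must be finite")
        if self.lower > self.upper:
            raise ConfigError(
                f"reference range for {self.variable!r}: lower {self.lower} > "
                f"upper {self.upper}"
            )


def compute_reference_range(values, variable: str = "") -> ReferenceRange:
    """Mean +/- one sample SD (n-1 denominator) over non-missing values.

    The range is computed on the pooled data of both groups, so it is
    invariant to the cohort split.
    """
    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if arr.size < 2:
        raise DerivationError(
            f"variable {variable!r}: need >=2 non-missing values for a "
            f"reference range, got {arr.size}"
        )
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    return ReferenceRange(variable=variable, lower=mean - sd, upper=mean + sd)


def compute_reference_ranges(table: CohortTable) -> dict[str, ReferenceRange]:
    """Reference ranges for every metric variable; underpowered ones skipped."""
    ranges: dict[str, ReferenceRange] = {}
    for var, meta in table.meta.items():
        if meta.data_kind != "metric" or var not in table.data.columns:
            continue
        try:
            ranges[var] = compute_reference_range(table.values_for(var), variable=var)
        except DerivationError as exc:
            warnings.warn(f"skipping variable {var!r}: {exc}", stacklevel=2)
    return ranges


def apply_overrides(
    ranges: Mapping[str, ReferenceRange],
    overrides: Mapping[str, tuple[float, float]],
    known_variables: set[str] | None = None,
) -> dict[str, ReferenceRange]:
    """Replace computed ranges with manual (e.g. literature-based) intervals."""
    known = set(ranges) if known_variables is None else known_variables
    result = dict(ranges)
    for var, bounds in overrides.items():
        if var not in known:
            raise ConfigError(f"override for unknown variable {var!r}")
        lower, upper = (float(bounds[0]), float(bounds[1]))
        if lower > upper:
            raise ConfigError(f"override for {var!r}: lower {lower} > upper {upper}")
        result[var] = ReferenceRange(
            variable=var, lower=lower, upper=upper, source="manual_override"
        )
    return result


def load_overrides(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read manual reference-range overrides from YAML or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        obj = yaml.safe_load(path.read_text()) or {}
        return {
            str(var): (float(b["lower"]), float(b["upper"]))
            if isinstance(b, Mapping)
            else (float(b[0]), float(b[1]))
            for var, b in obj.items()
        }
    with path.open(newline="") as fh:
        return {
            row["variable"]: (float(row["lower"]), float(row["upper"]))
            for row in csv.DictReader(fh)
        }


def attribute_id(variable: str, value: str) -> str:
    return f"{variable}={value}"


@dataclass(frozen=True)
class AttributeDef:
    """One binary attribute: a category value or a low/normal/high band."""

    attribute_id: str
    variable: str
    value: str
    description: str = ""
    broad_labels: tuple[str, ...] = ()
    ref_lower: float | None = None
    ref_upper: float | None = None


@dataclass
class IncidenceMatrix:
    """Member/non-member/missing status per participant and attribute.

    ``member`` and ``valid`` are boolean participant-by-attribute frames;
    a participant is a member iff member & valid, a non-member iff
    valid & ~member, and missing iff ~valid.
    """

    member: pd.DataFrame
    valid: pd.DataFrame
    attributes: list[AttributeDef]

    def __post_init__(self) -> None:
        if list(self.member.columns) != [a.attribute_id for a in self.attributes]:
            raise ValueError("incidence columns must match the attribute catalogue")

    @property
    def attribute_ids(self) -> list[str]:
        return [a.attribute_id for a in self.attributes]

    def attribute(self, attr_id: str) -> AttributeDef:
        for a in self.attributes:
            if a.attribute_id == attr_id:
                return a
        raise KeyError(attr_id)


def _metric_description(meta: VariableMeta, band: str, rng: ReferenceRange) -> str:
    base = meta.description or meta.name
    if band == BAND_LOW:
        return f"{base}; below reference range (< {rng.lower:.6g})"
    if band == BAND_HIGH:
        return f"{base}; above reference range (> {rng.upper:.6g})"
    return f"{base}; within reference range [{rng.lower:.6g}, {rng.upper:.6g}]"


def derive_attributes(
    table: CohortTable,
    ranges: Mapping[str, ReferenceRange],
) -> tuple[list[AttributeDef], IncidenceMatrix]:
    """Expand every variable into binary attributes with incidence status.

    Metric bands use a closed normal interval: low iff value < lower,
    normal iff lower <= value <= upper, high iff value > upper.  Binary
    variables without declared categories use the sorted observed values.
    """
    attrs: list[AttributeDef] = []
    member_cols: dict[str, np.ndarray] = {}
    valid_cols: dict[str, np.ndarray] = {}
    for var in table.variables:
        meta = table.meta[var]
        values = table.values_for(var)
        valid = values.notna().to_numpy()
        if meta.data_kind == "metric":
            if var not in ranges:
                continue  # no derivable range; variable skipped upstream
            rng = ranges[var]
            v = values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                band_members = {
                    BAND_LOW: (v < rng.lower),
                    BAND_NORMAL: (v >= rng.lower) & (v <= rng.upper),
                    BAND_HIGH: (v > rng.upper),
                }
            for band in BANDS:
                aid = attribute_id(var, band)
                attrs.append(
                    AttributeDef(
                        attribute_id=aid,
                        variable=var,
                        value=band,
                        description=_metric_description(meta, band, rng),
                        broad_labels=meta.broad_labels,
                        ref_lower=rng.lower,
                        ref_upper=rng.upper,
                    )
                )
                member_cols[aid] = band_members[band] & valid
                valid_cols[aid] = valid
        else:
            if meta.categories:
                categories = list(meta.categories)
            else:
                observed = values.dropna().astype(str)
                categories = sorted(observed.unique())
            str_values = values.astype(object).astype(str)
            for cat in categories:
                aid = attribute_id(var, cat)
                attrs.append(
                    AttributeDef(
                        attribute_id=aid,
                        variable=var,
                        value=cat,
                        description=f"{meta.description or var} = {cat}",
                        broad_labels=meta.broad_labels,
                    )
                )
                member_cols[aid] = (str_values == cat).to_numpy() & valid
                valid_cols[aid] = valid
    ids = [a.attribute_id for a in attrs]
    member = pd.DataFrame(
        {aid: member_cols[aid] for aid in ids}, index=table.participant_ids, dtype=bool
    )
    valid_df = pd.DataFrame(
        {aid: valid_cols[aid] for aid in ids}, index=table.participant_ids, dtype=bool
    )
    if not ids:  # degenerate but valid: no derivable attributes
        member = pd.DataFrame(index=table.participant_ids, dtype=bool)
        valid_df = pd.DataFrame(index=table.participant_ids, dtype=bool)
    return attrs, IncidenceMatrix(member=member, valid=valid_df, attributes=attrs)


def catalogue_frame(attrs: list[AttributeDef]) -> pd.DataFrame:
    """Derived attribute catalogue as a flat table (CSV-exportable)."""
    return pd.DataFrame(
        {
            "attribute_id": [a.attribute_id for a in attrs],
            "variable": [a.variable for a in attrs],
            "value": [a.value for a in attrs],
            "description": [a.description for a in attrs],
            "broad_labels": [";".join(a.broad_labels) for a in attrs],
            "ref_lower": [a.ref_lower for a in attrs],
            "ref_upper": [a.ref_upper for a in attrs],
        }
    )
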