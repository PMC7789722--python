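"""Readers and writers for the tabular inputs and outputs.

Region CSVs are accepted in the units the source tables print (mortality
per 1000 live births, coverage in percent) and converted to per-1
probabilities and proportions on read.  Machine outputs are written at
full precision so that a write -> read round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .types import FixedParams, RegionInputs, RegionTable, ValidationError

#: canonical CSV header -> RegionInputs field, with unit conversion tags
REGION_COLUMNS: Mapping[str, str] = {
    "region": "name",
    "q_infant_per1000": "q_infant",
    "q_child_per1000": "q_child",
    "cost_per_treatment_usd": "cost_per_treatment",
    "incidence_per_child_year": "incidence",
    "baseline_coverage_pct": "baseline_coverage",
    "birth_cohort": "birth_cohort",
    "reported_u5mr_per1000": "reported_u5mr",
    "urban_fraction": "urban_fraction",
}

_REQUIRED = ("region", "q_infant_per1000", "q_child_per1000",
             "cost_per_treatment_usd", "incidence_per_child_year",
             "baseline_coverage_pct")
_PER1000 = {"q_infant_per1000", "q_child_per1000", "reported_u5mr_per1000"}
_OPTIONAL_FIELDS = {"birth_cohort", "reported_u5mr", "urban_fraction"}


class SchemaError(ValueError):
    """The input file does not have the expected columns."""


def read_region_table(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    coverage_is_percent: bool = True,
) -> RegionTable:
    """Read a region CSV into a validated :class:`RegionTable`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping from the file's column names to the canonical
        column names in :data:`REGION_COLUMNS`; identity by default.
    coverage_is_percent:
        If True (default, matching the printed tables) the coverage column
        holds percents and is divided by 100.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no regions")

    regions = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, fieldname in REGION_COLUMNS.items():
            if col not in df.columns:
                continue
            value = row[col]
            if fieldname != "name" and pd.isna(value):
                if fieldname in _OPTIONAL_FIELDS:
                    value = None
                else:
                    raise ValidationError(
                        f"{path}: missing value for {col} in region "
                        f"{row['region']!r}")
            elif fieldname != "name":
                value = float(value)
                if col in _PER1000:
                    value /= 1000.0
                elif col == "baseline_coverage_pct" and coverage_is_percent:
                    value /= 100.0
            kwargs[fieldname] = value
        regions.append(RegionInputs(**kwargs))
    return RegionTable(tuple(regions))


def region_table_to_frame(table: RegionTable) -> pd.DataFrame:
    """Render a RegionTable back into the canonical CSV column layout."""
    rows = []
    for r in table:
        rows.append({
            "region": r.name,
            "q_infant_per1000": r.q_infant * 1000.0,
            "q_child_per1000": r.q_child * 1000.0,
            "cost_per_treatment_usd": r.cost_per_treatment,
            "incidence_per_child_year": r.incidence,
            "baseline_coverage_pct": r.baseline_coverage * 100.0,
            "birth_cohort": r.birth_cohort,
            "reported_u5mr_per1000": (
                None if r.reported_u5mr is None else r.reported_u5mr * 1000.0),
            "urban_fraction": r.urban_fraction,
        })
    return pd.DataFrame(rows)


def write_region_table(table: RegionTable, path: Union[str, Path]) -> None:
    region_table_to_frame(table).to_csv(path, index=False,
                                        float_format="%.17g")


def write_results(results, path: Union[str, Path], format: str = "csv") -> None:
    """Write a result table (DataFrame, list of dataclasses/dicts) to disk.

    Round-trip stable: values are stored at full float precision.
    """
    df = _as_frame(results)
    if df.empty:
        raise ValidationError("empty results")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown format {format!r}")


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, RegionTable):
        return region_table_to_frame(results)
    items = list(results)
    if items and dataclasses.is_dataclass(items[0]):
        return pd.DataFrame([dataclasses.asdict(x) for x in items])
    return pd.DataFrame(items)


def read_params(path: Union[str, Path]) -> FixedParams:
    """Read :class:`FixedParams` from a YAML or JSON mapping.

    Unspecified fields keep their base-case defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    unknown = set(data) - set(FixedParams.field_names())
    if unknown:
        raise SchemaError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return FixedParams(**data)


def write_params(params: FixedParams, path: Union[str, Path]) -> None:
    path = Path(path)
    data = dataclasses.asdict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
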