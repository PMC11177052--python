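"""Table schemas, CSV I/O and validation shared by every pipeline stage.

The pipeline consumes flat, MIMIC-style relational event tables:

``stays``
    one row per ICU stay with patient covariates,
``glucose_events``
    timestamped glucose measurements with a sample type,
``nutrition_events``
    rate-based enteral nutrition intervals with a product id,
``medication_events``
    insulin / dextrose / glucocorticoid intervals or pushes,
``ventilation_events`` / ``rass_events``
    charted-state series,
``products``
    product id -> carbohydrate content (g/mL) lookup.

All tables are comma-separated UTF-8 CSV with a header row; timestamps are
timezone-naive ISO-8601 at second resolution (``YYYY-MM-DDTHH:MM:SS``) on the
local clock, which is what anchors the 24-h phenomenon under study.  Missing
values use the single sentinel ``NA``.  Column lists and dtypes are documented
in ``docs/schemas.md`` and encoded in :data:`SCHEMAS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"
NA_SENTINEL = "NA"

#: mg/dL -> mmol/L conversion factor (1 / 18.016 g/mol, conventional rounding)
MGDL_TO_MMOLL = 0.0555

SAMPLE_TYPES = ("whole_blood", "serum", "capillary")
#: preference order for deduplicating simultaneous measurements (best first)
SAMPLE_TYPE_PREFERENCE = {"whole_blood": 0, "serum": 1, "capillary": 2}

MEDICATION_KINDS = ("insulin", "dextrose", "glucocorticoid")
INSULIN_CLASSES = ("rapid", "short", "intermediate", "long")
DEXTROSE_MODES = ("infusion", "push")
VENTILATION_STATES = ("invasive", "non_invasive", "none")

# Category level labels (reference level first), mirroring the adjusted-model
# covariate bands; upper bounds are inclusive.
AGE_LEVELS = ("<55", "55-65", "66-75", ">75")
CARB_LEVELS = ("<=4.5", "4.5<x<=6.5", "6.5<x<=8.5", ">8.5")
INSULIN_LEVELS = ("0", "0<x<=1.5", "1.5<x<=3", ">3")
DEXTROSE_LEVELS = ("0", "0<x<=0.5", "0.5<x<=2", ">2")


class SchemaError(ValueError):
    """A table is structurally invalid (e.g. a required column is missing)."""


@dataclass
class RowError:
    """A single rejected row."""

    table: str
    row: int  # 0-based data-row index (header excluded)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[row {self.row}]: {self.message}"


# column name -> dtype tag: id | timestamp | timestamp? | float | float? |
# int? | bool | str
SCHEMAS: dict[str, dict[str, str]] = {
    "stays": {
        "stay_id": "id",
        "patient_id": "id",
        "admit_time": "timestamp",
        "discharge_time": "timestamp",
        "is_readmission": "bool",
        "age_years": "float",
        "sex": "str",
        "diabetes": "bool",
        "race": "str",
        "admission_type": "str",
        "sofa_admission": "int?",
        "oasis": "int?",
        "in_hospital_mortality": "bool",
    },
    "glucose_events": {
        "stay_id": "id",
        "chart_time": "timestamp",
        "store_time": "timestamp?",
        "value_mmol_l": "float",
        "sample_type": "str",
    },
    "nutrition_events": {
        "stay_id": "id",
        "product_id": "id",
        "start_time": "timestamp",
        "end_time": "timestamp",
        "rate_ml_h": "float",
    },
    "medication_events": {
        "stay_id": "id",
        "kind": "str",
        "subtype": "str",
        "start_time": "timestamp",
        "end_time": "timestamp",
        "rate": "float?",
        "amount": "float?",
    },
    "ventilation_events": {
        "stay_id": "id",
        "charted_time": "timestamp",
        "ventilation": "str",
    },
    "rass_events": {
        "stay_id": "id",
        "charted_time": "timestamp",
        "rass": "int?",
    },
    "products": {
        "product_id": "id",
        "carb_g_ml": "float?",
    },
}

#: fixed column order of the analysis table (the modelling unit: one glucose
#: measurement joined to its time-matched, categorised covariates)
ANALYSIS_COLUMNS = [
    "stay_id",
    "resolved_time",
    "glucose_mmol_l",
    "hour_bin",
    "sample_type",
    "age_years",
    "age_cat",
    "sex",
    "diabetes",
    "carb_rate_g_h",
    "carb_cat",
    "insulin_rate_u_h",
    "insulin_cat",
    "dextrose_rate_g_h",
    "dextrose_cat",
    "glucocorticoid",
    "days_since_admission",
    "time_to_next_sample_h",
    "ventilation",
    "rass",
]

_ANALYSIS_DTYPES = {
    "stay_id": "id",
    "resolved_time": "timestamp",
    "glucose_mmol_l": "float",
    "hour_bin": "int?",
    "sample_type": "str",
    "age_years": "float",
    "age_cat": "str",
    "sex": "str",
    "diabetes": "bool",
    "carb_rate_g_h": "float",
    "carb_cat": "str",
    "insulin_rate_u_h": "float",
    "insulin_cat": "str",
    "dextrose_rate_g_h": "float",
    "dextrose_cat": "str",
    "glucocorticoid": "bool",
    "days_since_admission": "float",
    "time_to_next_sample_h": "float?",
    "ventilation": "str",
    "rass": "int?",
}


@dataclass
class TableBundle:
    """Validated in-memory cohort: one DataFrame per input table."""

    stays: pd.DataFrame
    glucose_events: pd.DataFrame
    nutrition_events: pd.DataFrame
    medication_events: pd.DataFrame
    ventilation_events: pd.DataFrame
    rass_events: pd.DataFrame
    products: pd.DataFrame
    errors: list[RowError] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def table_names(self) -> tuple[str, ...]:
        return tuple(SCHEMAS)


def _parse_timestamps(raw: pd.Series) -> tuple[pd.Series, np.ndarray]:
    parsed = pd.to_datetime(raw, format=TIMESTAMP_FORMAT, errors="coerce")
    bad = parsed.isna().to_numpy() & raw.notna().to_numpy()
    return parsed, bad


def _parse_bools(raw: pd.Series) -> tuple[pd.Series, np.ndarray]:
    lowered = raw.astype("string").str.lower()
    mapped = lowered.map({"true": True, "false": False})
    bad = mapped.isna().to_numpy() & raw.notna().to_numpy()
    return mapped.astype("boolean"), bad


def parse_table(df: pd.DataFrame, name: str) -> tuple[pd.DataFrame, list[RowError]]:
    """Coerce a raw string-typed DataFrame to the schema of table *name*.

    Returns the typed frame (all rows, including invalid ones) plus a list of
    row-level errors; callers decide whether to drop or raise.
    """
    schema = SCHEMAS[name] if name in SCHEMAS else _ANALYSIS_DTYPES
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} is missing required column(s): {', '.join(missing)}")
    errors: list[RowError] = []
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        raw = df[col]
        if kind in ("timestamp", "timestamp?"):
            parsed, bad = _parse_timestamps(raw)
            for i in np.flatnonzero(bad):
                errors.append(RowError(name, int(df.index[i]), f"unparseable timestamp in {col!r}: {raw.iloc[i]!r}"))
            if kind == "timestamp" and raw.isna().any():
                for i in np.flatnonzero(raw.isna().to_numpy()):
                    errors.append(RowError(name, int(df.index[i]), f"missing required timestamp {col!r}"))
            out[col] = parsed
        elif kind in ("float", "float?"):
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = parsed.isna().to_numpy() & raw.notna().to_numpy()
            for i in np.flatnonzero(bad):
                errors.append(RowError(name, int(df.index[i]), f"non-numeric value in {col!r}: {raw.iloc[i]!r}"))
            if kind == "float" and raw.isna().any():
                for i in np.flatnonzero(raw.isna().to_numpy()):
                    errors.append(RowError(name, int(df.index[i]), f"missing required value {col!r}"))
            out[col] = parsed.astype(float)
        elif kind == "int?":
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = parsed.isna().to_numpy() & raw.notna().to_numpy()
            for i in np.flatnonzero(bad):
                errors.append(RowError(name, int(df.index[i]), f"non-integer value in {col!r}: {raw.iloc[i]!r}"))
            out[col] = parsed.astype("Float64").astype("Int64")
        elif kind == "bool":
            parsed, bad = _parse_bools(raw)
            for i in np.flatnonzero(bad | raw.isna().to_numpy()):
                errors.append(RowError(name, int(df.index[i]), f"invalid boolean in {col!r}: {raw.iloc[i]!r}"))
            out[col] = parsed
        else:  # id / str
            out[col] = raw.astype("string")
    return out, errors


def _invariant_errors(df: pd.DataFrame, name: str) -> list[RowError]:
    """Row-level semantic checks beyond dtype coercion."""
    errs: list[RowError] = []

    def flag(mask: pd.Series, message: str) -> None:
        for i in df.index[mask.fillna(False)]:
            errs.append(RowError(name, int(i), message))

    if name == "stays":
        flag(df["discharge_time"] <= df["admit_time"], "discharge_time must be after admit_time")
        flag(df["age_years"] < 0, "age_years must be non-negative")
        flag(~df["sex"].isin(["male", "female"]), "sex must be 'male' or 'female'")
    elif name == "glucose_events":
        flag(df["value_mmol_l"] <= 0, "glucose value must be positive")
        flag(~df["sample_type"].isin(SAMPLE_TYPES), f"sample_type must be one of {SAMPLE_TYPES}")
    elif name == "nutrition_events":
        flag(df["end_time"] < df["start_time"], "end_time before start_time")
        flag(df["rate_ml_h"] < 0, "nutrition rate must be non-negative")
    elif name == "medication_events":
        flag(~df["kind"].isin(MEDICATION_KINDS), f"kind must be one of {MEDICATION_KINDS}")
        flag(df["end_time"] < df["start_time"], "end_time before start_time")
        is_insulin = df["kind"] == "insulin"
        flag(is_insulin & ~df["subtype"].isin(INSULIN_CLASSES), "insulin event without a valid action class")
        is_dex = df["kind"] == "dextrose"
        flag(is_dex & ~df["subtype"].isin(DEXTROSE_MODES), "dextrose event without a valid mode")
        dosed = df["kind"].isin(["insulin", "dextrose"])
        has_rate = df["rate"].notna()
        has_amount = df["amount"].notna()
        flag(dosed & (has_rate == has_amount), "exactly one of rate/amount required for insulin and dextrose")
        flag(df["rate"] < 0, "rate must be non-negative")
        flag(df["amount"] < 0, "amount must be non-negative")
    elif name == "ventilation_events":
        flag(~df["ventilation"].isin(VENTILATION_STATES), f"ventilation must be one of {VENTILATION_STATES}")
    elif name == "rass_events":
        flag((df["rass"] < -5) | (df["rass"] > 4), "RASS must lie in -5..+4")
    elif name == "products":
        flag(df["carb_g_ml"] < 0, "carbohydrate content must be non-negative")
    return errs


def validate_table(df: pd.DataFrame, name: str) -> tuple[pd.DataFrame, list[RowError]]:
    """Type-coerce and invariant-check one table; invalid rows are dropped."""
    typed, errors = parse_table(df.astype("string"), name)
    errors += _invariant_errors(typed, name)
    bad_rows = {e.row for e in errors}
    kept = typed.loc[[i for i in typed.index if i not in bad_rows]].reset_index(drop=True)
    return kept, errors


def read_tables(paths: Mapping[str, str], strict: bool = False) -> TableBundle:
    """Read and validate the cohort tables.

    Parameters
    ----------
    paths
        Mapping from table name (a key of :data:`SCHEMAS`) to a CSV path.
    strict
        If True, any row-level error raises; otherwise offending rows are
        dropped and collected in ``bundle.errors``.
    """
    missing = [t for t in SCHEMAS if t not in paths]
    if missing:
        raise SchemaError(f"no path given for table(s): {', '.join(missing)}")
    frames: dict[str, pd.DataFrame] = {}
    all_errors: list[RowError] = []
    for name in SCHEMAS:
        raw = pd.read_csv(paths[name], dtype="string", na_values=[NA_SENTINEL], keep_default_na=False)
        kept, errors = validate_table(raw, name)
        frames[name] = kept
        all_errors += errors
    if strict and all_errors:
        raise SchemaError("; ".join(str(e) for e in all_errors[:20]))
    return TableBundle(**frames, errors=all_errors)


def _format_for_csv(df: pd.DataFrame, schema: Mapping[str, str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        s = df[col]
        if kind.startswith("timestamp"):
            out[col] = pd.to_datetime(s).dt.strftime(TIMESTAMP_FORMAT)
        elif kind == "bool":
            out[col] = s.map(lambda v: NA_SENTINEL if pd.isna(v) else ("true" if v else "false"))
        elif kind == "int?":
            out[col] = s.map(lambda v: NA_SENTINEL if pd.isna(v) else str(int(v)))
        elif kind.startswith("float"):
            out[col] = s.map(lambda v: NA_SENTINEL if pd.isna(v) else repr(float(v)))
        else:
            out[col] = s.astype("string")
        out[col] = out[col].fillna(NA_SENTINEL)
    return out


def write_tables(bundle: TableBundle, out_dir: str) -> dict[str, str]:
    """Write every bundle table as CSV under *out_dir*; returns name->path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in SCHEMAS:
        path = os.path.join(out_dir, f"{name}.csv")
        _format_for_csv(bundle.table(name), SCHEMAS[name]).to_csv(path, index=False)
        paths[name] = path
    return paths


def write_analysis_table(rows: pd.DataFrame, path: str) -> None:
    """Write the analysis table with the documented fixed column order.

    Missing optional values (``time_to_next_sample_h``, ``rass``) are written
    as the explicit ``NA`` sentinel so the file round-trips losslessly.
    """
    missing = [c for c in ANALYSIS_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"analysis table is missing column(s): {', '.join(missing)}")
    _format_for_csv(rows[ANALYSIS_COLUMNS], _ANALYSIS_DTYPES).to_csv(path, index=False)


def read_analysis_table(path: str) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype="string", na_values=[NA_SENTINEL], keep_default_na=False)
    typed, errors = parse_table(raw, "analysis")
    if errors:
        raise SchemaError("; ".join(str(e) for e in errors[:20]))
    typed["hour_bin"] = typed["hour_bin"].astype(int)
    return typed[ANALYSIS_COLUMNS]


def hour_of_day(times: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Hour-of-day bin: the timestamp's hour rounded down, on a 0-23 scale."""
    return pd.DatetimeIndex(times).hour.to_numpy()


def length_of_stay_days(stays: pd.DataFrame) -> pd.Series:
    """Total ICU length of stay (admission to discharge) in days."""
    delta = stays["discharge_time"] - stays["admit_time"]
    return delta.dt.total_seconds() / 86400.0


def categorise_age(age_years: Iterable[float]) -> pd.Categorical:
    """Age bands: <55 (reference), 55-65, 66-75, >75 years.

    Integer-age convention: <55 means <=54; the 65/66 boundary assigns 65 to
    the 55-65 band.
    """
    age = np.asarray(list(age_years), dtype=float)
    if (age < 0).any():
        raise ValueError("negative age")
    labels = np.select(
        [age < 55, age <= 65, age <= 75],
        [AGE_LEVELS[0], AGE_LEVELS[1], AGE_LEVELS[2]],
        default=AGE_LEVELS[3],
    )
    return pd.Categorical(labels, categories=list(AGE_LEVELS))


def _band(values: np.ndarray, edges: tuple[float, float, float], levels: tuple[str, ...], zero_reference: bool) -> pd.Categorical:
    if (values < 0).any():
        raise ValueError("negative rate")
    lo, mid, hi = edges
    if zero_reference:
        conds = [values == 0, values <= mid, values <= hi]
    else:
        conds = [values <= lo, values <= mid, values <= hi]
    labels = np.select(conds, list(levels[:3]), default=levels[3])
    return pd.Categorical(labels, categories=list(levels))


def categorise_carb(rate_g_h: Iterable[float]) -> pd.Categorical:
    """Carbohydrate administration bands (g/h): <=4.5 ref / (4.5,6.5] / (6.5,8.5] / >8.5."""
    return _band(np.asarray(list(rate_g_h), dtype=float), (4.5, 6.5, 8.5), CARB_LEVELS, zero_reference=False)


def categorise_insulin(rate_u_h: Iterable[float]) -> pd.Categorical:
    """Insulin administration bands (units/h): 0 ref / (0,1.5] / (1.5,3] / >3."""
    return _band(np.asarray(list(rate_u_h), dtype=float), (0.0, 1.5, 3.0), INSULIN_LEVELS, zero_reference=True)


def categorise_dextrose(rate_g_h: Iterable[float]) -> pd.Categorical:
    """Dextrose administration bands (g/h): 0 ref / (0,0.5] / (0.5,2] / >2."""
    return _band(np.asarray(list(rate_g_h), dtype=float), (0.0, 0.5, 2.0), DEXTROSE_LEVELS, zero_reference=True)
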