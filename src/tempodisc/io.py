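"""File formats: response/scored CSV tables, country tables, JSON reports.

All delimited text is UTF-8, comma-separated with a header row; times are
integer months, money is decimal in local currency units, booleans are 0/1
and numbers use the decimal point regardless of locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .instrument import CountryAnchor, IMMEDIATE, DELAYED, TERMINAL_PATTERNS
from .scoring import SCORED_COLUMNS

__all__ = [
    "SchemaError",
    "RESPONSE_COLUMNS",
    "read_responses",
    "write_responses",
    "read_scored",
    "write_scored",
    "read_country_table",
    "write_country_table",
    "write_json",
]


class SchemaError(ValueError):
    """Raised when a table does not match the expected schema."""


RESPONSE_COLUMNS = [
    "participant_id",
    "country_id",
    "choices_small_gain",
    "choices_loss",
    "choices_large_gain",
    "choice_present_bias",
    "choice_subadditivity",
    "choice_delay_framing",
    "choice_speedup_framing",
    "indifference_value",
    "indifference_censored",
    "attention_choice",
    "nonsense_flag",
    "total_time_seconds",
    "completion_fraction",
    "age",
    "income",
    "assets",
    "debt",
    "employment",
]

_BOOL_COLUMNS = ("indifference_censored", "nonsense_flag")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def _bad_rows(mask: pd.Series) -> list[int]:
    return mask[mask].index.tolist()[:10]


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read and validate a raw response table."""
    df = pd.read_csv(path, dtype={"participant_id": str, "country_id": str})
    _require_columns(df, RESPONSE_COLUMNS, f"response table {path}")
    for col in ("choices_small_gain", "choices_loss", "choices_large_gain"):
        bad = ~df[col].isin(TERMINAL_PATTERNS)
        if bad.any():
            raise SchemaError(
                f"{path}: column {col} has invalid staircase patterns in rows "
                f"{_bad_rows(bad)}"
            )
    for col in (
        "choice_present_bias",
        "choice_subadditivity",
        "choice_delay_framing",
        "choice_speedup_framing",
    ):
        bad = ~df[col].isin([IMMEDIATE, DELAYED])
        if bad.any():
            raise SchemaError(
                f"{path}: column {col} has invalid choices in rows {_bad_rows(bad)}"
            )
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int).astype(bool)
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, RESPONSE_COLUMNS, "response table")
    out = df[RESPONSE_COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False)


_SCORED_BOOLS = [
    c
    for c in SCORED_COLUMNS
    if c
    not in (
        "participant_id",
        "country_id",
        "category_small_gain",
        "category_loss",
        "category_large_gain",
        "indifference_value",
        "discounting_score",
        "z_score",
    )
]


def read_scored(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "country_id": str})
    _require_columns(df, SCORED_COLUMNS, f"scored table {path}")
    for col in _SCORED_BOOLS:
        df[col] = df[col].astype(int).astype(bool)
    return df


def write_scored(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, SCORED_COLUMNS, "scored table")
    out = df[SCORED_COLUMNS].copy()
    for col in _SCORED_BOOLS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False)


_ANCHOR_FIELDS = (
    "country_id",
    "currency_label",
    "anchor_value",
    "large_multiplier",
    "gini",
    "log_gdp_pc",
    "inflation_rate",
)


def read_country_table(path: str | Path) -> list[CountryAnchor]:
    """Read country anchors from YAML, JSON or CSV.

    YAML/JSON accept either a bare list of records or a mapping with a
    ``countries`` key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"country table {path} does not exist")
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        if isinstance(raw, dict):
            raw = raw.get("countries", raw)
        if not isinstance(raw, list):
            raise SchemaError(f"{path}: expected a list of country records")
        records = raw
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        _require_columns(df, ("country_id", "anchor_value"), f"country table {path}")
        records = df.to_dict("records")
    else:
        raise SchemaError(f"unsupported country-table format: {path.suffix}")

    anchors = []
    for i, rec in enumerate(records):
        unknown = set(rec) - set(_ANCHOR_FIELDS)
        if unknown:
            raise SchemaError(f"{path}: record {i} has unknown fields {sorted(unknown)}")
        kwargs = {k: v for k, v in rec.items() if not pd.isna(v)}
        try:
            anchors.append(CountryAnchor(**kwargs))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: record {i} invalid: {exc}") from exc
    if not anchors:
        raise SchemaError(f"{path}: no country records found")
    return anchors


def write_country_table(anchors: list[CountryAnchor], path: str | Path) -> None:
    path = Path(path)
    records = [
        {k: getattr(a, k) for k in _ANCHOR_FIELDS if getattr(a, k) is not None}
        for a in anchors
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"countries": records}, fh, sort_keys=False)
    elif path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"countries": records}, fh, indent=2)
    else:
        pd.DataFrame(records).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
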