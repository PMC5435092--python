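"""Readers and writers for the five-table delimited-text dataset.

Files are UTF-8 CSV with ISO-8601 dates; missing closing dates and
episode links are empty fields.  Reading validates schema, date syntax
(with the offending row number) and referential integrity, so the
analysis stages can assume a well-formed dataset.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dataset import CARE_EVENT_TYPES, EHRDataset, TABLE_COLUMNS
from .errors import MissingInputError, ParseError

_DATE_COLUMNS = {
    "patients": ["reg_start", "reg_end"],
    "episodes": ["start_date", "end_date"],
    "care_events": ["date"],
    "prescriptions": ["date"],
}
_NULLABLE_DATES = {("episodes", "end_date")}
_INT_COLUMNS = {
    "practices": ["year", "listed_patients", "registration_weeks"],
    "patients": ["birth_year", "birth_quarter"],
}
_FLOAT_COLUMNS = {"practices": ["coded_fraction"]}


def _parse_dates(df: pd.DataFrame, table: str, col: str, filename: str) -> pd.Series:
    raw = df[col].fillna("").astype(str)
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    nullable = (table, col) in _NULLABLE_DATES
    bad = parsed.isna() & (raw != "") if nullable else parsed.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(
            f"{filename}: malformed date {raw[bad.idxmax()]!r} in column "
            f"{col!r} at line {row}"
        )
    return parsed


def read_dataset(directory: str | Path) -> EHRDataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise MissingInputError(f"missing input file: {path}")
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path.name}: missing columns {missing}")
        df = df[cols]
        for col in _DATE_COLUMNS.get(name, []):
            df[col] = _parse_dates(df, name, col, path.name)
        for col in _INT_COLUMNS.get(name, []):
            try:
                df[col] = df[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path.name}: non-integer value in {col!r}") from exc
        for col in _FLOAT_COLUMNS.get(name, []):
            df[col] = df[col].astype(float)
        tables[name] = df

    events = tables["care_events"]
    if len(events):
        bad = ~events["type"].isin(CARE_EVENT_TYPES)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ParseError(
                f"care_events.csv: unknown event type "
                f"{events['type'][bad.idxmax()]!r} at line {row}"
            )
    for name in ("care_events", "prescriptions"):
        col = tables[name]["episode_id"]
        tables[name]["episode_id"] = col.where(col.notna() & (col != ""), None)

    dataset = EHRDataset(**tables)
    dataset.validate()
    return dataset


def write_dataset(dataset: EHRDataset, directory: str | Path) -> dict[str, Path]:
    """Write one CSV per table; returns a table → path manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for name, df in dataset.tables().items():
        out = df.copy()
        for col in _DATE_COLUMNS.get(name, []):
            if len(out):
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        for col in _FLOAT_COLUMNS.get(name, []):
            if len(out):
                out[col] = out[col].map(lambda v: f"{v:.3f}")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        manifest[name] = path
    return manifest
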