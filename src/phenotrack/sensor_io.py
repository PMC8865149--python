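"""Delimited-text I/O for the study's canonical file layouts.

All files are UTF-8 CSV with a header row.  Timestamps are UTC epoch
milliseconds; day/hour semantics are governed by each subject's IANA
timezone recorded in the demographics table.

Layouts::

    gps.csv           timestamp,latitude,longitude,accuracy
    accel.csv         timestamp,x,y,z
    surveys.csv       subject,delivered,completed,instrument,q1..q8,total
    visits.csv        subject,visit_index,date,madrs
    calls.csv         subject,timestamp,direction,hashed_number
    demographics.csv  subject,age,sex,diagnosis,timezone,os

Readers return time-sorted frames; malformed rows (unparseable timestamps,
out-of-range coordinates, invalid enums) are counted in ``frame.attrs
["n_rejected"]`` and logged, never silently dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_DIRECTIONS = ("incoming", "outgoing", "missed")

GPS_COLUMNS = ["timestamp", "latitude", "longitude", "accuracy"]
ACCEL_COLUMNS = ["timestamp", "x", "y", "z"]
SURVEY_COLUMNS = ["subject", "delivered", "completed", "instrument"] + [
    f"q{i}" for i in range(1, 9)
] + ["total"]
VISIT_COLUMNS = ["subject", "visit_index", "date", "madrs"]
CALL_COLUMNS = ["subject", "timestamp", "direction", "hashed_number"]
DEMOGRAPHICS_COLUMNS = ["subject", "age", "sex", "diagnosis", "timezone", "os"]


class SchemaError(ValueError):
    """A required column is absent from an input file."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _reject(df: pd.DataFrame, bad: pd.Series, path, reason: str) -> pd.DataFrame:
    n = int(bad.sum())
    if n:
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        logger.warning("%s: rejected %d row(s) (%s), e.g. lines %s", path, n, reason, lines)
    out = df[~bad]
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0) + n
    return out


def _numeric(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def read_gps(path) -> pd.DataFrame:
    """Read a GPS stream; rows sorted by timestamp on return."""
    df = pd.read_csv(path)
    _check_columns(df, GPS_COLUMNS, path)
    df = _numeric(df[GPS_COLUMNS].copy(), GPS_COLUMNS)
    bad = (
        df["timestamp"].isna()
        | df["latitude"].isna()
        | df["longitude"].isna()
        | (df["latitude"].abs() > 90)
        | (df["longitude"].abs() > 180)
        | (df["accuracy"] < 0)
    )
    df = _reject(df, bad, path, "unparseable or out-of-range fields")
    df["timestamp"] = df["timestamp"].astype(np.int64)
    out = df.sort_values("timestamp", kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_gps(df: pd.DataFrame, path) -> None:
    df[GPS_COLUMNS].to_csv(path, index=False)


def read_accel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ACCEL_COLUMNS, path)
    df = _numeric(df[ACCEL_COLUMNS].copy(), ACCEL_COLUMNS)
    bad = df[ACCEL_COLUMNS].isna().any(axis=1) | ~np.isfinite(df[ACCEL_COLUMNS]).all(axis=1)
    df = _reject(df, bad, path, "non-finite fields")
    df["timestamp"] = df["timestamp"].astype(np.int64)
    out = df.sort_values("timestamp", kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_accel(df: pd.DataFrame, path) -> None:
    df[ACCEL_COLUMNS].to_csv(path, index=False)


def read_surveys(path) -> pd.DataFrame:
    """Read PHQ-8 survey records; ``completed`` may be empty (not completed)."""
    df = pd.read_csv(path)
    _check_columns(df, SURVEY_COLUMNS, path)
    df = df[SURVEY_COLUMNS].copy()
    num_cols = ["delivered", "completed"] + [f"q{i}" for i in range(1, 9)] + ["total"]
    df = _numeric(df, num_cols)
    items = df[[f"q{i}" for i in range(1, 9)]]
    bad = (
        df["delivered"].isna()
        | (df["total"] < 0)
        | (df["total"] > 24)
        | ((items < 0) | (items > 3)).any(axis=1)
        | (df["completed"].notna() & (df["completed"] < df["delivered"]))
    )
    df = _reject(df, bad, path, "invalid survey fields")
    out = df.sort_values("delivered", kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_surveys(df: pd.DataFrame, path) -> None:
    df[SURVEY_COLUMNS].to_csv(path, index=False)


def read_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, VISIT_COLUMNS, path)
    df = df[VISIT_COLUMNS].copy()
    df = _numeric(df, ["visit_index", "madrs"])
    parsed = pd.to_datetime(df["date"], errors="coerce")
    bad = (
        df["visit_index"].isna()
        | df["madrs"].isna()
        | (df["madrs"] < 0)
        | (df["madrs"] > 60)
        | parsed.isna()
    )
    df["date"] = parsed.dt.date
    df = _reject(df, bad, path, "invalid visit fields")
    out = df.sort_values(["subject", "visit_index"], kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_visits(df: pd.DataFrame, path) -> None:
    df[VISIT_COLUMNS].to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CALL_COLUMNS, path)
    df = df[CALL_COLUMNS].copy()
    df = _numeric(df, ["timestamp"])
    bad = df["timestamp"].isna() | ~df["direction"].isin(CALL_DIRECTIONS)
    df = _reject(df, bad, path, "invalid call fields")
    df["timestamp"] = df["timestamp"].astype(np.int64)
    out = df.sort_values("timestamp", kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_calls(df: pd.DataFrame, path) -> None:
    df[CALL_COLUMNS].to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DEMOGRAPHICS_COLUMNS, path)
    df = df[DEMOGRAPHICS_COLUMNS].copy()
    df = _numeric(df, ["age"])
    df = _reject(df, df["age"].isna() | (df["age"] < 0), path, "invalid age")
    out = df.sort_values("subject", kind="stable", ignore_index=True)
    out.attrs["n_rejected"] = df.attrs.get("n_rejected", 0)
    return out


def write_demographics(df: pd.DataFrame, path) -> None:
    df[DEMOGRAPHICS_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# whole-cohort layout
# ---------------------------------------------------------------------------


def write_cohort(dataset, directory) -> Path:
    """Write a simulated cohort in the canonical directory layout.

    ``<dir>/demographics.csv``, ``visits.csv``, ``surveys.csv``,
    ``calls.csv``, one ``<dir>/<subject>/gps.csv`` + ``accel.csv`` per
    subject, a ``manifest.yaml`` with the generating configuration, and the
    simulator ground truth under ``<dir>/truth/``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_demographics(dataset.demographics, directory / "demographics.csv")
    write_visits(dataset.visits, directory / "visits.csv")
    write_surveys(dataset.surveys, directory / "surveys.csv")
    write_calls(dataset.calls, directory / "calls.csv")
    for subject, df in dataset.gps.items():
        sub = directory / subject
        sub.mkdir(exist_ok=True)
        write_gps(df, sub / "gps.csv")
    for subject, df in dataset.accel.items():
        sub = directory / subject
        sub.mkdir(exist_ok=True)
        write_accel(df, sub / "accel.csv")
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    dataset.truth_daily.to_csv(truth_dir / "daily.csv", index=False)
    dataset.latent.to_csv(truth_dir / "latent.csv", index=False)
    dataset.outages.to_csv(truth_dir / "outages.csv", index=False)
    dataset.config.to_yaml(directory / "manifest.yaml")
    return directory


def read_cohort_tables(directory) -> dict:
    """Read back the table-level parts of a cohort directory."""
    directory = Path(directory)
    out = {
        "demographics": read_demographics(directory / "demographics.csv"),
        "visits": read_visits(directory / "visits.csv"),
        "surveys": read_surveys(directory / "surveys.csv"),
        "calls": read_calls(directory / "calls.csv"),
        "gps": {},
        "accel": {},
    }
    for sub in out["demographics"]["subject"]:
        gps_path = directory / sub / "gps.csv"
        accel_path = directory / sub / "accel.csv"
        if gps_path.exists():
            out["gps"][sub] = read_gps(gps_path)
        if accel_path.exists():
            out["accel"][sub] = read_accel(accel_path)
    return out
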