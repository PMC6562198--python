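"""Delimited-text readers and writers for the three input tables.

Interchange dialect: comma-separated with a header row, ISO-8601
timestamps at minute resolution (``YYYY-MM-DDTHH:MM``), lowercase analyte
tokens, ``true``/``false`` booleans.  Columns:

* ``admissions.csv`` — admission_id, age, sex, admit_time, discharge_time,
  admission_method, specialty, death_in_hospital, death_time,
  icu_admission_time (the last two may be empty)
* ``vitals.csv`` — admission_id, obs_time, heart_rate, systolic_bp,
  respiratory_rate, temperature, spo2, supplemental_oxygen, consciousness
  (an AVPU letter or an integer GCS in 3..15)
* ``labs.csv`` — admission_id, received_time, analyte, value

Vitals rows that are not a complete NEWS-sufficient set are rejected and
counted (with line numbers) rather than failing the load; structural
problems — missing columns, unparseable timestamps, unknown analyte
tokens — raise :class:`SchemaError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import ANALYTES, AVPU_LEVELS

TIME_FORMAT = "%Y-%m-%dT%H:%M"

ADMISSION_COLUMNS = [
    "admission_id", "age", "sex", "admit_time", "discharge_time",
    "admission_method", "specialty", "death_in_hospital", "death_time",
    "icu_admission_time",
]
VITALS_COLUMNS = [
    "admission_id", "obs_time", "heart_rate", "systolic_bp", "respiratory_rate",
    "temperature", "spo2", "supplemental_oxygen", "consciousness",
]
LABS_COLUMNS = ["admission_id", "received_time", "analyte", "value"]

_VITAL_NUMERIC = ["heart_rate", "systolic_bp", "respiratory_rate", "temperature", "spo2"]


class SchemaError(ValueError):
    """A structural violation of the documented table schemas."""


@dataclass
class ReadReport:
    rejected_vitals_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_vitals_rows)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _parse_times(s: pd.Series, name: str, allow_na: bool = False) -> pd.Series:
    out = pd.to_datetime(s, format="ISO8601", errors="coerce")
    bad = out.isna() & ~(s.isna() | (s.astype(str).str.strip() == ""))
    if bad.any():
        raise SchemaError(f"{name}: unparseable timestamps, e.g. {s[bad].iloc[0]!r}")
    if not allow_na and out.isna().any():
        raise SchemaError(f"{name}: missing timestamps")
    return out


def read_admissions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ADMISSION_COLUMNS, "admissions")
    out = pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "age": pd.to_numeric(df["age"]).astype(int),
            "sex": df["sex"],
            "admit_time": _parse_times(df["admit_time"], "admissions.admit_time"),
            "discharge_time": _parse_times(df["discharge_time"], "admissions.discharge_time"),
            "admission_method": df["admission_method"],
            "specialty": df["specialty"],
            "death_in_hospital": df["death_in_hospital"].str.lower() == "true",
            "death_time": _parse_times(df["death_time"], "admissions.death_time", allow_na=True),
            "icu_admission_time": _parse_times(
                df["icu_admission_time"], "admissions.icu_admission_time", allow_na=True
            ),
        }
    )
    bad_sex = ~out["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise SchemaError(f"admissions: unknown sex token {out['sex'][bad_sex].iloc[0]!r}")
    inconsistent = out["death_in_hospital"] != out["death_time"].notna()
    if inconsistent.any():
        raise SchemaError("admissions: death_in_hospital inconsistent with death_time")
    return out


def read_vitals(path, report: ReadReport | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, VITALS_COLUMNS, "vitals")
    report = report if report is not None else ReadReport()

    ok = pd.Series(True, index=df.index)
    numeric = {}
    for col in _VITAL_NUMERIC:
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
        ok &= numeric[col].notna()
    oxy = df["supplemental_oxygen"].astype(str).str.lower()
    ok &= oxy.isin(["true", "false"])
    cons = df["consciousness"].astype(str).str.strip()
    is_avpu = cons.isin(AVPU_LEVELS)
    gcs_num = pd.to_numeric(cons.where(~is_avpu), errors="coerce")
    ok &= is_avpu | (gcs_num.between(3, 15) & (gcs_num % 1 == 0))

    for idx in df.index[~ok]:
        # +2: header line and 1-based numbering
        report.rejected_vitals_rows.append((int(idx) + 2, "incomplete or malformed vitals set"))

    kept = df[ok]
    out = pd.DataFrame(
        {
            "admission_id": kept["admission_id"],
            "obs_time": _parse_times(kept["obs_time"], "vitals.obs_time"),
            **{col: numeric[col][ok].astype(float) for col in _VITAL_NUMERIC},
            "supplemental_oxygen": oxy[ok] == "true",
            "avpu": cons[ok].where(is_avpu[ok]),
            "gcs": gcs_num[ok].astype(float),
        }
    ).reset_index(drop=True)
    return out


def read_labs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, LABS_COLUMNS, "labs")
    unknown = ~df["analyte"].isin(ANALYTES)
    if unknown.any():
        raise SchemaError(f"labs: unknown analyte token {df['analyte'][unknown].iloc[0]!r}")
    value = pd.to_numeric(df["value"], errors="coerce")
    if value.isna().any() or (value <= 0).any():
        raise SchemaError("labs: values must be positive numbers")
    return pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "received_time": _parse_times(df["received_time"], "labs.received_time"),
            "analyte": df["analyte"],
            "value": value.astype(float),
        }
    )


def read_tables(admissions_path, vitals_path, labs_path):
    """Load and validate the three input tables.

    Returns ``(admissions, vitals, labs, report)`` where *report* counts
    rejected (incomplete) vitals rows with their line numbers.
    """
    report = ReadReport()
    return (
        read_admissions(admissions_path),
        read_vitals(vitals_path, report),
        read_labs(labs_path),
        report,
    )


# ---------------------------------------------------------------------------
# Writers (canonical formatting, so identical frames give identical bytes)


def _fmt_time(s: pd.Series) -> pd.Series:
    return s.dt.strftime(TIME_FORMAT).fillna("")


def _fmt_number(x) -> str:
    if pd.isna(x):
        return ""
    f = float(x)
    return str(int(f)) if f.is_integer() else repr(f)


def write_admissions(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "age": df["age"].astype(int),
            "sex": df["sex"],
            "admit_time": _fmt_time(df["admit_time"]),
            "discharge_time": _fmt_time(df["discharge_time"]),
            "admission_method": df["admission_method"],
            "specialty": df["specialty"],
            "death_in_hospital": np.where(df["death_in_hospital"], "true", "false"),
            "death_time": _fmt_time(df["death_time"]),
            "icu_admission_time": _fmt_time(df["icu_admission_time"]),
        }
    )
    out.to_csv(path, index=False)


def write_vitals(df: pd.DataFrame, path) -> None:
    consciousness = df["avpu"].copy().astype(object)
    has_gcs = consciousness.isna() & df["gcs"].notna()
    consciousness.loc[has_gcs] = df.loc[has_gcs, "gcs"].astype(int).astype(str)
    out = pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "obs_time": _fmt_time(df["obs_time"]),
            **{c: df[c].map(_fmt_number) for c in _VITAL_NUMERIC},
            "supplemental_oxygen": np.where(df["supplemental_oxygen"], "true", "false"),
            "consciousness": consciousness,
        }
    )
    out.to_csv(path, index=False)


def write_labs(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "received_time": _fmt_time(df["received_time"]),
            "analyte": df["analyte"],
            "value": df["value"].map(_fmt_number),
        }
    )
    out.to_csv(path, index=False)


def write_cohort_tables(cohort, outdir) -> dict[str, Path]:
    """Write a synthetic cohort's three tables (+ ground truth) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "admissions": outdir / "admissions.csv",
        "vitals": outdir / "vitals.csv",
        "labs": outdir / "labs.csv",
        "truth": outdir / "truth.csv",
    }
    write_admissions(cohort.admissions, paths["admissions"])
    write_vitals(cohort.vitals, paths["vitals"])
    write_labs(cohort.labs, paths["labs"])
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths
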