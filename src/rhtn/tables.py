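"""Reading and writing the three record tables.

The on-disk dialect is deliberately minimal: comma-separated UTF-8 with a
single header row and ISO-8601 dates.  ``load_tables`` returns typed
pandas DataFrames; rows violating the schema invariants are dropped, not
repaired, and counted in a :class:`ValidationReport` so that
``accepted + rejected == input rows`` per table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rhtn.config import StudyConfig
from rhtn.drug_coding import DrugClass

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "death_date",
    "registration_date",
    "practice_uts_date",
    "transfer_out_date",
    "last_collection_date",
    "htn_diagnosis_date",
]
PRESCRIPTION_COLUMNS = ["patient_id", "issue_date", "drug_class", "days_supply"]
BP_COLUMNS = ["patient_id", "measure_date", "systolic", "diastolic"]

_PATIENT_DATE_COLS = [c for c in PATIENT_COLUMNS if c.endswith("_date")]
_OPTIONAL_PATIENT_DATES = {"death_date", "transfer_out_date", "htn_diagnosis_date"}


@dataclasses.dataclass
class TableReport:
    table: str
    n_input: int
    n_accepted: int
    n_rejected: int
    reject_reasons: dict[str, int] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class ValidationReport:
    patients: TableReport
    prescriptions: TableReport
    bp: TableReport

    def as_dict(self) -> dict:
        return {r.table: dataclasses.asdict(r) for r in
                (self.patients, self.prescriptions, self.bp)}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
    return df


def _load_patients(path: Path) -> tuple[pd.DataFrame, TableReport]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, PATIENT_COLUMNS, "patients")
    n_in = len(df)
    raw_dates = df[_PATIENT_DATE_COLS].copy()
    df = _parse_dates(df, _PATIENT_DATE_COLS)

    reasons: dict[str, int] = {}
    ok = pd.Series(True, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        mask = mask & ok
        if mask.any():
            reasons[reason] = reasons.get(reason, 0) + int(mask.sum())
        ok[mask] = False

    reject(~df["sex"].isin(["male", "female"]), "invalid_sex")
    for c in _PATIENT_DATE_COLS:
        had_value = raw_dates[c].notna() & (raw_dates[c].astype(str).str.len() > 0)
        bad = had_value & df[c].isna()
        if c in _OPTIONAL_PATIENT_DATES:
            reject(bad, f"unparseable_{c}")
        else:
            reject(bad | df[c].isna(), f"missing_or_unparseable_{c}")
    # birth precedes everything else; end-of-record dates follow registration
    for c in _PATIENT_DATE_COLS:
        if c != "birth_date":
            reject(df[c].notna() & (df[c] <= df["birth_date"]), "date_before_birth")
    for c in ("death_date", "transfer_out_date"):
        reject(df[c].notna() & (df[c] < df["registration_date"]),
               "exit_before_registration")
    reject(df["patient_id"].duplicated(keep="first"), "duplicate_patient_id")

    out = df[ok].reset_index(drop=True)
    return out, TableReport("patients", n_in, len(out), n_in - len(out), reasons)


def _load_prescriptions(path: Path, config: StudyConfig) -> tuple[pd.DataFrame, TableReport]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "issue_date", "drug_class"], "prescriptions")
    n_in = len(df)
    if "days_supply" not in df.columns:
        df["days_supply"] = config.days_supply_default
    df["days_supply"] = pd.to_numeric(df["days_supply"], errors="coerce")
    df.loc[df["days_supply"].isna(), "days_supply"] = config.days_supply_default
    df = _parse_dates(df, ["issue_date"])

    reasons: dict[str, int] = {}
    ok = pd.Series(True, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        mask = mask & ok
        if mask.any():
            reasons[reason] = reasons.get(reason, 0) + int(mask.sum())
        ok[mask] = False

    reject(df["issue_date"].isna(), "unparseable_issue_date")
    valid_classes = {c.value for c in DrugClass}
    reject(~df["drug_class"].isin(valid_classes), "unknown_drug_class")
    reject(df["days_supply"] < 1, "nonpositive_days_supply")

    out = df[ok].reset_index(drop=True)
    out["days_supply"] = out["days_supply"].astype(int)
    return out, TableReport("prescriptions", n_in, len(out), n_in - len(out), reasons)


def _load_bp(path: Path) -> tuple[pd.DataFrame, TableReport]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, BP_COLUMNS, "bp")
    n_in = len(df)
    df = _parse_dates(df, ["measure_date"])
    df["systolic"] = pd.to_numeric(df["systolic"], errors="coerce")
    df["diastolic"] = pd.to_numeric(df["diastolic"], errors="coerce")

    reasons: dict[str, int] = {}
    ok = pd.Series(True, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        mask = mask & ok
        if mask.any():
            reasons[reason] = reasons.get(reason, 0) + int(mask.sum())
        ok[mask] = False

    reject(df["measure_date"].isna(), "unparseable_measure_date")
    reject(df["systolic"].isna() | df["diastolic"].isna(), "missing_value")
    # sanity bounds: 40 <= diastolic < systolic <= 350
    reject(
        (df["diastolic"] < 40)
        | (df["systolic"] > 350)
        | (df["diastolic"] >= df["systolic"]),
        "out_of_range",
    )
    out = df[ok].reset_index(drop=True)
    return out, TableReport("bp", n_in, len(out), n_in - len(out), reasons)


def load_tables(
    patients_path: str | Path,
    prescriptions_path: str | Path,
    bp_path: str | Path,
    config: Optional[StudyConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ValidationReport]:
    """Load and validate the three record tables.

    Returns typed DataFrames (dates as ``datetime64[ns]``) and a
    :class:`ValidationReport` counting rejected rows per table and reason.
    A missing required column raises :class:`SchemaError`.
    """
    config = config or StudyConfig()
    patients, rp = _load_patients(Path(patients_path))
    rx, rr = _load_prescriptions(Path(prescriptions_path), config)
    bp, rb = _load_bp(Path(bp_path))
    return patients, rx, bp, ValidationReport(rp, rr, rb)


def _date_to_iso(series: pd.Series) -> pd.Series:
    out = series.dt.strftime("%Y-%m-%d")
    return out.fillna("")


def write_tables(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    bp: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three tables as CSV with ISO dates; returns file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = patients[PATIENT_COLUMNS].copy()
    for c in _PATIENT_DATE_COLS:
        p[c] = _date_to_iso(p[c])
    paths["patients"] = out_dir / "patients.csv"
    p.to_csv(paths["patients"], index=False)

    r = prescriptions[PRESCRIPTION_COLUMNS].copy()
    r["issue_date"] = _date_to_iso(r["issue_date"])
    paths["prescriptions"] = out_dir / "prescriptions.csv"
    r.to_csv(paths["prescriptions"], index=False)

    b = bp[BP_COLUMNS].copy()
    b["measure_date"] = _date_to_iso(b["measure_date"])
    b["systolic"] = b["systolic"].astype(int)
    b["diastolic"] = b["diastolic"].astype(int)
    paths["bp"] = out_dir / "bp.csv"
    b.to_csv(paths["bp"], index=False)
    return paths
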