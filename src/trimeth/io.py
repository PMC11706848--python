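"""CSV dialects read and written by the pipeline.

All files are plain UTF-8 CSV with a header row.

droplet table   : plate_id, well_id, sample_id, channel, target, role, amplitude
                  (one row per droplet per read channel; QuantaSoft-export-like)
sample sheet    : sample_id, patient_id, timepoint, plasma_volume_ml,
                  template_volume_ul, spiked_cpp1_copies
clinical table  : patient_id, inclusion_date, recurrence_date, death_date,
                  death_cause, data_cutoff, <covariate columns>; ISO-8601 dates,
                  empty string for absent dates
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

from trimeth.survival import DEFAULT_DATA_CUTOFF, DeathCause, PatientRecord

__all__ = [
    "read_droplets",
    "read_sample_sheet",
    "read_clinical",
    "clinical_to_records",
    "write_csv",
]

DROPLET_COLUMNS = ["plate_id", "well_id", "sample_id", "channel", "target", "role", "amplitude"]
SAMPLE_SHEET_COLUMNS = [
    "sample_id", "patient_id", "timepoint",
    "plasma_volume_ml", "template_volume_ul", "spiked_cpp1_copies",
]
CLINICAL_DATE_COLUMNS = ["inclusion_date", "recurrence_date", "death_date", "data_cutoff"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {', '.join(missing)}")


def read_droplets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "well_id": str, "plate_id": str})
    _require(df, DROPLET_COLUMNS, f"droplet table {path}")
    df["sample_id"] = df["sample_id"].fillna("")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    _require(df, SAMPLE_SHEET_COLUMNS, f"sample sheet {path}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"sample sheet {path}: duplicate sample_id(s) {dupes}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    _require(df, ["patient_id", "inclusion_date"], f"clinical table {path}")
    return df


def _parse_date(value: str) -> _dt.date | None:
    if not value or value != value:  # empty or NaN
        return None
    return _dt.date.fromisoformat(str(value))


def clinical_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a clinical table into PatientRecord objects."""
    known = {"patient_id", "inclusion_date", "recurrence_date", "death_date",
             "death_cause", "data_cutoff"}
    cov_cols = [c for c in df.columns if c not in known]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cause = d.get("death_cause") or "unknown"
        records.append(
            PatientRecord(
                patient_id=str(d["patient_id"]),
                inclusion_date=_parse_date(d["inclusion_date"]),
                covariates={c: d[c] for c in cov_cols},
                recurrence_date=_parse_date(d.get("recurrence_date", "")),
                death_date=_parse_date(d.get("death_date", "")),
                death_cause=DeathCause(cause),
                data_cutoff=_parse_date(d.get("data_cutoff", "")) or DEFAULT_DATA_CUTOFF,
            )
        )
    return records


def write_csv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write a CSV deterministically (stable column order, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return path
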