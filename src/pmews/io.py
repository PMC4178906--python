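"""Patient-cohort CSV I/O and record conversion helpers."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .bands import ValidationError
from .scoring import (
    REQUIRED_COLUMNS,
    PatientRecord,
    SocialFactors,
    VitalSigns,
    parse_consciousness,
)

__all__ = [
    "read_patient_csv",
    "write_patient_csv",
    "records_from_frame",
    "frame_from_records",
]


def read_patient_csv(path, require_label: bool = False) -> pd.DataFrame:
    """Read a patient cohort CSV, checking the required column set."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column: {col}")
    if require_label and "needs_ems" not in df.columns:
        raise ValidationError(f"{path}: missing required column: needs_ems")
    return df


def write_patient_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a patient-CSV DataFrame to typed records."""
    records = []
    has_label = "needs_ems" in df.columns
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                vitals=VitalSigns(
                    respiratory_rate=float(row.respiratory_rate),
                    spo2=float(row.spo2),
                    heart_rate=float(row.heart_rate),
                    systolic_bp=float(row.systolic_bp),
                    temperature=float(row.temperature_c),
                    consciousness=parse_consciousness(row.consciousness),
                ),
                social=SocialFactors(
                    age=float(row.age_years),
                    socially_isolated=bool(row.socially_isolated),
                    chronic_disease=bool(row.chronic_disease),
                    performance_status=int(row.performance_status),
                ),
                needs_ems=bool(row.needs_ems) if has_label else None,
            )
        )
    return records


def frame_from_records(records: Iterable[PatientRecord]) -> pd.DataFrame:
    from .scoring import CONSCIOUSNESS_CANONICAL

    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "respiratory_rate": r.vitals.respiratory_rate,
                "spo2": r.vitals.spo2,
                "heart_rate": r.vitals.heart_rate,
                "systolic_bp": r.vitals.systolic_bp,
                "temperature_c": r.vitals.temperature,
                "consciousness": CONSCIOUSNESS_CANONICAL[r.vitals.consciousness],
                "age_years": r.social.age,
                "socially_isolated": int(r.social.socially_isolated),
                "chronic_disease": int(r.social.chronic_disease),
                "performance_status": int(r.social.performance_status),
                **(
                    {"needs_ems": int(r.needs_ems)}
                    if r.needs_ems is not None
                    else {}
                ),
            }
        )
    return pd.DataFrame(rows)
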