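"""PMEWS scoring engine.

The physiological-social modified early warning score (PMEWS) combines

* a physiological component (a MEWS-style sum over respiratory rate, SpO2,
  heart rate, systolic blood pressure, temperature and consciousness, each
  banded 0-3, temperature 0-2; range 0-17), and
* a social component: one point each for age > 65 (strict), social isolation
  (lives alone / no fixed abode) and chronic disease, plus the 0-4
  performance-status scale (range 0-7).

Total PMEWS = physiological + social, range 0-24. Age exactly 65 scores 0.

Two scoring paths are provided and kept consistent by tests: a per-record
dataclass path (:func:`total_pmews`) and a vectorised DataFrame path
(:func:`score_dataframe`) used by the simulation and pipeline layers.

Missing physiological data is an error under the default ``strict`` policy
(the study the instrument comes from discarded incomplete forms); the
opt-in ``missing_zero`` policy scores a missing parameter as normal (0) and
logs each affected record.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bands import ScoreBandTable, ValidationError, load_instrument

__all__ = [
    "Consciousness",
    "VitalSigns",
    "SocialFactors",
    "PatientRecord",
    "PMEWSResult",
    "ParseError",
    "parse_consciousness",
    "score_parameter",
    "score_consciousness",
    "physiological_score",
    "social_score",
    "total_pmews",
    "score_dataframe",
    "PHYSIO_PARAMETERS",
    "PHYSIO_MAX",
    "SOCIAL_MAX",
    "TOTAL_MAX",
    "VITAL_COLUMNS",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger("pmews")

PHYSIO_PARAMETERS = (
    "respiratory_rate",
    "spo2",
    "heart_rate",
    "systolic_bp",
    "temperature",
    "consciousness",
)
PHYSIO_MAX = 17  # 3 + 3 + 3 + 3 + 2 + 3
SOCIAL_MAX = 7  # three one-point flags + performance status 0-4
TOTAL_MAX = PHYSIO_MAX + SOCIAL_MAX

#: CSV column per physiological parameter
VITAL_COLUMNS = {
    "respiratory_rate": "respiratory_rate",
    "spo2": "spo2",
    "heart_rate": "heart_rate",
    "systolic_bp": "systolic_bp",
    "temperature": "temperature_c",
    "consciousness": "consciousness",
}

REQUIRED_COLUMNS = (
    "patient_id",
    "respiratory_rate",
    "spo2",
    "heart_rate",
    "systolic_bp",
    "temperature_c",
    "consciousness",
    "age_years",
    "socially_isolated",
    "chronic_disease",
    "performance_status",
)


class ParseError(ValueError):
    """Unrecognised categorical token in patient input."""


class Consciousness(enum.IntEnum):
    """Level of consciousness; the integer value is the sub-score."""

    ALERT = 0
    CONFUSED_AGITATED = 1
    VOICE = 2
    PAIN_UNRESPONSIVE = 3


_CONSCIOUSNESS_TOKENS = {
    "alert": Consciousness.ALERT,
    "confused": Consciousness.CONFUSED_AGITATED,
    "agitated": Consciousness.CONFUSED_AGITATED,
    "confused/agitated": Consciousness.CONFUSED_AGITATED,
    "confused_agitated": Consciousness.CONFUSED_AGITATED,
    "voice": Consciousness.VOICE,
    "pain": Consciousness.PAIN_UNRESPONSIVE,
    "unresponsive": Consciousness.PAIN_UNRESPONSIVE,
    "pain/unresponsive": Consciousness.PAIN_UNRESPONSIVE,
    "pain_unresponsive": Consciousness.PAIN_UNRESPONSIVE,
    "pain unconscious": Consciousness.PAIN_UNRESPONSIVE,
}

#: canonical token written to CSV for each level
CONSCIOUSNESS_CANONICAL = {
    Consciousness.ALERT: "alert",
    Consciousness.CONFUSED_AGITATED: "confused_agitated",
    Consciousness.VOICE: "voice",
    Consciousness.PAIN_UNRESPONSIVE: "pain_unresponsive",
}


def parse_consciousness(token) -> Consciousness:
    """Parse a consciousness token (case-insensitive) to a level.

    Accepted tokens: alert | confused | agitated | voice | pain |
    unresponsive (plus slashed/underscored combinations). Confused and
    agitated are synonymous, as are pain and unresponsive.
    """
    if isinstance(token, Consciousness):
        return token
    key = str(token).strip().lower()
    try:
        return _CONSCIOUSNESS_TOKENS[key]
    except KeyError:
        raise ParseError(
            f"unknown consciousness level {token!r}; accepted tokens: "
            + ", ".join(sorted(set(_CONSCIOUSNESS_TOKENS)))
        ) from None


@dataclass(frozen=True)
class VitalSigns:
    """One set of prehospital vital signs."""

    respiratory_rate: float  # breaths/min
    spo2: float  # %
    heart_rate: float  # beats/min
    systolic_bp: float  # mmHg
    temperature: float  # degC
    consciousness: Consciousness


@dataclass(frozen=True)
class SocialFactors:
    """Social / patient-data items of the instrument."""

    age: float  # years
    socially_isolated: bool
    chronic_disease: bool
    performance_status: int  # 0 (normal activity) .. 4 (bed-bound)

    def validate(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age: {self.age} is negative")
        if self.performance_status not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"performance_status: {self.performance_status} not in 0-4"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: vitals + social factors + optional gold-standard label.

    ``needs_ems`` is the emergency-medicine specialist's dichotomous
    judgment of whether the patient required EMS transport; ``None`` when
    the record is unlabeled.
    """

    patient_id: str
    vitals: VitalSigns
    social: SocialFactors
    needs_ems: Optional[bool] = None


@dataclass(frozen=True)
class PMEWSResult:
    """Per-parameter sub-scores plus the three aggregate scores."""

    subscores: Mapping[str, int]
    physiological_score: int
    social_score: int
    total: int


_DEFAULT_INSTRUMENT = None


def default_instrument() -> dict:
    """The packaged instrument definition (cached)."""
    global _DEFAULT_INSTRUMENT
    if _DEFAULT_INSTRUMENT is None:
        _DEFAULT_INSTRUMENT = load_instrument()
    return _DEFAULT_INSTRUMENT


def score_parameter(table: ScoreBandTable, value: float) -> int:
    """Sub-score of one numeric vital sign under its band table."""
    return table.score_value(value)


def score_consciousness(level) -> int:
    """Sub-score of a consciousness level (ALERT 0 ... PAIN_UNRESPONSIVE 3)."""
    return int(parse_consciousness(level))


def _physio_subscores(vitals: VitalSigns, tables) -> dict[str, int]:
    sub = {}
    for name in PHYSIO_PARAMETERS[:-1]:
        sub[name] = score_parameter(tables[name], getattr(vitals, name))
    sub["consciousness"] = score_consciousness(vitals.consciousness)
    return sub


def physiological_score(vitals: VitalSigns, tables=None) -> int:
    """MEWS-style physiological component, range 0-17."""
    if tables is None:
        tables = default_instrument()["tables"]
    return sum(_physio_subscores(vitals, tables).values())


def social_score(social: SocialFactors) -> int:
    """Social component: age>65 + isolation + chronic disease + performance
    status; range 0-7. Age exactly 65 scores 0 (strict inequality)."""
    social.validate()
    return (
        int(social.age > 65)
        + int(bool(social.socially_isolated))
        + int(bool(social.chronic_disease))
        + int(social.performance_status)
    )


def total_pmews(record: PatientRecord, tables=None) -> PMEWSResult:
    """Score one patient record; validation errors name the patient."""
    if tables is None:
        tables = default_instrument()["tables"]
    try:
        sub = _physio_subscores(record.vitals, tables)
        soc = social_score(record.social)
    except (ValidationError, ParseError) as exc:
        raise type(exc)(f"patient {record.patient_id}: {exc}") from None
    phys = sum(sub.values())
    return PMEWSResult(
        subscores=sub,
        physiological_score=phys,
        social_score=soc,
        total=phys + soc,
    )


def _validate_frame(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column: {col}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id: {dup!r}")
    age = pd.to_numeric(df["age_years"], errors="coerce")
    if (age < 0).any() or age.isna().any():
        bad = df.loc[(age < 0) | age.isna(), "patient_id"].tolist()[:5]
        raise ValidationError(f"age_years invalid for patients {bad}")
    ps = pd.to_numeric(df["performance_status"], errors="coerce")
    if (~ps.isin([0, 1, 2, 3, 4])).any():
        bad = df.loc[~ps.isin([0, 1, 2, 3, 4]), "patient_id"].tolist()[:5]
        raise ValidationError(f"performance_status outside 0-4 for patients {bad}")
    for flag in ("socially_isolated", "chronic_disease"):
        v = pd.to_numeric(df[flag], errors="coerce")
        if (~v.isin([0, 1])).any():
            bad = df.loc[~v.isin([0, 1]), "patient_id"].tolist()[:5]
            raise ValidationError(f"{flag} must be 0/1; invalid for patients {bad}")


def score_dataframe(
    df: pd.DataFrame,
    *,
    instrument=None,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """Score a patient cohort held as a DataFrame (patient-CSV schema).

    Adds one ``score_<parameter>`` column per physiological parameter plus
    ``physiological_score``, ``social_score`` and ``total_pmews``; input
    columns are preserved.

    Parameters
    ----------
    missing_policy : ``"strict"`` (default) raises on any missing
        physiological value; ``"missing_zero"`` scores missing parameters as
        normal (sub-score 0) and logs each affected patient.
    """
    if missing_policy not in ("strict", "missing_zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if instrument is None:
        instrument = default_instrument()
    tables = instrument["tables"]
    levels = instrument["consciousness_levels"]
    _validate_frame(df)
    out = df.copy()

    for name in PHYSIO_PARAMETERS[:-1]:
        col = VITAL_COLUMNS[name]
        values = pd.to_numeric(out[col], errors="coerce").to_numpy(dtype=float)
        missing = np.isnan(values)
        scores = np.zeros(len(out), dtype=int)
        if missing.any():
            if missing_policy == "strict":
                bad = out.loc[missing, "patient_id"].tolist()[:5]
                raise ValidationError(
                    f"{col}: missing value for patients {bad} under strict policy"
                )
            for pid in out.loc[missing, "patient_id"]:
                logger.warning(
                    "patient %s: missing %s scored as 0 (missing_zero policy)",
                    pid,
                    col,
                )
        present = ~missing
        if present.any():
            scores[present] = tables[name].score_values(values[present])
        out[f"score_{name}"] = scores

    tok = out["consciousness"].astype(str).str.strip().str.lower()
    mapped = tok.map({k: int(v) for k, v in _CONSCIOUSNESS_TOKENS.items()})
    missing_tok = out["consciousness"].isna()
    if missing_policy == "missing_zero" and missing_tok.any():
        for pid in out.loc[missing_tok, "patient_id"]:
            logger.warning(
                "patient %s: missing consciousness scored as alert "
                "(missing_zero policy)",
                pid,
            )
        mapped = mapped.mask(missing_tok, 0)
    if mapped.isna().any():
        unknown = out.loc[mapped.isna(), "consciousness"].unique()[:5]
        raise ParseError(
            f"unknown consciousness level(s) {list(unknown)}; accepted "
            f"tokens: {sorted(set(_CONSCIOUSNESS_TOKENS))}"
        )
    out["score_consciousness"] = mapped.astype(int)

    out["physiological_score"] = sum(
        out[f"score_{name}"] for name in PHYSIO_PARAMETERS
    )
    age = pd.to_numeric(out["age_years"], errors="coerce")
    out["social_score"] = (
        (age > 65).astype(int)
        + pd.to_numeric(out["socially_isolated"]).astype(int)
        + pd.to_numeric(out["chronic_disease"]).astype(int)
        + pd.to_numeric(out["performance_status"]).astype(int)
    )
    out["total_pmews"] = out["physiological_score"] + out["social_score"]
    return out
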