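"""Scoring engine: vignettes, aggregation invariants, policies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmews import (
    Consciousness,
    ParseError,
    PatientRecord,
    SocialFactors,
    ValidationError,
    VitalSigns,
    parse_consciousness,
    physiological_score,
    score_consciousness,
    score_dataframe,
    social_score,
    total_pmews,
)
from pmews.scoring import PHYSIO_MAX, SOCIAL_MAX, TOTAL_MAX

from conftest import random_cohort_frame


def _record(pid="p", rr=14, spo2=98, hr=80, sbp=120, temp=37.0,
            neuro=Consciousness.ALERT, age=30, iso=False, chronic=False, ps=0,
            label=None):
    return PatientRecord(
        pid,
        VitalSigns(rr, spo2, hr, sbp, temp, neuro),
        SocialFactors(age, iso, chronic, ps),
        needs_ems=label,
    )


@pytest.mark.parametrize(
    "token, expected",
    [
        ("alert", 0),
        ("ALERT", 0),
        ("confused", 1),
        ("Agitated", 1),
        ("confused/agitated", 1),
        ("voice", 2),
        ("pain", 3),
        ("Unresponsive", 3),
        (Consciousness.VOICE, 2),
    ],
)
def test_consciousness_tokens(token, expected):
    assert score_consciousness(token) == expected


def test_unknown_consciousness_token_lists_accepted():
    with pytest.raises(ParseError, match="alert"):
        parse_consciousness("sleepy")


def test_all_normal_vitals_score_zero():
    assert physiological_score(
        VitalSigns(14, 98, 80, 120, 37.0, Consciousness.ALERT)
    ) == 0


def test_worst_case_vitals_score_seventeen():
    assert physiological_score(
        VitalSigns(35, 85, 140, 65, 39.5, Consciousness.PAIN_UNRESPONSIVE)
    ) == PHYSIO_MAX


def test_mixed_vignette_scores_seven():
    # rr 20 -> 1, spo2 92 -> 2, hr 105 -> 1, sbp 95 -> 1, temp 38.2 -> 1,
    # confused -> 1
    assert physiological_score(
        VitalSigns(20, 92, 105, 95, 38.2, Consciousness.CONFUSED_AGITATED)
    ) == 7


@pytest.mark.parametrize(
    "age, iso, chronic, ps, expected",
    [
        (30, False, False, 0, 0),
        (70, True, True, 4, 7),
        (65, False, True, 2, 3),  # age exactly 65 scores 0 (strict >)
        (65.1, False, False, 0, 1),
        (66, False, False, 0, 1),
    ],
)
def test_social_score(age, iso, chronic, ps, expected):
    assert social_score(SocialFactors(age, iso, chronic, ps)) == expected


def test_social_score_invalid_performance_status():
    with pytest.raises(ValidationError, match="performance_status"):
        social_score(SocialFactors(40, False, False, 5))


def test_total_pmews_vignettes():
    assert total_pmews(_record()).total == 0
    worst = _record(rr=35, spo2=85, hr=140, sbp=65, temp=39.5,
                    neuro=Consciousness.PAIN_UNRESPONSIVE,
                    age=70, iso=True, chronic=True, ps=4)
    assert total_pmews(worst).total == TOTAL_MAX
    mixed = _record(rr=20, spo2=92, hr=105, sbp=95, temp=38.2,
                    neuro=Consciousness.CONFUSED_AGITATED,
                    age=65, chronic=True, ps=2)
    res = total_pmews(mixed)
    assert (res.physiological_score, res.social_score, res.total) == (7, 3, 10)


def test_validation_error_names_patient():
    bad = _record(pid="patient-42", spo2=150)
    with pytest.raises(ValidationError, match="patient-42"):
        total_pmews(bad)


valid_records = st.builds(
    _record,
    rr=st.integers(0, 70),
    spo2=st.integers(0, 100),
    hr=st.integers(0, 250),
    sbp=st.integers(0, 300),
    temp=st.floats(25.0, 45.0),
    neuro=st.sampled_from(list(Consciousness)),
    age=st.floats(0, 110),
    iso=st.booleans(),
    chronic=st.booleans(),
    ps=st.integers(0, 4),
)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(valid_records)
def test_additivity_bounds_and_determinism(record):
    res = total_pmews(record)
    assert res.total == res.physiological_score + res.social_score
    assert res.physiological_score == sum(res.subscores.values())
    assert 0 <= res.physiological_score <= PHYSIO_MAX
    assert 0 <= res.social_score <= SOCIAL_MAX
    assert 0 <= res.total <= TOTAL_MAX
    assert total_pmews(record) == res


def test_dataframe_path_matches_record_path():
    rng = np.random.default_rng(7)
    df = random_cohort_frame(rng, 300)
    scored = score_dataframe(df)
    from pmews.io import records_from_frame

    for i, rec in enumerate(records_from_frame(df)):
        res = total_pmews(rec)
        assert scored.loc[i, "physiological_score"] == res.physiological_score
        assert scored.loc[i, "social_score"] == res.social_score
        assert scored.loc[i, "total_pmews"] == res.total


def test_scored_frame_keeps_inputs_and_adds_subscores():
    rng = np.random.default_rng(3)
    df = random_cohort_frame(rng, 50)
    scored = score_dataframe(df)
    assert set(df.columns) <= set(scored.columns)
    for name in ("respiratory_rate", "spo2", "heart_rate", "systolic_bp",
                 "temperature", "consciousness"):
        assert f"score_{name}" in scored.columns


def test_missing_column_is_named():
    df = random_cohort_frame(np.random.default_rng(0), 5).drop(columns=["spo2"])
    with pytest.raises(ValidationError, match="spo2"):
        score_dataframe(df)


def test_missing_value_strict_names_patient():
    df = random_cohort_frame(np.random.default_rng(0), 5)
    df.loc[2, "heart_rate"] = np.nan
    with pytest.raises(ValidationError, match="p2"):
        score_dataframe(df)


def test_missing_value_policy_scores_zero_and_logs(caplog):
    df = random_cohort_frame(np.random.default_rng(0), 5)
    df.loc[2, "heart_rate"] = np.nan
    with caplog.at_level("WARNING", logger="pmews"):
        scored = score_dataframe(df, missing_policy="missing_zero")
    assert scored.loc[2, "score_heart_rate"] == 0
    assert any("p2" in rec.message for rec in caplog.records)


def test_duplicate_patient_id_rejected():
    df = random_cohort_frame(np.random.default_rng(0), 4)
    df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
    with pytest.raises(ValidationError, match="duplicate"):
        score_dataframe(df)
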