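"""Data model contracts and CSV round-trip identity."""

import pandas as pd
import pytest

from arcpk.exceptions import SchemaError, ValidationError
from arcpk.study_data import (
    ConcentrationRecord,
    DoseEvent,
    PlasmaProfile,
    StudyDataset,
    UrineInterval,
    read_study_tables,
    write_study_tables,
)
from arcpk.synthetic import inject_anomalies


def test_dose_event_validation():
    with pytest.raises(ValidationError):
        DoseEvent(analyte="iohexol", dose_per_bw=-1.0, occasion="M1")
    with pytest.raises(ValidationError):
        DoseEvent(analyte="unknown_marker", dose_per_bw=1.0, occasion="M1")


def test_blq_record_carries_no_concentration():
    rec = ConcentrationRecord(10.0, None, 0.25, blq=True)
    assert rec.concentration is None
    with pytest.raises(ValidationError):
        ConcentrationRecord(10.0, 0.1, 0.25, blq=True)
    with pytest.raises(ValidationError):
        ConcentrationRecord(1.0, None, 0.25, blq=False)


def test_profile_requires_increasing_times():
    dose = DoseEvent(analyte="iohexol", dose_per_bw=64.7, occasion="M1")
    recs = (ConcentrationRecord(1.0, 5.0, 0.25), ConcentrationRecord(1.0, 4.0, 0.25))
    with pytest.raises(ValidationError):
        PlasmaProfile(animal_id="A", group="control", occasion="M1", dose=dose,
                      body_weight=14.0, records=recs)


def test_urine_interval_validation():
    with pytest.raises(ValidationError):
        UrineInterval(start_h=2.0, end_h=1.0, volume_ml=10, conc_ug_per_ml=1)
    with pytest.raises(ValidationError):
        UrineInterval(start_h=0.0, end_h=1.0, volume_ml=-5, conc_ug_per_ml=1)


def test_roundtrip_identity_on_generated_dataset(default_dataset, tmp_path):
    """read(write(d)) reproduces every value of a full synthetic cohort."""
    write_study_tables(default_dataset, tmp_path)
    back = read_study_tables(tmp_path)
    assert sorted(back.animals) == sorted(default_dataset.animals)
    assert len(back.profiles) == len(default_dataset.profiles)
    for p in default_dataset.profiles:
        q = back.profile(p.animal_id, p.analyte, p.occasion)
        assert q.records == p.records
        assert q.body_weight == p.body_weight
        assert q.dose == p.dose
    assert back.urine == default_dataset.urine
    for aid, rec in default_dataset.animals.items():
        brec = back.animals[aid]
        assert brec.body_weight == rec.body_weight
        assert brec.hematology == rec.hematology
        assert brec.hematocrit == rec.hematocrit


def test_roundtrip_preserves_leak_flag(default_dataset, tmp_path):
    ds = inject_anomalies(default_dataset, {
        "urine_leak": [{"animal_id": "C02", "occasion": "M1", "interval": 1}]})
    write_study_tables(ds, tmp_path)
    df = pd.read_csv(tmp_path / "urine.csv")
    leaked = df[(df.animal_id == "C02") & (df.occasion == "M1")]["leaked"]
    assert leaked.tolist() == [0, 1, 0, 0, 0]
    back = read_study_tables(tmp_path)
    assert back.urine[("C02", "M1")][1].leaked


def test_empty_dataset_gives_header_only_files(tmp_path):
    write_study_tables(StudyDataset(), tmp_path)
    for name in ("plasma", "urine", "animals", "hematocrit"):
        df = pd.read_csv(tmp_path / f"{name}.csv")
        assert df.empty and len(df.columns) > 0
    back = read_study_tables(tmp_path)
    assert not back.animals and not back.profiles and not back.urine


def test_missing_column_is_schema_error(default_dataset, tmp_path):
    write_study_tables(default_dataset, tmp_path)
    df = pd.read_csv(tmp_path / "plasma.csv").drop(columns=["time_h"])
    df.to_csv(tmp_path / "plasma.csv", index=False)
    with pytest.raises(SchemaError, match="time_h"):
        read_study_tables(tmp_path)


def test_negative_time_reported_with_row_index(default_dataset, tmp_path):
    write_study_tables(default_dataset, tmp_path)
    df = pd.read_csv(tmp_path / "plasma.csv")
    df.loc[3, "time_h"] = -1.0
    df.to_csv(tmp_path / "plasma.csv", index=False)
    with pytest.raises(ValidationError, match="row 3"):
        read_study_tables(tmp_path)


def test_blq_cell_parses_to_censored_record(default_dataset, tmp_path):
    write_study_tables(default_dataset, tmp_path)
    back = read_study_tables(tmp_path)
    # default PAH profiles are right-censored at the LLOQ well before 10 h
    prof = back.profile("C01", "pah", "M1")
    blq = [r for r in prof.records if r.blq and r.time_h > 0]
    assert blq, "expected censored PAH tail records"
    assert all(r.concentration is None for r in blq)
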