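"""Cohort schema validation and lossless CSV/JSON round-trips."""

import csv

import pytest
from hypothesis import given, settings, strategies as st

from petct_screen.cohort import (
    Call,
    Cohort,
    CohortFormatError,
    Confirmation,
    CSV_COLUMNS,
    FollowUpOutcome,
    LesionFinding,
    LesionLocation,
    Modality,
    ModalityReading,
    PatientRecord,
    RiskFactor,
    read_cohort,
    write_cohort,
)
from petct_screen.simulate import SimulationParams, simulate_cohort


def _lesions(modality):
    return st.lists(
        st.builds(
            LesionFinding,
            modality=st.just(modality),
            location=st.sampled_from(LesionLocation),
            size_mm=(
                st.one_of(st.none(), st.floats(0.5, 40).map(lambda x: round(x, 1)))
                if modality is Modality.CT
                else st.none()
            ),
            multiple=st.booleans(),
            likert=st.integers(0, 5),
        ),
        max_size=3,
    )


def _reading(modality):
    return st.builds(
        ModalityReading, call=st.sampled_from(Call), lesions=_lesions(modality)
    )


_patients = st.builds(
    PatientRecord,
    patient_id=st.uuids().map(str),
    risk_factors=st.lists(
        st.sampled_from(RiskFactor), min_size=1, max_size=3, unique=True
    ),
    primary_site=st.sampled_from(["oropharynx", "larynx", "oral cavity;oropharynx"]),
    ct=_reading(Modality.CT),
    pet=_reading(Modality.PET),
    outcome=st.builds(
        FollowUpOutcome,
        dm_at_screening=st.booleans(),
        spt_at_screening=st.booleans(),
        dm_within_12mo=st.booleans(),
        spt_within_12mo=st.booleans(),
        locoregional_control=st.booleans(),
        confirmation=st.sampled_from(Confirmation),
    ),
)

_cohorts = st.lists(_patients, max_size=6, unique_by=lambda p: p.patient_id).map(
    lambda ps: Cohort(patients=ps)
)


@settings(max_examples=40, deadline=None)
@given(cohort=_cohorts, fmt=st.sampled_from(["csv", "json"]))
def test_round_trip_identity(cohort, fmt, tmp_path_factory):
    path = tmp_path_factory.mktemp("io") / f"cohort.{fmt}"
    write_cohort(cohort, path, fmt)
    assert read_cohort(path, fmt) == cohort


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_paper_fixture_round_trips(paper_cohort, tmp_path, fmt):
    path = tmp_path / f"fixture.{fmt}"
    write_cohort(paper_cohort, path, fmt)
    again = read_cohort(path, fmt)
    assert again == paper_cohort
    assert len(again) == 47


def test_empty_cohort_is_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_cohort(Cohort(), path, "csv")
    assert path.read_text().strip() == ",".join(CSV_COLUMNS)
    assert len(read_cohort(path, "csv")) == 0


def test_simulated_cohort_row_count(tmp_path):
    cohort = simulate_cohort(SimulationParams(n_patients=200, seed=3))
    path = tmp_path / "sim.csv"
    write_cohort(cohort, path, "csv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 200


def _write_modified(paper_cohort, tmp_path, **changes):
    path = tmp_path / "bad.csv"
    write_cohort(paper_cohort, path, "csv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    rows[0].update(changes)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return path


@pytest.mark.parametrize(
    "changes, message",
    [
        ({"ct_lesions": "lung:12:0:7", "ct_likert_max": "7"}, "likert"),
        ({"ct_lesions": "lung:-3:0:4", "ct_likert_max": "4"}, "lesion"),
        ({"dm_at_screening": "yes"}, "boolean"),
        ({"ct_likert_max": "1"}, "likert_max"),
        ({"ct_call": "maybe"}, "row 2"),
    ],
)
def test_schema_violations_are_named(paper_cohort, tmp_path, changes, message):
    path = _write_modified(paper_cohort, tmp_path, **changes)
    with pytest.raises(CohortFormatError, match=message):
        read_cohort(path, "csv")


def test_duplicate_patient_ids_rejected(paper_cohort, tmp_path):
    path = _write_modified(paper_cohort, tmp_path, patient_id="P02")
    with pytest.raises(CohortFormatError, match="unique"):
        read_cohort(path, "csv")


def test_pet_lesion_cannot_carry_size():
    with pytest.raises(ValueError, match="CT"):
        LesionFinding(
            modality=Modality.PET,
            location=LesionLocation.LUNG,
            size_mm=6.0,
            likert=3,
        )


def test_likert_max_is_highest_lesion_score():
    reading = ModalityReading(
        call=Call.NEGATIVE,
        lesions=[
            LesionFinding(modality=Modality.CT, location=LesionLocation.LUNG,
                          size_mm=4.0, likert=2),
            LesionFinding(modality=Modality.CT, location=LesionLocation.LUNG,
                          size_mm=8.0, likert=4),
        ],
    )
    assert reading.likert_max == 4
    assert ModalityReading(call=Call.NEGATIVE).likert_max == 0
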