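"""Domain types and tabular I/O for a distant-metastasis screening cohort.

A cohort is a collection of head-and-neck cancer patients who were screened
for distant metastases with contrast-enhanced chest CT and whole-body
FDG-PET. Each patient carries the two modality readings (the clinical
binary call *for distant metastases*, plus the individual lesions with
their ordinal suspicion scores), the screening/follow-up outcome flags that
define the reference standard, and the high-risk factors that made the
patient eligible for screening.

The on-disk formats are a flat CSV (one row per patient, lesion lists
packed into a delimited sub-field) and a JSON mirror with nested lesion
objects. Both round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Modality",
    "Call",
    "LesionLocation",
    "Confirmation",
    "RiskFactor",
    "LesionFinding",
    "ModalityReading",
    "FollowUpOutcome",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "CSV_COLUMNS",
]


class Modality(str, Enum):
    CT = "CT"
    PET = "PET"


class Call(str, Enum):
    """Binary clinical call for distant metastases (also reused for truth)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class LesionLocation(str, Enum):
    LUNG = "lung"
    EXTRA_PULMONARY = "extra_pulmonary"


class Confirmation(str, Enum):
    """How the reference-standard outcome was established."""

    HISTOPATHOLOGY = "histopathology"
    PROGRESSION = "progression"
    NONE = "none"


class RiskFactor(str, Enum):
    """High-risk factors for distant metastases in head and neck cancer."""

    GE3_NODES = "ge3_nodes"
    BILATERAL_NODES = "bilateral_nodes"
    NODE_GE6CM = "node_ge6cm"
    LOW_JUGULAR_NODES = "low_jugular_nodes"
    RECURRENCE = "recurrence"
    SECOND_PRIMARY = "second_primary"


class LesionFinding(BaseModel):
    """One lesion reported by one modality.

    ``likert`` is the five-point ordinal suspicion score for distant
    metastasis (1 definitely benign ... 5 definitely malignant); 0 is the
    below-scale sentinel used when a visible lesion is not suspicious for
    distant metastasis at all (e.g. a second primary tumor). ``size_mm`` is
    recorded for CT findings only — PET reports no calibrated diameter —
    and is never 0: an unknown size is absent, not zero, so it can never
    silently satisfy the sub-5-mm rule branch.
    """

    modality: Modality
    location: LesionLocation
    size_mm: Optional[float] = Field(default=None, gt=0)
    multiple: bool = False
    likert: int = Field(ge=0, le=5)

    @model_validator(mode="after")
    def _size_only_on_ct(self) -> "LesionFinding":
        if self.modality is Modality.PET and self.size_mm is not None:
            raise ValueError("size_mm may only be recorded for CT findings")
        return self


class ModalityReading(BaseModel):
    """One modality's report: the binary call plus the scored lesion list."""

    call: Call
    lesions: list[LesionFinding] = Field(default_factory=list)

    @property
    def likert_max(self) -> int:
        """Highest lesion score; 0 for an empty lesion list.

        When several lesions are scored in one patient, the most suspicious
        one carries the patient's ordinal score.
        """
        return max((les.likert for les in self.lesions), default=0)


class FollowUpOutcome(BaseModel):
    """Reference-standard flags: screening work-up plus 12-month follow-up.

    Flags are not mutually exclusive — a patient may harbour both a second
    primary tumor and distant metastases.
    """

    dm_at_screening: bool = False
    spt_at_screening: bool = False
    dm_within_12mo: bool = False
    spt_within_12mo: bool = False
    locoregional_control: bool = True
    confirmation: Confirmation = Confirmation.NONE


class PatientRecord(BaseModel):
    patient_id: str
    risk_factors: list[RiskFactor] = Field(min_length=1)
    primary_site: str
    ct: ModalityReading
    pet: ModalityReading
    outcome: FollowUpOutcome

    @field_validator("risk_factors")
    @classmethod
    def _factors_unique(cls, v: list[RiskFactor]) -> list[RiskFactor]:
        if len(set(v)) != len(v):
            raise ValueError("duplicate risk factors")
        return v

    @model_validator(mode="after")
    def _lesion_modalities(self) -> "PatientRecord":
        if any(les.modality is not Modality.CT for les in self.ct.lesions):
            raise ValueError("CT reading contains non-CT lesions")
        if any(les.modality is not Modality.PET for les in self.pet.lesions):
            raise ValueError("PET reading contains non-PET lesions")
        return self


class Cohort(BaseModel):
    patients: list[PatientRecord] = Field(default_factory=list)

    @field_validator("patients")
    @classmethod
    def _ids_unique(cls, v: list[PatientRecord]) -> list[PatientRecord]:
        ids = [p.patient_id for p in v]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_id values must be unique within a cohort")
        return v

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:  # type: ignore[override]
        return iter(self.patients)


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort file violates the documented schema."""


CSV_COLUMNS = [
    "patient_id",
    "risk_factors",
    "primary_site",
    "ct_call",
    "ct_likert_max",
    "ct_lesions",
    "pet_call",
    "pet_likert_max",
    "pet_lesions",
    "dm_at_screening",
    "spt_at_screening",
    "dm_within_12mo",
    "spt_within_12mo",
    "locoregional_control",
    "confirmation",
]


def _fmt_size(size: Optional[float]) -> str:
    if size is None:
        return ""
    return f"{size:g}"


def _pack_lesions(lesions: Sequence[LesionFinding]) -> str:
    return ";".join(
        f"{les.location.value}:{_fmt_size(les.size_mm)}:{int(les.multiple)}:{les.likert}"
        for les in lesions
    )


def _unpack_lesions(field: str, modality: Modality, where: str) -> list[LesionFinding]:
    lesions: list[LesionFinding] = []
    if not field:
        return lesions
    for spec in field.split(";"):
        parts = spec.split(":")
        if len(parts) != 4:
            raise CohortFormatError(
                f"{where}: lesion spec {spec!r} must have 4 ':'-separated fields"
            )
        loc, size_s, multiple_s, likert_s = parts
        try:
            lesions.append(
                LesionFinding(
                    modality=modality,
                    location=LesionLocation(loc),
                    size_mm=float(size_s) if size_s else None,
                    multiple=_parse_bool(multiple_s, where),
                    likert=int(likert_s),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise CohortFormatError(f"{where}: invalid lesion {spec!r}: {exc}") from exc
    return lesions


def _parse_bool(s: str, where: str) -> bool:
    if s == "0":
        return False
    if s == "1":
        return True
    raise CohortFormatError(f"{where}: boolean field must be 0 or 1, got {s!r}")


def _patient_to_row(p: PatientRecord) -> dict[str, str]:
    o = p.outcome
    return {
        "patient_id": p.patient_id,
        "risk_factors": ";".join(f.value for f in p.risk_factors),
        "primary_site": p.primary_site,
        "ct_call": p.ct.call.value,
        "ct_likert_max": str(p.ct.likert_max),
        "ct_lesions": _pack_lesions(p.ct.lesions),
        "pet_call": p.pet.call.value,
        "pet_likert_max": str(p.pet.likert_max),
        "pet_lesions": _pack_lesions(p.pet.lesions),
        "dm_at_screening": str(int(o.dm_at_screening)),
        "spt_at_screening": str(int(o.spt_at_screening)),
        "dm_within_12mo": str(int(o.dm_within_12mo)),
        "spt_within_12mo": str(int(o.spt_within_12mo)),
        "locoregional_control": str(int(o.locoregional_control)),
        "confirmation": o.confirmation.value,
    }


def _row_to_patient(row: dict[str, str], rownum: int) -> PatientRecord:
    def get(col: str) -> str:
        val = row.get(col)
        if val is None:
            raise CohortFormatError(f"row {rownum}: missing column {col!r}")
        return val

    where = f"row {rownum}"
    try:
        ct = ModalityReading(
            call=Call(get("ct_call")),
            lesions=_unpack_lesions(get("ct_lesions"), Modality.CT, f"{where}, ct_lesions"),
        )
        pet = ModalityReading(
            call=Call(get("pet_call")),
            lesions=_unpack_lesions(get("pet_lesions"), Modality.PET, f"{where}, pet_lesions"),
        )
        outcome = FollowUpOutcome(
            dm_at_screening=_parse_bool(get("dm_at_screening"), where),
            spt_at_screening=_parse_bool(get("spt_at_screening"), where),
            dm_within_12mo=_parse_bool(get("dm_within_12mo"), where),
            spt_within_12mo=_parse_bool(get("spt_within_12mo"), where),
            locoregional_control=_parse_bool(get("locoregional_control"), where),
            confirmation=Confirmation(get("confirmation")),
        )
        patient = PatientRecord(
            patient_id=get("patient_id"),
            risk_factors=[RiskFactor(f) for f in get("risk_factors").split(";") if f],
            primary_site=get("primary_site"),
            ct=ct,
            pet=pet,
            outcome=outcome,
        )
    except CohortFormatError:
        raise
    except (ValueError, ValidationError) as exc:
        raise CohortFormatError(f"{where}: {exc}") from exc

    for col, reading in (("ct_likert_max", ct), ("pet_likert_max", pet)):
        try:
            stated = int(get(col))
        except ValueError as exc:
            raise CohortFormatError(f"{where}, column {col!r}: not an integer") from exc
        if stated != reading.likert_max:
            raise CohortFormatError(
                f"{where}, column {col!r}: stated {stated} but lesions imply "
                f"{reading.likert_max}"
            )
    return patient


def write_cohort(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort to ``path`` as CSV or JSON (see module docstring)."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for p in cohort:
                writer.writerow(_patient_to_row(p))
    elif format == "json":
        payload = {
            "patients": [
                {
                    **p.model_dump(mode="json"),
                    "ct": {**p.ct.model_dump(mode="json"), "likert_max": p.ct.likert_max},
                    "pet": {**p.pet.model_dump(mode="json"), "likert_max": p.pet.likert_max},
                }
                for p in cohort
            ]
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort(path: str | Path, format: str = "csv") -> Cohort:
    """Read a cohort file, validating every field and recomputing likert_max."""
    path = Path(path)
    if format == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CohortFormatError(f"{path}: empty file (no header)")
            missing = set(CSV_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise CohortFormatError(f"{path}: missing columns {sorted(missing)}")
            patients = [_row_to_patient(row, i) for i, row in enumerate(reader, start=2)]
    elif format == "json":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise CohortFormatError(f"{path}: invalid JSON: {exc}") from exc
        patients = []
        for i, obj in enumerate(payload.get("patients", [])):
            try:
                stated = {
                    "ct": obj.get("ct", {}).pop("likert_max", None),
                    "pet": obj.get("pet", {}).pop("likert_max", None),
                }
                patient = PatientRecord.model_validate(obj)
            except ValidationError as exc:
                raise CohortFormatError(f"patient #{i}: {exc}") from exc
            for key, reading in (("ct", patient.ct), ("pet", patient.pet)):
                if stated[key] is not None and stated[key] != reading.likert_max:
                    raise CohortFormatError(
                        f"patient #{i}: {key} likert_max {stated[key]} inconsistent "
                        f"with lesions ({reading.likert_max})"
                    )
            patients.append(patient)
    else:
        raise ValueError(f"unknown format {format!r}")
    try:
        return Cohort(patients=patients)
    except ValidationError as exc:
        raise CohortFormatError(str(exc)) from exc
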