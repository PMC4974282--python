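"""Reference-standard adjudication and analysis-set construction.

The reference standard is the clinical diagnostic work-up plus 12 months
of follow-up: a patient is truth-positive for distant metastases if
metastases were established at screening or manifested within the
follow-up window. Screening calls are then classed TP/FP/FN/TN against
that truth.

Two nested analysis sets are derived from a cohort:

* the *evaluable* set drops patients who developed a second primary tumor
  during follow-up together with distant metastases — imaging cannot
  attribute those metastases to the index tumor versus the new primary,
  so their truth is indeterminate;
* the *locoregional-control* subset further keeps only patients without
  locoregional recurrence, removing metastases that may have been
  reseeded after screening rather than missed by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .cohort import Call, Cohort, FollowUpOutcome, PatientRecord

__all__ = [
    "ReferenceClass",
    "SetLabel",
    "AnalysisSet",
    "dm_truth",
    "adjudicate",
    "all_patients_set",
    "evaluable_set",
    "locoregional_set",
]


class ReferenceClass(str, Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


class SetLabel(str, Enum):
    ALL = "all"
    EVALUABLE = "evaluable"
    LOCOREGIONAL_CONTROL = "locoregional_control"


@dataclass(frozen=True)
class AnalysisSet:
    label: SetLabel
    patients: tuple[PatientRecord, ...]
    excluded: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.patients)


def dm_truth(outcome: FollowUpOutcome) -> Call:
    """Reference-standard truth for distant metastases.

    Positive iff metastases were established at screening or manifested
    during the 12-month follow-up window.
    """
    if outcome.dm_at_screening or outcome.dm_within_12mo:
        return Call.POSITIVE
    return Call.NEGATIVE


def adjudicate(call: Call, truth: Call) -> ReferenceClass:
    """Class one screening call against the reference standard."""
    call, truth = Call(call), Call(truth)
    if call is Call.POSITIVE:
        return ReferenceClass.TP if truth is Call.POSITIVE else ReferenceClass.FP
    return ReferenceClass.FN if truth is Call.POSITIVE else ReferenceClass.TN


def all_patients_set(cohort: Cohort) -> AnalysisSet:
    return AnalysisSet(SetLabel.ALL, tuple(cohort.patients))


def evaluable_set(cohort: Cohort) -> AnalysisSet:
    """Drop patients whose metastasis origin is indeterminate.

    A patient is excluded iff a second primary tumor arose during
    follow-up *and* the patient is truth-positive for distant metastases:
    the metastases may stem from the new primary rather than the index
    tumor, so neither TP nor FN status can be assigned.
    """
    kept: list[PatientRecord] = []
    excluded: list[tuple[str, str]] = []
    for p in cohort:
        if p.outcome.spt_within_12mo and dm_truth(p.outcome) is Call.POSITIVE:
            excluded.append(
                (
                    p.patient_id,
                    "second primary tumor during follow-up with distant metastases "
                    "of indeterminate origin",
                )
            )
        else:
            kept.append(p)
    return AnalysisSet(SetLabel.EVALUABLE, tuple(kept), tuple(excluded))


def locoregional_set(evaluable: AnalysisSet) -> AnalysisSet:
    """Restrict an evaluable set to patients with locoregional control."""
    if evaluable.label is not SetLabel.EVALUABLE:
        raise ValueError("locoregional_set expects the evaluable analysis set")
    kept = tuple(p for p in evaluable.patients if p.outcome.locoregional_control)
    excluded = evaluable.excluded + tuple(
        (p.patient_id, "no locoregional control during follow-up")
        for p in evaluable.patients
        if not p.outcome.locoregional_control
    )
    return AnalysisSet(SetLabel.LOCOREGIONAL_CONTROL, kept, excluded)
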