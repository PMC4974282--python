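"""Combined PET + CT interpretation rule for distant-metastasis screening.

Whole-body FDG-PET cannot reliably detect lung nodules below its spatial
resolution limit (taken as 5 mm diameter), while chest CT resolves small
nodules but is frequently indeterminate about their nature. The combined
reading therefore resolves the two clinical reports into a single call:

* PET positive → combined positive, unconditionally. A metabolically
  active lesion is treated as malignant regardless of how CT interpreted
  any corresponding solid lesion.
* PET negative, CT positive → decided by lesion size. A suspicious CT
  lesion strictly below 5 mm is invisible to PET, so PET's negativity
  carries no information and CT's call stands (combined positive). At
  5 mm and above a negative PET argues against malignancy and the CT
  finding is discounted (combined negative).
* Both negative → combined negative.

When CT reports several suspicious lesions, the *smallest* drives the size
branch: any sub-threshold lesion is by construction beyond PET's reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .cohort import Call, ModalityReading

__all__ = ["PET_DETECTION_LIMIT_MM", "Rule", "CombinedCall", "classify_pair", "classify_patient"]

#: PET spatial-resolution cut-off; lesions strictly below it take the CT branch.
PET_DETECTION_LIMIT_MM = 5.0


class Rule(str, Enum):
    """Which branch of the decision rule produced the combined call."""

    BOTH_POSITIVE = "both_positive"
    PET_ONLY_POSITIVE = "pet_only_positive"
    CT_SMALL_LESION = "ct_small_lesion"
    CT_LARGE_LESION_DISCOUNTED = "ct_large_lesion_discounted"
    BOTH_NEGATIVE = "both_negative"


@dataclass(frozen=True)
class CombinedCall:
    call: Call
    rule_fired: Rule


def classify_pair(
    pet_call: Call,
    ct_call: Call,
    smallest_suspicious_ct_size_mm: Optional[float] = None,
    *,
    detection_limit_mm: float = PET_DETECTION_LIMIT_MM,
) -> CombinedCall:
    """Classify one patient from the two binary calls and the CT lesion size.

    ``smallest_suspicious_ct_size_mm`` is required whenever ``ct_call`` is
    positive (the size branch cannot be evaluated without it) and ignored
    otherwise. Exactly one rule fires for every admissible input.
    """
    pet_call = Call(pet_call)
    ct_call = Call(ct_call)
    if pet_call is Call.POSITIVE:
        if ct_call is Call.POSITIVE:
            return CombinedCall(Call.POSITIVE, Rule.BOTH_POSITIVE)
        return CombinedCall(Call.POSITIVE, Rule.PET_ONLY_POSITIVE)
    if ct_call is Call.POSITIVE:
        if smallest_suspicious_ct_size_mm is None:
            raise ValueError(
                "CT call is positive but no suspicious-lesion size was supplied; "
                "the size branch cannot be evaluated"
            )
        if smallest_suspicious_ct_size_mm <= 0:
            raise ValueError("lesion size must be positive")
        if smallest_suspicious_ct_size_mm < detection_limit_mm:
            return CombinedCall(Call.POSITIVE, Rule.CT_SMALL_LESION)
        return CombinedCall(Call.NEGATIVE, Rule.CT_LARGE_LESION_DISCOUNTED)
    return CombinedCall(Call.NEGATIVE, Rule.BOTH_NEGATIVE)


def classify_patient(ct: ModalityReading, pet: ModalityReading) -> CombinedCall:
    """Apply the combined rule to one patient's two readings.

    The binary clinical calls drive the rule; Likert scores are not
    consulted (they feed the ROC analysis only, and the combined reading
    was defined over the binary reports). When CT is positive, every CT
    lesion with a recorded size counts as suspicious and the minimum size
    enters the rule.
    """
    size: Optional[float] = None
    if ct.call is Call.POSITIVE:
        sizes = [les.size_mm for les in ct.lesions if les.size_mm is not None]
        if not sizes:
            raise ValueError(
                "CT reading is positive but carries no lesion with a recorded size"
            )
        size = min(sizes)
    return classify_pair(pet.call, ct.call, size)
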