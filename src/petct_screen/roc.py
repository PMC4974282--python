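"""ROC analysis over five-point ordinal reader scores.

Each patient carries an ordinal suspicion score 0-5 (0 = no lesion
suspicious for distant metastasis; 1 definitely benign ... 5 definitely
malignant) and a binary reference-standard truth. The empirical ROC curve
places one operating point at each threshold t = 0..6 under the rule
"call positive iff score >= t"; its trapezoidal area equals the
Mann-Whitney two-sample statistic with ties counted one half.

Inference on the AUC uses the placement-value (DeLong) estimator: the
variance of the empirical AUC, and for two score sets obtained from the
*same* patients (a paired reader design, e.g. CT vs PET) the covariance
between the two AUCs, yielding normal tests of each AUC against the
chance value 0.5 and of the paired difference.

The Q-point is the operating point jointly optimising sensitivity and
specificity, implemented as the Youden-J maximiser with ties broken
toward higher sensitivity (the screening context values sensitivity over
specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .adjudicate import AnalysisSet, dm_truth
from .cohort import Call, Modality

__all__ = [
    "OperatingPoint",
    "RocResult",
    "AucComparison",
    "patient_scores",
    "empirical_roc",
    "auc_inference",
    "q_point",
]

THRESHOLDS = tuple(range(0, 7))  # "positive iff score >= t"; 0 -> all, 6 -> none


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    operating_points: tuple[OperatingPoint, ...]
    auc: float
    auc_se: Optional[float] = None
    p_vs_half: Optional[float] = None

    @property
    def q_point(self) -> OperatingPoint:
        return q_point(self)


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    p_a_vs_half: float
    p_b_vs_half: float
    p_a_vs_b: float
    covariance: float


def patient_scores(
    analysis_set: AnalysisSet, modality: Modality
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient (score, truth) arrays for one modality.

    The patient's score is the highest Likert score over the modality's
    lesions (0 when none); truth comes from the reference standard.
    """
    modality = Modality(modality)
    scores = np.array(
        [
            (p.ct if modality is Modality.CT else p.pet).likert_max
            for p in analysis_set.patients
        ],
        dtype=float,
    )
    truths = np.array(
        [dm_truth(p.outcome) is Call.POSITIVE for p in analysis_set.patients],
        dtype=bool,
    )
    return scores, truths


def _check_scores(scores: np.ndarray, truths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if scores.shape != truths.shape or scores.ndim != 1:
        raise ValueError("scores and truths must be aligned 1-d arrays")
    if truths.all() or (~truths).all():
        raise ValueError(
            "degenerate truth: ROC needs at least one positive and one negative patient"
        )
    return scores, truths


def _placements(scores: np.ndarray, truths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values: v10 over positives, v01 over negatives.

    v10_i is the fraction of negatives scored below positive i (ties at
    half), and symmetrically for v01; computed against sorted opposite-
    class scores so large cohorts stay cheap.
    """
    pos = scores[truths]
    neg = scores[~truths]

    def place(x: np.ndarray, against_sorted: np.ndarray) -> np.ndarray:
        below = np.searchsorted(against_sorted, x, side="left")
        below_or_equal = np.searchsorted(against_sorted, x, side="right")
        return (below + below_or_equal) / (2.0 * len(against_sorted))

    return place(pos, np.sort(neg)), 1.0 - place(neg, np.sort(pos))


def _threshold_grid(scores: np.ndarray) -> list[float]:
    """Thresholds for the "positive iff score >= t" sweep.

    Scores on the ordinal 0-5 scale use the fixed grid 0..6 (0 calls
    everyone positive, 6 no one); any other score values — e.g. a
    monotone relabelling — use their own sorted unique values plus a
    sentinel above the maximum, which yields the identical curve.
    """
    if np.all((scores == np.round(scores)) & (scores >= 0) & (scores <= 5)):
        return [float(t) for t in THRESHOLDS]
    vals = np.unique(scores)
    return [float(v) for v in vals] + [float(vals[-1]) + 1.0]


def empirical_roc(scores: Sequence[float], truths: Sequence[bool]) -> RocResult:
    """Empirical ROC curve and trapezoidal AUC over ordinal thresholds."""
    scores, truths = _check_scores(np.asarray(scores), np.asarray(truths))
    n_pos = int(truths.sum())
    n_neg = len(truths) - n_pos
    points = []
    for t in _threshold_grid(scores):
        called = scores >= t
        sens = float((called & truths).sum()) / n_pos
        spec = float((~called & ~truths).sum()) / n_neg
        points.append(OperatingPoint(t, sens, spec))
    # rising threshold traces the curve from (1,1) down to (0,0); reversing
    # keeps tied-FPR points in curve order, which argsort would not
    fpr = np.array([1.0 - p.specificity for p in points])[::-1]
    tpr = np.array([p.sensitivity for p in points])[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    v10, v01 = _placements(scores, truths)
    se = _auc_se(v10, v01)
    p = _p_vs_half(float(np.mean(v10)), se)
    return RocResult(tuple(points), auc, auc_se=se, p_vs_half=p)


def _auc_se(v10: np.ndarray, v01: np.ndarray) -> Optional[float]:
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        return None
    var = float(np.var(v10, ddof=1)) / m + float(np.var(v01, ddof=1)) / n
    return float(np.sqrt(var))


def _p_vs_half(auc: float, se: Optional[float]) -> Optional[float]:
    if se is None:
        return None
    if se == 0.0:
        return 1.0 if auc == 0.5 else 0.0
    return float(2 * norm.sf(abs(auc - 0.5) / se))


def auc_inference(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    truths: Sequence[bool],
) -> AucComparison:
    """Paired comparison of two empirical AUCs on the same patients.

    Both score vectors must come from the identical patient list (paired
    design); the placement-value covariance then accounts for the
    correlation between the two AUC estimates. Returns normal-theory
    two-sided p-values for each AUC against 0.5 and for the difference.
    A zero-variance difference (e.g. identical score vectors) has p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired design requires equally long score vectors")
    a, truths_arr = _check_scores(a, np.asarray(truths))
    b, _ = _check_scores(b, truths_arr)

    v10_a, v01_a = _placements(a, truths_arr)
    v10_b, v01_b = _placements(b, truths_arr)
    auc_a = float(np.mean(v10_a))
    auc_b = float(np.mean(v10_b))
    m, n = len(v10_a), len(v01_a)
    if m < 2 or n < 2:
        raise ValueError("need at least two positives and two negatives for inference")

    se_a = _auc_se(v10_a, v01_a)
    se_b = _auc_se(v10_b, v01_b)
    cov = float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m + float(
        np.cov(v01_a, v01_b, ddof=1)[0, 1]
    ) / n

    var_diff = se_a**2 + se_b**2 - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 0:
        p_ab = 1.0 if diff == 0 else 0.0
    else:
        p_ab = float(2 * norm.sf(abs(diff) / np.sqrt(var_diff)))
    return AucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        se_a=se_a,
        se_b=se_b,
        p_a_vs_half=_p_vs_half(auc_a, se_a),
        p_b_vs_half=_p_vs_half(auc_b, se_b),
        p_a_vs_b=p_ab,
        covariance=cov,
    )


def q_point(curve: RocResult | Sequence[OperatingPoint]) -> OperatingPoint:
    """Operating point maximising Youden's J = sens + spec - 1.

    Ties are broken toward the lower threshold, i.e. toward higher
    sensitivity.
    """
    points = curve.operating_points if isinstance(curve, RocResult) else tuple(curve)
    if not points:
        raise ValueError("empty curve")
    best = points[0]
    for pt in points[1:]:
        if pt.sensitivity + pt.specificity > best.sensitivity + best.specificity:
            best = pt
    return best
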