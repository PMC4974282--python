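"""Generative simulator for distant-metastasis screening cohorts.

The generator emulates the screening setting the validation cohort came
from: roughly a quarter of high-risk patients harbour distant metastases
within the 12-month reference window, about one in nine develops a second
primary tumor, metastatic lung nodules straddle the 5-mm PET detection
limit, CT detects a metastatic lesion with moderate sensitivity and high
specificity, and PET detection is gated by lesion size (essentially blind
below 5 mm). Defaults reproduce the operating characteristics of the
study setting: CT 50% sensitive / 97% specific, PET 100% specific with
size-gated sensitivity whose marginal is 50% under the default size
mixture (37.5% of metastatic lesions sub-5-mm x 0% detection, 62.5%
supra-5-mm x 80% detection).

Lesion sizes follow a two-component lognormal mixture with one mode below
and one above the cut-off; only the mass on each side of 5 mm matters to
the combined rule. Everything is driven by a single integer seed and is
bit-reproducible.

A second generator, :func:`simulate_paired_scores`, draws paired ordinal
Likert scores (0-5) for two modalities from a correlated latent binormal
model with prescribed latent AUCs; it backs the ROC parameter-recovery
checks, since per-patient scores for the real cohort were never
published.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .cohort import (
    Call,
    Cohort,
    Confirmation,
    FollowUpOutcome,
    LesionFinding,
    LesionLocation,
    Modality,
    ModalityReading,
    PatientRecord,
    RiskFactor,
)

__all__ = ["SizeMixture", "SimulationParams", "simulate_cohort", "simulate_paired_scores"]


class SizeMixture(BaseModel):
    """Two-component lognormal lesion-size mixture (millimetres)."""

    weight_small: float = Field(default=0.375, ge=0, le=1)
    median_small_mm: float = Field(default=3.5, gt=0)
    sigma_small: float = Field(default=0.25, gt=0)
    median_large_mm: float = Field(default=12.0, gt=0)
    sigma_large: float = Field(default=0.4, gt=0)

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.weight_small:
            median, sigma = self.median_small_mm, self.sigma_small
        else:
            median, sigma = self.median_large_mm, self.sigma_large
        return float(np.exp(np.log(median) + sigma * rng.standard_normal()))


class SimulationParams(BaseModel):
    """Generative parameters; defaults emulate the study conditions."""

    n_patients: int = Field(default=200, ge=1)
    dm_prevalence: float = Field(default=0.26, ge=0, le=1)
    spt_prevalence: float = Field(default=0.11, ge=0, le=1)
    lesion_size_distribution: SizeMixture = Field(default_factory=SizeMixture)
    pet_sensitivity_sub_5mm: float = Field(default=0.0, ge=0, le=1)
    pet_sensitivity_supra_5mm: float = Field(default=0.8, ge=0, le=1)
    ct_sensitivity: float = Field(default=0.50, ge=0, le=1)
    ct_specificity: float = Field(default=0.97, ge=0, le=1)
    pet_specificity: float = Field(default=1.0, ge=0, le=1)
    #: Likert emission over scores 1..5 for truly malignant detected lesions.
    likert_malignant: tuple[float, ...] = (0.0, 0.05, 0.15, 0.35, 0.45)
    #: Likert emission over scores 1..5 for false-positive lesions.
    likert_benign: tuple[float, ...] = (0.30, 0.35, 0.25, 0.08, 0.02)
    locoregional_failure_rate: float = Field(default=5 / 47, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _emissions_normalised(self) -> "SimulationParams":
        for name in ("likert_malignant", "likert_benign"):
            probs = getattr(self, name)
            if len(probs) != 5 or any(p < 0 for p in probs) or not math.isclose(
                sum(probs), 1.0, abs_tol=1e-9
            ):
                raise ValueError(f"{name} must be 5 non-negative probabilities summing to 1")
        return self


def _draw_likert(rng: np.random.Generator, probs: Sequence[float]) -> int:
    return int(rng.choice(np.arange(1, 6), p=np.asarray(probs, dtype=float)))


_SITES = ["oral cavity", "oropharynx", "hypopharynx", "larynx"]
_FACTORS = list(RiskFactor)


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Draw a cohort; identical params (incl. seed) give identical cohorts."""
    rng = np.random.default_rng(params.seed)
    mix = params.lesion_size_distribution
    patients: list[PatientRecord] = []
    for i in range(params.n_patients):
        has_dm = rng.random() < params.dm_prevalence
        has_spt = rng.random() < params.spt_prevalence
        spt_at_screening = bool(has_spt and rng.random() < 0.6)
        spt_within_12mo = bool(has_spt and not spt_at_screening)

        ct_lesions: list[LesionFinding] = []
        pet_lesions: list[LesionFinding] = []
        ct_call = pet_call = Call.NEGATIVE
        dm_at_screening = dm_within_12mo = False

        if has_dm:
            size = mix.draw(rng)
            multiple = bool(rng.random() < 0.3)
            if rng.random() < params.ct_sensitivity:
                ct_call = Call.POSITIVE
                ct_lesions.append(
                    LesionFinding(
                        modality=Modality.CT,
                        location=LesionLocation.LUNG,
                        size_mm=size,
                        multiple=multiple,
                        likert=_draw_likert(rng, params.likert_malignant),
                    )
                )
            pet_sens = (
                params.pet_sensitivity_sub_5mm
                if size < 5.0
                else params.pet_sensitivity_supra_5mm
            )
            if rng.random() < pet_sens:
                pet_call = Call.POSITIVE
                pet_lesions.append(
                    LesionFinding(
                        modality=Modality.PET,
                        location=LesionLocation.LUNG,
                        likert=_draw_likert(rng, params.likert_malignant),
                    )
                )
            if ct_call is Call.POSITIVE or pet_call is Call.POSITIVE:
                dm_at_screening = True
            else:
                dm_within_12mo = True
        else:
            if rng.random() >= params.ct_specificity:
                ct_call = Call.POSITIVE
                ct_lesions.append(
                    LesionFinding(
                        modality=Modality.CT,
                        location=LesionLocation.LUNG,
                        size_mm=mix.draw(rng),
                        likert=_draw_likert(rng, params.likert_benign),
                    )
                )
            if rng.random() >= params.pet_specificity:
                pet_call = Call.POSITIVE
                pet_lesions.append(
                    LesionFinding(
                        modality=Modality.PET,
                        location=LesionLocation.LUNG,
                        likert=_draw_likert(rng, params.likert_benign),
                    )
                )

        confirmation = Confirmation.NONE
        if dm_at_screening or spt_at_screening:
            confirmation = Confirmation.HISTOPATHOLOGY
        elif dm_within_12mo or spt_within_12mo:
            confirmation = Confirmation.PROGRESSION

        patients.append(
            PatientRecord(
                patient_id=f"S{i + 1:05d}",
                risk_factors=[_FACTORS[int(rng.integers(len(_FACTORS)))]],
                primary_site=_SITES[int(rng.integers(len(_SITES)))],
                ct=ModalityReading(call=ct_call, lesions=ct_lesions),
                pet=ModalityReading(call=pet_call, lesions=pet_lesions),
                outcome=FollowUpOutcome(
                    dm_at_screening=dm_at_screening,
                    spt_at_screening=spt_at_screening,
                    dm_within_12mo=dm_within_12mo,
                    spt_within_12mo=spt_within_12mo,
                    locoregional_control=bool(
                        rng.random() >= params.locoregional_failure_rate
                    ),
                    confirmation=confirmation,
                ),
            )
        )
    return Cohort(patients=patients)


#: Latent-score cutpoints mapping a standard-normal-scale reader signal to
#: the ordinal 0-5 scale; chosen once to spread the six levels over both
#: latent class distributions for AUCs in the 0.7-0.9 range.
DEFAULT_CUTPOINTS = (-0.6, 0.0, 0.6, 1.2, 1.8)


def ordinal_auc(mu: float, cutpoints: Sequence[float]) -> float:
    """Population AUC (ties at half) of cutpoint-discretised binormal scores.

    Negatives have latent N(0,1), positives N(mu,1); discretising onto an
    ordinal scale introduces ties, so this is smaller than the continuous
    binormal AUC Phi(mu/sqrt(2)).
    """
    edges = np.concatenate(([-np.inf], np.asarray(cutpoints, dtype=float), [np.inf]))
    p_neg = np.diff(norm.cdf(edges))
    p_pos = np.diff(norm.cdf(edges - mu))
    cum_below = np.concatenate(([0.0], np.cumsum(p_neg)))[:-1]
    return float(np.sum(p_pos * (cum_below + p_neg / 2)))


def latent_separation(auc: float, cutpoints: Optional[Sequence[float]] = None) -> float:
    """Latent mean separation giving the requested AUC.

    With ``cutpoints`` given, calibrates against the *ordinal* (discretised,
    ties at half) AUC — the quantity an empirical ROC over the scores
    estimates; without, returns the continuous binormal separation
    ``sqrt(2) * Phi^-1(auc)``.
    """
    if not 0 < auc < 1:
        raise ValueError("auc must be in (0, 1)")
    mu_cont = math.sqrt(2.0) * float(norm.ppf(auc))
    if cutpoints is None:
        return mu_cont
    from scipy.optimize import brentq

    lo, hi = mu_cont - 3.0, mu_cont + 3.0
    return float(brentq(lambda m: ordinal_auc(m, cutpoints) - auc, lo, hi, xtol=1e-10))


def simulate_paired_scores(
    n: int,
    auc_a: float,
    auc_b: float,
    prevalence: float = 0.26,
    correlation: float = 0.5,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
    seed: Optional[int] = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired ordinal scores for two modalities on the same patients.

    Each patient has a binary truth (Bernoulli ``prevalence``) and a
    correlated bivariate-normal latent signal, discretised onto 0-5 by
    ``cutpoints``. Truth-positive latent means are calibrated so the
    population AUC *of the ordinal scores* equals ``auc_a`` / ``auc_b``.
    Returns (scores_a, scores_b, truths).
    """
    rng = np.random.default_rng(seed)
    truths = rng.random(n) < prevalence
    if truths.all() or (~truths).all():
        raise ValueError("degenerate draw: adjust n or prevalence")
    cov = np.array([[1.0, correlation], [correlation, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    mu = np.array(
        [latent_separation(auc_a, cutpoints), latent_separation(auc_b, cutpoints)]
    )
    z[truths] += mu
    edges = np.asarray(cutpoints, dtype=float)
    scores = np.searchsorted(edges, z, side="left")
    return scores[:, 0].astype(int), scores[:, 1].astype(int), truths
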