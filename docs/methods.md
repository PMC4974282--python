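# Methods

## Setting and model

The package models a screening study in head-and-neck squamous cell
carcinoma (HNSCC): patients with high-risk factors for dissemination
(≥3 nodal metastases, bilateral nodes, a node ≥6 cm, low jugular nodes,
tumor recurrence, or a second primary tumor) undergo both whole-body
FDG-PET and contrast-enhanced chest CT before treatment. Each scan is
reported as a binary call for distant metastases, and each visible lesion
also receives a five-point ordinal Likert suspicion score
(1 definitely benign … 5 definitely malignant). A patient with no lesion
suspicious for distant metastasis carries the below-scale sentinel 0; in
particular, patients whose scans were positive only for a synchronous
second primary tumor are scored 0 — and negative — *with respect to
distant metastases*, even though the second primary itself was seen by
both modalities. When a patient has several lesions, the highest score
represents the patient in the ordinal analyses.

### The combined reading

The combined call is `PET-positive OR (CT-positive AND smallest
suspicious lesion < 5 mm)`. The rationale is physical: PET's spatial
resolution makes it effectively blind below about 5 mm, so a negative PET
cannot discount a sub-5-mm CT finding, whereas at ≥5 mm a negative PET is
informative and overrides CT. PET positivity always wins: metabolically
active lesions are treated as malignant regardless of CT's reading of any
solid lesion. Three deliberate choices:

* **The size threshold is strict** — exactly 5.0 mm falls on the
  "PET-visible" side and is discounted when PET is negative.
* **The minimum lesion size drives the branch** when CT reports several
  suspicious lesions: any sub-threshold lesion is by construction
  invisible to PET.
* **Likert scores are not consulted by the rule** — the combined reading
  operates on the binary clinical reports; ordinal scores feed only the
  ROC analysis. A CT-positive reading must carry at least one lesion with
  a recorded size, otherwise classification raises a contract error
  rather than guessing.
* **A PET-positive/CT-negative finding is positive unconditionally.** A
  location-dependent refinement for this branch has been suggested but
  never specified; the simplification is consistent with every such case
  in the validation cohort (both were true positives).

### Reference standard and analysis sets

Truth is defined over diagnostic work-up plus 12 months of follow-up: a
patient is truth-positive iff metastases were established at screening or
manifested within the window. Calls are adjudicated TP/FP/FN/TN in the
usual way. Two nested analysis subsets are derived:

* **Evaluable set** — excludes patients who developed a second primary
  during follow-up *and* are metastasis-positive: imaging cannot
  attribute such metastases to the index HNSCC versus the new primary, so
  no TP/FN status is assignable. The reconstructed cohort has 2 such
  patients (47 → 45).
* **Locoregional-control subset** — further keeps only patients without
  locoregional recurrence (45 → 40 in the fixture), removing follow-up
  metastases that may have been reseeded by a recurrence after screening
  rather than missed by it. Time-to-event structure is deliberately not
  modelled — the study design uses a single 12-month window, so a pair of
  booleans suffices.

### Accuracy statistics

Sensitivity, specificity, PPV, NPV and accuracy are binomial proportions
with exact Clopper–Pearson 95 % intervals (confidence level
configurable), computed through the beta-quantile identity and verified
in the tests against an independent bisection of the binomial tails and
against `statsmodels`. Point estimates render as integer percentages
rounded half away from zero (37/40 = 92.5 % prints as 93); interval
bounds render to the nearest integer. When comparing to the published
tables the tests allow ±1 percentage point on bounds only: the published
rounding of some upper bounds is inconsistent (e.g. an exact upper bound
of 99.9 % printed as 99), and whether that software rounded or truncated
is unknowable. A metric with a zero denominator (e.g. sensitivity in an
all-negative cohort) is flagged undefined and rendered as a dash; the
remaining metrics are still produced.

### ROC analysis

The empirical curve places one operating point at each threshold
t = 0…6 under "positive iff score ≥ t" (0 calls everyone positive, 6 no
one); scores outside the ordinal range — produced e.g. by monotone
relabelling — use their own sorted unique values as thresholds, which
yields the identical curve. The trapezoidal area over these points equals
the Mann–Whitney two-sample statistic with ties counted one half; the
tests enforce this equality against brute-force pair counting and
`sklearn`. Variance, and for paired designs (two modalities scored on the
same patients) the AUC covariance, use the placement-value (DeLong)
estimator with sample (ddof = 1) moments; AUC-vs-0.5 and
difference-of-AUC tests are two-sided normal. Which variance estimator
the original analysis used is unstated; the placement-value method is
this package's choice, cross-checked against a permutation reference in
the tests. A zero-variance difference (identical score vectors) reports
p = 1 by convention. The Q-point — "highest sensitivity/specificity" — is
implemented as the Youden-J maximiser with ties broken toward the lower
threshold, i.e. toward sensitivity, since in screening for incurable
disease a missed metastasis costs more than a work-up of a false
positive. Smooth (binormal) curve fitting is out of scope; the curves are
empirical five-point curves.

## The reconstructed cohort

The 47-patient validation cohort is rebuilt from the complete
cross-tabulation the published results narrative provides (scan calls by
modality, discordant-pair lesion sizes, follow-up events by scan stratum,
analysis-set sizes, risk-factor and site marginals). Thirty named
constraints are checked by `validate_fixture`; the reconstruction
satisfies all simultaneously. Points where the published record
under-determines the data, resolved here once and deterministically:

* Risk factors sum to 57 and primary sites to 49 over 47 patients (some
  patients had multiple factors; two had synchronous dual primaries).
  The overflow assignments go to the earliest patients in a fixed
  canonical order; only the marginals are meaningful.
* The five patients without locoregional control are configured
  screen-negative, exactly one of them metastasis-positive — the only
  configuration consistent with both published accuracy tables at once.
* The screening-detected second primary with disseminated lung/bone
  spread is truth-*negative* for distant metastases of the index tumor
  (the spread belongs to the bronchogenic second primary): the published
  group counts (12 metastasis + 5 second-primary patients, 8
  screen-detected metastases = 4 both-positive + 2 PET-only + 2 CT-only)
  and the table arithmetic admit no other reading.
* Individual Likert scores were never published. The fixture assigns
  plausible scores (high for confirmed metastases, 0 for second-primary
  patients, a few benign 1–2 nodules among true negatives) so the ROC
  pipeline runs end-to-end, but fixture ROC outputs are reconstruction
  artifacts and are asserted nowhere.

## The simulator

`simulate_cohort` draws cohorts from the study's conditions: metastasis
prevalence 0.26 and second-primary prevalence 0.11 (as in the cohort:
12/47 and 5/47), CT sensitivity 0.50 and specificity 0.97, PET
specificity 1.00, and PET sensitivity gated by lesion size — 0 below
5 mm, 0.8 above, which under the default size mixture (37.5 % of
metastatic lesions in a lognormal mode with 3.5 mm median, the rest at
12 mm median) gives the marginal PET sensitivity of 0.50 observed in the
study. Lesion sizes use a two-component lognormal purely to place mass on
both sides of the cut-off; the rule only ever compares sizes to 5 mm.
Likert scores come from per-truth categorical emissions (malignant
lesions skewed to 4–5, false positives to 1–3). Locoregional failure is
independent at rate 5/47. Everything derives from one integer seed via
`numpy`'s PCG64; identical parameters give identical cohorts.

What the simulator does *not* emulate: correlated reader errors between
modalities, multiple lesions per patient, extra-pulmonary metastases,
second-primary imaging findings, or informative censoring — so passing
recovery tests demonstrate estimator correctness under the generative
model, not clinical performance on real populations.

`simulate_paired_scores` backs the ROC recovery checks: a correlated
bivariate-normal latent reader signal (default correlation 0.5) per
patient, discretised onto 0–5 by fixed cutpoints (−0.6, 0, 0.6, 1.2,
1.8). Discretisation with ties-at-half shrinks the AUC of the underlying
continuous signal, so the latent class separation is calibrated by
root-finding so that the *ordinal* scores' population AUC equals the
requested target (0.84 / 0.78 in the validation drivers) — that is the
quantity the empirical estimator actually estimates.

## Problem sizes and tolerances

The exact-interval oracle comparison covers every 0 ≤ k ≤ n ≤ 60 at
1 × 10⁻⁹; AUC/pair-counting equality is checked on 200 random instances
of up to 60 patients at 1 × 10⁻¹²; simulator calibration and paired ROC
recovery use cohorts of 5 000 patients (sampling error ≈ 1–2 percentage
points on the recovered characteristics, hence the 0.02 recovery bands);
small-sample AUC recovery averages 400 cohorts of 45. Accuracy-table
reproduction on the fixture is exact (integer rounding) for all point
estimates and ±1 percentage point for interval bounds, as discussed
above.

## Known limitations

* The fixture is one consistent reconstruction, not the original data;
  attributes beyond the published counts are conventions.
* The location-dependent branch for PET-positive/CT-negative findings is
  intentionally unimplemented (never specified); the rule treats all such
  findings as positive.
* No McNemar or other paired comparison of sensitivities between
  modalities, no survival analysis, no multi-reader variance modelling,
  and no image handling — the pipeline consumes reader calls.
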