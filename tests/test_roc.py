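"""ROC curve, AUC, paired inference and Q-point against independent oracles."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from petct_screen.adjudicate import all_patients_set
from petct_screen.cohort import Modality
from petct_screen.fixture import build_paper_fixture
from petct_screen.roc import (
    OperatingPoint,
    auc_inference,
    empirical_roc,
    patient_scores,
    q_point,
)
from petct_screen.simulate import simulate_paired_scores


def brute_force_auc(scores, truths):
    """Pair-counting oracle: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x, y in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_known_instance_matches_pair_counting():
    scores = [5, 5, 4, 3, 1, 0] + [0, 0, 0, 0, 0, 1, 1, 2, 2, 3]
    truths = [True] * 6 + [False] * 10
    assert empirical_roc(scores, truths).auc == pytest.approx(
        brute_force_auc(scores, truths), abs=1e-12
    )


def test_trapezoid_equals_pair_counting_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(4, 60))
        scores = rng.integers(0, 6, n)
        truths = rng.random(n) < 0.4
        if truths.all() or not truths.any():
            continue
        roc = empirical_roc(scores, truths)
        assert roc.auc == pytest.approx(brute_force_auc(scores, truths), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(truths, scores), abs=1e-12)


def test_perfect_separation_and_chance_level():
    truths = [True] * 4 + [False] * 6
    assert empirical_roc([5, 5, 5, 5, 1, 1, 1, 1, 1, 1], truths).auc == 1.0
    assert empirical_roc([3, 2, 1, 0, 3, 2, 1, 0, 3, 2],
                         [True, True, True, True, False, False, False, False, True, False]
                         ).auc == pytest.approx(0.5, abs=0.2)
    # identically distributed scores give exactly 0.5
    scores = [0, 1, 2, 3, 4, 5] * 2
    truths = [True] * 6 + [False] * 6
    assert empirical_roc(scores, truths).auc == pytest.approx(0.5, abs=1e-12)


def test_monotone_relabelling_leaves_auc_unchanged():
    rng = np.random.default_rng(11)
    relabel = {0: 0, 1: 2, 2: 3, 3: 7, 4: 20, 5: 100}  # strictly increasing
    for _ in range(20):
        scores = rng.integers(0, 6, 40)
        truths = rng.random(40) < 0.3
        if truths.all() or not truths.any():
            continue
        mapped = np.array([relabel[s] for s in scores])
        assert empirical_roc(mapped, truths).auc == pytest.approx(
            empirical_roc(scores, truths).auc, abs=1e-12
        )


def test_operating_points_are_monotone():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 6, 50)
    truths = rng.random(50) < 0.4
    pts = empirical_roc(scores, truths).operating_points
    assert [p.threshold for p in pts] == list(range(7))
    sens = [p.sensitivity for p in pts]
    spec = [p.specificity for p in pts]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert all(a <= b for a, b in zip(spec, spec[1:]))
    assert sens[0] == 1.0 and spec[0] == 0.0
    assert sens[-1] == 0.0 and spec[-1] == 1.0


def test_degenerate_truth_is_contract_error():
    with pytest.raises(ValueError, match="degenerate"):
        empirical_roc([1, 2, 3], [True, True, True])


def test_patient_scores_use_highest_lesion_score(paper_cohort):
    sets = all_patients_set(paper_cohort)
    scores, truths = patient_scores(sets, Modality.CT)
    assert len(scores) == 47
    assert scores.max() == 5  # most suspicious both-positive patient
    assert int(truths.sum()) == 14  # 12 determinate + 2 indeterminate-origin
    # patients without lesions carry the below-scale sentinel 0
    assert (scores == 0).sum() > 20


class TestQPoint:
    def test_perfect_separation(self):
        truths = [True] * 3 + [False] * 5
        roc = empirical_roc([5, 5, 4, 1, 0, 0, 1, 2], truths)
        q = q_point(roc)
        assert (q.sensitivity, q.specificity) == (1.0, 1.0)
        # thresholds 3 and 4 both separate perfectly; tie goes to the lower
        assert q.threshold == 3

    def test_published_style_curve_prefers_sensitivity(self):
        points = [
            OperatingPoint(1, 0.58, 0.94),
            OperatingPoint(3, 0.40, 0.98),
        ]
        assert q_point(points).threshold == 1

    def test_tie_broken_toward_lower_threshold(self):
        points = [
            OperatingPoint(1, 0.8, 0.6),
            OperatingPoint(2, 0.6, 0.8),
        ]
        assert q_point(points).threshold == 1


class TestAucInference:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(13)
        scores = rng.integers(0, 6, 40)
        truths = rng.random(40) < 0.4
        cmp = auc_inference(scores, scores, truths)
        assert cmp.auc_a == cmp.auc_b
        assert cmp.p_a_vs_b == 1.0

    def test_separation_vs_chance_on_20_paired_patients(self):
        rng = np.random.default_rng(17)
        truths = np.array([True] * 8 + [False] * 12)
        scores_a = np.where(truths, 5, 1)  # perfect separation
        scores_b = rng.integers(0, 6, 20)  # chance level
        cmp = auc_inference(scores_a, scores_b, truths)
        assert cmp.auc_a == 1.0
        assert cmp.p_a_vs_b < 0.05
        # brute-force permutation reference on the paired differences
        p_perm = _permutation_p(scores_a, scores_b, truths, rng, n_perm=2000)
        assert p_perm < 0.05

    def test_recovers_latent_aucs_in_repeated_small_samples(self):
        aucs_a, aucs_b = [], []
        for rep in range(400):
            a, b, t = simulate_paired_scores(45, 0.84, 0.78, seed=1000 + rep)
            if t.all() or not t.any() or t.sum() < 2 or (~t).sum() < 2:
                continue
            cmp = auc_inference(a, b, t)
            aucs_a.append(cmp.auc_a)
            aucs_b.append(cmp.auc_b)
        se_a = np.std(aucs_a) / np.sqrt(len(aucs_a))
        se_b = np.std(aucs_b) / np.sqrt(len(aucs_b))
        assert np.mean(aucs_a) == pytest.approx(0.84, abs=max(4 * se_a, 0.015))
        assert np.mean(aucs_b) == pytest.approx(0.78, abs=max(4 * se_b, 0.015))

    def test_covariance_vanishes_when_pairing_is_broken(self):
        a, b, t = simulate_paired_scores(2000, 0.84, 0.78, correlation=0.6, seed=29)
        paired = auc_inference(a, b, t)
        rng = np.random.default_rng(31)
        b_shuffled = b.copy()
        for cls in (True, False):  # permute within truth class: marginals intact
            idx = np.flatnonzero(t == cls)
            b_shuffled[idx] = b_shuffled[rng.permutation(idx)]
        broken = auc_inference(a, b_shuffled, t)
        assert paired.covariance > 3 * abs(broken.covariance)
        assert abs(broken.covariance) < 0.25 * paired.se_a * paired.se_b

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            auc_inference([1, 2, 3], [1, 2], [True, False, True])


def _permutation_p(a, b, truths, rng, n_perm=2000):
    observed = abs(brute_force_auc(a, truths) - brute_force_auc(b, truths))
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(brute_force_auc(aa, truths) - brute_force_auc(bb, truths)) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
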