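"""Exact binomial intervals and the accuracy-profile machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from petct_screen.accuracy import (
    ContingencyTable,
    accuracy_profile,
    build_table,
    clopper_pearson,
    render_cell,
    render_table,
    round_half_away,
)
from petct_screen.adjudicate import dm_truth
from petct_screen.cohort import Call
from petct_screen.combine import classify_patient
from petct_screen.pipeline import modality_tables


def bisect_interval(k, n, confidence=0.95, tol=1e-12):
    """Independent oracle: bisection on the binomial tail probabilities."""
    alpha = 1 - confidence

    def solve(f, lo, hi):
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: alpha / 2 - binom.sf(k - 1, n, p), 0.0, 1.0)
    high = 1.0 if k == n else solve(lambda p: binom.cdf(k, n, p) - alpha / 2, 0.0, 1.0)
    return low, high


@pytest.mark.parametrize(
    "k, n, printed",
    [
        (6, 12, (21, 79)),  # sensitivity cells of the n=45 table
        (8, 11, (39, 94)),  # combined sensitivity, locoregional-control set
        (29, 29, (88, 100)),  # specificity at k = n
        (8, 8, (63, 100)),  # PPV of the combined reading
    ],
)
def test_printed_interval_pairs(k, n, printed):
    low, high = clopper_pearson(k, n)
    assert (round_half_away(100 * low), round_half_away(100 * high)) == printed


def test_zero_successes_interval_against_bisection():
    low, high = clopper_pearson(0, 10)
    assert low == 0.0
    b_low, b_high = bisect_interval(0, 10)
    assert high == pytest.approx(b_high, abs=1e-9)
    assert high == pytest.approx(0.3085, abs=5e-4)


@pytest.mark.parametrize("n", [1, 7, 23, 45])
def test_interval_matches_bisection_oracle(n):
    for k in range(n + 1):
        assert clopper_pearson(k, n) == pytest.approx(bisect_interval(k, n), abs=1e-9)


@given(k=st.integers(0, 50), n=st.integers(1, 50), conf=st.sampled_from([0.9, 0.95, 0.99]))
def test_interval_invariants(k, n, conf):
    if k > n:
        k = n
    low, high = clopper_pearson(k, n, conf)
    assert 0.0 <= low <= k / n <= high <= 1.0
    if k == 0:
        assert low == 0.0
    if k == n:
        assert high == 1.0
    sm_low, sm_high = proportion_confint(k, n, alpha=1 - conf, method="beta")
    assert low == pytest.approx(sm_low, abs=1e-12)
    assert high == pytest.approx(sm_high, abs=1e-12)


@pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
def test_exact_interval_coverage_is_conservative(p):
    """Across 10,000 binomial draws the exact interval covers >= 95%."""
    n = 30
    rng = np.random.default_rng(2024)
    bounds = np.array([clopper_pearson(k, n) for k in range(n + 1)])
    ks = rng.binomial(n, p, size=10_000)
    covered = (bounds[ks, 0] <= p) & (p <= bounds[ks, 1])
    assert covered.mean() >= 0.95


@pytest.mark.parametrize("k, n", [(2, 0), (5, 3)])
def test_interval_contract_errors(k, n):
    with pytest.raises(ValueError):
        clopper_pearson(k, n)


def test_build_table_on_fixture_matches_published_counts(evaluable, lrc):
    truths45 = [dm_truth(p.outcome) for p in evaluable.patients]
    ct45 = build_table([p.ct.call for p in evaluable.patients], truths45)
    assert (ct45.tp, ct45.fp, ct45.fn, ct45.tn) == (6, 1, 6, 32)

    truths40 = [dm_truth(p.outcome) for p in lrc.patients]
    combined40 = build_table(
        [classify_patient(p.ct, p.pet).call for p in lrc.patients], truths40
    )
    assert (combined40.tp, combined40.fp, combined40.fn, combined40.tn) == (8, 0, 3, 29)


def test_build_table_all_negative():
    table = build_table([Call.NEGATIVE] * 5, [Call.NEGATIVE] * 5)
    assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 0, 5)


def test_build_table_length_mismatch():
    with pytest.raises(ValueError, match="aligned"):
        build_table([Call.POSITIVE], [Call.POSITIVE, Call.NEGATIVE])


def test_accuracy_profile_combined_reading_values():
    profile = accuracy_profile(ContingencyTable(tp=8, fp=0, fn=4, tn=33))
    assert profile["sensitivity"].point == pytest.approx(8 / 12)
    assert profile["specificity"].point == 1.0
    assert profile["accuracy"].point == pytest.approx(41 / 45)
    assert profile["npv"].numerator == 33 and profile["npv"].denominator == 37


def test_accuracy_profile_undefined_metrics_flagged():
    profile = accuracy_profile(ContingencyTable(tp=0, fp=0, fn=0, tn=10))
    assert profile["sensitivity"] is None and profile["ppv"] is None
    assert profile["specificity"].point == 1.0
    assert profile["accuracy"].point == 1.0


@given(
    st.tuples(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    ).filter(lambda t: sum(t) > 0)
)
def test_accuracy_times_total_is_tp_plus_tn(counts):
    table = ContingencyTable(*counts)
    acc = accuracy_profile(table)["accuracy"]
    assert acc.point * table.total == pytest.approx(table.tp + table.tn)


def test_rendering_rounds_half_away_from_zero():
    assert round_half_away(92.5) == 93
    assert round_half_away(87.5) == 88
    assert round_half_away(66.7) == 67
    est = accuracy_profile(ContingencyTable(tp=8, fp=0, fn=3, tn=29))["accuracy"]
    assert render_cell(est).startswith("93 ")  # 37/40 = 92.5%


def test_render_table_layout(evaluable):
    tables, _ = modality_tables(evaluable)
    profiles = {name: accuracy_profile(t) for name, t in tables.items()}
    text = render_table(profiles, "n = 45 patients")
    flat = " ".join(text.split())
    assert "PET and CT 67 (35-90) 100 (89-100) 100 (63-100) 89 (75-97) 91 (79-98)" in flat


def test_render_undefined_cell_is_dash():
    profiles = {"CT": accuracy_profile(ContingencyTable(tp=0, fp=0, fn=0, tn=4))}
    assert "-" in render_table(profiles, "n = 4")
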