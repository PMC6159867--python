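"""Diagnostic accuracy, rank-sum tests, step-down correction, correlation."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sfemg.stats import (
    DiagnosticTable,
    build_diagnostic_table,
    diagnostic_accuracy,
    normalization_extubation_correlation,
    rank_sum_compare,
    rank_sum_exact_p,
    rank_sum_normal_p,
    stepwise_correction,
    time_to_normalization,
    window_comparisons,
)


def test_diagnostic_accuracy_study_counts():
    """24/28 true positives and 16/38 false positives give sensitivity ~86%
    and specificity 57.89%; the cross-product odds ratio is 8.25."""
    res = diagnostic_accuracy(DiagnosticTable(tp=24, fn=4, fp=16, tn=22))
    assert round(res.sensitivity_pct) == 86
    assert res.specificity_pct == pytest.approx(57.89, abs=0.005)
    assert res.odds_ratio == pytest.approx(528 / 64)
    assert res.or_ci_low < res.odds_ratio < res.or_ci_high
    assert res.p_value < 0.001


def test_diagnostic_accuracy_perfect_corner():
    res = diagnostic_accuracy(DiagnosticTable(tp=10, fn=0, fp=0, tn=10))
    assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0
    assert res.corrected and math.isfinite(res.odds_ratio)


def test_odds_ratio_invariant_to_cell_scaling():
    a = diagnostic_accuracy(DiagnosticTable(6, 2, 3, 9))
    b = diagnostic_accuracy(DiagnosticTable(18, 6, 9, 27))
    assert a.odds_ratio == pytest.approx(b.odds_ratio)


def test_diagnostic_empty_errors():
    with pytest.raises(ValueError):
        diagnostic_accuracy(DiagnosticTable(0, 0, 0, 0))


def test_rank_sum_tied_singletons():
    u, p = rank_sum_compare([5.0], [5.0])
    assert u == pytest.approx(0.5) and p == 1.0


def test_rank_sum_disjoint_triples():
    u, p = rank_sum_compare([1, 2, 3], [10, 11, 12])
    assert u == 0.0 and p == pytest.approx(2 / 20)


def test_rank_sum_empty_group_errors():
    with pytest.raises(ValueError):
        rank_sum_compare([], [1.0])


def test_rank_sum_normal_matches_exact_at_n8():
    """Edgeworth-refined approximation vs full enumeration, within 0.01."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.uniform(size=8)
        b = rng.uniform(size=8) + rng.uniform(-0.8, 0.8)
        _, pe = rank_sum_exact_p(a, b)
        _, pn = rank_sum_normal_p(a, b)
        assert abs(pe - pn) < 0.01


def test_rank_sum_matches_scipy_exact():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        u, p = rank_sum_compare(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def _stepdown_reference(ps, alpha):
    """Independent literal step-through of the published step-down rule."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    flags = [False] * m
    for rank, idx in enumerate(order):
        if ps[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


@pytest.mark.parametrize(
    "ps, expected",
    [
        ([1e-5, 0.006, 0.0003, 0.10, 0.5], [True, True, True, False, False]),
        ([1.0] * 5, [False] * 5),
        ([0.009, 0.013, 0.5, 0.6, 0.7], [True, False, False, False, False]),
    ],
)
def test_stepdown_examples(ps, expected):
    assert stepwise_correction(ps) == expected


def test_stepdown_equals_bruteforce_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(200):
        ps = rng.uniform(size=int(rng.integers(1, 8))).tolist()
        got = stepwise_correction(ps, 0.05)
        assert got == _stepdown_reference(ps, 0.05)
        # Holm's procedure in statsmodels (boundary-tie handling aside)
        sm = multipletests(ps, alpha=0.05, method="holm")[0].tolist()
        assert got == sm


@given(
    ps=st.lists(st.floats(0, 1), min_size=1, max_size=6),
    a1=st.floats(0.001, 0.3),
    a2=st.floats(0.001, 0.3),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_stepdown_monotone_in_alpha(ps, a1, a2):
    lo, hi = sorted((a1, a2))
    f_lo = stepwise_correction(ps, lo)
    f_hi = stepwise_correction(ps, hi)
    assert all(h or not l for l, h in zip(f_lo, f_hi))


def test_stepdown_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        stepwise_correction([0.5, 1.2])


def _series(rows):
    return pd.DataFrame(rows, columns=["hours_post_ingestion", "abnormal"])


def test_time_to_normalization_first_crossing():
    assert time_to_normalization(_series([(20, True), (68, False), (116, False)])) == (68.0, False)
    assert time_to_normalization(_series([(20, True), (68, True)])) == (
        pytest.approx(math.nan, nan_ok=True),
        True,
    )
    assert time_to_normalization(_series([(12, False)])) == (12.0, False)
    with pytest.raises(ValueError):
        time_to_normalization(_series([]))


def test_correlation_trivial_and_null():
    pairs = [(t, t) for t in np.linspace(10, 200, 20)]
    assert normalization_extubation_correlation(pairs).r == pytest.approx(1.0)

    rng = np.random.default_rng(0)
    pairs = list(zip(rng.normal(size=1000), rng.normal(size=1000)))
    assert abs(normalization_extubation_correlation(pairs).r) < 0.1

    with pytest.raises(ValueError):
        normalization_extubation_correlation([(1.0, 2.0), (2.0, 3.0)])


def _toy_cohort():
    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(6)],
            "ims_label": [True, True, True, False, False, False],
        }
    )
    sessions = pd.DataFrame(
        {
            "session_id": [f"s{i}" for i in range(6)],
            "patient_id": [f"p{i}" for i in range(6)],
            "hours_post_ingestion": [10.0, 12.0, 15.0, 10.0, 18.0, 20.0],
            "median_jitter_us": [150.0, 90.0, 20.0, 30.0, 31.0, 50.0],
        }
    )
    return sessions, patients


def test_build_diagnostic_table_counts():
    sessions, patients = _toy_cohort()
    t = build_diagnostic_table(sessions, patients, cutoff_us=33.4)
    assert (t.tp, t.fn, t.fp, t.tn) == (2, 1, 1, 2)


def test_build_diagnostic_table_uses_earliest_session():
    sessions, patients = _toy_cohort()
    extra = pd.DataFrame(
        {
            "session_id": ["sx"],
            "patient_id": ["p2"],
            "hours_post_ingestion": [5.0],
            "median_jitter_us": [180.0],
        }
    )
    t = build_diagnostic_table(pd.concat([sessions, extra]), patients)
    assert t.tp == 3 and t.fn == 0


def test_build_diagnostic_table_degenerate_stratum():
    sessions, patients = _toy_cohort()
    only_neg = patients[~patients["ims_label"]]
    t = build_diagnostic_table(sessions[sessions.patient_id.isin(only_neg.patient_id)], only_neg)
    res = diagnostic_accuracy(t)
    assert math.isnan(res.sensitivity_pct) and math.isfinite(res.specificity_pct)


def test_build_diagnostic_table_no_window_sessions_errors():
    sessions, patients = _toy_cohort()
    with pytest.raises(ValueError):
        build_diagnostic_table(sessions, patients, window_h=(1000.0, 2000.0))


def test_window_comparisons_empty_window_gets_p_one():
    sessions, patients = _toy_cohort()
    res = window_comparisons(sessions, patients, windows_h=((0, 24), (24, 48)))
    assert res[0].p_value < 1.0 and res[1].p_value == 1.0
    assert not res[1].significant_after_correction
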