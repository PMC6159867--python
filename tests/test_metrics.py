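"""Jitter (MCD), blocking, cap and session-summary behaviour."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfemg.config import MetricsConfig
from sfemg.metrics import (
    FibreResult,
    InsufficientResponses,
    apply_cap,
    compute_blocking,
    compute_mcd,
    measure_fibre,
    summarize_session,
)


@pytest.mark.parametrize(
    "latencies, expected",
    [
        ([4000.0, 4000.0, 4000.0], 0.0),
        ([4000.0, 4010.0, 3990.0, 4010.0], (10 + 20 + 20) / 3),
        ([1.0, 2.0], 1.0),
    ],
)
def test_mcd_hand_examples(latencies, expected):
    assert compute_mcd(latencies) == pytest.approx(expected, abs=1e-9)


def test_mcd_needs_two_latencies():
    with pytest.raises(InsufficientResponses):
        compute_mcd([4000.0])
    with pytest.raises(ValueError):
        compute_mcd([4000.0, math.nan])


def test_mcd_gaussian_closed_form():
    """For iid Gaussian latencies E[MCD] = 2*sigma/sqrt(pi)."""
    rng = np.random.default_rng(0)
    sigma = 30.0
    vals = [compute_mcd(rng.normal(4000, sigma, 100)) for _ in range(500)]
    assert np.mean(vals) == pytest.approx(2 * sigma / math.sqrt(math.pi), rel=0.02)


@given(
    lat=st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40),
    shift=st.floats(-1e5, 1e5),
    scale=st.floats(0.01, 100),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_mcd_invariances(lat, shift, scale):
    """Translation invariance, linear scaling, and the range bound."""
    base = compute_mcd(lat)
    assert compute_mcd([v + shift for v in lat]) == pytest.approx(base, rel=1e-9, abs=1e-6)
    assert compute_mcd([v * scale for v in lat]) == pytest.approx(base * scale, rel=1e-9, abs=1e-6)
    assert base <= (max(lat) - min(lat)) + 1e-9


def test_mcd_range_equality_at_n2():
    assert compute_mcd([10.0, 50.0]) == pytest.approx(40.0)


@pytest.mark.parametrize(
    "present, expected",
    [([True] * 100, 0.0), ([False] * 100, 100.0), ([True] * 80 + [False] * 20, 20.0)],
)
def test_blocking_percentage(present, expected):
    assert compute_blocking(present) == pytest.approx(expected)


def test_blocking_empty_errors():
    with pytest.raises(ValueError):
        compute_blocking([])


def test_blocking_binomial_recovery():
    rng = np.random.default_rng(1)
    ests = [compute_blocking(rng.random(100) >= 0.2) for _ in range(500)]
    assert 18.0 <= float(np.mean(ests)) <= 22.0


@pytest.mark.parametrize(
    "mcd, blocking, expected",
    [
        (250.0, 30.0, (200.0, True)),
        (30.0, 0.0, (30.0, False)),
        (None, 100.0, (200.0, True)),
        (250.0, 0.0, (250.0, False)),  # cap needs blocking alongside extreme jitter
        (200.0, 30.0, (200.0, False)),
    ],
)
def test_apply_cap(mcd, blocking, expected):
    assert apply_cap(mcd, blocking) == expected


def test_apply_cap_undefined_without_blocking_errors():
    with pytest.raises(ValueError):
        apply_cap(None, 0.0)


def test_measure_fibre_spanning_pairs():
    lat = np.array([4000.0, math.nan, 4020.0, 4010.0])
    present = np.array([True, False, True, True])
    res = measure_fibre("f0", lat, present)
    assert res.n_spanning_pairs == 1
    assert res.mcd_us == pytest.approx((20 + 10) / 2)
    res2 = measure_fibre("f0", lat, present, MetricsConfig(include_spanning_pairs=False))
    assert res2.mcd_us == pytest.approx(10.0)


def test_measure_fibre_complete_block_capped():
    res = measure_fibre("f0", [math.nan] * 10, [False] * 10)
    assert res.capped and res.mcd_us == 200.0 and res.blocking_pct == 100.0


def _fibres(mcds, blocking=0.0):
    return [FibreResult(f"f{i}", m, blocking, False, 100) for i, m in enumerate(mcds)]


def test_session_summary_rules():
    s = summarize_session(_fibres([25.0] * 20))
    assert s.median_jitter_us == 25.0 and not s.abnormal

    capped = [FibreResult(f"f{i}", 200.0, 50.0, True, 50) for i in range(20)]
    s = summarize_session(capped)
    assert s.median_jitter_us == 200.0 and s.abnormal

    # the abnormality rule is strictly 'greater than'
    s = summarize_session(_fibres([30.0, 33.4, 34.0]))
    assert s.median_jitter_us == pytest.approx(33.4) and not s.abnormal


def test_session_no_accepted_fibres_unanalysable():
    fibres = [FibreResult("f0", 50.0, 0.0, False, 100, accepted=False)]
    s = summarize_session(fibres)
    assert not s.analysable and s.n_fibres_accepted == 0


@given(st.lists(st.floats(1.0, 199.0), min_size=3, max_size=21), st.integers(0, 20))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_session_abnormality_monotone(mcds, idx):
    """Raising any fibre's MCD never flips a session from abnormal to normal."""
    before = summarize_session(_fibres(mcds)).abnormal
    raised = list(mcds)
    raised[idx % len(raised)] += 50.0
    after = summarize_session(_fibres(raised)).abnormal
    assert after or not before
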