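"""Potential detection, shape analysis and the fibre rejection taxonomy."""
import copy
import math

import numpy as np
import pytest
from numpy.random import SeedSequence, default_rng

from sfemg.config import QualificationConfig
from sfemg.metrics import compute_mcd
from sfemg.qualify import (
    InsufficientPresent,
    Polarity,
    PotentialMeasurement,
    RejectReason,
    classify_fibre,
    detect_potential,
    measure_shape_consistency,
    qualify_fibre,
)
from sfemg.simulate import FibreGroundTruth, sample_ground_truth, simulate_fibre


def test_noise_only_sweep_absent(acq):
    rng = np.random.default_rng(0)
    sweep = 10.0 * rng.standard_normal(acq.n_samples)
    m = detect_potential(sweep, acq)
    assert not m.present


def test_constant_sweep_absent_no_error(acq):
    m = detect_potential(np.zeros(acq.n_samples), acq)
    assert not m.present


def test_nan_sweep_errors(acq):
    sweep = np.zeros(acq.n_samples)
    sweep[100] = math.nan
    with pytest.raises(ValueError, match="NaN"):
        detect_potential(sweep, acq)


def test_clean_potential_latency_accuracy(acq):
    """Measured peak latency lands within one sample period of the truth."""
    truth = FibreGroundTruth(mean_latency_us=4200.0, jitter_sd_us=30.0, amplitude_uv=300.0)
    rec = simulate_fibre(truth, acq, SeedSequence([13, 0]))
    qc, ms = qualify_fibre(rec)
    lat = np.array([m.peak_latency_us for m in ms if m.present])
    err = lat - rec.true_latencies_us[rec.true_present]
    assert abs(np.mean(err)) < acq.sample_period_us      # bias below one sample
    assert np.std(err) < 5.0                             # interpolation + noise error


def test_positive_going_polarity(acq):
    truth = FibreGroundTruth(artifact_class="positive_going", jitter_sd_us=20.0)
    rec = simulate_fibre(truth, acq, 3)
    qc, ms = qualify_fibre(rec)
    polarities = [m.polarity for m in ms if m.present]
    assert polarities.count(Polarity.POSITIVE_GOING) > len(polarities) / 2
    assert qc.verdict == "rejected" and RejectReason.POSITIVE_GOING in qc.reasons


def test_measured_amplitude_and_rise_time(acq):
    truth = FibreGroundTruth(amplitude_uv=300.0, rise_time_us=150.0, jitter_sd_us=10.0)
    rec = simulate_fibre(truth, acq, 4)
    _, ms = qualify_fibre(rec)
    present = [m for m in ms if m.present]
    med_amp = np.median([m.amplitude_uv for m in present])
    med_rise = np.median([m.rise_time_us for m in present])
    # band-limiting trims a little amplitude; peak-to-peak ~ 2x negative peak
    assert 350.0 < med_amp < 700.0
    assert 80.0 < med_rise < 300.0


def test_identical_snippets_score_one(quiet_acq):
    rec = simulate_fibre(FibreGroundTruth(jitter_sd_us=0.0), quiet_acq, 5)
    _, ms = qualify_fibre(rec)
    scores = [m.shape_score for m in ms if m.present]
    assert min(scores) > 0.999


def test_composite_flagged(acq):
    hits = 0
    for seed in range(10):
        rng = default_rng(SeedSequence([77, seed]))
        truth = sample_ground_truth("composite", rng)
        rec = simulate_fibre(truth, acq, SeedSequence([78, seed]))
        qc, _ = qualify_fibre(rec)
        if qc.reasons & {RejectReason.COMPOSITE_NOTCH_SHOULDER, RejectReason.INCONSISTENT_SHAPE}:
            hits += 1
    assert hits >= 8


def test_clean_fibres_mostly_accepted(acq):
    accepted = 0
    for seed in range(20):
        rng = default_rng(SeedSequence([79, seed]))
        rec = simulate_fibre(sample_ground_truth("clean", rng), acq, SeedSequence([80, seed]))
        qc, _ = qualify_fibre(rec)
        accepted += qc.verdict == "accepted"
    assert accepted >= 18


def test_shape_analysis_needs_five_present(acq, qcfg):
    rec = simulate_fibre(FibreGroundTruth(jitter_sd_us=20.0), acq, 6)
    ms = [
        detect_potential(rec.sweeps[i], acq, config=qcfg, sweep_index=i) for i in range(3)
    ]
    with pytest.raises(InsufficientPresent):
        measure_shape_consistency(rec.sweeps[:3], ms, acq, qcfg)


def _measurement(i, latency, present=True, amplitude=300.0, polarity=Polarity.NEGATIVE_GOING):
    return PotentialMeasurement(
        i, present, peak_latency_us=latency, amplitude_uv=amplitude,
        rise_time_us=150.0, polarity=polarity, half_width_us=100.0, trough_depth_uv=280.0,
    )


def test_threshold_hovering_rule():
    """Blocking while the provisional jitter is normal => stimulation artifact."""
    ms = [_measurement(i, 4000.0 + (i % 2) * 10) for i in range(80)]
    ms += [PotentialMeasurement(80 + i, False) for i in range(20)]
    qc = classify_fibre(ms, provisional_jitter_us=15.0)
    assert RejectReason.THRESHOLD_HOVERING in qc.reasons

    # high provisional jitter: the same blocking is junctional, fibre accepted
    qc2 = classify_fibre(ms, provisional_jitter_us=80.0)
    assert RejectReason.THRESHOLD_HOVERING not in qc2.reasons


def test_threshold_hovering_never_fires_without_blocking():
    ms = [_measurement(i, 4000.0 + (i % 3)) for i in range(100)]
    qc = classify_fibre(ms, provisional_jitter_us=5.0)
    assert RejectReason.THRESHOLD_HOVERING not in qc.reasons


def test_latency_jump_rejected(acq):
    truth = FibreGroundTruth(
        mean_latency_us=4000.0, jitter_sd_us=25.0, artifact_class="latency_jump"
    )
    rec = simulate_fibre(truth, acq, 9)
    qc, _ = qualify_fibre(rec)
    assert RejectReason.LATENCY_JUMP in qc.reasons


def test_too_few_responses():
    ms = [_measurement(i, 4000.0) for i in range(3)]
    ms += [PotentialMeasurement(3 + i, False) for i in range(97)]
    qc = classify_fibre(ms)
    assert qc.verdict == "rejected" and RejectReason.TOO_FEW_RESPONSES in qc.reasons


def test_complete_block_is_a_finding_not_a_failure():
    ms = [PotentialMeasurement(i, False) for i in range(100)]
    qc = classify_fibre(ms)
    assert qc.verdict == "accepted" and qc.complete_block


def test_classification_idempotent_and_nonmutating():
    ms = [_measurement(i, 4000.0 + (i % 5) * 20) for i in range(100)]
    snapshot = copy.deepcopy(ms)
    qc1 = classify_fibre(ms, provisional_jitter_us=compute_mcd([m.peak_latency_us for m in ms]))
    qc2 = classify_fibre(ms, provisional_jitter_us=compute_mcd([m.peak_latency_us for m in ms]))
    assert qc1 == qc2
    assert ms == snapshot


def test_classify_empty_errors():
    with pytest.raises(ValueError):
        classify_fibre([])


def test_fibre_level_selection_criteria():
    small = [_measurement(i, 4000.0 + (i % 2) * 30, amplitude=60.0) for i in range(100)]
    qc = classify_fibre(small, provisional_jitter_us=40.0)
    assert RejectReason.CRITERIA_NOT_MET in qc.reasons
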