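"""Detection and qualification of apparent single-fibre potentials.

Each sweep is screened for a single-fibre action potential; accepted
potentials are measured (negative-peak latency with sub-sample refinement,
peak-to-peak amplitude, rise time, polarity) and the fibre as a whole is
accepted or rejected following the screening rules an electromyographer
applies before measuring jitter:

* positive-going potentials indicate damaged fibres -> rejected;
* notches/shoulders or an inconsistent shape across sweeps indicate a
  composite of more than one fibre -> rejected;
* blocking with normal jitter signifies stimulation hovering around the
  fibre's threshold (not junctional failure) -> rejected;
* sudden latency jumps indicate electrode movement -> rejected;
* two fibres overlapping at near-identical latency cannot be measured
  reliably -> rejected.

All other measurable fibres are accepted, minimizing observer bias.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .config import AcquisitionConfig, QualificationConfig
from .metrics import compute_mcd
from .simulate import FibreRecording

__all__ = [
    "Polarity",
    "RejectReason",
    "PotentialMeasurement",
    "ShapeReport",
    "FibreQC",
    "detect_potential",
    "measure_shape_consistency",
    "classify_fibre",
    "qualify_fibre",
]


class Polarity(str, Enum):
    NEGATIVE_GOING = "negative_going"
    POSITIVE_GOING = "positive_going"


class RejectReason(str, Enum):
    POSITIVE_GOING = "positive_going"
    COMPOSITE_NOTCH_SHOULDER = "composite_notch_shoulder"
    INCONSISTENT_SHAPE = "inconsistent_shape"
    THRESHOLD_HOVERING = "threshold_hovering_block_normal_jitter"
    LATENCY_JUMP = "latency_jump"
    OVERLAPPING_FIBRES = "overlapping_fibres"
    TOO_FEW_RESPONSES = "too_few_responses"
    CRITERIA_NOT_MET = "criteria_not_met"


@dataclass
class PotentialMeasurement:
    """Per-sweep measurement of the apparent single-fibre potential."""

    sweep_index: int
    present: bool
    peak_latency_us: float = float("nan")
    amplitude_uv: float = 0.0          # peak-to-peak within +-1 ms of the peak
    rise_time_us: float = float("nan")
    polarity: Polarity = Polarity.NEGATIVE_GOING
    shape_score: float = float("nan")  # similarity to the fibre's median waveform, [0, 1]
    n_troughs: int = 0                 # distinct supra-threshold negative troughs
    half_width_us: float = float("nan")
    trough_depth_uv: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude_uv must be >= 0")
        if not math.isnan(self.shape_score) and not 0.0 <= self.shape_score <= 1.0:
            raise ValueError("shape_score must be in [0, 1]")


@dataclass
class ShapeReport:
    """Outcome of sweep-superimposition shape analysis for one fibre."""

    shape_scores: np.ndarray
    median_snippet: np.ndarray
    notch_shoulder: bool        # secondary inflection / extra extremum in the median
    inconsistent: bool          # too many sweeps dissimilar from the median
    inconsistent_fraction: float


@dataclass
class FibreQC:
    """Qualification verdict for one fibre."""

    verdict: str                       # "accepted" | "rejected"
    reasons: set[RejectReason] = field(default_factory=set)
    n_present: int = 0
    n_sweeps: int = 0
    complete_block: bool = False       # zero responses: a valid clinical finding

    def __post_init__(self) -> None:
        if self.verdict not in ("accepted", "rejected"):
            raise ValueError("verdict must be 'accepted' or 'rejected'")
        if (self.verdict == "rejected") != bool(self.reasons):
            raise ValueError("rejected exactly when reasons is nonempty")


def _refine_minimum(y: np.ndarray, i0: int, half: int, dt_us: float) -> float:
    """Sub-sample location of a minimum by least-squares parabola around i0.

    Fits a quadratic over ``i0 +- half`` samples; falls back to the discrete
    minimum when the fit is not convex.  Returns microseconds.
    """
    lo = max(0, i0 - half)
    hi = min(len(y), i0 + half + 1)
    x = np.arange(lo, hi, dtype=float) - i0
    yw = y[lo:hi]
    # closed-form quadratic least squares (Vandermonde normal equations)
    s0 = x.size
    s1, s2, s3, s4 = x.sum(), (x**2).sum(), (x**3).sum(), (x**4).sum()
    b0, b1, b2 = yw.sum(), (x * yw).sum(), (x**2 * yw).sum()
    m = np.array([[s4, s3, s2], [s3, s2, s1], [s2, s1, s0]])
    try:
        a, b, _ = np.linalg.solve(m, np.array([b2, b1, b0]))
    except np.linalg.LinAlgError:
        return i0 * dt_us
    if a <= 0:
        return i0 * dt_us
    vertex = float(np.clip(-b / (2.0 * a), -half, half))
    return (i0 + vertex) * dt_us


def detect_potential(
    sweep: np.ndarray,
    acq: AcquisitionConfig,
    search_window_ms: tuple[float, float] | None = None,
    config: QualificationConfig | None = None,
    noise_rms_uv: float | None = None,
    sweep_index: int = 0,
    smoothed: np.ndarray | None = None,
) -> PotentialMeasurement:
    """Screen one sweep for a single-fibre potential and measure it.

    A response is present iff, inside the search window, the dominant
    deflection passes both the amplitude criterion (peak-to-peak above
    ``min_amplitude_uv``) and a noise-relative criterion (trough depth above
    ``presence_snr`` times the baseline noise RMS) -- the published criteria
    select fibres, so the noise clause is what keeps noise spikes from
    counting as responses.  The negative-peak latency is refined to
    sub-sample precision with a least-squares parabola; polarity is judged
    by lobe order (a potential whose dominant positive lobe *follows* the
    trough is positive-going).
    """
    cfg = config or QualificationConfig()
    y = np.asarray(sweep, dtype=float)
    if y.ndim != 1 or y.size != acq.n_samples:
        raise ValueError("sweep length must match the acquisition config")
    if np.isnan(y).any():
        raise ValueError("corrupt input: sweep contains NaN samples")

    dt = acq.sample_period_us
    if search_window_ms is None:
        search_window_ms = (
            cfg.search_start_ms,
            acq.sweep_window_ms - cfg.search_stop_before_end_ms,
        )
    lo_ms, hi_ms = search_window_ms
    if not (0 <= lo_ms < hi_ms <= acq.sweep_window_ms):
        raise ValueError("search window must lie within the sweep")

    if smoothed is not None:
        ys = smoothed
    else:
        win = min(cfg.smooth_window_samples, y.size - 1)
        if win % 2 == 0:
            win -= 1
        ys = savgol_filter(y, win, 3) if win >= 5 else y

    if noise_rms_uv is None:
        nb = int(cfg.baseline_ms * 1e-3 * acq.sample_rate_hz)
        noise_rms_uv = float(np.std(ys[: max(nb, 8)]))
    noise_rms_uv = max(noise_rms_uv, 1e-9)

    i_lo = int(lo_ms * 1e-3 * acq.sample_rate_hz)
    i_hi = int(hi_ms * 1e-3 * acq.sample_rate_hz)
    seg = ys[i_lo:i_hi]
    if seg.size == 0 or np.ptp(seg) == 0.0:
        return PotentialMeasurement(sweep_index, False)

    i0 = i_lo + int(np.argmin(seg))
    depth = -ys[i0]

    one_ms = int(1e-3 * acq.sample_rate_hz)
    a_lo, a_hi = max(0, i0 - one_ms), min(y.size, i0 + one_ms)
    p2p = float(np.ptp(ys[a_lo:a_hi]))

    present = (depth > cfg.presence_snr * noise_rms_uv) and (p2p > cfg.min_amplitude_uv)
    if not present:
        return PotentialMeasurement(sweep_index, False, amplitude_uv=max(p2p, 0.0))

    latency = _refine_minimum(ys, i0, 4, dt)

    pos_before = float(np.max(ys[a_lo:i0])) if i0 > a_lo else 0.0
    pos_after = float(np.max(ys[i0 + 1 : a_hi])) if a_hi > i0 + 1 else 0.0
    positive_going = (pos_before < 0.5 * depth) and (
        pos_after > max(2.0 * max(pos_before, 0.0), 3.0 * noise_rms_uv)
    )
    polarity = Polarity.POSITIVE_GOING if positive_going else Polarity.NEGATIVE_GOING

    # rise time: preceding positive peak, else the 10%-of-depth onset crossing
    pre = ys[a_lo:i0]
    rise = float("nan")
    if pre.size:
        j = int(np.argmax(pre))
        if pre[j] > max(3.0 * noise_rms_uv, 0.1 * depth):
            rise = (i0 - (a_lo + j)) * dt
        else:
            above = np.flatnonzero(pre > -0.1 * depth)
            if above.size:
                rise = (i0 - (a_lo + above[-1])) * dt

    # distinct supra-threshold troughs (overlapping-fibre evidence); the
    # thresholds sit well above the band-limit ringing (~20% of depth)
    tr_height = max(cfg.presence_snr * noise_rms_uv, cfg.trough_rel_prominence * depth)
    min_dist = max(3, int(0.6 * cfg.smooth_window_samples))
    peaks, _ = find_peaks(
        -ys[i_lo:i_hi],
        height=tr_height,
        prominence=cfg.trough_rel_prominence * depth,
        distance=min_dist,
    )
    n_troughs = int(len(peaks))

    half_level = -0.5 * depth
    below = ys[a_lo:a_hi] < half_level
    half_width = float(np.count_nonzero(below)) * dt

    return PotentialMeasurement(
        sweep_index,
        True,
        peak_latency_us=latency,
        amplitude_uv=p2p,
        rise_time_us=rise,
        polarity=polarity,
        shape_score=float("nan"),
        n_troughs=n_troughs,
        half_width_us=half_width,
        trough_depth_uv=depth,
    )


def _extract_snippets(
    sweeps: np.ndarray,
    measurements: Sequence[PotentialMeasurement],
    acq: AcquisitionConfig,
    cfg: QualificationConfig,
) -> tuple[np.ndarray, list[int]]:
    half = int(cfg.snippet_half_ms * 1e-3 * acq.sample_rate_hz)
    snippets, idx = [], []
    for m in measurements:
        if not m.present or math.isnan(m.peak_latency_us):
            continue
        centre = int(round(m.peak_latency_us / acq.sample_period_us))
        lo, hi = centre - half, centre + half + 1
        if lo < 0 or hi > sweeps.shape[1]:
            continue
        snippets.append(sweeps[m.sweep_index, lo:hi])
        idx.append(m.sweep_index)
    if not snippets:
        return np.empty((0, 2 * half + 1)), []
    return np.asarray(snippets), idx


def _median_snippet_irregular(
    med: np.ndarray, noise_rms_uv: float, acq: AcquisitionConfig, cfg: QualificationConfig
) -> bool:
    """Notch/shoulder screen on the pointwise-median, peak-aligned waveform.

    A unitary biphasic potential has one positive lobe followed by one
    trough in the analysis region.  Extra prominent extrema (double troughs,
    bumps) or a shoulder on the rising limb (a prominent local maximum of the
    first derivative's magnitude pattern) mark a composite.
    """
    dt = acq.sample_period_us
    n = med.size
    centre = n // 2
    depth = -float(med[centre])
    if depth <= 0:
        return False
    # Band-limiting gives every unitary potential a phase-locked undershoot/
    # overshoot pattern of ~15-20% of the trough depth; the notch screen
    # therefore looks only between the positive lobe and ~0.5 ms after the
    # trough, with a prominence floor above the ringing level.
    prom = max(cfg.notch_prominence_frac * depth, 4.0 * noise_rms_uv)
    pre = med[:centre]
    bumps, _ = find_peaks(pre, prominence=prom)
    pos_peak = int(bumps[-1]) if len(bumps) else max(0, centre - int(400 / dt))
    hi = min(n, centre + int(520 / dt))
    troughs, _ = find_peaks(-med[pos_peak:hi], prominence=prom)
    guard = max(2, int(60 / dt))
    if any(abs(t + pos_peak - centre) > guard for t in troughs):
        return True
    # shoulder screen: the derivative along the rising limb of a unitary
    # potential is a single negative valley; an interior local maximum of the
    # derivative marks a shoulder
    limb = med[pos_peak : centre + 1]
    if limb.size >= 7:
        d = np.gradient(limb)
        d_scale = float(np.max(np.abs(d)))
        if d_scale > 0:
            hills, _ = find_peaks(d, prominence=0.25 * d_scale)
            if len(hills) >= 1:
                return True
    return False


def measure_shape_consistency(
    recording_or_sweeps: FibreRecording | np.ndarray,
    measurements: Sequence[PotentialMeasurement],
    acq: AcquisitionConfig | None = None,
    config: QualificationConfig | None = None,
    noise_rms_uv: float | None = None,
) -> ShapeReport:
    """Score each sweep's waveform against the fibre's median waveform.

    Snippets are aligned on the measured negative peak; the shape score is
    the Pearson correlation with the pointwise median snippet mapped to
    [0, 1].  Also raises the composite flags: a notch/shoulder in the median
    waveform, or too large a fraction of dissimilar sweeps.  Updates the
    ``shape_score`` of the supplied measurements in place.
    """
    cfg = config or QualificationConfig()
    if isinstance(recording_or_sweeps, FibreRecording):
        sweeps = recording_or_sweeps.sweeps
        acq = recording_or_sweeps.acquisition
    else:
        sweeps = np.asarray(recording_or_sweeps, dtype=float)
        if acq is None:
            raise ValueError("acq is required when passing a raw sweep matrix")
    n_present = sum(m.present for m in measurements)
    if n_present < cfg.min_present_sweeps:
        raise InsufficientPresent(
            f"shape analysis needs >= {cfg.min_present_sweeps} present sweeps, got {n_present}"
        )
    if noise_rms_uv is None:
        nb = int(cfg.baseline_ms * 1e-3 * acq.sample_rate_hz)
        noise_rms_uv = float(np.std(sweeps[:, : max(nb, 8)]))

    snippets, idx = _extract_snippets(sweeps, measurements, acq, cfg)
    med = np.median(snippets, axis=0)
    med_c = med - med.mean()
    denom_m = float(np.linalg.norm(med_c))
    scores = np.full(len(measurements), np.nan)
    for row, sweep_i in enumerate(idx):
        s = snippets[row] - snippets[row].mean()
        denom = float(np.linalg.norm(s)) * denom_m
        r = float(np.dot(s, med_c) / denom) if denom > 0 else 0.0
        scores[sweep_i] = 0.5 * (r + 1.0)
    for m in measurements:
        if not math.isnan(scores[m.sweep_index]):
            m.shape_score = float(np.clip(scores[m.sweep_index], 0.0, 1.0))

    valid = scores[~np.isnan(scores)]
    frac_low = float(np.mean(valid < cfg.shape_score_threshold)) if valid.size else 0.0
    notch = _median_snippet_irregular(med, noise_rms_uv / math.sqrt(max(len(idx), 1)), acq, cfg)
    return ShapeReport(
        shape_scores=scores,
        median_snippet=med,
        notch_shoulder=notch,
        inconsistent=frac_low > cfg.inconsistency_tolerance,
        inconsistent_fraction=frac_low,
    )


class InsufficientPresent(ValueError):
    """Too few present sweeps for shape statistics."""


def _latency_jump(latencies: np.ndarray, cfg: QualificationConfig) -> bool:
    """Sudden-shift screen on the running-median latency.

    Compares the stride-1 running median (window ``latency_jump_window_sweeps``)
    against itself one window later, so a step lands fully across some pair
    regardless of where it falls relative to window boundaries.
    """
    w = cfg.latency_jump_window_sweeps
    if latencies.size < 2 * w:
        w = max(3, latencies.size // 2)
    if latencies.size < 2 * w:
        return False
    meds = np.array(
        [np.median(latencies[i : i + w]) for i in range(latencies.size - w + 1)]
    )
    lagged = np.abs(meds[w:] - meds[:-w])
    return bool(lagged.size and lagged.max() > cfg.latency_jump_threshold_us)


def classify_fibre(
    measurements: Sequence[PotentialMeasurement],
    provisional_jitter_us: float | None = None,
    shape: ShapeReport | None = None,
    config: QualificationConfig | None = None,
) -> FibreQC:
    """Accept or reject a fibre from its per-sweep measurements.

    Applies, in order of screening practice: response-count floor, modal
    polarity, sudden latency jumps, overlapping-fibre evidence (recurring
    double troughs, or strongly varying trough width/depth), the composite
    flags from shape analysis, the fibre-level amplitude/rise-time selection
    criteria, and the threshold-hovering rule (any blocking while the
    provisional jitter is within the normal range).  Reasons accumulate; the
    fibre is rejected iff any reason fired.  Zero responses are treated as a
    complete junctional block -- a valid finding, not a recording failure.
    """
    cfg = config or QualificationConfig()
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements supplied")
    n_sweeps = len(ms)
    present = [m for m in ms if m.present]
    n_present = len(present)
    reasons: set[RejectReason] = set()

    if n_present == 0:
        return FibreQC("accepted", set(), 0, n_sweeps, complete_block=True)
    if n_present < cfg.min_present_sweeps:
        reasons.add(RejectReason.TOO_FEW_RESPONSES)
        return FibreQC("rejected", reasons, n_present, n_sweeps)

    n_positive = sum(m.polarity is Polarity.POSITIVE_GOING for m in present)
    if n_positive > n_present / 2:
        reasons.add(RejectReason.POSITIVE_GOING)

    latencies = np.array([m.peak_latency_us for m in present])
    if _latency_jump(latencies, cfg):
        reasons.add(RejectReason.LATENCY_JUMP)

    n_double = sum(m.n_troughs >= 2 for m in present)
    widths = np.array([m.half_width_us for m in present if not math.isnan(m.half_width_us)])
    depths = np.array([m.trough_depth_uv for m in present])
    width_sd = float(np.std(widths)) if widths.size >= 5 else 0.0
    depth_cv = float(np.std(depths) / np.mean(depths)) if depths.size >= 5 and np.mean(depths) > 0 else 0.0
    if (
        n_double >= cfg.overlap_min_recurrences
        or width_sd > cfg.overlap_width_sd_us
        or depth_cv > cfg.overlap_depth_cv
    ):
        reasons.add(RejectReason.OVERLAPPING_FIBRES)

    if shape is not None:
        if shape.notch_shoulder:
            reasons.add(RejectReason.COMPOSITE_NOTCH_SHOULDER)
        if shape.inconsistent:
            reasons.add(RejectReason.INCONSISTENT_SHAPE)

    med_amp = float(np.median([m.amplitude_uv for m in present]))
    rises = [m.rise_time_us for m in present if not math.isnan(m.rise_time_us)]
    med_rise = float(np.median(rises)) if rises else float("nan")
    if med_amp <= cfg.min_amplitude_uv or (
        not math.isnan(med_rise) and med_rise > cfg.max_rise_time_us
    ):
        reasons.add(RejectReason.CRITERIA_NOT_MET)

    n_blocked = n_sweeps - n_present
    if provisional_jitter_us is None and n_present >= 2:
        provisional_jitter_us = compute_mcd(latencies)
    if (
        n_blocked > 0
        and provisional_jitter_us is not None
        and provisional_jitter_us <= cfg.normal_jitter_cutoff_us
    ):
        reasons.add(RejectReason.THRESHOLD_HOVERING)

    verdict = "rejected" if reasons else "accepted"
    return FibreQC(verdict, reasons, n_present, n_sweeps)


def qualify_fibre(
    recording: FibreRecording,
    config: QualificationConfig | None = None,
) -> tuple[FibreQC, list[PotentialMeasurement]]:
    """Run the full qualification chain on one recording.

    Detects the potential in every sweep (sharing one baseline noise
    estimate), runs shape analysis when enough responses are present, and
    classifies the fibre.  Returns the verdict and the per-sweep
    measurements (with shape scores filled in).
    """
    cfg = config or QualificationConfig()
    acq = recording.acquisition
    # one smoothing pass and one baseline noise estimate for the whole fibre
    win = min(cfg.smooth_window_samples, recording.sweeps.shape[1] - 1)
    if win % 2 == 0:
        win -= 1
    smooth = (
        savgol_filter(recording.sweeps, win, 3, axis=1)
        if win >= 5
        else recording.sweeps
    )
    nb = int(cfg.baseline_ms * 1e-3 * acq.sample_rate_hz)
    noise = float(np.std(smooth[:, : max(nb, 8)]))
    measurements = [
        detect_potential(
            recording.sweeps[i],
            acq,
            config=cfg,
            noise_rms_uv=noise,
            sweep_index=i,
            smoothed=smooth[i],
        )
        for i in range(recording.sweeps.shape[0])
    ]
    shape: ShapeReport | None = None
    if sum(m.present for m in measurements) >= cfg.min_present_sweeps:
        shape = measure_shape_consistency(
            recording, measurements, config=cfg, noise_rms_uv=noise
        )
    qc = classify_fibre(measurements, shape=shape, config=cfg)
    return qc, measurements
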