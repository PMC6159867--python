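"""Configuration objects for the stimulated-SfEMG analysis pipeline.

Every stage of the pipeline (acquisition emulation, potential qualification,
jitter metrics, cohort statistics, cohort synthesis) is parameterized by a
small dataclass.  Defaults follow the clinical protocol the package models:
10/s stimulation, 100 sweeps per fibre, ~20 fibres per session, a 1-10 kHz
recording band, the 200 us jitter cap and the 33.4 us upper limit of normal
jitter.  All configs validate their invariants eagerly and raise
``ConfigError`` naming the offending field.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

logger = logging.getLogger("sfemg")

__all__ = [
    "ConfigError",
    "AcquisitionConfig",
    "QualificationConfig",
    "MetricsConfig",
    "StatsConfig",
    "CohortConfig",
    "PipelineConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {message}")


@dataclass
class AcquisitionConfig:
    """Acquisition protocol for stimulated single-fibre EMG.

    The stimulated protocol delivers rectangular pulses at ``stimulus_rate_hz``
    and records ``sweeps_per_fibre`` stimulus-locked sweeps per fibre, aiming
    for ``fibres_per_session`` fibres per patient visit.  The amplifier band
    is ``highpass_hz``..``lowpass_hz``.  The sample rate and sweep window are
    recording-system choices: 50 kHz resolves sub-sample jitter well below the
    normal 33.4 us limit, and a 20 ms window houses facial-muscle latencies of
    3-6 ms with generous margin.
    """

    stimulus_rate_hz: float = 10.0
    sweeps_per_fibre: int = 100
    fibres_per_session: int = 20
    sample_rate_hz: float = 50_000.0
    sweep_window_ms: float = 20.0
    highpass_hz: float = 1000.0
    lowpass_hz: float = 10_000.0
    stimulus_pulse_width_ms: float = 0.1
    max_stimulus_ma: float = 3.0
    noise_rms_uv: float = 10.0

    def __post_init__(self) -> None:
        _require(self.stimulus_rate_hz > 0, "stimulus_rate_hz", "must be > 0")
        _require(self.sweeps_per_fibre >= 1, "sweeps_per_fibre", "must be >= 1")
        _require(self.fibres_per_session >= 1, "fibres_per_session", "must be >= 1")
        _require(
            self.sweep_window_ms * self.stimulus_rate_hz <= 1000.0,
            "sweep_window_ms",
            "sweeps must not overlap: window [ms] x rate [1/s] must be <= 1000",
        )
        _require(
            0 < self.highpass_hz < self.lowpass_hz,
            "highpass_hz",
            "need 0 < highpass_hz < lowpass_hz",
        )
        _require(
            self.lowpass_hz < self.sample_rate_hz / 2,
            "lowpass_hz",
            "must be below the Nyquist frequency",
        )
        _require(
            0.05 <= self.stimulus_pulse_width_ms <= 0.2,
            "stimulus_pulse_width_ms",
            "protocol uses pulse widths in 0.05-0.2 ms",
        )
        _require(self.noise_rms_uv >= 0, "noise_rms_uv", "must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_window_ms * 1e-3 * self.sample_rate_hz))

    @property
    def sample_period_us(self) -> float:
        return 1e6 / self.sample_rate_hz

    @property
    def sweep_window_us(self) -> float:
        return self.sweep_window_ms * 1000.0


@dataclass
class QualificationConfig:
    """Thresholds for apparent single-fibre potential qualification.

    ``min_amplitude_uv`` and ``max_rise_time_us`` are the field's selection
    criteria for genuine near-electrode single-fibre potentials; the remaining
    knobs operationalize the published rejection taxonomy (positive-going,
    composite/notch-shoulder, inconsistent shape, threshold-hovering blocking
    with normal jitter, sudden latency jumps, overlapping fibres).
    """

    min_amplitude_uv: float = 100.0        # peak-to-peak selection criterion
    max_rise_time_us: float = 500.0        # rise time <= 0.5 ms
    presence_snr: float = 5.0              # negative peak > presence_snr x noise RMS
    baseline_ms: float = 1.0               # pre-potential window for noise RMS
    search_start_ms: float = 1.5           # earliest physiological latency searched
    search_stop_before_end_ms: float = 0.5
    min_present_sweeps: int = 5            # floor for shape/jitter statistics
    shape_score_threshold: float = 0.95
    inconsistency_tolerance: float = 0.10  # fraction of sweeps allowed below score threshold
    normal_jitter_cutoff_us: float = 33.4  # threshold-hovering rule bound
    latency_jump_threshold_us: float = 500.0
    latency_jump_window_sweeps: int = 10
    snippet_half_ms: float = 1.0           # half-width of peak-aligned shape snippets
    smooth_window_samples: int = 7         # Savitzky-Golay window for detection
    trough_rel_prominence: float = 0.5     # secondary-trough prominence vs presence level
    overlap_min_recurrences: int = 3       # sweeps with double troughs to call overlap
    overlap_width_sd_us: float = 25.0      # half-width variability bound
    overlap_depth_cv: float = 0.07         # trough-depth variability bound
    notch_prominence_frac: float = 0.22    # median-snippet extra-extremum prominence

    def __post_init__(self) -> None:
        _require(self.min_amplitude_uv > 0, "min_amplitude_uv", "must be > 0")
        _require(self.max_rise_time_us > 0, "max_rise_time_us", "must be > 0")
        _require(self.min_present_sweeps >= 2, "min_present_sweeps", "must be >= 2")
        _require(
            0 <= self.shape_score_threshold <= 1,
            "shape_score_threshold",
            "must be in [0, 1]",
        )
        _require(
            0 <= self.inconsistency_tolerance <= 1,
            "inconsistency_tolerance",
            "must be in [0, 1]",
        )
        _require(
            self.latency_jump_threshold_us > 0,
            "latency_jump_threshold_us",
            "must be > 0",
        )


@dataclass
class MetricsConfig:
    """Constants for jitter (MCD) and blocking quantification."""

    cap_us: float = 200.0            # extreme jitter-with-blocking cap
    cutoff_us: float = 33.4          # upper limit of normal median jitter
    include_spanning_pairs: bool = True  # consecutive present sweeps across blocked gaps
    session_rule: str = "median"     # how a session's abnormality is called

    def __post_init__(self) -> None:
        _require(self.cap_us > 0, "cap_us", "must be > 0")
        _require(self.cutoff_us > 0, "cutoff_us", "must be > 0")
        _require(
            self.session_rule in {"median", "any_fibre", "fraction"},
            "session_rule",
            "must be one of median | any_fibre | fraction",
        )


_DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 24.0),
    (24.0, 48.0),
    (48.0, 72.0),
    (72.0, 96.0),
    (96.0, math.inf),
)


@dataclass
class StatsConfig:
    """Cohort-level inference constants."""

    alpha: float = 0.05
    windows_h: tuple[tuple[float, float], ...] = _DEFAULT_WINDOWS
    cutoff_us: float = 33.4
    prediction_window_h: tuple[float, float] = (0.0, 24.0)
    exclude_deaths_prediscarge: bool = True

    def __post_init__(self) -> None:
        _require(0 < self.alpha < 1, "alpha", "must be in (0, 1)")
        for lo, hi in self.windows_h:
            _require(lo < hi, "windows_h", "window bounds must satisfy lo < hi")


# Group-level median time courses, hours post ingestion -> target value.
# The IMS+ jitter course starts above the 200 us cap (so the capped session
# median sits at the cap on day 1) and reaches the normal range by ~day 9;
# the IMS- course stays inside the 27-33.4 us normal band.  Blocking courses
# likewise: near-complete blocking on day 1 in IMS+, ~normal by day 9-10.
DEFAULT_IMS_POS_JITTER_COURSE: tuple[tuple[float, float], ...] = (
    (24.0, 260.0),
    (48.0, 95.0),
    (72.0, 32.0),
    (96.0, 29.5),
    (144.0, 29.0),
    (216.0, 28.5),
)
DEFAULT_IMS_NEG_JITTER_COURSE: tuple[tuple[float, float], ...] = (
    (24.0, 30.5),
    (96.0, 29.5),
    (216.0, 28.5),
)
DEFAULT_IMS_POS_BLOCK_COURSE: tuple[tuple[float, float], ...] = (
    (24.0, 0.90),
    (48.0, 0.35),
    (72.0, 0.15),
    (96.0, 0.08),
    (144.0, 0.04),
    (240.0, 0.02),
)
DEFAULT_IMS_NEG_BLOCK_COURSE: tuple[tuple[float, float], ...] = ((24.0, 0.01), (240.0, 0.01))


@dataclass
class CohortConfig:
    """Synthetic cohort of organophosphate-poisoned patients.

    Each patient gets an IMS label (Bernoulli at ``ims_prevalence``), a
    severity multiplier applied to the group median jitter/blocking courses,
    a session schedule (first test within 24 h of ingestion unless the
    patient arrives as a delayed transfer, then roughly every other day until
    discharge or death), and clinical covariates: intubation/extubation
    times, red-cell AChE on admission, and death for a fraction of IMS+
    patients whose jitter never recovers.

    Extubation for surviving intubated IMS+ patients is the realized
    jitter-normalization time plus Gaussian noise (``extubation_noise_sd_h``),
    which is the dial controlling the normalization-extubation Pearson r; the
    default is calibrated so the default preset yields r ~= 0.49.
    """

    n_patients: int = 120
    ims_prevalence: float = 0.525
    seed: int = 0
    fibres_per_session: int = 20
    sweeps_per_fibre: int = 100
    mean_latency_us: float = 4000.0
    ims_pos_jitter_course: tuple[tuple[float, float], ...] = DEFAULT_IMS_POS_JITTER_COURSE
    ims_neg_jitter_course: tuple[tuple[float, float], ...] = DEFAULT_IMS_NEG_JITTER_COURSE
    ims_pos_block_course: tuple[tuple[float, float], ...] = DEFAULT_IMS_POS_BLOCK_COURSE
    ims_neg_block_course: tuple[tuple[float, float], ...] = DEFAULT_IMS_NEG_BLOCK_COURSE
    severity_sigma_pos: float = 0.5       # lognormal sigma of IMS+ patient multipliers
    severity_taper: tuple[tuple[float, float], ...] = ((72.0, 1.0), (216.0, 0.45))
    # late-time exponent on the severity multiplier: individual recovery
    # courses converge as receptor turnover completes
    severity_sigma_neg: float = 0.15       # lognormal sigma of IMS- patient multipliers
    fibre_sigma: float = 0.30              # lognormal sigma of fibre-level jitter spread
    block_fibre_sigma: float = 0.50
    normal_jitter_mean_us: float = 30.0    # recovered / healthy fibre median jitter
    normal_jitter_sd_us: float = 1.5
    cutoff_us: float = 33.4
    cap_us: float = 200.0
    transfer_delay_prob: float = 0.45      # fraction first tested after 24 h (late transfers)
    first_session_range_h: tuple[float, float] = (4.0, 23.0)
    delayed_first_range_h: tuple[float, float] = (24.0, 72.0)
    schedule_gap_mean_h: float = 48.0
    schedule_gap_sd_h: float = 7.0
    schedule_gap_min_h: float = 24.0
    death_prob_ims_pos: float = 0.254
    death_time_median_h: float = 72.0
    death_relapse_frac: float = 0.5        # fatal courses that mimic recovery, then relapse
    death_time_sigma: float = 0.5
    discharge_median_pos_h: float = 264.0
    discharge_sigma_pos: float = 0.35
    discharge_median_neg_h: float = 60.0
    discharge_sigma_neg: float = 0.50
    stay_severity_exponent_neg: float = 6.0  # sicker IMS- patients stay longer
    transfer_severity_bias_neg: float = 1.0  # delayed IMS- transfers skew sicker (z-shift)
    intubation_prob_neg: float = 0.82
    intubation_median_pos_h: float = 7.5
    intubation_sigma_pos: float = 1.0
    intubation_median_neg_h: float = 3.2
    intubation_sigma_neg: float = 1.2
    extubation_noise_sd_h: float = 148.0   # calibrated for Pearson r ~= 0.49
    extubation_offset_neg_h: float = 50.0
    ache_pos_params: tuple[float, ...] = (0.25,)       # exponential scale, U/gHb
    ache_neg_params: tuple[float, ...] = (0.5, 2.5)    # P(zero), exponential scale

    def __post_init__(self) -> None:
        _require(self.n_patients >= 0, "n_patients", "must be >= 0")
        _require(0 <= self.ims_prevalence <= 1, "ims_prevalence", "must be in [0, 1]")
        _require(self.fibres_per_session >= 1, "fibres_per_session", "must be >= 1")
        _require(self.sweeps_per_fibre >= 2, "sweeps_per_fibre", "must be >= 2")
        for name in (
            "ims_pos_jitter_course",
            "ims_neg_jitter_course",
            "ims_pos_block_course",
            "ims_neg_block_course",
        ):
            course = getattr(self, name)
            _require(len(course) >= 1, name, "course needs at least one knot")
            _require(
                all(v >= 0 for _, v in course),
                name,
                "course values must be non-negative",
            )
            hours = [h for h, _ in course]
            _require(hours == sorted(hours), name, "course knots must be sorted by hour")
        _require(
            0 <= self.transfer_delay_prob <= 1, "transfer_delay_prob", "must be in [0, 1]"
        )
        _require(
            0 <= self.death_prob_ims_pos <= 1, "death_prob_ims_pos", "must be in [0, 1]"
        )
        _require(self.extubation_noise_sd_h >= 0, "extubation_noise_sd_h", "must be >= 0")
        _require(self.seed == int(self.seed), "seed", "must be an integer")


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus the master seed."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    qualification: QualificationConfig = field(default_factory=QualificationConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    demo_signal_fibres: int = 8   # fibres run through the waveform tier by `run`

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "acquisition": AcquisitionConfig,
    "qualification": QualificationConfig,
    "metrics": MetricsConfig,
    "stats": StatsConfig,
    "cohort": CohortConfig,
}


def _build_section(cls: type, data: Mapping[str, Any], section: str) -> Any:
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            logger.warning("ignoring unknown config key %s.%s", section, key)
            continue
        f = known[key]
        # JSON has no tuples; coerce list-valued fields back.
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ConfigError as exc:
        raise ConfigError(f"{section}.{exc.args[0]}") from None
    except TypeError as exc:
        raise ConfigError(f"{section}: {exc}") from None


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a plain mapping.

    Omitted fields take the protocol defaults; unknown keys are logged and
    ignored; invalid values raise :class:`ConfigError` naming the field.
    """
    sections: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, Mapping):
                raise ConfigError(f"{key}: expected a JSON object")
            sections[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "seed":
            if not isinstance(value, int):
                raise ConfigError("seed: must be an integer")
            sections["seed"] = value
        elif key == "demo_signal_fibres":
            if not isinstance(value, int) or value < 0:
                raise ConfigError("demo_signal_fibres: must be a non-negative integer")
            sections["demo_signal_fibres"] = value
        else:
            logger.warning("ignoring unknown config key %s", key)
    return PipelineConfig(**sections)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a JSON file.

    An empty file or empty object yields all defaults (cap 200 us, cutoff
    33.4 us, 10/s stimulation, 100 sweeps, 20 fibres).
    """
    path = Path(path)
    text = path.read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, Mapping):
        raise ConfigError("top level: config must be a JSON object")
    return config_from_dict(data)


def interp_course(course: Sequence[tuple[float, float]], hours: float) -> float:
    """Interpolate a (hours, value) course at ``hours``.

    Interpolation is linear in log-value over hours (time courses here are
    decays spanning an order of magnitude), constant beyond the end knots.
    Zero-valued knots fall back to linear interpolation.
    """
    import numpy as np

    hs = np.asarray([h for h, _ in course], dtype=float)
    vs = np.asarray([v for _, v in course], dtype=float)
    if np.any(vs <= 0):
        return float(np.interp(hours, hs, vs))
    return float(np.exp(np.interp(hours, hs, np.log(vs))))
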