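"""Synthesis of stimulated single-fibre EMG recordings with known ground truth.

The generator realizes the stimulated protocol: a train of supra-threshold
stimuli at 10/s, 100 stimulus-locked sweeps per fibre.  Each responding sweep
contains one biphasic single-fibre action potential (SFAP) whose negative
peak occurs at ``mean_latency + N(0, jitter_sd)``; transmission failures are
Bernoulli(``block_prob``) and leave a noise-only sweep.  Waveforms and noise
are band-limited to the amplifier band (1-10 kHz by default).

Besides clean fibres the generator produces the recording-artifact classes an
electromyographer screens out: positive-going potentials (damaged fibres),
composites of two fibres, threshold-hovering stimulation (blocking with
normal jitter), sudden latency jumps (electrode movement), and overlapping
fibres at near-identical latency.  Ground truth (per-sweep latencies and
response flags) travels with every recording so downstream estimates can be
scored against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .config import AcquisitionConfig

__all__ = [
    "ArtifactClass",
    "FibreGroundTruth",
    "FibreRecording",
    "simulate_fibre",
    "simulate_session",
    "sample_ground_truth",
    "sfap_template",
    "band_limit",
]


class ArtifactClass(str, Enum):
    CLEAN = "clean"
    POSITIVE_GOING = "positive_going"
    COMPOSITE = "composite"
    THRESHOLD_HOVERING = "threshold_hovering"
    LATENCY_JUMP = "latency_jump"
    OVERLAPPING = "overlapping"


@dataclass
class FibreGroundTruth:
    """Latent parameters of one simulated muscle fibre.

    ``jitter_sd`` is the SD of the Gaussian latency noise whose downstream
    estimate is the MCD (E[MCD] = 2*sigma/sqrt(pi) for iid Gaussian
    latencies); ``block_prob`` is the per-stimulus transmission failure
    probability whose estimate is the blocking percentage.
    """

    mean_latency_us: float = 4000.0
    jitter_sd_us: float = 25.0
    block_prob: float = 0.0
    amplitude_uv: float = 300.0       # negative-peak magnitude
    rise_time_us: float = 150.0       # positive-peak -> negative-peak interval
    artifact_class: ArtifactClass = ArtifactClass.CLEAN

    def __post_init__(self) -> None:
        if self.jitter_sd_us < 0:
            raise ValueError("jitter_sd_us must be >= 0")
        if not 0.0 <= self.block_prob <= 1.0:
            raise ValueError("block_prob must be in [0, 1]")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude_uv must be > 0")
        if self.rise_time_us <= 0:
            raise ValueError("rise_time_us must be > 0")
        self.artifact_class = ArtifactClass(self.artifact_class)


@dataclass
class FibreRecording:
    """Stimulus-locked sweep matrix for one fibre plus acquisition metadata.

    ``sweeps`` is (n_sweeps, n_samples) in microvolts with the stimulus at
    t=0 of each row.  ``true_latencies_us`` / ``true_present`` carry the
    generator's ground truth (NaN latency where the response blocked);
    ``extras`` holds artifact-specific latent draws (companion latencies,
    jump location, ...).
    """

    sweeps: np.ndarray
    acquisition: AcquisitionConfig
    fibre_id: str = "f000"
    session_id: str = "s000"
    ground_truth: FibreGroundTruth | None = None
    true_latencies_us: np.ndarray | None = None
    true_present: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D (n_sweeps, n_samples) matrix")
        n_expected = self.acquisition.n_samples
        if self.sweeps.shape[1] != n_expected:
            raise ValueError(
                f"each sweep must have sweep_window x sample_rate = {n_expected} samples"
            )


def band_limit(
    x: np.ndarray,
    sample_rate_hz: float,
    highpass_hz: float,
    lowpass_hz: float,
) -> np.ndarray:
    """Zero-phase band-limiting of sweeps to [highpass_hz, lowpass_hz].

    Implemented as spectral masking with raised-cosine transitions placed
    *inside* the passband edges, so the returned signal carries essentially
    no energy outside the band (the generator synthesizes the amplifier's
    output rather than modelling its analog filter).  Operates on the last
    axis.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    mask = np.zeros_like(freqs)
    hp_hi = highpass_hz * 1.3
    lp_lo = lowpass_hz * 0.85
    inside = (freqs >= hp_hi) & (freqs <= lp_lo)
    mask[inside] = 1.0
    rising = (freqs >= highpass_hz) & (freqs < hp_hi)
    mask[rising] = 0.5 * (1 - np.cos(np.pi * (freqs[rising] - highpass_hz) / (hp_hi - highpass_hz)))
    falling = (freqs > lp_lo) & (freqs <= lowpass_hz)
    mask[falling] = 0.5 * (1 + np.cos(np.pi * (freqs[falling] - lp_lo) / (lowpass_hz - lp_lo)))
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * mask, n=n, axis=-1)


def sfap_template(
    t_us: np.ndarray,
    latency_us: float | np.ndarray,
    rise_time_us: float,
    amplitude_uv: float,
    sign: float = 1.0,
) -> np.ndarray:
    """Biphasic SFAP waveform: first derivative of a Gaussian.

    The positive lobe peaks ``rise_time_us`` before the negative peak, which
    sits at ``latency_us`` with magnitude ``amplitude_uv``.  ``sign=-1``
    flips the waveform (a positive-going potential, the signature of a
    damaged fibre).  Broadcasts over array-valued latencies.
    """
    s = rise_time_us / 2.0
    centre = np.asarray(latency_us) - s
    u = (t_us - np.atleast_1d(centre)[..., None]) / s
    w = -amplitude_uv * np.sqrt(np.e) * u * np.exp(-0.5 * u * u)
    out = sign * w
    if np.isscalar(latency_us):
        return out[0]
    return out


def sample_ground_truth(
    artifact_class: ArtifactClass | str,
    rng: Generator,
    acq: AcquisitionConfig | None = None,
) -> FibreGroundTruth:
    """Draw class-typical fibre parameters for QC validation studies.

    Latencies span the facial-muscle range (3-5.5 ms), amplitudes and rise
    times the range accepted by the selection criteria.  Threshold-hovering
    fibres get *normal* jitter (expected MCD below 33.4 us) with substantial
    blocking, which is exactly the combination the taxonomy rejects.
    """
    cls = ArtifactClass(artifact_class)
    common = dict(
        mean_latency_us=float(rng.uniform(3000, 5500)),
        amplitude_uv=float(rng.uniform(200, 500)),
        rise_time_us=float(rng.uniform(120, 200)),
        artifact_class=cls,
    )
    if cls is ArtifactClass.CLEAN:
        return FibreGroundTruth(jitter_sd_us=float(rng.uniform(15, 60)), block_prob=0.0, **common)
    if cls is ArtifactClass.POSITIVE_GOING:
        return FibreGroundTruth(jitter_sd_us=float(rng.uniform(15, 60)), block_prob=0.0, **common)
    if cls is ArtifactClass.COMPOSITE:
        return FibreGroundTruth(jitter_sd_us=float(rng.uniform(8, 20)), block_prob=0.0, **common)
    if cls is ArtifactClass.THRESHOLD_HOVERING:
        return FibreGroundTruth(
            jitter_sd_us=float(rng.uniform(5, 25)),
            block_prob=float(rng.uniform(0.1, 0.5)),
            **common,
        )
    if cls is ArtifactClass.LATENCY_JUMP:
        common["mean_latency_us"] = float(rng.uniform(3000, 4500))
        return FibreGroundTruth(jitter_sd_us=float(rng.uniform(15, 40)), block_prob=0.0, **common)
    if cls is ArtifactClass.OVERLAPPING:
        return FibreGroundTruth(jitter_sd_us=float(rng.uniform(35, 60)), block_prob=0.0, **common)
    raise ValueError(f"unknown artifact class {artifact_class!r}")


def _as_rng(seed: int | SeedSequence | Generator) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def simulate_fibre(
    truth: FibreGroundTruth,
    acq: AcquisitionConfig,
    seed: int | SeedSequence | Generator,
    fibre_id: str = "f000",
    session_id: str = "s000",
) -> FibreRecording:
    """Simulate the stimulus-locked sweep matrix of one fibre.

    Each sweep is either a band-limited SFAP at a jittered latency plus
    noise, or noise only where transmission blocked.  The artifact class
    modifies the waveform as documented on :class:`ArtifactClass`.  Raises
    ``ValueError`` if the potential could leave the sweep window
    (mean latency + 5 x jitter SD beyond the window).
    """
    rng = _as_rng(seed)
    window_us = acq.sweep_window_us
    margin = truth.rise_time_us + 500.0  # waveform tail must fit too
    if truth.mean_latency_us + 5.0 * truth.jitter_sd_us + margin > window_us:
        raise ValueError(
            "mean_latency + 5*jitter_sd (+ waveform extent) exceeds the sweep window"
        )
    if truth.mean_latency_us - 5.0 * truth.jitter_sd_us - margin < 0:
        raise ValueError("potential would precede the stimulus; lower jitter or raise latency")

    n_sweeps = acq.sweeps_per_fibre
    n_samples = acq.n_samples
    t_us = np.arange(n_samples) * acq.sample_period_us

    latencies = truth.mean_latency_us + truth.jitter_sd_us * rng.standard_normal(n_sweeps)
    blocked = rng.random(n_sweeps) < truth.block_prob
    extras: dict = {}

    cls = truth.artifact_class
    if cls is ArtifactClass.LATENCY_JUMP:
        lo = max(1, int(0.2 * n_sweeps))
        hi = max(lo + 1, int(0.8 * n_sweeps))
        jump_at = int(rng.integers(lo, hi))
        step = float(rng.uniform(600, 1500))
        # step direction chosen towards the window centre so the waveform stays inside
        if truth.mean_latency_us > window_us / 2:
            step = -step
        latencies[jump_at:] += step
        extras["jump_at_sweep"] = jump_at
        extras["jump_step_us"] = step

    sign = -1.0 if cls is ArtifactClass.POSITIVE_GOING else 1.0
    signal = sfap_template(t_us, latencies, truth.rise_time_us, truth.amplitude_uv, sign=sign)
    signal[blocked] = 0.0

    if cls in (ArtifactClass.COMPOSITE, ArtifactClass.OVERLAPPING):
        if cls is ArtifactClass.COMPOSITE:
            offset = float(rng.uniform(100, 400))
            comp_jitter = 15.0
        else:
            offset = float(rng.uniform(-50, 50))
            comp_jitter = truth.jitter_sd_us
        comp_amp = float(rng.uniform(0.6, 1.0) if cls is ArtifactClass.COMPOSITE else rng.uniform(0.7, 1.0))
        comp_lat = truth.mean_latency_us + offset + comp_jitter * rng.standard_normal(n_sweeps)
        comp = sfap_template(t_us, comp_lat, truth.rise_time_us, comp_amp * truth.amplitude_uv)
        comp[blocked] = 0.0
        signal = signal + comp
        extras.update(
            companion_offset_us=offset,
            companion_amplitude_uv=comp_amp * truth.amplitude_uv,
            companion_latencies_us=comp_lat,
        )

    signal = band_limit(signal, acq.sample_rate_hz, acq.highpass_hz, acq.lowpass_hz)

    if acq.noise_rms_uv > 0:
        noise = band_limit(
            rng.standard_normal((n_sweeps, n_samples)),
            acq.sample_rate_hz,
            acq.highpass_hz,
            acq.lowpass_hz,
        )
        noise *= acq.noise_rms_uv / max(noise.std(), 1e-12)
        signal = signal + noise

    lat_out = latencies.copy()
    lat_out[blocked] = np.nan
    return FibreRecording(
        sweeps=signal,
        acquisition=acq,
        fibre_id=fibre_id,
        session_id=session_id,
        ground_truth=truth,
        true_latencies_us=lat_out,
        true_present=~blocked,
        extras=extras,
    )


def simulate_session(
    truths: Sequence[FibreGroundTruth],
    acq: AcquisitionConfig,
    seed: int,
    session_id: str = "s000",
) -> list[FibreRecording]:
    """Simulate one patient visit: an independent recording per fibre truth.

    Random streams are derived per fibre from ``SeedSequence([seed, index])``
    so a fibre's sweeps do not depend on how many other fibres are recorded.
    """
    if len(truths) == 0:
        raise ValueError("need at least one fibre ground truth")
    recordings = []
    for i, truth in enumerate(truths):
        recordings.append(
            simulate_fibre(
                truth,
                acq,
                SeedSequence([int(seed), i]),
                fibre_id=f"f{i:03d}",
                session_id=session_id,
            )
        )
    return recordings
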