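"""Fibre-level jitter (MCD) and blocking quantification, caps and session summaries.

Jitter is the mean consecutive difference (MCD) of response latencies over
the sweep train; blocking is the percentage of stimuli without a response.
Extremely abnormal fibres -- jitter above the 200 us cap together with
blocking, including completely blocked fibres whose MCD is undefined -- are
capped at 200 us.  A patient-session is summarized by the median jitter and
median blocking over accepted fibres and called abnormal when the median
jitter exceeds the 33.4 us upper limit of the normal range (27-33.4 us).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import MetricsConfig

__all__ = [
    "InsufficientResponses",
    "FibreResult",
    "SessionSummary",
    "compute_mcd",
    "compute_blocking",
    "apply_cap",
    "summarize_session",
]


class InsufficientResponses(ValueError):
    """Fewer responses than the computation needs (MCD requires >= 2)."""


@dataclass
class FibreResult:
    """Jitter and blocking measurement for one fibre."""

    fibre_id: str
    mcd_us: float                  # 200 when capped; NaN never (cap covers full block)
    blocking_pct: float
    capped: bool
    n_responses: int
    accepted: bool = True
    n_spanning_pairs: int = 0      # consecutive-present pairs that straddle blocked sweeps

    def __post_init__(self) -> None:
        if not math.isnan(self.mcd_us) and self.mcd_us < 0:
            raise ValueError("mcd_us must be >= 0")
        if not 0.0 <= self.blocking_pct <= 100.0:
            raise ValueError("blocking_pct must be in [0, 100]")


@dataclass
class SessionSummary:
    """Per patient-visit summary over accepted fibres."""

    session_id: str
    patient_id: str
    hours_post_ingestion: float
    median_jitter_us: float
    median_blocking_pct: float
    abnormal: bool
    n_fibres_accepted: int
    jitter_iqr_us: tuple[float, float] = (float("nan"), float("nan"))
    blocking_iqr_pct: tuple[float, float] = (float("nan"), float("nan"))
    n_fibres_blocking: int = 0     # fibres with any blocking (the <2-in-20 normality rule)
    analysable: bool = True


def compute_mcd(latencies_us: Sequence[float]) -> float:
    """Mean consecutive difference of response latencies, in microseconds.

    MCD = (1/(n-1)) * sum |L_{i+1} - L_i| over the latencies in acquisition
    order.  For iid Gaussian latencies with SD sigma, E[MCD] = 2*sigma/sqrt(pi).
    """
    lat = np.asarray(latencies_us, dtype=float)
    if lat.ndim != 1:
        raise ValueError("latencies must be a 1-D sequence")
    if np.isnan(lat).any():
        raise ValueError("latencies must not contain NaN; drop absent sweeps first")
    if lat.size < 2:
        raise InsufficientResponses("MCD needs at least 2 response latencies")
    return float(np.mean(np.abs(np.diff(lat))))


def compute_blocking(present: Sequence[bool]) -> float:
    """Percentage of stimuli without a response: 100 x absent / total."""
    p = np.asarray(present, dtype=bool)
    if p.size == 0:
        raise ValueError("need at least one sweep")
    return float(100.0 * (p.size - p.sum()) / p.size)


def apply_cap(
    mcd_us: float | None,
    blocking_pct: float,
    cap_us: float = 200.0,
) -> tuple[float, bool]:
    """Cap extremely abnormal jitter-with-blocking results at ``cap_us``.

    Rules: jitter above the cap together with any blocking -> the cap;
    a fibre whose MCD is undefined because (nearly) every response blocked
    -> the cap; anything else passes through unchanged.
    """
    if not 0.0 <= blocking_pct <= 100.0:
        raise ValueError("blocking_pct must be in [0, 100]")
    if mcd_us is None or (isinstance(mcd_us, float) and math.isnan(mcd_us)):
        if blocking_pct > 0.0:
            return cap_us, True
        raise ValueError("MCD undefined without blocking: nothing to cap")
    if mcd_us > cap_us and blocking_pct > 0.0:
        return cap_us, True
    return float(mcd_us), False


def measure_fibre(
    fibre_id: str,
    latencies_us: Sequence[float],
    present: Sequence[bool],
    config: MetricsConfig | None = None,
    accepted: bool = True,
) -> FibreResult:
    """Full fibre measurement: MCD over present sweeps, blocking, cap.

    ``latencies_us`` holds one entry per sweep with NaN where absent;
    consecutive differences are taken between successive *present* sweeps.
    Pairs spanning blocked sweeps are counted and, when
    ``include_spanning_pairs`` is off, excluded from the MCD.
    """
    cfg = config or MetricsConfig()
    lat = np.asarray(latencies_us, dtype=float)
    pres = np.asarray(present, dtype=bool)
    if lat.shape != pres.shape:
        raise ValueError("latencies and presence must align sweep-for-sweep")
    blocking = compute_blocking(pres)
    idx = np.flatnonzero(pres)
    n_span = int(np.sum(np.diff(idx) > 1)) if idx.size >= 2 else 0
    if idx.size < 2:
        mcd, capped = apply_cap(None, blocking, cfg.cap_us) if blocking > 0 else (np.nan, False)
        return FibreResult(fibre_id, mcd, blocking, capped, int(idx.size), accepted, n_span)
    seq = lat[idx]
    diffs = np.abs(np.diff(seq))
    if not cfg.include_spanning_pairs:
        keep = np.diff(idx) == 1
        diffs = diffs[keep]
        if diffs.size == 0:
            mcd_val: float | None = None
        else:
            mcd_val = float(np.mean(diffs))
    else:
        mcd_val = float(np.mean(diffs))
    if mcd_val is None:
        mcd, capped = apply_cap(None, blocking, cfg.cap_us)
    else:
        mcd, capped = apply_cap(mcd_val, blocking, cfg.cap_us)
    return FibreResult(fibre_id, mcd, blocking, capped, int(idx.size), accepted, n_span)


def summarize_session(
    fibres: Sequence[FibreResult],
    session_id: str = "s000",
    patient_id: str = "p000",
    hours_post_ingestion: float = float("nan"),
    config: MetricsConfig | None = None,
) -> SessionSummary:
    """Median jitter / blocking over accepted fibres and the abnormality call.

    The abnormality rule is pluggable (``session_rule``): the default calls a
    session abnormal when the *median* accepted-fibre jitter exceeds the
    cutoff (strictly); ``any_fibre`` when any fibre exceeds it; ``fraction``
    when more than half do.  Sessions without accepted fibres are marked
    unanalysable.
    """
    cfg = config or MetricsConfig()
    acc = [f for f in fibres if f.accepted and not math.isnan(f.mcd_us)]
    if len(fibres) == 0:
        raise ValueError("need at least one fibre result")
    if not acc:
        return SessionSummary(
            session_id,
            patient_id,
            hours_post_ingestion,
            float("nan"),
            float("nan"),
            False,
            0,
            analysable=False,
        )
    mcds = np.array([f.mcd_us for f in acc])
    blocks = np.array([f.blocking_pct for f in acc])
    med_j = float(np.median(mcds))
    med_b = float(np.median(blocks))
    if cfg.session_rule == "median":
        abnormal = med_j > cfg.cutoff_us
    elif cfg.session_rule == "any_fibre":
        abnormal = bool(np.any(mcds > cfg.cutoff_us))
    else:  # fraction
        abnormal = bool(np.mean(mcds > cfg.cutoff_us) > 0.5)
    q1j, q3j = np.percentile(mcds, [25, 75])
    q1b, q3b = np.percentile(blocks, [25, 75])
    return SessionSummary(
        session_id,
        patient_id,
        hours_post_ingestion,
        med_j,
        med_b,
        abnormal,
        len(acc),
        (float(q1j), float(q3j)),
        (float(q1b), float(q3b)),
        n_fibres_blocking=int(sum(f.blocking_pct > 0 for f in acc)),
    )
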