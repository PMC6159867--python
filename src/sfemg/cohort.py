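"""Synthetic cohorts of organophosphate-poisoned patients with known ground truth.

The generator emulates a prospective cohort: every patient is labelled IMS+
(develops the intermediate syndrome, 24-96 h post ingestion) or IMS- at the
configured prevalence; stimulated-SfEMG sessions follow the clinical
schedule (first test within 24 h of ingestion unless the patient arrives as
a delayed transfer, then roughly every other day until discharge or death).

Each patient owns a severity multiplier applied to the group-level median
jitter and blocking time courses: the IMS+ course starts above the 200 us
cap (most fibres completely blocked) and recovers into the normal range by
~day 9, the IMS- course stays inside the 27-33.4 us normal band.  Session
measurements are realized at the *latency tier*: per-sweep response
latencies and presence flags are drawn from the same latent model the
waveform synthesizer uses, and fibre MCD / blocking / caps / session medians
are computed with the package's own metrics code.  This keeps whole-cohort
simulation cheap enough for repeated-seed studies while exercising the same
estimators as the waveform tier.

Clinical covariates: intubation (all IMS+, most IMS-), extubation (for
surviving intubated IMS+ patients: the realized jitter-normalization time
plus Gaussian noise, the dial behind the normalization-extubation
correlation), death for a fraction of IMS+ patients whose jitter never
recovers, and admission red-cell AChE drawn near-zero for IMS+.
"""
from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .config import CohortConfig, MetricsConfig, interp_course
from .metrics import measure_fibre, summarize_session
from .simulate import FibreGroundTruth

__all__ = ["simulate_cohort", "patient_fibre_truths"]


def _lognormal(rng: Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _patient_profile(cfg: CohortConfig, rng: Generator, pid: int) -> dict:
    """Draw one patient's latent clinical profile."""
    ims = bool(rng.random() < cfg.ims_prevalence)
    delayed = bool(rng.random() < cfg.transfer_delay_prob)
    lo, hi = cfg.delayed_first_range_h if delayed else cfg.first_session_range_h
    first_h = float(rng.uniform(lo, hi))
    if ims:
        severity = float(math.exp(cfg.severity_sigma_pos * rng.standard_normal()))
        died = bool(rng.random() < cfg.death_prob_ims_pos)
        death_h = _lognormal(rng, cfg.death_time_median_h, cfg.death_time_sigma) if died else math.inf
        relapse = died and (rng.random() < cfg.death_relapse_frac)
        discharge_h = _lognormal(rng, cfg.discharge_median_pos_h, cfg.discharge_sigma_pos)
        intubated = True
        intubation_h = _lognormal(rng, cfg.intubation_median_pos_h, cfg.intubation_sigma_pos)
        ache = float(rng.exponential(cfg.ache_pos_params[0]))
    else:
        relapse = False
        # late transfers to a tertiary centre skew sicker within the IMS- group
        z_sev = rng.standard_normal() + (cfg.transfer_severity_bias_neg if delayed else 0.0)
        severity = float(math.exp(cfg.severity_sigma_neg * z_sev))
        died = False
        death_h = math.inf
        # length of stay tracks severity: the IMS- patients still in hospital
        # at late time points are the near-boundary ones
        discharge_h = _lognormal(
            rng,
            cfg.discharge_median_neg_h * severity**cfg.stay_severity_exponent_neg,
            cfg.discharge_sigma_neg,
        )
        intubated = bool(rng.random() < cfg.intubation_prob_neg)
        intubation_h = (
            _lognormal(rng, cfg.intubation_median_neg_h, cfg.intubation_sigma_neg)
            if intubated
            else math.nan
        )
        p_zero, scale = cfg.ache_neg_params
        ache = 0.0 if rng.random() < p_zero else float(rng.exponential(scale))
    discharge_h = max(discharge_h, first_h + 2.0)
    return dict(
        patient_id=f"p{pid:03d}",
        ims_label=ims,
        severity=severity,
        died=died,
        relapse=relapse,
        death_h=death_h,
        discharge_h=discharge_h,
        intubated=intubated,
        intubation_h=intubation_h,
        first_session_h=first_h,
        ache_u_per_ghb=ache,
    )


def _death_phase(prof: dict, hours: float) -> str:
    """Fatal-course phase: relapse patients mimic recovery until shortly
    before death, the rest stay persistently abnormal."""
    if not prof["died"]:
        return "alive"
    if prof["relapse"] and hours < prof["death_h"] - 36.0:
        return "recovering"
    return "terminal"


def _target_jitter(cfg: CohortConfig, prof: dict, hours: float) -> float:
    """Patient's target median jitter (us) at ``hours`` post ingestion.

    IMS- targets are truncated at the normal cutoff by design (their
    trajectories never exceed 33.4 us).  Most fatal courses never recover
    (admission-level jitter persists until death); a configurable fraction
    declines like survivors and relapses to extreme values shortly before
    death, as described for a minority of fatal poisonings.
    """
    severity = prof["severity"]
    if prof["ims_label"]:
        phase = _death_phase(prof, hours)
        if phase == "terminal":
            t_eff = min(hours, max(prof["first_session_h"], 24.0))
            base = interp_course(cfg.ims_pos_jitter_course, t_eff) * severity
            return max(base, 120.0)
        taper = min(1.0, interp_course(cfg.severity_taper, hours))
        base = interp_course(cfg.ims_pos_jitter_course, hours) * severity**taper
        return max(base, cfg.normal_jitter_mean_us)
    base = interp_course(cfg.ims_neg_jitter_course, hours) * severity
    return min(base, cfg.cutoff_us)


def _target_block(cfg: CohortConfig, prof: dict, hours: float) -> float:
    severity = prof["severity"]
    if prof["ims_label"]:
        phase = _death_phase(prof, hours)
        if phase == "terminal":
            t_eff = min(hours, max(prof["first_session_h"], 24.0))
            return min(0.98, interp_course(cfg.ims_pos_block_course, t_eff) * severity)
        return min(0.98, interp_course(cfg.ims_pos_block_course, hours) * severity)
    return min(0.5, interp_course(cfg.ims_neg_block_course, hours) * severity)


def patient_fibre_truths(
    cfg: CohortConfig,
    target_jitter_us: float,
    target_block: float,
    rng: Generator,
) -> list[FibreGroundTruth]:
    """Draw per-fibre ground truths realizing a session's target medians.

    Fibre jitter SDs scatter lognormally around ``target / (2/sqrt(pi))`` so
    the median fibre MCD tracks the target; when blocking is severe a
    matching fraction of fibres blocks completely (the day-1 picture in
    severe poisoning: median fibre blocking of 100%).
    """
    mcd_factor = 2.0 / math.sqrt(math.pi)
    truths = []
    for _ in range(cfg.fibres_per_session):
        jit = (
            target_jitter_us
            / mcd_factor
            * math.exp(cfg.fibre_sigma * rng.standard_normal())
        )
        p_full = float(np.clip((target_block - 0.5) * 1.6, 0.0, 0.9))
        if rng.random() < p_full:
            bp = 1.0
        else:
            bp = float(
                np.clip(target_block * math.exp(cfg.block_fibre_sigma * rng.standard_normal()), 0.0, 0.98)
            )
        truths.append(
            FibreGroundTruth(
                mean_latency_us=cfg.mean_latency_us,
                jitter_sd_us=max(jit, 1.0),
                block_prob=bp,
            )
        )
    return truths


def _realize_session(
    cfg: CohortConfig,
    truths: Iterable[FibreGroundTruth],
    rng: Generator,
    session_id: str,
    patient_id: str,
    hours: float,
    mcfg: MetricsConfig,
) -> tuple[object, list[dict]]:
    """Latency-tier realization: draw latencies/presence, measure fibres."""
    fibre_rows = []
    results = []
    for i, tr in enumerate(truths):
        lat = tr.mean_latency_us + tr.jitter_sd_us * rng.standard_normal(cfg.sweeps_per_fibre)
        present = rng.random(cfg.sweeps_per_fibre) >= tr.block_prob
        lat_masked = lat.copy()
        lat_masked[~present] = np.nan
        res = measure_fibre(f"{session_id}-f{i:03d}", lat_masked, present, mcfg)
        results.append(res)
        fibre_rows.append(
            dict(
                fibre_id=res.fibre_id,
                session_id=session_id,
                patient_id=patient_id,
                gt_jitter_sd_us=tr.jitter_sd_us,
                gt_block_prob=tr.block_prob,
                mcd_us=res.mcd_us,
                blocking_pct=res.blocking_pct,
                capped=res.capped,
                n_responses=res.n_responses,
            )
        )
    summary = summarize_session(
        results, session_id, patient_id, hours_post_ingestion=hours, config=mcfg
    )
    return summary, fibre_rows


def simulate_cohort(
    cfg: CohortConfig | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a full cohort; returns ``patients``, ``sessions``, ``fibres`` tables.

    Randomness is derived per patient from ``SeedSequence([seed, patient])``
    so adding patients does not perturb existing ones.  The patients table
    carries the latent profile (``gt_``-prefixed columns) next to observables
    so downstream estimates can be validated against the generator.
    """
    cfg = cfg or CohortConfig()
    if seed is None:
        seed = cfg.seed
    seed = int(seed)
    mcfg = MetricsConfig(cap_us=cfg.cap_us, cutoff_us=cfg.cutoff_us)

    patient_rows, session_rows, fibre_rows = [], [], []
    for pid in range(cfg.n_patients):
        rng = default_rng(SeedSequence([seed, pid]))
        prof = _patient_profile(cfg, rng, pid)
        end_h = min(prof["discharge_h"], prof["death_h"])

        hours = prof["first_session_h"]
        times = []
        while hours <= end_h:
            times.append(hours)
            gap = max(
                cfg.schedule_gap_min_h,
                rng.normal(cfg.schedule_gap_mean_h, cfg.schedule_gap_sd_h),
            )
            hours += gap
        if not times:
            times = [prof["first_session_h"]]

        norm_h = math.nan
        for si, t in enumerate(times):
            tj = _target_jitter(cfg, prof, t)
            tb = _target_block(cfg, prof, t)
            sid = f"{prof['patient_id']}-s{si:02d}"
            truths = patient_fibre_truths(cfg, tj, tb, rng)
            summary, rows = _realize_session(
                cfg, truths, rng, sid, prof["patient_id"], t, mcfg
            )
            fibre_rows.extend(rows)
            session_rows.append(
                dict(
                    session_id=sid,
                    patient_id=prof["patient_id"],
                    hours_post_ingestion=t,
                    median_jitter_us=summary.median_jitter_us,
                    median_blocking_pct=summary.median_blocking_pct,
                    abnormal=summary.abnormal,
                    n_fibres_accepted=summary.n_fibres_accepted,
                    n_fibres_blocking=summary.n_fibres_blocking,
                    gt_target_jitter_us=tj,
                    gt_target_block=tb,
                )
            )
            if math.isnan(norm_h) and summary.analysable and not summary.abnormal:
                norm_h = t

        extub_h = math.nan
        if prof["intubated"] and not prof["died"]:
            if prof["ims_label"]:
                if not math.isnan(norm_h):
                    extub_h = norm_h + rng.normal(0.0, cfg.extubation_noise_sd_h)
                else:
                    extub_h = prof["discharge_h"] - rng.uniform(12.0, 36.0)
                extub_h = max(extub_h, prof["intubation_h"] + 6.0)
            else:
                extub_h = prof["intubation_h"] + _lognormal(
                    rng, cfg.extubation_offset_neg_h, 0.5
                )
                extub_h = min(extub_h, prof["discharge_h"])

        patient_rows.append(
            dict(
                patient_id=prof["patient_id"],
                ims_label=prof["ims_label"],
                intubated=prof["intubated"],
                died=prof["died"],
                ingestion_time_h=0.0,
                intubation_h=prof["intubation_h"],
                extubation_time_h=extub_h,
                death_h=prof["death_h"] if prof["died"] else math.nan,
                discharge_h=prof["discharge_h"],
                first_session_h=prof["first_session_h"],
                normalization_h=norm_h,
                ache_u_per_ghb=prof["ache_u_per_ghb"],
                gt_severity=prof["severity"],
            )
        )

    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id", "ims_label", "intubated", "died", "ingestion_time_h",
            "intubation_h", "extubation_time_h", "death_h", "discharge_h",
            "first_session_h", "normalization_h", "ache_u_per_ghb", "gt_severity",
        ],
    )
    sessions = pd.DataFrame(
        session_rows,
        columns=[
            "session_id", "patient_id", "hours_post_ingestion", "median_jitter_us",
            "median_blocking_pct", "abnormal", "n_fibres_accepted",
            "n_fibres_blocking", "gt_target_jitter_us", "gt_target_block",
        ],
    )
    fibres = pd.DataFrame(
        fibre_rows,
        columns=[
            "fibre_id", "session_id", "patient_id", "gt_jitter_sd_us",
            "gt_block_prob", "mcd_us", "blocking_pct", "capped", "n_responses",
        ],
    )
    return {"patients": patients, "sessions": sessions, "fibres": fibres}
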