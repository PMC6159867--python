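"""End-to-end pipeline: simulate -> qualify -> analyze -> cohort statistics.

``run_pipeline`` ties the stages together and writes all artifacts plus a
run manifest (config, seed, package version) so a run is reproducible from
the manifest alone.  The cohort stage works on the latency-tier cohort
tables; a configurable handful of fibres additionally flows through the
full waveform tier (synthesis, per-sweep detection, qualification, fibre
metrics) to exercise the signal chain on every run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import __version__
from .cohort import simulate_cohort
from .config import MetricsConfig, PipelineConfig
from .io import write_cohort_tables, write_fibre_csv, write_json
from .metrics import measure_fibre, summarize_session
from .qualify import qualify_fibre
from .simulate import FibreGroundTruth, simulate_session
from .stats import (
    build_diagnostic_table,
    diagnostic_accuracy,
    normalization_extubation_correlation,
    rank_sum_compare,
    time_to_normalization,
    window_comparisons,
)

logger = logging.getLogger("sfemg")

__all__ = ["run_pipeline", "analyze_recordings", "cohort_statistics", "normalization_pairs"]


def analyze_recordings(recordings, qual_config, metrics_config) -> tuple[pd.DataFrame, object]:
    """Qualify and measure a list of fibre recordings from one session.

    Returns the per-fibre results table and the session summary computed
    over accepted fibres (complete-block fibres count as accepted and enter
    at the cap).
    """
    rows = []
    results = []
    session_id = recordings[0].session_id if recordings else "s000"
    for rec in recordings:
        qc, measurements = qualify_fibre(rec, qual_config)
        present = np.array([m.present for m in measurements], dtype=bool)
        lat = np.array(
            [m.peak_latency_us if m.present else math.nan for m in measurements]
        )
        accepted = qc.verdict == "accepted"
        res = measure_fibre(rec.fibre_id, lat, present, metrics_config, accepted=accepted)
        results.append(res)
        rows.append(
            dict(
                fibre_id=rec.fibre_id,
                session_id=rec.session_id,
                verdict=qc.verdict,
                reasons=";".join(sorted(r.value for r in qc.reasons)),
                complete_block=qc.complete_block,
                n_present=qc.n_present,
                mcd_us=res.mcd_us,
                blocking_pct=res.blocking_pct,
                capped=res.capped,
            )
        )
    summary = summarize_session(results, session_id=session_id, config=metrics_config)
    counts = pd.Series([r["verdict"] for r in rows]).value_counts().to_dict()
    logger.info("session %s qualification: %s", session_id, counts)
    return pd.DataFrame(rows), summary


def normalization_pairs(patients: pd.DataFrame, sessions: pd.DataFrame) -> tuple[list, int]:
    """(normalization, extubation) pairs for intubated patients.

    A patient contributes a pair when intubated, with an observed extubation
    and at least one normal session; others with an abnormal-only course or
    death are censored.
    """
    pairs = []
    censored = 0
    for _, pat in patients[patients["intubated"].astype(bool)].iterrows():
        psess = sessions[sessions["patient_id"] == pat["patient_id"]].sort_values(
            "hours_post_ingestion"
        )
        if psess.empty:
            continue
        t_norm, cens = time_to_normalization(psess)
        if cens or not np.isfinite(pat["extubation_time_h"]):
            censored += 1
            continue
        pairs.append((t_norm, float(pat["extubation_time_h"])))
    return pairs, censored


def cohort_statistics(tables: dict[str, pd.DataFrame], stats_config) -> dict:
    """All cohort-level results as a JSON-ready dict."""
    patients, sessions = tables["patients"], tables["sessions"]
    out: dict = {"n_patients": int(len(patients))}
    if patients.empty or sessions.empty:
        out["note"] = "empty cohort: no statistics computed"
        return out

    try:
        table = build_diagnostic_table(
            sessions, patients, stats_config.cutoff_us, stats_config.prediction_window_h
        )
        acc = diagnostic_accuracy(table)
        out["diagnostic_table"] = dict(tp=table.tp, fn=table.fn, fp=table.fp, tn=table.tn)
        out["diagnostic"] = dict(
            sensitivity_pct=acc.sensitivity_pct,
            specificity_pct=acc.specificity_pct,
            odds_ratio=acc.odds_ratio,
            or_ci_low=acc.or_ci_low,
            or_ci_high=acc.or_ci_high,
            p_value=acc.p_value,
        )
    except ValueError as exc:
        out["diagnostic"] = {"error": str(exc)}

    wins = window_comparisons(
        sessions, patients, stats_config.windows_h, stats_config.alpha
    )
    out["windows"] = [
        dict(
            window_h=list(w.window_h),
            n_pos=w.n_pos,
            n_neg=w.n_neg,
            u=None if math.isnan(w.statistic_u) else w.statistic_u,
            p_value=w.p_value,
            significant=w.significant_after_correction,
        )
        for w in wins
    ]

    pairs, censored = normalization_pairs(patients, sessions)
    if len(pairs) >= 3:
        corr = normalization_extubation_correlation(pairs, censored)
        out["normalization_extubation"] = dict(
            n_pairs=corr.n_pairs, n_censored=corr.n_censored, r=corr.r, p_value=corr.p_value
        )
    else:
        out["normalization_extubation"] = {"error": "fewer than 3 uncensored pairs"}

    ims = patients["ims_label"].astype(bool)
    ache_pos = patients.loc[ims, "ache_u_per_ghb"].to_numpy()
    ache_neg = patients.loc[~ims, "ache_u_per_ghb"].to_numpy()
    if ache_pos.size and ache_neg.size:
        u, p = rank_sum_compare(ache_pos, ache_neg)
        out["ache_comparison"] = dict(
            median_pos=float(np.median(ache_pos)),
            median_neg=float(np.median(ache_neg)),
            u=u,
            p_value=p,
        )
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run simulate -> qualify -> analyze -> cohort-stats, writing artifacts.

    Writes cohort tables (CSV), demo waveform-tier fibres (CSV + sidecars),
    per-fibre qualification results, ``results.json`` and ``manifest.json``.
    Identical seeds yield byte-identical results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        tables = simulate_cohort(config.cohort, seed=config.seed)
        write_cohort_tables(tables, out_dir)

        results: dict = {"seed": config.seed}
        if config.demo_signal_fibres > 0:
            stage = "qualify"
            rng = default_rng(SeedSequence([config.seed, 101]))
            truths = [
                FibreGroundTruth(jitter_sd_us=float(rng.uniform(15, 60)))
                for _ in range(config.demo_signal_fibres)
            ]
            acq = config.acquisition
            recs = simulate_session(truths, acq, seed=config.seed, session_id="demo")
            demo_dir = out_dir / "demo_fibres"
            for rec in recs:
                write_fibre_csv(rec, demo_dir)
            stage = "analyze"
            fibre_df, summary = analyze_recordings(
                recs, config.qualification, config.metrics
            )
            fibre_df.to_csv(out_dir / "demo_fibre_results.csv", index=False, lineterminator="\n")
            results["demo_session"] = dict(
                median_jitter_us=summary.median_jitter_us,
                median_blocking_pct=summary.median_blocking_pct,
                abnormal=summary.abnormal,
                n_fibres_accepted=summary.n_fibres_accepted,
            )

        stage = "cohort-stats"
        results["cohort"] = cohort_statistics(tables, config.stats)
        write_json(out_dir / "results.json", results)

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "sfemg_version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        write_json(out_dir / "manifest.json", manifest)
        return results
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}")
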