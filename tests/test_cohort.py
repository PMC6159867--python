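"""Cohort generator: prevalence, trajectories, schedules, covariates."""
import numpy as np
import pytest
from scipy.stats import binom

from sfemg.cohort import simulate_cohort
from sfemg.config import CohortConfig
from sfemg.pipeline import normalization_pairs
from sfemg.stats import build_diagnostic_table, diagnostic_accuracy


def test_identical_seed_identical_cohort():
    a = simulate_cohort(CohortConfig(n_patients=15), seed=5)
    b = simulate_cohort(CohortConfig(n_patients=15), seed=5)
    for key in a:
        assert a[key].equals(b[key])


def test_adding_patients_preserves_existing_ones():
    small = simulate_cohort(CohortConfig(n_patients=10), seed=4)
    large = simulate_cohort(CohortConfig(n_patients=12), seed=4)
    assert small["patients"].equals(large["patients"].iloc[:10].reset_index(drop=True))


def test_prevalence_within_binomial_ci():
    cfg = CohortConfig(n_patients=200)
    t = simulate_cohort(cfg, seed=3)
    lo, hi = binom.interval(0.95, 200, cfg.ims_prevalence)
    assert lo <= t["patients"]["ims_label"].sum() <= hi


def test_zero_prevalence_trajectories_stay_normal():
    t = simulate_cohort(CohortConfig(n_patients=30, ims_prevalence=0.0), seed=2)
    assert not t["patients"]["ims_label"].any()
    assert t["sessions"]["gt_target_jitter_us"].max() <= 33.4 + 1e-9


def test_day1_ims_pos_median_at_cap():
    """The IMS+ group median jitter within 24 h sits at the 200 us cap."""
    t = simulate_cohort(CohortConfig(), seed=7)
    ses = t["sessions"].merge(t["patients"][["patient_id", "ims_label"]], on="patient_id")
    d1 = ses[ses.hours_post_ingestion < 24].sort_values("hours_post_ingestion")
    first = d1.groupby("patient_id").first()
    assert first[first.ims_label]["median_jitter_us"].median() == pytest.approx(200.0)
    # and near-complete blocking in the same sessions
    assert first[first.ims_label]["median_blocking_pct"].median() >= 90.0


def test_first_sessions_within_24h_unless_delayed_transfer():
    cfg = CohortConfig(n_patients=60, transfer_delay_prob=0.0)
    t = simulate_cohort(cfg, seed=1)
    assert t["patients"]["first_session_h"].max() < 24.0


def test_schedule_roughly_every_other_day():
    t = simulate_cohort(CohortConfig(n_patients=40), seed=6)
    gaps = (
        t["sessions"]
        .sort_values(["patient_id", "hours_post_ingestion"])
        .groupby("patient_id")["hours_post_ingestion"]
        .diff()
        .dropna()
    )
    assert gaps.min() >= 20.0
    assert 36.0 <= gaps.mean() <= 60.0


def test_empty_cohort_tables():
    t = simulate_cohort(CohortConfig(n_patients=0), seed=1)
    for key in ("patients", "sessions", "fibres"):
        assert len(t[key]) == 0 and len(t[key].columns) > 0


def test_fibre_truth_columns_support_recovery():
    """Measured fibre MCD tracks the generated jitter SD (2/sqrt(pi) factor)."""
    t = simulate_cohort(CohortConfig(n_patients=20), seed=9)
    f = t["fibres"]
    clean = f[(f.gt_block_prob < 0.05) & (f.gt_jitter_sd_us < 80)].dropna(subset=["mcd_us"])
    assert len(clean) > 100
    ratio = clean["mcd_us"] / clean["gt_jitter_sd_us"]
    assert ratio.mean() == pytest.approx(2 / np.sqrt(np.pi), rel=0.05)


def test_simulated_sensitivity_matches_generator_rate():
    """Diagnostic sensitivity equals the generator's day-1 IMS+ abnormality
    rate (the configured targets are all far above the cutoff on day 1)."""
    cfg = CohortConfig(n_patients=200)
    t = simulate_cohort(cfg, seed=11)
    table = build_diagnostic_table(t["sessions"], t["patients"])
    res = diagnostic_accuracy(table)
    n_pos = table.tp + table.fn
    target_rate = 1.0  # every IMS+ day-1 target exceeds the cutoff by design
    lo, hi = binom.interval(0.95, n_pos, max(target_rate - 0.02, 0.0))
    assert lo <= table.tp <= n_pos
    assert res.sensitivity_pct >= 95.0


def test_extubation_only_for_intubated_survivors():
    t = simulate_cohort(CohortConfig(n_patients=120), seed=13)
    pat = t["patients"]
    died = pat[pat.died]
    assert died["extubation_time_h"].isna().all()
    not_intub = pat[~pat.intubated.astype(bool)]
    assert not_intub["extubation_time_h"].isna().all()
    pairs, censored = normalization_pairs(pat, t["sessions"])
    assert len(pairs) >= 3 and censored >= 0


def test_invalid_cohort_config():
    from sfemg.config import ConfigError

    with pytest.raises(ConfigError):
        CohortConfig(ims_prevalence=1.5)
    with pytest.raises(ConfigError):
        CohortConfig(n_patients=-1)
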