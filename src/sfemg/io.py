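"""File formats for recordings, results and cohort tables.

Sweep matrices are written one CSV per fibre (header row = sample times in
ms, one row per sweep, values in microvolts) with a JSON sidecar holding the
acquisition settings, identifiers and - for synthetic data - the ground
truth.  Cohort tables are plain CSV with units embedded in the column names
(``mcd_us``, ``blocking_pct``, ``hours_post_ingestion``); missing values are
empty fields, all files UTF-8 with LF line endings.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .simulate import ArtifactClass, FibreGroundTruth, FibreRecording

__all__ = [
    "write_fibre_csv",
    "read_fibre_csv",
    "write_cohort_tables",
    "read_cohort_tables",
    "write_json",
    "read_json",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, ArtifactClass):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_fibre_csv(recording: FibreRecording, directory: str | Path) -> Path:
    """Write one fibre's sweep matrix as CSV plus a JSON metadata sidecar.

    Returns the CSV path; the sidecar shares the stem with suffix ``.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.session_id}_{recording.fibre_id}"
    csv_path = directory / f"{stem}.csv"
    acq = recording.acquisition
    times_ms = np.arange(acq.n_samples) / acq.sample_rate_hz * 1e3
    header = ",".join(f"{t:.6g}" for t in times_ms)
    np.savetxt(csv_path, recording.sweeps, delimiter=",", header=header, comments="", fmt="%.6g")
    meta = {
        "fibre_id": recording.fibre_id,
        "session_id": recording.session_id,
        "acquisition": _jsonable(recording.acquisition),
        "ground_truth": _jsonable(recording.ground_truth) if recording.ground_truth else None,
        "true_latencies_us": _jsonable(recording.true_latencies_us),
        "true_present": _jsonable(
            recording.true_present.astype(int) if recording.true_present is not None else None
        ),
    }
    write_json(directory / f"{stem}.json", meta)
    return csv_path


def read_fibre_csv(csv_path: str | Path) -> FibreRecording:
    """Read a fibre recording written by :func:`write_fibre_csv`."""
    csv_path = Path(csv_path)
    sweeps = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    meta = read_json(csv_path.with_suffix(".json"))
    acq = AcquisitionConfig(**meta["acquisition"])
    gt = None
    if meta.get("ground_truth"):
        gt = FibreGroundTruth(**meta["ground_truth"])
    lat = meta.get("true_latencies_us")
    lat_arr = (
        np.array([math.nan if v is None else v for v in lat], dtype=float)
        if lat is not None
        else None
    )
    pres = meta.get("true_present")
    pres_arr = np.array(pres, dtype=bool) if pres is not None else None
    return FibreRecording(
        sweeps=sweeps,
        acquisition=acq,
        fibre_id=meta["fibre_id"],
        session_id=meta["session_id"],
        ground_truth=gt,
        true_latencies_us=lat_arr,
        true_present=pres_arr,
    )


_TABLE_FILES = {"patients": "patients.csv", "sessions": "sessions.csv", "fibres": "fibres.csv"}


def write_cohort_tables(tables: dict[str, pd.DataFrame], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in _TABLE_FILES.items():
        if name in tables:
            tables[name].to_csv(directory / fname, index=False, lineterminator="\n")


def read_cohort_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    out = {}
    for name, fname in _TABLE_FILES.items():
        path = directory / fname
        if path.exists():
            out[name] = pd.read_csv(path)
    return out
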