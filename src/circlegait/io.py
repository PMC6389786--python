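"""Plain-text readers and writers for trials, segmentations and cohorts.

Trial CSVs carry the header ``time_s,acc_vt,acc_ml,acc_ap`` preceded by
optional ``#``-prefixed metadata lines (``# direction=...``,
``# medication=...``, ``# bounds=start,end``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import AccelTrial, StepSegmentation

__all__ = ["read_accel_csv", "write_segmentation_csv", "read_cohort_csv"]

TRIAL_COLUMNS = ("time_s", "acc_vt", "acc_ml", "acc_ap")


def read_accel_csv(path: str | Path) -> AccelTrial:
    """Read a trial CSV, validating header, row shape and timestamp grid."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" in line:
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    header = [c.strip() for c in lines[body_start].strip().split(",")]
    missing = [c for c in TRIAL_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    data = {c: [] for c in header}
    for ln, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.strip().split(",")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{ln}: expected {len(header)} fields, got {len(parts)}")
        try:
            for c, p in zip(header, parts):
                data[c].append(float(p))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed value ({exc})") from None

    time = np.asarray(data["time_s"])
    if time.size >= 2:
        dt = np.diff(time)
        if (np.abs(dt - dt[0]) > 1e-6).any():
            raise ValueError(f"{path}: non-uniform timestamps beyond 1e-6 s tolerance")
    bounds = (0, time.size)
    if "bounds" in meta:
        a, b = (int(v) for v in meta["bounds"].split(","))
        bounds = (a, b)
    return AccelTrial(
        time=time,
        acc_vt=np.asarray(data["acc_vt"]),
        acc_ml=np.asarray(data["acc_ml"]),
        acc_ap=np.asarray(data["acc_ap"]),
        direction=meta.get("direction", "clockwise"),
        medication=meta.get("medication", "NA"),
        trial_bounds=bounds,
    )


def write_segmentation_csv(path: str | Path, seg: StepSegmentation) -> None:
    onsets = seg.step_onsets
    df = pd.DataFrame(
        {
            "onset_sample": onsets[:-1] if onsets.size else [],
            "onset_time_s": seg.onset_times[:-1] if onsets.size else [],
            "step_duration_s": seg.step_durations,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing column(s) {sorted(missing)}")
    return df
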