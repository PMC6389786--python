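"""Realignment, offset removal and template-matching step segmentation.

A trial arrives with a quiet-standing prefix.  Three operations convert it
into an analysable form:

1. :func:`realign_axes` removes static sensor misalignment by the rigid
   rotation that takes the mean standing acceleration vector onto +VT.
2. :func:`remove_initial_offset` subtracts the mean of the first 20 samples
   from each axis, which also removes the gravity offset on VT.
3. :func:`segment_step_cycles` detects step onsets on the AP axis with an
   iterative template-matching scheme seeded by the dominant step frequency.

:func:`validate_segmentation` quantifies agreement between a detected
segmentation and reference step-onset times via the mean absolute
stride-duration difference and ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import G, AccelTrial, StepSegmentation

__all__ = [
    "realign_axes",
    "remove_initial_offset",
    "segment_step_cycles",
    "validate_segmentation",
    "SegmentationAgreement",
]

#: Frequency band (Hz) searched for the dominant step frequency.
STEP_FREQ_BAND = (1.2, 3.5)
#: Normalised cross-correlation threshold for accepting an onset.
NCC_THRESHOLD = 0.3
#: Maximum template refinement iterations.
MAX_TEMPLATE_ITER = 5
#: Peak-to-median PSD power ratio below which no dominant frequency exists.
DOMINANCE_RATIO = 5.0


def _standing_window(trial: AccelTrial) -> slice:
    start = trial.trial_bounds[0]
    if start < trial.sample_rate:  # need >= 1 s of standing
        raise ValueError("trial must carry at least 1 s of standing before the walking bounds")
    return slice(0, start)


def realign_axes(trial: AccelTrial) -> AccelTrial:
    """Rotate all samples so the mean standing acceleration points along +VT.

    The rotation is the minimal rigid rotation (axis = cross product of the
    mean vector with +VT, angle = their separation), so per-sample vector
    norms are preserved.  A standing mean whose magnitude is outside
    [0.5 g, 1.5 g] signals bad calibration and raises.
    """
    win = _standing_window(trial)
    mean_vec = trial.axes()[win].mean(axis=0)
    mag = float(np.linalg.norm(mean_vec))
    if not (0.5 * G <= mag <= 1.5 * G):
        raise ValueError(f"standing mean magnitude {mag:.2f} m/s^2 outside [0.5g, 1.5g]: bad calibration")
    u = mean_vec / mag
    target = np.array([1.0, 0.0, 0.0])  # +VT
    axis = np.cross(u, target)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, target))
    if s < 1e-12:
        if c > 0:
            return trial  # already aligned
        # antiparallel: rotate 180 degrees about ML
        R = np.diag([-1.0, 1.0, -1.0])
    else:
        k = axis / s
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(np.arccos(np.clip(c, -1, 1))) * K + (1 - c) * (K @ K)
    rotated = trial.axes() @ R.T
    return trial.with_axes(rotated[:, 0], rotated[:, 1], rotated[:, 2])


def remove_initial_offset(trial: AccelTrial) -> AccelTrial:
    """Subtract the mean of the first 20 samples (standing) from each axis."""
    if trial.n_samples < 20:
        raise ValueError("need at least 20 samples for offset removal")
    return trial.with_axes(
        trial.acc_vt - trial.acc_vt[:20].mean(),
        trial.acc_ml - trial.acc_ml[:20].mean(),
        trial.acc_ap - trial.acc_ap[:20].mean(),
    )


def _dominant_step_frequency(ap: np.ndarray, fs: float) -> float | None:
    """Welch-PSD peak in the step-frequency band, or None when no peak dominates."""
    nper = min(len(ap), 900)
    freqs, pxx = sps.welch(ap - ap.mean(), fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, nfft=max(9000, nper), detrend=False)
    band = (freqs >= STEP_FREQ_BAND[0]) & (freqs <= STEP_FREQ_BAND[1])
    p = pxx[band]
    if p.size == 0 or p.max() <= 0:
        return None
    med = np.median(pxx[freqs <= 10.0])
    if med <= 0 or p.max() / med < DOMINANCE_RATIO:
        return None
    return float(freqs[band][int(np.argmax(p))])


def _normalized_xcorr(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding zero-mean normalised cross-correlation of ``template`` along ``x``.

    Output[i] is the NCC of ``x[i:i+L]`` with the template, in [-1, 1].
    """
    L = template.size
    t = template - template.mean()
    t_norm = np.linalg.norm(t)
    if t_norm < 1e-12:
        return np.zeros(x.size - L + 1)
    win = np.lib.stride_tricks.sliding_window_view(x, L)
    wm = win.mean(axis=1, keepdims=True)
    wc = win - wm
    denom = np.linalg.norm(wc, axis=1) * t_norm
    num = wc @ t
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 1e-12, num / denom, 0.0)
    return ncc


def _anchor_to_rising_zero(template: np.ndarray) -> np.ndarray:
    """Circularly shift a cyclic template so it starts at its steepest upward
    zero-crossing.

    Template matching alone locks onsets to an arbitrary waveform phase; an
    onset at step-phase fraction c contaminates every stride duration with
    c times the local stride-time change.  Anchoring the template at a
    canonical landmark (the sharp AP rise, the initial-contact convention)
    pins that phase to the cycle boundary.
    """
    t = template - template.mean()
    nxt = np.roll(t, -1)
    rising = (t <= 0) & (nxt > 0)
    if not rising.any():
        return template
    slopes = np.where(rising, nxt - t, -np.inf)
    return np.roll(template, -int(np.argmax(slopes)))


def _mean_cycle_template(x: np.ndarray, onsets: np.ndarray) -> np.ndarray | None:
    """Pointwise mean of the cycles between consecutive onsets, each resampled
    to the median cycle length, anchored at its steepest upward zero-crossing."""
    lengths = np.diff(onsets)
    lengths = lengths[lengths > 1]
    if lengths.size < 2:
        return None
    target = int(np.median(lengths))
    cycles = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a < 2:
            continue
        seg = x[a:b]
        cycles.append(np.interp(np.linspace(0, seg.size - 1, target), np.arange(seg.size), seg))
    if len(cycles) < 2:
        return None
    return _anchor_to_rising_zero(np.mean(cycles, axis=0))


def segment_step_cycles(trial: AccelTrial) -> StepSegmentation:
    """Detect step onsets on the AP axis by iterative template matching.

    The dominant step frequency seeds a peak-picking pass; the mean step
    cycle forms a template whose normalised cross-correlation against the AP
    signal yields refined onsets (threshold 0.3, minimum separation half a
    step period); the template is re-formed from the detected cycles until
    the onset count stabilises or 5 iterations elapse.  Failures (white
    noise, too few onsets) are flagged on the returned segmentation instead
    of raising.
    """
    start, end = trial.trial_bounds
    fs = trial.sample_rate
    ap = trial.acc_ap[start:end]
    if ap.size < 3 * fs:
        return StepSegmentation(np.empty(0, int), fs, failed=True, reason="walking portion shorter than 3 s")

    f_step = _dominant_step_frequency(ap, fs)
    if f_step is None:
        return StepSegmentation(np.empty(0, int), fs, failed=True, reason="no dominant step frequency in band")
    min_sep = max(int(round(0.5 / f_step * fs)), 2)

    # initial candidates: raw AP peaks at least half a step period apart
    cand, _ = sps.find_peaks(ap, distance=min_sep)
    if cand.size < 4:
        return StepSegmentation(np.empty(0, int), fs, failed=True, reason="fewer than 4 candidate onsets")

    onsets = cand
    for _ in range(MAX_TEMPLATE_ITER):
        template = _mean_cycle_template(ap, onsets)
        if template is None:
            return StepSegmentation(np.empty(0, int), fs, failed=True, reason="could not form step template")
        ncc = _normalized_xcorr(ap, template)
        new_onsets, _ = sps.find_peaks(ncc, height=NCC_THRESHOLD, distance=min_sep)
        if new_onsets.size < 4:
            return StepSegmentation(np.empty(0, int), fs, failed=True, reason="fewer than 4 onsets detected")
        stable = new_onsets.size == onsets.size
        onsets = new_onsets
        if stable:
            break
    return StepSegmentation(onsets + start, fs)


@dataclass
class SegmentationAgreement:
    """Agreement between an estimated and a reference stride-duration series."""

    mean_abs_diff_ms: float
    mean_abs_diff_pct: float  # as % of the mean reference stride duration
    icc: float
    n_matched: int
    count_mismatch: bool = False  # onset counts differ by more than 20%


def _icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    import pingouin as pg

    n = a.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["est", "ref"], n),
        "value": np.concatenate([a, b]),
    })
    res = pg.intraclass_corr(data=df, targets="target", raters="rater", ratings="value")
    # two-way random effects, absolute agreement, single measurement
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def validate_segmentation(estimated: StepSegmentation, reference_onsets: np.ndarray) -> SegmentationAgreement:
    """Compare estimated stride durations with ground-truth onset times.

    Each estimated onset is matched to the nearest reference onset; stride
    durations (alternate-onset differences) are then paired through that
    matching.  Requires at least 3 matched strides.
    """
    if estimated.failed:
        raise ValueError(f"cannot validate a failed segmentation: {estimated.reason}")
    ref = np.sort(np.asarray(reference_onsets, dtype=float))
    est_t = estimated.onset_times
    if est_t.size < 5 or ref.size < 5:
        raise ValueError("need at least 3 strides (5 onsets) on both sides")

    match = np.searchsorted(ref, est_t)
    match = np.clip(match, 1, ref.size - 1)
    match = np.where(np.abs(ref[match] - est_t) < np.abs(ref[match - 1] - est_t), match, match - 1)

    est_strides, ref_strides = [], []
    for i in range(est_t.size - 2):
        j = match[i]
        if j + 2 < ref.size and match[i + 2] == j + 2:
            est_strides.append(est_t[i + 2] - est_t[i])
            ref_strides.append(ref[j + 2] - ref[j])
    est_s = np.asarray(est_strides)
    ref_s = np.asarray(ref_strides)
    if est_s.size < 3:
        raise ValueError("fewer than 3 matched strides")

    diff_ms = float(np.mean(np.abs(est_s - ref_s)) * 1000.0)
    pct = diff_ms / (float(np.mean(ref_s)) * 1000.0) * 100.0
    icc = 1.0 if np.allclose(est_s, ref_s) else _icc_2_1(est_s, ref_s)
    n_est, n_ref = est_t.size, ref.size
    mismatch = abs(n_est - n_ref) > 0.2 * n_ref
    return SegmentationAgreement(diff_ms, pct, icc, est_s.size, mismatch)
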