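"""The 24 gait characteristics computed from a segmented walking trial.

All features are computed on the raw, unfiltered walking portion of the
trial (no band-pass filtering anywhere in the chain).  Temporal features
come from the step segmentation; amplitude and rhythmicity features from
the acceleration series themselves; spectral features from a Welch power
spectral density with a 900-sample Hanning window, 50% overlap and a
9000-point FFT (0.0111 Hz resolution at 100 Hz sampling).

Conventions that matter:

* Left/right leg identity is unobservable from a single lower-back sensor;
  "right vs left" step asymmetry is operationalised as odd- vs even-indexed
  steps.
* Harmonic ratios use amplitudes at exact integer multiples of the stride
  frequency, obtained by direct evaluation of the Fourier coefficient over
  an integer number of strides (no spectral-bin snapping): even/odd for VT
  and AP (biphasic per stride), odd/even for ML (monophasic per stride).
* The index of harmonicity uses the step frequency as fundamental for VT
  and AP and the stride frequency for ML, mirroring the same parity logic.
* Stride-time variability is the SD after trimming ceil(0.05 n) values from
  each tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import FEATURE_NAMES, AccelTrial, GaitFeatureVector, StepSegmentation

__all__ = [
    "PsdEstimate",
    "welch_psd",
    "temporal_counts",
    "step_time_asymmetry",
    "stride_time_stats",
    "signal_sd",
    "cyclic_regularity",
    "harmonic_ratio",
    "index_of_harmonicity",
    "spectral_peak_features",
    "extract_feature_vector",
    "average_directions",
]

WELCH_WINDOW = 900
WELCH_OVERLAP = 0.5
WELCH_NFFT = 9000
PEAK_BAND = (0.3, 5.0)  # Hz, search band for the dominant spectral peak
HARMONIC_COUNT = 20  # harmonics of the stride frequency used for HR
IH_HARMONICS = 6
IH_BAND_HZ = 0.15  # half-width of the search band around each harmonic
HR_CAP = 1e6  # reported when the denominator sum underflows


@dataclass
class PsdEstimate:
    """One-sided Welch PSD with the fixed spectral settings."""

    freqs: np.ndarray
    power: np.ndarray
    window_len: int
    overlap: float
    nfft: int
    sample_rate: float
    single_segment: bool = False  # signal shorter than one full window

    @property
    def resolution(self) -> float:
        return self.sample_rate / self.nfft


def welch_psd(x: np.ndarray, sample_rate: float = 100.0) -> PsdEstimate:
    """Welch PSD: Hanning window of 900 samples, 50% overlap, 9000-point FFT.

    Signals shorter than one window fall back to a single flagged segment;
    below 300 samples the spectrum is uninterpretable and this raises.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 300:
        raise ValueError(f"signal too short for spectral analysis: {x.size} samples")
    nper = min(x.size, WELCH_WINDOW)
    freqs, power = sps.welch(
        x - x.mean(),
        fs=sample_rate,
        window="hann",
        nperseg=nper,
        noverlap=int(nper * WELCH_OVERLAP),
        nfft=max(WELCH_NFFT, nper),
        detrend=False,
    )
    return PsdEstimate(freqs, power, nper, WELCH_OVERLAP, max(WELCH_NFFT, nper),
                       sample_rate, single_segment=nper < WELCH_WINDOW)


def temporal_counts(seg: StepSegmentation, trial: AccelTrial) -> tuple[int, float]:
    """Number of detected steps and the walking duration in seconds."""
    start, end = trial.trial_bounds
    return seg.n_steps, (end - start) / trial.sample_rate


def step_time_asymmetry(seg: StepSegmentation) -> float:
    """|mean(odd-indexed step durations) - mean(even-indexed step durations)|."""
    d = seg.step_durations
    if d.size < 4:
        raise ValueError("step-time asymmetry needs at least 4 steps")
    return float(abs(d[1::2].mean() - d[0::2].mean()))


def trimmed_sd(values: np.ndarray, trim: float = 0.05) -> float:
    """Descriptive (population) SD after removing ceil(trim*n) values from
    each tail.  The population form keeps trimming monotone: dropping the
    extremes can never increase the reported spread, which the ddof=1 form
    does not guarantee (its shrinking denominator can dominate)."""
    v = np.sort(np.asarray(values, dtype=float))
    k = math.ceil(trim * v.size)
    kept = v[k : v.size - k] if v.size > 2 * k else v
    return float(np.std(kept)) if kept.size > 1 else 0.0


def stride_time_stats(seg: StepSegmentation) -> tuple[float, float]:
    """Median stride time and the 5%-trimmed SD of stride durations."""
    s = seg.stride_durations
    if s.size < 5:
        raise ValueError("stride-time statistics need at least 5 strides")
    return float(np.median(s)), trimmed_sd(s)


def signal_sd(trial: AccelTrial) -> dict[str, float]:
    """Per-axis sample SD over the walking portion ('movement intensity')."""
    return {ax: float(np.std(trial.walking(ax), ddof=1)) for ax in ("vt", "ml", "ap")}


def cyclic_regularity(x: np.ndarray, period_s: float, sample_rate: float = 100.0) -> float:
    """Normalised unbiased autocovariance at a lag of one period.

    c(k) = sum (x_t - xbar)(x_{t+k} - xbar) / (N - k), normalised by the
    population variance; the value returned is the maximum over lags within
    +-10% of ``period_s`` (robust to one-sample quantisation of the period).
    The unbiased normalisation can overshoot 1 slightly; the overshoot is
    reported, not clipped.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lag0 = int(round(period_s * sample_rate))
    lo, hi = int(math.floor(lag0 * 0.9)), int(math.ceil(lag0 * 1.1))
    if hi >= n // 2:
        raise ValueError("regularity lag window exceeds half the series length")
    xc = x - x.mean()
    var = float(np.mean(xc**2))
    if var < 1e-24:
        raise ValueError("zero-variance signal has undefined regularity")
    best = -np.inf
    for k in range(max(lo, 1), hi + 1):
        c = float(np.dot(xc[:-k], xc[k:]) / (n - k))
        best = max(best, c / var)
    return best


def _fourier_amplitude(x: np.ndarray, freq: float, sample_rate: float) -> float:
    """Amplitude of the Fourier coefficient of ``x`` at an arbitrary frequency."""
    n = x.size
    t = np.arange(n) / sample_rate
    coeff = np.sum(x * np.exp(-2j * np.pi * freq * t)) / n
    return 2.0 * abs(coeff)


def harmonic_ratio(x: np.ndarray, median_stride_time: float, axis: str,
                   sample_rate: float = 100.0) -> float:
    """Ratio of summed even- to odd-harmonic amplitudes of the stride frequency.

    VT and AP accelerations are biphasic per stride, so their rhythmicity is
    carried by the even harmonics and HR = sum(even)/sum(odd); ML is
    monophasic per stride and the ratio is inverted.  Amplitudes of
    harmonics 1..20 are evaluated directly at k times the stride frequency
    over an integer number of strides starting at the segment origin.
    """
    x = np.asarray(x, dtype=float)
    f0 = 1.0 / median_stride_time
    stride_samples = median_stride_time * sample_rate
    m = int(x.size // stride_samples)
    if m < 5:
        raise ValueError("harmonic ratio needs at least 5 strides of signal")
    seg = x[: int(round(m * stride_samples))]
    seg = seg - seg.mean()
    amps = np.array([
        _fourier_amplitude(seg, k * f0, sample_rate) for k in range(1, HARMONIC_COUNT + 1)
    ])
    even, odd = amps[1::2].sum(), amps[0::2].sum()
    num, den = (even, odd) if axis in ("vt", "ap") else (odd, even)
    if den < 1e-12:
        return HR_CAP
    return float(num / den)


def index_of_harmonicity(psd: PsdEstimate, fundamental: float) -> float:
    """Fundamental-peak PSD over the cumulative PSD of the first six harmonics.

    ``fundamental`` is the step frequency for VT/AP and the stride frequency
    for ML.  Each harmonic's power is the PSD maximum within +-0.15 Hz of
    the harmonic frequency; harmonics beyond the Nyquist band are dropped.
    """
    powers = []
    for i in range(1, IH_HARMONICS + 1):
        f = i * fundamental
        if f > psd.freqs[-1]:
            break
        band = (psd.freqs >= f - IH_BAND_HZ) & (psd.freqs <= f + IH_BAND_HZ)
        if not band.any():
            break
        powers.append(float(psd.power[band].max()))
    if not powers or sum(powers) <= 0:
        raise ValueError("no harmonic power found for index of harmonicity")
    return powers[0] / sum(powers)


def spectral_peak_features(psd: PsdEstimate) -> tuple[float, float]:
    """Normalised peak power (1/Hz) and FWHM width (Hz) of the dominant peak.

    The dominant peak is the PSD maximum in the 0.3-5 Hz locomotion band;
    its magnitude is normalised by the trapezoid-integrated PSD over the
    full band, and its width is the full width at half maximum found by
    linear interpolation on each flank.
    """
    band = (psd.freqs >= PEAK_BAND[0]) & (psd.freqs <= PEAK_BAND[1])
    if not band.any():
        raise ValueError("empty dominant-peak search band")
    p_band = psd.power[band]
    if not np.all(np.isfinite(p_band)):
        raise ValueError("non-finite PSD in the search band")
    i_local = int(np.argmax(p_band))
    i_peak = np.flatnonzero(band)[i_local]
    peak = float(psd.power[i_peak])
    total = float(np.trapezoid(psd.power, psd.freqs))
    if total <= 0:
        raise ValueError("degenerate PSD: zero integrated power")
    half = peak / 2.0

    def _cross(direction: int) -> float:
        i = i_peak
        while 0 < i < psd.freqs.size - 1 and psd.power[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= psd.freqs.size:
            return psd.freqs[i]
        f0, f1 = psd.freqs[i], psd.freqs[j]
        p0, p1 = psd.power[i], psd.power[j]
        if p0 == p1:
            return f0
        return f0 + (half - p0) / (p1 - p0) * (f1 - f0)

    width = _cross(+1) - _cross(-1)
    return peak / total, float(max(width, psd.resolution))


def extract_feature_vector(trial: AccelTrial, seg: StepSegmentation | None = None) -> GaitFeatureVector:
    """Compute the full 24-feature vector from a preprocessed trial.

    ``seg`` may be supplied (e.g. ground-truth onsets in simulation
    studies); otherwise the template-matching segmentation is run.  Features
    whose preconditions fail are set to NaN and flagged rather than
    aborting the whole vector.
    """
    from .preprocess import segment_step_cycles

    if seg is None:
        seg = segment_step_cycles(trial)
    values: dict[str, float] = {k: float("nan") for k in FEATURE_NAMES}
    flags: dict[str, str] = {}
    if seg.failed:
        return GaitFeatureVector(values, {"segmentation": seg.reason})
    fs = trial.sample_rate

    n_steps, total_dur = temporal_counts(seg, trial)
    values["n_steps"] = float(n_steps)
    values["total_duration"] = total_dur

    def _try(names, fn):
        try:
            result = fn()
        except ValueError as exc:
            for nm in names:
                flags[nm] = str(exc)
            return
        if len(names) == 1:
            values[names[0]] = float(result)
        else:
            for nm, v in zip(names, result):
                values[nm] = float(v)

    _try(["step_time_asymmetry"], lambda: step_time_asymmetry(seg))
    _try(["median_stride_time", "stride_time_variability"], lambda: stride_time_stats(seg))

    sds = signal_sd(trial)
    for ax in ("vt", "ml", "ap"):
        values[f"sd_{ax}"] = sds[ax]

    med_stride = values["median_stride_time"]
    if np.isnan(med_stride):
        med_stride = float(np.median(seg.stride_durations)) if seg.stride_durations.size else float("nan")
    med_step = med_stride / 2.0

    walking = {ax: trial.walking(ax) - trial.walking(ax).mean() for ax in ("vt", "ml", "ap")}
    for ax in ("vt", "ap"):
        _try([f"step_regularity_{ax}"], lambda ax=ax: cyclic_regularity(walking[ax], med_step, fs))
        _try([f"stride_regularity_{ax}"], lambda ax=ax: cyclic_regularity(walking[ax], med_stride, fs))
    for ax in ("vt", "ml", "ap"):
        _try([f"harmonic_ratio_{ax}"], lambda ax=ax: harmonic_ratio(walking[ax], med_stride, ax, fs))

    for ax in ("vt", "ml", "ap"):
        try:
            psd = welch_psd(walking[ax], fs)
        except ValueError as exc:
            for stem in ("index_harmonicity", "norm_peak_power", "width_peak_power"):
                flags[f"{stem}_{ax}"] = str(exc)
            continue
        if psd.single_segment:
            flags.setdefault("psd", "single-segment Welch fallback (signal shorter than 900 samples)")
        fundamental = (2.0 if ax in ("vt", "ap") else 1.0) / med_stride
        _try([f"index_harmonicity_{ax}"], lambda psd=psd, f=fundamental: index_of_harmonicity(psd, f))
        _try([f"norm_peak_power_{ax}", f"width_peak_power_{ax}"], lambda psd=psd: spectral_peak_features(psd))

    return GaitFeatureVector(values, flags)


def average_directions(v_cw: GaitFeatureVector, v_ccw: GaitFeatureVector) -> GaitFeatureVector:
    """Arithmetic mean of the clockwise and counter-clockwise feature vectors.

    A feature flagged in one direction falls back to the other direction's
    value (kept flagged); flagged in both stays NaN.
    """
    values: dict[str, float] = {}
    flags = dict(v_cw.flags)
    flags.update(v_ccw.flags)
    for name in FEATURE_NAMES:
        a, b = v_cw.values[name], v_ccw.values[name]
        if np.isnan(a) and np.isnan(b):
            values[name] = float("nan")
        elif np.isnan(a):
            values[name] = b
        elif np.isnan(b):
            values[name] = a
        else:
            values[name] = (a + b) / 2.0
    return GaitFeatureVector(values, flags)
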