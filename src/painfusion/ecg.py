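"""ECG preprocessing and per-second heart-rate extraction.

QRS detection follows the classic Pan–Tompkins recipe: band-pass filtering
(5–15 Hz), differentiation, squaring, and moving-window integration (150 ms),
followed by adaptive dual-threshold peak decision with search-back for missed
beats and T-wave discrimination.  Beat timing then yields inter-beat
intervals (IBIs); the mean IBI mu (in samples) converts to heart rate via
HR = 60 * fs / mu.  Per-second heart rate is computed on consecutive 1-s
segments with a neighbour-mean fill rule for segments where fewer than two
usable beats make the IBI undefined.

Filtering is zero-phase (forward-backward) so detected R indices stay on the
raw signal's time axis.  All indices are 0-based; intervals are in samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ECGSignal",
    "RPeakSeries",
    "IBISummary",
    "HeartRateSeries",
    "InsufficientBeatsError",
    "UnrecoverableRecordError",
    "pan_tompkins_preprocess",
    "detect_r_peaks",
    "compute_mean_ibi",
    "compute_heart_rate",
    "hr_per_second",
    "read_ecg_csv",
    "write_hr_csv",
]

# Pan-Tompkins constants (original algorithm's choices)
_BAND = (5.0, 15.0)          # Hz pass-band
_INTEGRATION_S = 0.150       # moving-window integration length
_REFRACTORY_S = 0.200        # minimum beat spacing
_TWAVE_S = 0.360             # T-wave discrimination window
_THR_UPDATE = 0.125          # running-estimate update coefficient


class InsufficientBeatsError(ValueError):
    """Fewer than two R peaks: the mean IBI is undefined."""


class UnrecoverableRecordError(ValueError):
    """No 1-s segment yielded a heart-rate value."""


@dataclass
class ECGSignal:
    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class RPeakSeries:
    indices: np.ndarray
    fs: float
    empty_warning: bool = False

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)


@dataclass
class IBISummary:
    intervals: np.ndarray   # samples between consecutive R peaks
    n: int
    mu: float               # mean IBI in samples


@dataclass
class HeartRateSeries:
    values: np.ndarray       # BPM per 1-second segment
    filled_mask: np.ndarray  # True where the value came from the fill rule


# ---------------------------------------------------------------------------
# Pan-Tompkins stages
# ---------------------------------------------------------------------------

def pan_tompkins_preprocess(ecg: ECGSignal):
    """Return the four intermediate signals of the preprocessing chain.

    band-passed, derivative, squared, and moving-window-integrated signals,
    all with the same length as the input.
    """
    if ecg.fs < 30:
        raise ValueError("sampling frequency too low for the 5-15 Hz pass-band")
    x = ecg.samples
    nyq = ecg.fs / 2.0
    b, a = sps.butter(2, [_BAND[0] / nyq, _BAND[1] / nyq], btype="band")
    padlen = min(3 * (max(len(a), len(b)) - 1), len(x) - 1)
    bandpassed = sps.filtfilt(b, a, x, padlen=padlen)

    # five-point derivative (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]) scaled by fs
    dkernel = np.array([2, 1, 0, -1, -2]) * (ecg.fs / 8.0)
    derivative = np.convolve(np.pad(bandpassed, 2, mode="edge"), dkernel[::-1],
                             mode="valid")
    squared = derivative**2
    win = max(int(round(_INTEGRATION_S * ecg.fs)), 1)
    integrated = np.convolve(np.pad(squared, (win - 1, 0), mode="edge"),
                             np.ones(win) / win, mode="valid")
    # centre the integration delay so peaks align with the QRS
    shift = win // 2
    if shift:
        integrated = np.concatenate(
            [integrated[shift:], np.full(shift, integrated[-1])])
    return bandpassed, derivative, squared, integrated


def detect_r_peaks(ecg: ECGSignal) -> RPeakSeries:
    """Adaptive-threshold QRS detection on the integrated signal.

    Candidates are local maxima of the moving-window-integrated signal;
    running signal/noise levels set the detection threshold; a search-back at
    half threshold recovers missed beats when more than 1.66x the running RR
    average elapses; candidates within 360 ms whose band-passed slope is less
    than half the previous accepted slope are rejected as T waves; a 200 ms
    refractory period is always enforced.  Accepted peaks are refined to the
    local maximum of the band-passed signal.
    """
    if ecg.duration < 2.0:
        raise ValueError("record must be at least 2 s long for QRS detection")
    bandpassed, derivative, _, integrated = pan_tompkins_preprocess(ecg)
    fs = ecg.fs
    refractory = int(round(_REFRACTORY_S * fs))
    twave_win = int(round(_TWAVE_S * fs))

    padded = np.concatenate([[-np.inf], integrated, [-np.inf]])
    cand, _ = sps.find_peaks(padded, distance=max(refractory // 2, 1))
    cand = cand - 1  # boundary maxima stay detectable
    if len(cand) == 0 or np.ptp(integrated) < 1e-12:
        return RPeakSeries(indices=np.array([], dtype=int), fs=fs,
                           empty_warning=True)

    # initialise levels from the first 2 s
    head = integrated[: int(2 * fs)]
    spki = 0.25 * head.max()
    npki = 0.5 * head.mean()

    def slope_at(i: int) -> float:
        lo, hi = max(i - refractory // 2, 0), min(i + refractory // 2 + 1, len(derivative))
        return float(np.abs(derivative[lo:hi]).max())

    accepted: list[int] = []
    rr_avg = None

    def accept(i: int, value: float):
        nonlocal spki, rr_avg
        accepted.append(i)
        spki = _THR_UPDATE * value + (1 - _THR_UPDATE) * spki
        if len(accepted) >= 2:
            rr = np.diff(accepted[-9:])
            nonlocal_rr = float(np.mean(rr))
            return nonlocal_rr
        return None

    for i in cand:
        threshold = npki + 0.25 * (spki - npki)
        if accepted and i - accepted[-1] < refractory:
            continue
        if integrated[i] > threshold:
            # T-wave discrimination: close to previous beat with weak slope
            if accepted and i - accepted[-1] < twave_win:
                if slope_at(i) < 0.5 * slope_at(accepted[-1]):
                    npki = _THR_UPDATE * integrated[i] + (1 - _THR_UPDATE) * npki
                    continue
            new_rr = accept(i, integrated[i])
            if new_rr is not None:
                rr_avg = new_rr
        else:
            npki = _THR_UPDATE * integrated[i] + (1 - _THR_UPDATE) * npki
            # search-back: expected beat window elapsed without detection
            if accepted and rr_avg and (i - accepted[-1]) > 1.66 * rr_avg:
                lo = accepted[-1] + refractory
                window = [j for j in cand if lo <= j <= i]
                if window:
                    j = max(window, key=lambda j: integrated[j])
                    if integrated[j] > 0.5 * threshold:
                        new_rr = accept(j, integrated[j])
                        if new_rr is not None:
                            rr_avg = new_rr

    if not accepted:
        return RPeakSeries(indices=np.array([], dtype=int), fs=fs,
                           empty_warning=True)

    # refine each beat to the band-passed local maximum
    refined = []
    half = refractory // 2
    for i in accepted:
        lo, hi = max(i - half, 0), min(i + half + 1, len(bandpassed))
        refined.append(lo + int(np.argmax(np.abs(bandpassed[lo:hi]))))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement
    keep = [0]
    for k in range(1, len(refined)):
        if refined[k] - refined[keep[-1]] >= refractory:
            keep.append(k)
    return RPeakSeries(indices=refined[keep], fs=fs)


# ---------------------------------------------------------------------------
# IBI and heart rate
# ---------------------------------------------------------------------------

def compute_mean_ibi(peaks: RPeakSeries) -> IBISummary:
    """Mean inter-beat interval in samples: mu = (1/n) sum(RR_{i+1} - RR_i)."""
    idx = np.asarray(peaks.indices, dtype=float)
    if len(idx) < 2:
        raise InsufficientBeatsError("need at least 2 R peaks to form an IBI")
    intervals = np.diff(idx)
    return IBISummary(intervals=intervals, n=len(intervals),
                      mu=float(intervals.mean()))


def compute_heart_rate(ibi: IBISummary, fs: float) -> float:
    """HR = 60 * fs / mu, in beats per minute."""
    if ibi.mu <= 0:
        raise ValueError("mean IBI must be positive")
    return 60.0 * fs / ibi.mu


def hr_per_second(ecg: ECGSignal, window_s: float | None = None,
                  peaks: RPeakSeries | None = None) -> HeartRateSeries:
    """Per-second heart rate with the neighbour-mean fill rule.

    The record is split into ``floor(window_s)`` consecutive 1-s segments.
    R peaks are detected once on the whole record; a peak belongs to segment
    k when its index falls in ``[k*fs, (k+1)*fs)``, and the first peak after
    the segment is included so the IBI bracketing the boundary contributes to
    the earlier segment.  Segments with fewer than two usable peaks are
    filled with the mean of the nearest preceding and following computed
    values (single nearest value at the boundaries).
    """
    if window_s is None:
        window_s = ecg.duration
    if window_s < 2:
        raise ValueError("window must be at least 2 s (fill rule needs neighbours)")
    if ecg.duration + 1e-9 < window_s:
        raise ValueError("record shorter than the requested window")
    theta = int(np.floor(window_s))
    if peaks is None:
        peaks = detect_r_peaks(ECGSignal(ecg.samples[: int(round(window_s * ecg.fs))],
                                         ecg.fs))
    idx = np.asarray(peaks.indices)

    values = np.full(theta, np.nan)
    for k in range(theta):
        lo, hi = k * ecg.fs, (k + 1) * ecg.fs
        inside = idx[(idx >= lo) & (idx < hi)]
        if len(inside) == 0:
            continue
        after = idx[idx >= hi]
        usable = np.concatenate([inside, after[:1]]) if len(after) else inside
        if len(usable) < 2:
            continue
        values[k] = compute_heart_rate(
            compute_mean_ibi(RPeakSeries(indices=usable, fs=ecg.fs)), ecg.fs)

    filled = np.isnan(values)
    if filled.all():
        raise UnrecoverableRecordError("no segment produced a heart-rate value")
    computed = np.flatnonzero(~filled)
    for k in np.flatnonzero(filled):
        before = computed[computed < k]
        after = computed[computed > k]
        if len(before) and len(after):
            values[k] = 0.5 * (values[before[-1]] + values[after[0]])
        elif len(before):
            values[k] = values[before[-1]]
        else:
            values[k] = values[after[0]]
    return HeartRateSeries(values=values, filled_mask=filled)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ecg_csv(path: str | Path, fs: float) -> ECGSignal:
    """Read a two-column (sample_index, amplitude) CSV."""
    df = pd.read_csv(path)
    col = df.columns[-1]
    return ECGSignal(samples=df[col].to_numpy(dtype=float), fs=fs)


def write_hr_csv(series: HeartRateSeries, path: str | Path) -> None:
    pd.DataFrame({
        "second_index": np.arange(len(series.values)),
        "bpm": series.values,
        "filled_flag": series.filled_mask.astype(int),
    }).to_csv(path, index=False)
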