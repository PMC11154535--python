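"""Heart-rate proxy from green-channel micro-variation (video PPG).

Blood-volume changes modulate skin color slightly; averaged over a patch of
body pixels the green channel carries a periodic component at the pulse
frequency.  The stages are:

1. ``green_trace`` — mean green value H(t) over a square region C of side
   ``gamma_px`` centered on the centroid G(t); frames with no valid centroid
   or with mask area below the alpha_th gate yield gaps (NaN).
2. ``bandpass`` — zero-phase 2nd-order Butterworth bandpass, default
   passband 4.76-7.14 Hz (285-428 beats/min, the resting pulse band of a
   small rodent).  Gaps are bridged by linear interpolation before
   filtering and re-masked after, so filter transients never fabricate beats.
3. ``find_peaks_mountain_climbing`` — windowed strict local maxima with a
   minimum spacing of one period of the upper cutoff frequency.
4. ``heart_rate`` — per-frame rate series h(t) = t_h / T from inter-peak
   intervals T, held constant between peaks (causal zero-order hold).
   With the scaling constant t_h (default 0.7 s) h counts beats per
   t_h-second window; the raw frequency 1/T in Hz is h / t_h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, lfilter

from .config import ConfigError


@dataclass
class CardiacParams:
    gamma_px: int                 # side of region C, px
    fl: float = 4.76              # lower cutoff, Hz
    fh: float = 7.14              # upper cutoff, Hz
    fs: float = 60.0              # frame rate, Hz
    t_h: float = 0.7              # rate scaling constant, s
    order: int = 2                # effective bandpass order
    zero_phase: bool = True       # forward-backward filtering

    def __post_init__(self) -> None:
        if self.gamma_px <= 0:
            raise ConfigError("gamma_px must be positive")
        if not (0 < self.fl < self.fh < self.fs / 2):
            raise ConfigError(
                f"need 0 < fl < fh < fs/2, got fl={self.fl}, fh={self.fh}, "
                f"fs={self.fs}")
        if self.t_h <= 0:
            raise ConfigError("t_h must be positive")


@dataclass
class CardiacTrace:
    raw: np.ndarray               # H(t), NaN in gaps
    filtered: np.ndarray          # bandpassed, NaN in gaps
    peaks: np.ndarray             # peak times, s, strictly increasing
    intervals: np.ndarray         # T_i = t_i - t_{i-1}, s
    rate: np.ndarray              # h(t) per frame, NaN where undefined
    params: CardiacParams

    def to_frame(self) -> pd.DataFrame:
        n = len(self.raw)
        t = np.arange(n)
        is_peak = np.zeros(n, dtype=bool)
        idx = np.round(self.peaks * self.params.fs).astype(int)
        is_peak[idx[(idx >= 0) & (idx < n)]] = True
        return pd.DataFrame({"t": t, "H_raw": self.raw,
                             "H_filtered": self.filtered, "is_peak": is_peak,
                             "h": self.rate,
                             "valid": ~np.isnan(self.raw)})


def mean_green_patch(frame: np.ndarray, centroid: Sequence[float],
                     gamma_px: int) -> float:
    """Mean green value over the gamma_px-sided square centered at the
    centroid, clipped to the frame bounds."""
    h, w = frame.shape[:2]
    cx, cy = float(centroid[0]), float(centroid[1])
    half = gamma_px / 2.0
    x0, x1 = int(max(0, round(cx - half))), int(min(w, round(cx + half)))
    y0, y1 = int(max(0, round(cy - half))), int(min(h, round(cy + half)))
    if x1 <= x0 or y1 <= y0:
        return math.nan
    return float(np.asarray(frame[y0:y1, x0:x1, 1], dtype=np.float64).mean())


def green_trace(frames: Sequence[np.ndarray],
                centroids: Sequence[Optional[Sequence[float]]],
                gamma_px: int,
                areas: Optional[Sequence[float]] = None,
                alpha_th: float = 0.0) -> np.ndarray:
    """Raw trace H(t); NaN where the centroid is invalid or area < alpha_th."""
    if gamma_px <= 0:
        raise ConfigError("gamma_px must be positive")
    out = []
    for i, (frame, c) in enumerate(zip(frames, centroids)):
        gated = areas is not None and areas[i] < alpha_th
        if c is None or gated:
            out.append(math.nan)
        else:
            out.append(mean_green_patch(frame, c, gamma_px))
    return np.asarray(out, dtype=np.float64)


def _bridge_gaps(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    valid = ~np.isnan(x)
    if valid.all():
        return x.copy(), valid
    if not valid.any():
        raise ConfigError("trace contains no valid samples")
    idx = np.arange(len(x))
    bridged = np.interp(idx, idx[valid], x[valid])
    return bridged, valid


def bandpass(raw: np.ndarray, fl: float = 4.76, fh: float = 7.14,
             fs: float = 60.0, order: int = 2,
             zero_phase: bool = True) -> np.ndarray:
    """Butterworth bandpass of effective ``order`` (default 2nd order).

    Zero-phase forward-backward application by default so that peak times
    are not delayed (the causal variant, for live use, is ``zero_phase=
    False``).  NaN gaps are bridged by linear interpolation before
    filtering and restored after.
    """
    if not (0 < fl < fh < fs / 2):
        raise ConfigError(f"need 0 < fl < fh < fs/2 (Nyquist), got "
                          f"fl={fl}, fh={fh}, fs={fs}")
    if order < 2 or order % 2:
        raise ConfigError("order must be an even integer >= 2")
    raw = np.asarray(raw, dtype=np.float64)
    b, a = butter(order // 2, [fl, fh], btype="bandpass", fs=fs)
    min_len = 3 * max(len(a), len(b))
    bridged, valid = _bridge_gaps(raw)
    if len(bridged) <= min_len:
        raise ConfigError(f"series too short for filter warm-up "
                          f"(need > {min_len} samples, got {len(bridged)})")
    if zero_phase:
        y = filtfilt(b, a, bridged)
    else:
        y = lfilter(b, a, bridged)
    y[~valid] = np.nan
    return y


def find_peaks_mountain_climbing(filtered: np.ndarray, fs: float,
                                 fh: float = 7.14,
                                 valid: Optional[np.ndarray] = None
                                 ) -> np.ndarray:
    """Peak times (s) by windowed local-maximum search ("mountain climbing").

    A sample is a peak when it exceeds every earlier sample and is at least
    as large as every later sample within a window of floor(fs/fh) - 1
    samples on each side — ties resolve to the earliest index.  The window
    enforces a minimum peak spacing of one period of the maximum expected
    frequency; the one-sample guard below a full period keeps legitimate
    beats at the upper cutoff (whose sampled spacing alternates around
    fs/fh and sometimes quantizes one sample short) from suppressing each
    other.  Endpoints (no neighbor on one side) are never peaks.  Peaks
    falling on masked (invalid) samples are dropped.
    """
    x = np.asarray(filtered, dtype=np.float64)
    n = len(x)
    if n == 0:
        return np.array([])
    w = max(1, math.floor(fs / fh) - 1)
    xi = np.where(np.isnan(x), -np.inf, x)
    peaks = []
    for i in range(1, n - 1):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        if not np.isfinite(xi[i]):
            continue
        if xi[i] > xi[lo:i].max() and xi[i] >= xi[i + 1:hi].max():
            peaks.append(i)
    if valid is not None:
        peaks = [i for i in peaks if valid[i]]
    return np.asarray(peaks, dtype=np.float64) / fs


def heart_rate(peaks: np.ndarray, t_h: float, fs: float,
               n_frames: int,
               valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame rate series h(t) = t_h / T by causal zero-order hold.

    The rate of the most recent completed inter-peak interval is held from
    that interval's closing peak until the next peak (and past the last
    peak); frames before the second peak, and masked frames, are NaN.
    """
    if t_h <= 0:
        raise ConfigError("t_h must be positive")
    rate = np.full(n_frames, np.nan)
    peaks = np.asarray(peaks, dtype=np.float64)
    if len(peaks) >= 2:
        intervals = np.diff(peaks)
        change_frames = np.round(peaks[1:] * fs).astype(int)
        for k, start in enumerate(change_frames):
            end = change_frames[k + 1] if k + 1 < len(change_frames) else n_frames
            rate[max(0, start):max(0, end)] = t_h / intervals[k]
    if valid is not None:
        rate[~np.asarray(valid, dtype=bool)] = np.nan
    return rate


def process_trace(raw: np.ndarray, params: CardiacParams) -> CardiacTrace:
    """Run the full trace pipeline: bandpass, peaks, intervals, rate."""
    valid = ~np.isnan(np.asarray(raw, dtype=np.float64))
    filtered = bandpass(raw, params.fl, params.fh, params.fs,
                        params.order, params.zero_phase)
    peaks = find_peaks_mountain_climbing(filtered, params.fs, params.fh,
                                         valid=valid)
    intervals = np.diff(peaks) if len(peaks) >= 2 else np.array([])
    rate = heart_rate(peaks, params.t_h, params.fs, len(raw), valid=valid)
    return CardiacTrace(raw=np.asarray(raw, dtype=np.float64),
                        filtered=filtered, peaks=peaks, intervals=intervals,
                        rate=rate, params=params)
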