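"""Time-series analysis of volume sequences.

VOI traces (mean over a fixed voxel block per frame), 5-frame moving-
average smoothing, per-voxel time-to-peak maps of contrast enhancement,
and Fourier extraction of physiological rates (respiration, heartbeat)
from detrended traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hemipact.core import Volume, VolumeSequence

__all__ = [
    "VOI",
    "TimeSeries",
    "voi_trace",
    "moving_average",
    "time_to_peak_map",
    "dominant_frequency",
]


@dataclass(frozen=True)
class VOI:
    """A volume of interest: a ``size`` voxel block centered on a voxel."""

    center: tuple[int, int, int]
    size: tuple[int, int, int] = (10, 10, 10)

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        out = []
        for c, s in zip(self.center, self.size):
            lo = c - s // 2
            out.append(slice(lo, lo + s))
        return tuple(out)

    def validate(self, shape: tuple[int, int, int]) -> None:
        for sl, n in zip(self.slices, shape):
            if sl.start < 0 or sl.stop > n:
                raise ValueError(f"VOI {self} does not fit inside grid of shape {shape}")


@dataclass
class TimeSeries:
    """Sampled scalar trace with its frame rate."""

    values: np.ndarray
    frame_rate_hz: float
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("TimeSeries needs a 1D array of length >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate_hz

    def __len__(self) -> int:
        return len(self.values)


def voi_trace(sequence: VolumeSequence, voi: VOI, label: str = "") -> TimeSeries:
    """Per-frame mean of the VOI voxels."""
    voi.validate(sequence[0].shape)
    sl = voi.slices
    vals = np.array([float(f.values[sl].mean()) for f in sequence.frames])
    return TimeSeries(vals, sequence.frame_rate_hz, label=label)


def moving_average(series: TimeSeries, window: int = 5) -> TimeSeries:
    """Centered moving mean; edges use the shrinking window that fits."""
    if window % 2 != 1:
        raise ValueError(f"window must be odd, got {window}")
    n = len(series)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = series.values[lo:hi].mean()
    return TimeSeries(out, series.frame_rate_hz, label=series.label)


def _smooth_axis0(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean along axis 0 with shrinking edges."""
    n = arr.shape[0]
    half = window // 2
    csum = np.cumsum(arr, axis=0)
    out = np.empty_like(arr, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        top = csum[hi - 1]
        bottom = csum[lo - 1] if lo > 0 else 0.0
        out[i] = (top - bottom) / (hi - lo)
    return out


def time_to_peak_map(
    sequence: VolumeSequence,
    baseline_frames: int = 5,
    smoothing_window: int = 5,
) -> Volume:
    """Per-voxel time (s) of maximum smoothed, baseline-subtracted enhancement.

    The per-voxel trace is smoothed with the same centered moving-average
    filter used for VOI traces, the mean of the first ``baseline_frames``
    frames is subtracted, and the time of the (first) maximum is
    recorded.  Voxels whose trace is constant carry NaN.
    """
    if len(sequence) < 2:
        raise ValueError("time-to-peak needs at least two frames")
    arr = sequence.as_array()
    if smoothing_window > 1 and smoothing_window <= arr.shape[0]:
        arr = _smooth_axis0(arr, smoothing_window)
    baseline = arr[: max(1, baseline_frames)].mean(axis=0)
    enh = arr - baseline
    idx = np.argmax(enh, axis=0)  # first maximum on ties
    ttp = idx / sequence.frame_rate_hz
    flat = np.ptp(arr, axis=0) == 0
    ttp = np.where(flat, np.nan, ttp)
    first = sequence[0]
    return Volume(ttp, first.voxel_mm, first.origin_mm)


def dominant_frequency(
    series: TimeSeries,
    band_hz: tuple[float, float] = (0.2, 1.5),
    detrend: bool = True,
    window: str = "hann",
) -> float | None:
    """Frequency (Hz) of the largest FFT magnitude within ``band_hz``.

    The series is detrended (mean and linear trend removed) and tapered
    with a Hann window before the FFT; without the taper, the spectral
    leakage of a strong aperiodic trend (e.g. a contrast bolus) decays
    only as 1/k and can mask a weak physiological line within the band.
    Returns None when the series carries no variation.
    """
    x = series.values.astype(float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two samples")
    if np.ptp(x) == 0:
        return None
    if detrend:
        t = np.arange(n, dtype=float)
        coef = np.polyfit(t, x, 1)
        x = x - np.polyval(coef, t)
    if window == "hann":
        x = x * np.hanning(n)
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    freqs = np.fft.rfftfreq(n, d=1.0 / series.frame_rate_hz)
    mag = np.abs(np.fft.rfft(x))
    lo, hi = band_hz
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band_hz} contains no FFT bins at rate {series.frame_rate_hz}")
    band_freqs = freqs[sel]
    band_mag = mag[sel]
    return float(band_freqs[int(np.argmax(band_mag))])
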