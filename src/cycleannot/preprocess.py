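"""Normalization, filtering, rest detection, and insole-IMU synchronization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from cycleannot.datamodel import TimeSeries

__all__ = [
    "SyncEstimate",
    "active_regions",
    "lowpass",
    "normalize_maxabs",
    "normalize_per_person",
    "rest_mask",
    "sync_insole_imu",
]


@dataclass(frozen=True)
class SyncEstimate:
    """Result of the insole-to-IMU cross-correlation search."""

    ratio: float  # resampling factor mapping insole samples onto the IMU rate
    lag_s: float  # insole delay relative to the IMU clock
    score: float  # peak normalized cross-correlation


def normalize_maxabs(series: TimeSeries, channel: str) -> TimeSeries:
    """Scale one channel so its maximum absolute value is 1."""
    samples = series.samples.copy()
    idx = series.channel_names.index(channel) if channel in series.channel_names else None
    if idx is None:
        raise KeyError(f"no channel named {channel!r}")
    peak = np.max(np.abs(samples[:, idx])) if samples.shape[0] else 0.0
    if peak == 0.0:
        raise ValueError(f"channel {channel!r} is all zero; max-abs scaling undefined")
    samples[:, idx] = samples[:, idx] / peak
    return series.with_samples(samples)


def normalize_per_person(features: np.ndarray) -> np.ndarray:
    """Z-score each feature column over a subject's full recording.

    Zero-variance columns are left at 0 with a warning instead of
    dividing by zero.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("per-person normalization needs at least 2 frames")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    flat = sd == 0.0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance feature column(s) left at 0",
            stacklevel=2,
        )
    sd = np.where(flat, 1.0, sd)
    return (features - mean) / sd


def rest_mask(
    series: TimeSeries,
    window_s: float = 0.10,
    threshold: float = 0.01,
    channels: tuple[str, ...] = ("GZ",),
    lowpass_hz: float = 20.0,
) -> np.ndarray:
    """Per-frame boolean mask of low-energy (rest/sit) frames.

    Energy is the centered moving average of the squared magnitude of
    the max-abs-normalized motion channels; frames below ``threshold``
    are rest.  Channels are band-limited to ``lowpass_hz`` first so that
    wide-band sensor noise does not raise the rest-energy floor (human
    movement lives well below 20 Hz).  GZ alone is the default energy
    source: its max-abs scale is set by the mid-swing pulses and is
    stable under filtering, unlike the impact-dominated AX scale.
    """
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    present = [c for c in channels if c in series.channel_names]
    if not present:
        raise KeyError(f"none of {channels} present in series")
    energy = np.zeros(series.n_frames)
    sos = None
    if 0 < lowpass_hz < series.rate_hz / 2:
        sos = sps.butter(4, lowpass_hz, btype="low", fs=series.rate_hz, output="sos")
    for name in present:
        x = series.channel(name)
        if sos is not None and x.size > 20:
            x = sps.sosfiltfilt(sos, x)
        peak = np.max(np.abs(x)) if x.size else 0.0
        if peak > 0:
            x = x / peak
        energy += x**2
    n = max(1, int(round(window_s * series.rate_hz)))
    smoothed = uniform_filter1d(energy, size=n, mode="nearest")
    return smoothed < threshold


def active_regions(
    rest: np.ndarray, rate_hz: float, t0_s: float = 0.0, close_gap_s: float = 0.5
) -> list[tuple[float, float]]:
    """Contiguous non-rest spans of a frame mask, in seconds.

    Rest flickers shorter than ``close_gap_s`` are closed over: genuine
    rest periods last seconds, while energy dips inside a bout last a
    fraction of a cycle.
    """
    active = ~np.asarray(rest, dtype=bool)
    if not active.any():
        return []
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = [0] if active[0] else []
    starts += [int(i) + 1 for i in edges if not active[i]]
    ends = [int(i) + 1 for i in edges if active[i]]
    if active[-1]:
        ends.append(active.size)
    regions: list[tuple[float, float]] = []
    for a, b in zip(starts, ends):
        lo, hi = t0_s + a / rate_hz, t0_s + b / rate_hz
        if regions and lo - regions[-1][1] < close_gap_s:
            regions[-1] = (regions[-1][0], hi)
        else:
            regions.append((lo, hi))
    return regions


def lowpass(series: TimeSeries, cutoff_hz: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass over every channel (DC gain 1)."""
    nyquist = series.rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=series.rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, series.samples, axis=0)
    return series.with_samples(filtered)


def sync_insole_imu(
    insole_ax: TimeSeries,
    shoe_ax: TimeSeries,
    ratio_min: float = 1.4,
    ratio_max: float = 3.3,
    ratio_step: float = 0.001,
    max_lag_s: float = 1.0,
    channel: str | None = None,
) -> SyncEstimate:
    """Estimate the insole resampling ratio and lag against the shoe IMU.

    For every candidate ratio on the grid, the insole acceleration is
    linearly resampled onto the IMU rate and cross-correlated with the
    shoe axis; the (ratio, lag) pair with the highest normalized
    correlation wins.  Ties break toward smaller |lag|, then smaller
    ratio.
    """
    x = _single_channel(insole_ax, channel)
    y = _single_channel(shoe_ax, channel)
    if x.size < 4 or y.size < 4:
        raise ValueError("signals too short to synchronize")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant signal; synchronization undefined")
    rate = shoe_ax.rate_hz
    y_z = (y - y.mean()) / y.std()
    max_lag = max(1, int(round(max_lag_s * rate)))

    n_ratio = int(round((ratio_max - ratio_min) / ratio_step)) + 1
    ratios = ratio_min + ratio_step * np.arange(n_ratio)

    best = SyncEstimate(ratio=float("nan"), lag_s=float("nan"), score=-np.inf)
    src_idx = np.arange(x.size)
    for ratio in ratios:
        m = int(np.floor((x.size - 1) * ratio)) + 1
        up = np.interp(np.arange(m) / ratio, src_idx, x)
        up_z = (up - up.mean()) / (up.std() + 1e-300)
        # full cross-correlation; positive lag = insole delayed vs IMU
        corr = sps.correlate(y_z, up_z, mode="full", method="fft")
        lags = np.arange(-(m - 1), y_z.size)
        counts = np.minimum(np.minimum(lags + m, y_z.size - lags), min(m, y_z.size))
        keep = np.abs(lags) <= max_lag
        if not np.any(keep):
            continue
        score = corr[keep] / np.maximum(counts[keep], 1)
        lag_set = lags[keep]
        order = np.lexsort((lag_set, np.abs(lag_set), -score))
        i = order[0]
        if score[i] > best.score + 1e-12:
            best = SyncEstimate(
                ratio=float(round(ratio, 6)),
                lag_s=float(lag_set[i] / rate),
                score=float(score[i]),
            )
    return best


def _single_channel(series: TimeSeries, channel: str | None) -> np.ndarray:
    if channel is not None:
        return np.asarray(series.channel(channel), dtype=float)
    if series.samples.shape[1] != 1:
        # prefer an axial-acceleration channel when present
        for name in ("AX", "ax"):
            if name in series.channel_names:
                return series.channel(name)
        raise ValueError("multichannel series: specify channel=")
    return series.samples[:, 0]
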