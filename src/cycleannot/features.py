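"""Sliding-window feature extraction from the GZ and AX motion channels.

Per window and channel the extractor emits five features: the sample
variance, the three coefficients of the least-squares second-order
polynomial fit over window-local time, and the raw sample at the window
center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cycleannot.datamodel import TimeSeries

__all__ = ["FeatureMatrix", "extract_features", "features_per_foot", "FEATURES_PER_CHANNEL"]

FEATURES_PER_CHANNEL = 5


@dataclass
class FeatureMatrix:
    """Windowed feature frames with their center timestamps."""

    frames: np.ndarray  # steps x (5 * n_channels)
    step_s: float
    window_s: float
    frame_times_s: np.ndarray
    channel_names: list[str]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_features(self) -> int:
        return self.frames.shape[1]


def _window_features(x: np.ndarray, rate_hz: float, w: int, s: int) -> np.ndarray:
    """Features for one channel: shape (n_windows, 5).

    The quadratic fit is over window-local time centered at 0 (seconds),
    so the constant coefficient tracks the signal level at mid-window.
    """
    windows = sliding_window_view(x, w)[::s]  # trailing short windows dropped
    tau = (np.arange(w) - (w - 1) / 2.0) / rate_hz
    vandermonde = np.stack([tau**2, tau, np.ones_like(tau)], axis=1)
    projector = np.linalg.pinv(vandermonde)  # 3 x w
    coeffs = windows @ projector.T  # (n, 3): a, b, c of a*t^2 + b*t + c
    variance = windows.var(axis=1)
    raw = windows[:, (w - 1) // 2]
    return np.column_stack([variance, coeffs, raw])


def extract_features(
    gz: np.ndarray,
    ax: np.ndarray,
    rate_hz: float,
    window_s: float = 0.070,
    step_s: float = 0.005,
    t0_s: float = 0.0,
) -> FeatureMatrix:
    """Windowed features over the GZ and AX channels of one foot.

    Windows shorter than ``window_s`` at the signal edges are dropped;
    frame times are the window centers.
    """
    gz = np.asarray(gz, dtype=float)
    ax = np.asarray(ax, dtype=float)
    if gz.shape != ax.shape or gz.ndim != 1:
        raise ValueError("gz and ax must be equal-length 1-D arrays")
    w = int(round(window_s * rate_hz))
    s = int(round(step_s * rate_hz))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    if s < 1:
        raise ValueError("step must cover at least 1 sample")
    if w > gz.size:
        raise ValueError(f"window of {w} samples longer than signal ({gz.size})")
    frames = np.hstack(
        [_window_features(gz, rate_hz, w, s), _window_features(ax, rate_hz, w, s)]
    )
    starts = np.arange(0, gz.size - w + 1, s)
    times = t0_s + (starts + (w - 1) / 2.0) / rate_hz
    return FeatureMatrix(
        frames=frames,
        step_s=s / rate_hz,
        window_s=w / rate_hz,
        frame_times_s=times,
        channel_names=["GZ", "AX"],
    )


def features_per_foot(
    imu_left: TimeSeries | None,
    imu_right: TimeSeries | None,
    window_s: float = 0.070,
    step_s: float = 0.005,
) -> tuple[FeatureMatrix | None, FeatureMatrix | None]:
    """Independent feature matrices for the two feet (each foot its own model)."""
    if imu_left is None and imu_right is None:
        raise ValueError("at least one foot must be present")
    out = []
    for name, series in (("left", imu_left), ("right", imu_right)):
        if series is None:
            warnings.warn(f"missing {name} foot; returning single-foot features", stacklevel=2)
            out.append(None)
            continue
        out.append(
            extract_features(
                series.channel("GZ"),
                series.channel("AX"),
                series.rate_hz,
                window_s=window_s,
                step_s=step_s,
                t0_s=series.t0_s,
            )
        )
    return out[0], out[1]
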