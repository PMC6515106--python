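"""Unsupervised cycle segmentation for phase-less activities.

Two detectors anchor each cycle at the dominant peak of the normalized
GZ axis: plain peak detection (PD) with minimum height and distance
thresholds, and a local cyclicity estimator (LCE) that first finds
locally periodic regions via lagged self-correlation and then places
the per-period maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema, find_peaks

from cycleannot.datamodel import LabelTrack, Segment, TaskWindow, fill_gaps

__all__ = ["CycleMarks", "detect_lce", "detect_pd", "marks_to_track"]


@dataclass
class CycleMarks:
    """Strictly increasing cycle anchor times from one detector."""

    times_s: np.ndarray
    method: str  # "pd" | "lce"


def _check_normalized(x: np.ndarray) -> None:
    if x.size and np.max(np.abs(x)) > 1.0 + 1e-9:
        raise ValueError("signal not max-abs normalized")


def detect_pd(
    gz_norm: np.ndarray,
    rate_hz: float,
    min_distance_s: float = 0.4,
    min_height: float = 0.5,
    t0_s: float = 0.0,
) -> CycleMarks:
    """Mid-swing peak picking on the max-abs-normalized GZ axis.

    Local maxima at or above ``min_height`` are accepted greedily in
    descending height order subject to a pairwise spacing of at least
    ``min_distance_s``; equal heights break toward the earlier peak.
    """
    x = np.asarray(gz_norm, dtype=float)
    _check_normalized(x)
    if x.size < 3:
        return CycleMarks(np.empty(0), "pd")
    candidates, _ = find_peaks(x, height=min_height)
    min_gap = min_distance_s * rate_hz
    # greedy by descending height, earlier index wins ties
    order = sorted(candidates, key=lambda i: (-x[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    kept.sort()
    return CycleMarks(t0_s + np.asarray(kept, dtype=float) / rate_hz, "pd")


def detect_lce(
    gz_norm: np.ndarray,
    rate_hz: float,
    noise_threshold: float = 1.0,
    f_min: float = 0.5,
    f_max: float = 6.0,
    t0_s: float = 0.0,
    hop_s: float = 0.25,
) -> CycleMarks:
    """Cycle anchors from local cyclicity estimation.

    For every analysis position and candidate period p in
    ``[1/f_max, 1/f_min]`` the two adjacent p-long stretches of signal
    are correlated; a position is locally cyclic when its best
    correlation exceeds ``0.7 * noise_threshold`` at two consecutive
    positions (persistence suppresses chance noise correlations).
    Within each cyclic region the per-period GZ maxima are the anchors.
    """
    x = np.asarray(gz_norm, dtype=float)
    _check_normalized(x)
    p_min = max(2, int(round(rate_hz / f_max)))
    p_max = int(round(rate_hz / f_min))
    if x.size < 2 * p_min + 2:
        raise ValueError("signal too short for cyclicity estimation")
    p_max = min(p_max, (x.size - 1) // 2)
    hop = max(1, int(round(hop_s * rate_hz)))
    periods = _period_grid(p_min, p_max)
    threshold = 0.7 * noise_threshold

    positions = np.arange(0, x.size, hop)
    best_score = np.full(positions.size, -np.inf)
    best_period = np.zeros(positions.size, dtype=int)
    for k, pos in enumerate(positions):
        for p in periods:
            a = x[pos : pos + p]
            b = x[pos + p : pos + 2 * p]
            if b.size < p:
                break
            score = _ncc(a, b)
            if score > best_score[k]:
                best_score[k] = score
            # spacing uses the smallest period clearing the criterion,
            # otherwise the lag-2p subharmonic can shadow the true period
            if score >= threshold and best_period[k] == 0:
                best_period[k] = p
    cyclic = best_score >= threshold
    # persistence: require two consecutive cyclic positions
    persistent = cyclic & (np.roll(cyclic, 1) | np.roll(cyclic, -1))
    persistent[0] = cyclic[0] and (cyclic[1] if cyclic.size > 1 else False)
    persistent[-1] = cyclic[-1] and (cyclic[-2] if cyclic.size > 1 else False)

    anchors: list[int] = []
    for start_k, end_k in _runs(persistent):
        lo = positions[start_k]
        hi = min(int(positions[end_k - 1] + 2 * best_period[end_k - 1]), x.size)
        p_star = int(np.median(best_period[start_k:end_k]))
        region = x[lo:hi]
        marks = detect_pd(
            region,
            rate_hz,
            min_distance_s=0.6 * p_star / rate_hz,
            min_height=0.3,
        )
        anchors.extend(int(round(t * rate_hz)) + lo for t in marks.times_s)
    anchors = sorted(set(anchors))
    return CycleMarks(t0_s + np.asarray(anchors, dtype=float) / rate_hz, "lce")


def _period_grid(p_min: int, p_max: int, n: int = 24) -> list[int]:
    grid = np.unique(
        np.round(np.geomspace(p_min, max(p_min + 1, p_max), n)).astype(int)
    )
    return [int(p) for p in grid]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation of two equal-length stretches."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, mask.size))
    return runs


def marks_to_track(
    marks: CycleMarks,
    rest: np.ndarray,
    rate_hz: float,
    task: TaskWindow,
    t0_s: float = 0.0,
    foot: str = "left",
    activity: str = "cycle",
) -> LabelTrack:
    """Whole-cycle segments spanning anchor-to-anchor inside active regions."""
    from cycleannot.preprocess import active_regions

    regions = active_regions(rest, rate_hz, t0_s)

    def region_of(t: float) -> int | None:
        for k, (a, b) in enumerate(regions):
            if a <= t < b:
                return k
        return None

    segments: list[Segment] = []
    anchored = [
        (t, region_of(t))
        for t in marks.times_s
        if task.start_s <= t < task.end_s
    ]
    anchored = [(t, r) for t, r in anchored if r is not None]
    for (a, ra), (b, rb) in zip(anchored, anchored[1:]):
        if ra == rb:  # a cycle must lie within one active region
            segments.append(Segment(a, b, activity, "none", foot, source=marks.method))
    track = LabelTrack(foot=foot, segments=segments)
    return fill_gaps(track, task.start_s, task.end_s, activity="rest")
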