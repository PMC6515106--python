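"""Stance detection from pressure-insole rising/falling edges.

The positive and negative peaks of the derivative of the filtered,
[0,1]-normalized pressure channels mark foot loading and unloading; a
rule set aggregates the per-channel events into alternating stance
intervals and finally into a swing/stance label track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from cycleannot.datamodel import LabelTrack, Segment, TaskWindow, TimeSeries, fill_gaps
from cycleannot.postprocess import enforce_swing_boundaries, merge_consecutive
from cycleannot.preprocess import active_regions

__all__ = [
    "EdgeEvent",
    "EdgeRules",
    "aggregate_edges",
    "detect_channel_edges",
    "edges_to_track",
    "normalize_pressure01",
]


@dataclass(frozen=True)
class EdgeEvent:
    time_s: float
    polarity: str  # "rising" | "falling"
    channel: int
    strength: float  # derivative peak magnitude, 1/s


@dataclass(frozen=True)
class EdgeRules:
    """Aggregation rules for per-channel edges (empirical reconstruction).

    Stance start is the earliest rising edge in a cluster (heel sensors
    load first); stance end is the latest falling edge (toe sensors
    unload last).  Alternation is enforced by dropping the weaker of two
    same-polarity neighbors.
    """

    cluster_s: float = 0.10
    min_stance_s: float = 0.08
    min_swing_s: float = 0.08


def normalize_pressure01(series: TimeSeries) -> TimeSeries:
    """Rescale each pressure channel to span [0, 1] over the recording."""
    samples = series.samples.astype(float).copy()
    lo = samples.min(axis=0)
    hi = samples.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return series.with_samples((samples - lo) / span)


def detect_channel_edges(
    pressure: TimeSeries, channel: int, min_strength: float = 5.0
) -> list[EdgeEvent]:
    """Edges of one pressure channel as derivative-peak events.

    Input must already be filtered and normalized to [0, 1]; events are
    placed at the local extrema of the first difference whose magnitude
    exceeds ``min_strength`` (units 1/s).
    """
    x = pressure.samples[:, channel]
    if x.size and (x.min() < -0.01 or x.max() > 1.01):
        raise ValueError(
            "pressure channel not normalized to [0, 1]; call normalize_pressure01 first"
        )
    if x.size < 3:
        return []
    deriv = np.diff(x) * pressure.rate_hz
    events: list[EdgeEvent] = []
    for sign, polarity in ((1.0, "rising"), (-1.0, "falling")):
        peaks, props = find_peaks(sign * deriv, height=min_strength)
        for i, height in zip(peaks, props["peak_heights"]):
            events.append(
                EdgeEvent(
                    time_s=pressure.t0_s + (i + 0.5) / pressure.rate_hz,
                    polarity=polarity,
                    channel=channel,
                    strength=float(height),
                )
            )
    events.sort(key=lambda e: e.time_s)
    return events


def _cluster(events: list[EdgeEvent], cluster_s: float, keep: str) -> list[EdgeEvent]:
    """Merge same-polarity events within cluster_s; keep earliest or latest."""
    out: list[EdgeEvent] = []
    group: list[EdgeEvent] = []
    for ev in events:
        if group and ev.time_s - group[0].time_s > cluster_s:
            out.append(_collapse(group, keep))
            group = []
        group.append(ev)
    if group:
        out.append(_collapse(group, keep))
    return out


def _collapse(group: list[EdgeEvent], keep: str) -> EdgeEvent:
    chosen = group[0] if keep == "earliest" else group[-1]
    strength = max(e.strength for e in group)
    return EdgeEvent(chosen.time_s, chosen.polarity, chosen.channel, strength)


def aggregate_edges(
    per_channel: list[list[EdgeEvent]], rules: EdgeRules | None = None
) -> list[tuple[float, float]]:
    """Aggregate per-channel edges into alternating stance intervals."""
    rules = rules or EdgeRules()
    rising = sorted(
        (e for evs in per_channel for e in evs if e.polarity == "rising"),
        key=lambda e: e.time_s,
    )
    falling = sorted(
        (e for evs in per_channel for e in evs if e.polarity == "falling"),
        key=lambda e: e.time_s,
    )
    rising = _cluster(rising, rules.cluster_s, keep="earliest")
    falling = _cluster(falling, rules.cluster_s, keep="latest")

    merged = sorted(rising + falling, key=lambda e: e.time_s)
    # enforce rising/falling alternation: of two same-polarity neighbors
    # keep the stronger one
    alternating: list[EdgeEvent] = []
    for ev in merged:
        if alternating and alternating[-1].polarity == ev.polarity:
            if ev.strength > alternating[-1].strength:
                alternating[-1] = ev
            continue
        alternating.append(ev)
    # drop an unpaired leading falling / trailing rising edge
    if alternating and alternating[0].polarity == "falling":
        alternating = alternating[1:]
    if alternating and alternating[-1].polarity == "rising":
        alternating = alternating[:-1]

    stances: list[tuple[float, float]] = []
    for start, end in zip(alternating[::2], alternating[1::2]):
        if end.time_s - start.time_s < rules.min_stance_s:
            continue
        if stances and start.time_s - stances[-1][1] < rules.min_swing_s:
            stances[-1] = (stances[-1][0], end.time_s)  # gap too short: merge
            continue
        stances.append((start.time_s, end.time_s))
    return stances


def edges_to_track(
    stances: list[tuple[float, float]],
    rest: np.ndarray,
    rate_hz: float,
    task: TaskWindow,
    t0_s: float = 0.0,
    foot: str = "left",
) -> LabelTrack:
    """Swing/stance track from stance intervals and a per-frame rest mask.

    Swings fill the gaps between consecutive stances inside each active
    (non-rest) region, including the region-leading and region-trailing
    gaps, so every bout opens and closes with a swing.  The activity
    name comes from the task's single cyclic activity.
    """
    cyclic = sorted(task.allowed_activities - {"rest", "sit", "unknown"})
    if len(cyclic) != 1:
        raise ValueError(
            f"task {task.task_name!r} allows {cyclic}; edge detection needs "
            "exactly one cyclic activity"
        )
    activity = cyclic[0]
    rest = np.asarray(rest, dtype=bool)
    segments: list[Segment] = []
    for a, b in active_regions(rest, rate_hz, t0_s):
        a = max(a, task.start_s)
        b = min(b, task.end_s)
        inside = [(s, e) for s, e in stances if s >= a and e <= b]
        if not inside:
            continue
        cursor = a
        for s, e in inside:
            if s > cursor:
                segments.append(Segment(cursor, s, activity, "swing", foot, source="edges"))
            segments.append(Segment(s, e, activity, "stance", foot, source="edges"))
            cursor = e
        if b > cursor:
            segments.append(Segment(cursor, b, activity, "swing", foot, source="edges"))
    track = LabelTrack(foot=foot, segments=segments)
    track = fill_gaps(track, task.start_s, task.end_s, activity="rest")
    track = enforce_swing_boundaries(merge_consecutive(track))
    return track
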