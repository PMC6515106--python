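"""Label post-processing rules and statistical outlier flagging.

Two rules are applied to every prediction before it is handed to a
human corrector: consecutive same-label sections are joined, and every
activity bout must open and close with a swing phase.  Both rules are
idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

from cycleannot.datamodel import LabelTrack, Segment, iter_bouts

__all__ = ["enforce_swing_boundaries", "flag_outliers", "merge_consecutive"]

_EPS = 1e-9


def merge_consecutive(track: LabelTrack, eps: float = 1e-6) -> LabelTrack:
    """Join adjacent contiguous segments sharing (activity, phase).

    Whole-cycle segments are exempt: for cycling only the cycles are
    defined, so adjacent cycle markers are distinct annotations, not
    fragments of one section.
    """
    track.check_sorted()
    merged: list[Segment] = []
    for seg in track.segments:
        if (
            merged
            and seg.activity != "cycle"
            and merged[-1].label == seg.label
            and seg.start_s - merged[-1].end_s <= eps
        ):
            merged[-1] = replace(merged[-1], end_s=seg.end_s)
        else:
            merged.append(replace(seg))
    return LabelTrack(foot=track.foot, segments=merged)


def enforce_swing_boundaries(track: LabelTrack, eps: float = 1e-6) -> LabelTrack:
    """Relabel bout-leading/-trailing stance phases as rest.

    A bout may start and end only with a swing phase; offending boundary
    stances are relabeled rest (coverage preserved) rather than deleted.
    A single stance separating two adjacent non-rest bouts is a
    legitimate transition separator and is left alone.
    """
    track = merge_consecutive(track, eps=eps)
    segments = [replace(s) for s in track.segments]

    def is_separator(idx: int, direction: int) -> bool:
        # bout-edge stance adjoining a different non-rest activity
        cur = segments[idx]
        j = idx + direction
        if not 0 <= j < len(segments):
            return False
        other = segments[j]
        contiguous = (
            abs(other.start_s - cur.end_s) <= eps
            if direction > 0
            else abs(cur.start_s - other.end_s) <= eps
        )
        return (
            contiguous
            and other.activity not in ("rest", "sit", "unknown")
            and other.activity != cur.activity
        )

    changed = True
    while changed:
        changed = False
        probe = LabelTrack(foot=track.foot, segments=segments)
        for bout in iter_bouts(probe, eps=eps):
            if bout[0].activity == "cycle":
                continue
            first, last = bout[0], bout[-1]
            i_first = segments.index(first)
            i_last = segments.index(last)
            if first.phase == "stance" and not is_separator(i_first, -1):
                segments[i_first] = replace(first, activity="rest", phase="none")
                changed = True
                continue
            if last.phase == "stance" and not is_separator(i_last, +1):
                segments[i_last] = replace(last, activity="rest", phase="none")
                changed = True
    return merge_consecutive(LabelTrack(foot=track.foot, segments=segments), eps=eps)


def flag_outliers(track: LabelTrack, k: float = 3.0, eps: float = 1e-6) -> list[Segment]:
    """Flag cycles whose duration or swing fraction is > k sd off the mean.

    A cycle is a swing plus its following stance within one bout; the
    flagged object is the cycle's swing segment.  Labels are never
    modified.  Activities with fewer than 5 cycles are skipped with a
    warning (statistics too unstable).
    """
    cycles: dict[str, list[tuple[Segment, float, float]]] = {}
    for bout in iter_bouts(track, eps=eps):
        if bout[0].activity == "cycle":
            for seg in bout:
                cycles.setdefault("cycle", []).append((seg, seg.duration_s, 0.0))
            continue
        for a, b in zip(bout, bout[1:]):
            if a.phase == "swing" and b.phase == "stance":
                cycle_time = a.duration_s + b.duration_s
                cycles.setdefault(a.activity, []).append(
                    (a, cycle_time, a.duration_s / cycle_time)
                )
    flagged: list[Segment] = []
    for activity, items in cycles.items():
        if len(items) < 5:
            warnings.warn(
                f"only {len(items)} {activity} cycles; outlier statistics skipped",
                stacklevel=2,
            )
            continue
        times = [t for _, t, _ in items]
        fracs = [f for _, _, f in items]
        t_mean, t_sd = _mean_sd(times)
        f_mean, f_sd = _mean_sd(fracs)
        for seg, t, f in items:
            if abs(t - t_mean) > k * t_sd or abs(f - f_mean) > k * f_sd:
                flagged.append(seg)
    flagged.sort(key=lambda s: s.start_s)
    return flagged


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var**0.5
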