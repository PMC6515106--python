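"""Event-based comparison of predicted vs reference label tracks.

Boundaries (segmentation points between activities or phases) are
matched one-to-one within a 50 ms tolerance window; from the TP/FP/FN
counts four metrics are derived: F1 score, miss rate, false discovery
rate, and the labeling effort (fraction of reference labels that must
be added or deleted during manual correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from cycleannot.datamodel import BoundaryEvent, LabelTrack, track_to_boundaries

__all__ = [
    "MatchResult",
    "MetricsReport",
    "compute_metrics",
    "evaluate_tracks",
    "match_boundaries",
]


@dataclass
class MatchResult:
    true_positive: int
    false_positive: int
    false_negative: int
    pairs: list[tuple[float, float]] = field(default_factory=list)
    tolerance_s: float = 0.05


@dataclass
class MetricsReport:
    f1: float
    miss_rate: float
    false_discovery_rate: float
    effort: float
    per_activity: dict[str, "MetricsReport"] = field(default_factory=dict)

    def as_dict(self) -> dict:
        doc = {
            "f1": self.f1,
            "miss_rate": self.miss_rate,
            "false_discovery_rate": self.false_discovery_rate,
            "effort": self.effort,
        }
        if self.per_activity:
            doc["per_activity"] = {
                k: v.as_dict() for k, v in self.per_activity.items()
            }
        return doc


def match_boundaries(
    pred: list[BoundaryEvent],
    ref: list[BoundaryEvent],
    tolerance_s: float = 0.05,
    require_label_match: bool = False,
) -> MatchResult:
    """Maximum-cardinality one-to-one matching of boundary events.

    Greedy matching on the time-sorted lists is optimal for interval
    tolerance matching on a line: walk both lists, pair events within
    ``tolerance_s``, otherwise advance whichever side lags.  Unmatched
    predictions are false positives, unmatched references false
    negatives.
    """
    pairs: list[tuple[float, float]] = []
    i = j = 0
    while i < len(pred) and j < len(ref):
        p, r = pred[i], ref[j]
        if abs(p.time_s - r.time_s) <= tolerance_s and (
            not require_label_match or p.right_label == r.right_label
        ):
            pairs.append((p.time_s, r.time_s))
            i += 1
            j += 1
        elif p.time_s < r.time_s:
            i += 1
        else:
            j += 1
    return MatchResult(
        true_positive=len(pairs),
        false_positive=len(pred) - len(pairs),
        false_negative=len(ref) - len(pairs),
        pairs=pairs,
        tolerance_s=tolerance_s,
    )


def compute_metrics(match: MatchResult) -> MetricsReport:
    """F1, miss rate, FDR, and effort from the matched counts.

    Undefined ratios (0/0) are reported as NaN, never silently as 0.
    Effort is unbounded above: every spurious prediction adds to it.
    """
    tp, fp, fn = match.true_positive, match.false_positive, match.false_negative
    return MetricsReport(
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        miss_rate=_ratio(fn, tp + fn),
        false_discovery_rate=_ratio(fp, tp + fp),
        effort=_ratio(fp + fn, tp + fn),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def evaluate_tracks(
    pred: LabelTrack,
    ref: LabelTrack,
    tolerance_s: float = 0.05,
    require_label_match: bool = False,
    per_activity: bool = True,
) -> MetricsReport:
    """Event-based metrics of a predicted track against its reference.

    Boundaries inside reference spans labeled ``unknown`` are excluded
    from both sides.  Per-activity metrics attribute each reference
    boundary to the activity of its right-hand segment (falling back to
    the left-hand one at the closing boundary); unmatched predictions
    are attributed the same way from the predicted track.
    """
    if pred.foot != ref.foot:
        raise ValueError(f"foot mismatch: {pred.foot!r} vs {ref.foot!r}")
    unknown_spans = [
        (s.start_s, s.end_s) for s in ref.segments if s.activity == "unknown"
    ]

    def keep(event: BoundaryEvent) -> bool:
        return not any(a < event.time_s < b for a, b in unknown_spans)

    pred_events = [e for e in track_to_boundaries(pred) if keep(e)]
    ref_events = [e for e in track_to_boundaries(ref) if keep(e)]
    match = match_boundaries(
        pred_events, ref_events, tolerance_s, require_label_match
    )
    report = compute_metrics(match)
    if not per_activity:
        return report

    matched_pred = {p for p, _ in match.pairs}
    matched_ref = {r for _, r in match.pairs}
    counts: dict[str, list[int]] = {}
    for event in ref_events:
        activity = _attributed_activity(event)
        tp_fp_fn = counts.setdefault(activity, [0, 0, 0])
        if event.time_s in matched_ref:
            tp_fp_fn[0] += 1
        else:
            tp_fp_fn[2] += 1
    for event in pred_events:
        if event.time_s not in matched_pred:
            counts.setdefault(_attributed_activity(event), [0, 0, 0])[1] += 1
    report.per_activity = {
        activity: compute_metrics(
            MatchResult(tp, fp, fn, tolerance_s=tolerance_s)
        )
        for activity, (tp, fp, fn) in sorted(counts.items())
    }
    return report


def _attributed_activity(event: BoundaryEvent) -> str:
    label = event.right_label or event.left_label
    return label[0] if label is not None else "unknown"


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and sd of each global metric across subjects (NaNs dropped)."""
    out: dict[str, dict[str, float]] = {}
    for name in ("f1", "miss_rate", "false_discovery_rate", "effort"):
        values = [
            getattr(r, name) for r in reports if not math.isnan(getattr(r, name))
        ]
        if not values:
            out[name] = {"mean": math.nan, "sd": math.nan, "n": 0}
            continue
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / len(values)
        out[name] = {"mean": mean, "sd": var**0.5, "n": len(values)}
    return out
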