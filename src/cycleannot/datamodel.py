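"""Core data types, label-track algebra, and signal/label I/O.

Time convention: all segment times are in seconds and intervals are
half-open ``[start_s, end_s)``, so adjacent segments share a single
boundary time.  A :class:`LabelTrack` is the per-foot annotation object:
an ordered, non-overlapping list of activity+phase segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "CYCLIC_ACTIVITIES",
    "FEET",
    "PHASELESS_ACTIVITIES",
    "PHASES",
    "SIMPLE_ACTIVITIES",
    "BoundaryEvent",
    "FormatError",
    "InvalidTrackError",
    "LabelTrack",
    "Segment",
    "TaskWindow",
    "TimeSeries",
    "boundaries_to_track",
    "fill_gaps",
    "iter_bouts",
    "read_labels",
    "read_signals",
    "read_tasks",
    "track_to_boundaries",
    "write_labels",
    "write_signals",
    "write_tasks",
]

ACTIVITIES = (
    "walk",
    "jog",
    "run",
    "stairs",
    "jump",
    "hop",
    "skip",
    "side_step",
    "run_on_spot",
    "cycle",
    "sit",
    "rest",
    "unknown",
)
PHASES = ("swing", "stance", "none")
FEET = ("left", "right")

#: Activities with no swing/stance alternation ("simple" ones plus the
#: whole-cycle-only activity and the unknown filler).
PHASELESS_ACTIVITIES = frozenset({"sit", "rest", "unknown", "cycle"})
#: Simple activities: no phases, no repetitions.
SIMPLE_ACTIVITIES = frozenset({"sit", "rest"})
#: Activities whose bouts alternate swing/stance per foot.
CYCLIC_ACTIVITIES = tuple(
    a for a in ACTIVITIES if a not in PHASELESS_ACTIVITIES
) + ("cycle",)


class InvalidTrackError(ValueError):
    """A LabelTrack violates its ordering/overlap/phase invariants."""


class FormatError(ValueError):
    """A signal or label file is malformed."""


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel signal.

    Sample ``i`` is at time ``t0_s + i / rate_hz``.
    """

    channel_names: list[str]
    samples: np.ndarray  # frames x channels
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a frames x channels array")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.samples[:, idx]

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return TimeSeries(list(self.channel_names), samples, self.rate_hz, self.t0_s)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One labeled interval ``[start_s, end_s)`` on one foot."""

    start_s: float
    end_s: float
    activity: str
    phase: str = "none"
    foot: str = "left"
    source: str | None = None  # provenance (which method produced it)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.foot not in FEET:
            raise ValueError(f"unknown foot {self.foot!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.activity in PHASELESS_ACTIVITIES:
            if self.phase != "none":
                raise ValueError(
                    f"activity {self.activity!r} cannot carry phase {self.phase!r}"
                )
        elif self.phase == "none":
            raise ValueError(
                f"cyclic activity {self.activity!r} requires a swing/stance phase"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def label(self) -> tuple[str, str]:
        return (self.activity, self.phase)

    def __eq__(self, other: object) -> bool:  # source is provenance, not identity
        if not isinstance(other, Segment):
            return NotImplemented
        return (
            self.start_s == other.start_s
            and self.end_s == other.end_s
            and self.activity == other.activity
            and self.phase == other.phase
            and self.foot == other.foot
        )


@dataclass
class LabelTrack:
    """Ordered, non-overlapping activity+phase segments for one foot."""

    foot: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.foot not in FEET:
            raise ValueError(f"unknown foot {self.foot!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def span(self) -> tuple[float, float]:
        if not self.segments:
            return (0.0, 0.0)
        return (self.segments[0].start_s, self.segments[-1].end_s)

    def check_sorted(self, eps: float = 1e-9) -> None:
        """Raise :class:`InvalidTrackError` on unsorted or overlapping segments."""
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_s < prev.start_s:
                raise InvalidTrackError("segments are not sorted by start time")
            if cur.start_s < prev.end_s - eps:
                raise InvalidTrackError(
                    f"segments overlap: [{prev.start_s}, {prev.end_s}) and "
                    f"[{cur.start_s}, {cur.end_s})"
                )

    def validate(self, eps: float = 1e-9) -> None:
        """Full invariant check: ordering, phase alternation, swing bouts.

        Within every bout of one cyclic activity, phases must strictly
        alternate and the bout must open and close with a swing phase
        (an activity starts when the foot first leaves the ground and
        ends when it last touches down).  A lone stance is tolerated as
        a separator between two different non-rest activities.
        """
        self.check_sorted(eps=eps)
        for seg in self.segments:
            if seg.foot != self.foot:
                raise InvalidTrackError(
                    f"segment foot {seg.foot!r} does not match track foot {self.foot!r}"
                )
        for bout in iter_bouts(self, eps=eps):
            if bout[0].activity == "cycle":
                continue
            phases = [s.phase for s in bout]
            for a, b in zip(phases, phases[1:]):
                if a == b:
                    raise InvalidTrackError(
                        f"phases do not alternate within {bout[0].activity} bout "
                        f"at {bout[0].start_s:.3f}s"
                    )
            ok_lead = phases[0] == "swing" or self._adjoins_activity(bout[0], -1, eps)
            ok_trail = phases[-1] == "swing" or self._adjoins_activity(bout[-1], +1, eps)
            if not (ok_lead and ok_trail):
                raise InvalidTrackError(
                    f"{bout[0].activity} bout at {bout[0].start_s:.3f}s does not "
                    "start and end with swing"
                )

    def _adjoins_activity(self, seg: Segment, direction: int, eps: float) -> bool:
        # a bout-edge stance is a legitimate transition separator when it
        # directly adjoins a different non-rest activity on that side
        if seg.phase != "stance":
            return False
        idx = self.segments.index(seg)
        j = idx + direction
        if not 0 <= j < len(self.segments):
            return False
        other = self.segments[j]
        contiguous = (
            abs(other.start_s - seg.end_s) <= eps
            if direction > 0
            else abs(seg.start_s - other.end_s) <= eps
        )
        return (
            contiguous
            and other.activity not in ("rest", "sit", "unknown")
            and other.activity != seg.activity
        )


def iter_bouts(track: LabelTrack, eps: float = 1e-9) -> Iterable[list[Segment]]:
    """Yield maximal contiguous runs of one non-rest, non-sit activity."""
    bout: list[Segment] = []
    for seg in track.segments:
        if seg.activity in ("rest", "sit", "unknown"):
            if bout:
                yield bout
                bout = []
            continue
        if bout and (
            seg.activity != bout[-1].activity
            or seg.start_s > bout[-1].end_s + eps
        ):
            yield bout
            bout = []
        bout.append(seg)
    if bout:
        yield bout


@dataclass
class TaskWindow:
    """Protocol-level interval carrying the activities allowed inside it."""

    start_s: float
    end_s: float
    task_name: str
    allowed_activities: frozenset[str]

    def __post_init__(self) -> None:
        self.allowed_activities = frozenset(self.allowed_activities)
        if not self.allowed_activities:
            raise ValueError("allowed_activities must be non-empty")
        unknown = self.allowed_activities - set(ACTIVITIES)
        if unknown:
            raise ValueError(f"unknown activities {sorted(unknown)}")
        if not self.end_s > self.start_s:
            raise ValueError("task window end must exceed start")


@dataclass(frozen=True)
class BoundaryEvent:
    """A segmentation point between two activities or phases."""

    time_s: float
    left_label: tuple[str, str] | None
    right_label: tuple[str, str] | None


# ---------------------------------------------------------------------------
# label-track algebra
# ---------------------------------------------------------------------------


def track_to_boundaries(track: LabelTrack, eps: float = 1e-6) -> list[BoundaryEvent]:
    """All segmentation points of a track, in increasing time order.

    Every segment start and end contributes a boundary; endpoints closer
    than ``eps`` are merged (shared boundaries of contiguous segments
    count once).  A contiguous n-segment track therefore yields n + 1
    events.
    """
    track.check_sorted(eps=eps)
    if not track.segments:
        return []
    times: list[float] = []
    for seg in track.segments:
        for t in (seg.start_s, seg.end_s):
            if not times or t - times[-1] > eps:
                times.append(t)
    events = []
    for t in times:
        left = next(
            (s for s in track.segments if abs(s.end_s - t) <= eps), None
        )
        right = next(
            (s for s in track.segments if abs(s.start_s - t) <= eps), None
        )
        events.append(
            BoundaryEvent(
                time_s=t,
                left_label=left.label if left is not None else None,
                right_label=right.label if right is not None else None,
            )
        )
    return events


def boundaries_to_track(
    events: Sequence[BoundaryEvent], foot: str = "left"
) -> LabelTrack:
    """Reconstruct a contiguous track from its boundary events.

    Inverse of :func:`track_to_boundaries` on contiguous tracks; requires
    every inter-event span to carry a right-hand label.
    """
    segments = []
    for a, b in zip(events, events[1:]):
        if a.right_label is None:
            raise InvalidTrackError(
                f"boundary at {a.time_s}s has no right-hand label; track is not contiguous"
            )
        activity, phase = a.right_label
        segments.append(
            Segment(a.time_s, b.time_s, activity, phase=phase, foot=foot)
        )
    return LabelTrack(foot=foot, segments=segments)


def fill_gaps(
    track: LabelTrack,
    start_s: float,
    end_s: float,
    activity: str = "rest",
    min_gap_s: float = 1e-6,
) -> LabelTrack:
    """Tile ``[start_s, end_s)`` by filling gaps with ``activity`` segments."""
    track.check_sorted()
    filled: list[Segment] = []
    cursor = start_s
    for seg in track.segments:
        if seg.start_s - cursor > min_gap_s:
            filled.append(
                Segment(cursor, seg.start_s, activity, foot=track.foot)
            )
        filled.append(seg)
        cursor = max(cursor, seg.end_s)
    if end_s - cursor > min_gap_s:
        filled.append(Segment(cursor, end_s, activity, foot=track.foot))
    return LabelTrack(foot=track.foot, segments=filled)


def crop_track(track: LabelTrack, start_s: float, end_s: float) -> LabelTrack:
    """Clip all segments to ``[start_s, end_s)``, dropping empty remains."""
    out = []
    for seg in track.segments:
        a = max(seg.start_s, start_s)
        b = min(seg.end_s, end_s)
        if b > a:
            out.append(replace(seg, start_s=a, end_s=b))
    return LabelTrack(foot=track.foot, segments=out)


# ---------------------------------------------------------------------------
# I/O: signals
# ---------------------------------------------------------------------------


def write_signals(series: TimeSeries, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`TimeSeries` to CSV or HDF5 (chosen by extension)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={series.rate_hz!r}\n")
            fh.write(f"# t0_s={series.t0_s!r}\n")
            pd.DataFrame(series.samples, columns=series.channel_names).to_csv(
                fh, index=False
            )
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("samples", data=series.samples)
            ds.attrs["rate_hz"] = series.rate_hz
            ds.attrs["t0_s"] = series.t0_s
            ds.attrs["channel_names"] = [str(c) for c in series.channel_names]
    else:
        raise FormatError(f"unknown signal format {fmt!r}")


def read_signals(path: str | Path, format: str | None = None) -> TimeSeries:
    """Read a :class:`TimeSeries` written by :func:`write_signals`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            try:
                frame = pd.read_csv(fh, float_precision='round_trip')
            except Exception as exc:  # ragged rows, empty file, ...
                raise FormatError(f"malformed signal CSV {path}: {exc}") from exc
        if "rate_hz" not in meta:
            raise FormatError(f"{path} lacks a '# rate_hz=' header line")
        if frame.isna().any().any():
            raise FormatError(f"{path} has ragged or missing values")
        return TimeSeries(
            channel_names=list(frame.columns),
            samples=frame.to_numpy(dtype=float),
            rate_hz=meta["rate_hz"],
            t0_s=meta.get("t0_s", 0.0),
        )
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh["samples"]
            if "rate_hz" not in ds.attrs:
                raise FormatError(f"{path} lacks a rate_hz attribute")
            return TimeSeries(
                channel_names=[str(c) for c in np.asarray(ds.attrs["channel_names"]).tolist()],
                samples=ds[()].reshape(ds.shape[0] if ds.ndim else 0, -1),
                rate_hz=float(ds.attrs["rate_hz"]),
                t0_s=float(ds.attrs.get("t0_s", 0.0)),
            )
    raise FormatError(f"unknown signal format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# I/O: labels and tasks
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ["start_s", "end_s", "activity", "phase", "foot"]


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write a track as CSV (or JSON for a ``.json`` suffix)."""
    path = Path(path)
    rows = [
        {
            "start_s": s.start_s,
            "end_s": s.end_s,
            "activity": s.activity,
            "phase": s.phase,
            "foot": s.foot,
        }
        for s in track.segments
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"foot": track.foot, "segments": rows}, indent=1))
    else:
        pd.DataFrame(rows, columns=_LABEL_COLUMNS).to_csv(path, index=False)


def read_labels(path: str | Path, foot: str | None = None) -> LabelTrack:
    """Read a track written by :func:`write_labels`; rejects invalid rows."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        rows = doc["segments"]
        foot = foot or doc.get("foot")
    else:
        frame = pd.read_csv(path, float_precision='round_trip')
        missing = set(_LABEL_COLUMNS) - set(frame.columns)
        if missing:
            raise FormatError(f"{path} lacks columns {sorted(missing)}")
        rows = frame.to_dict("records")
    try:
        segments = [
            Segment(
                float(r["start_s"]),
                float(r["end_s"]),
                str(r["activity"]),
                phase=str(r["phase"]),
                foot=str(r["foot"]),
            )
            for r in rows
        ]
    except ValueError as exc:
        raise FormatError(f"invalid label row in {path}: {exc}") from exc
    feet = {s.foot for s in segments}
    if foot is None:
        if len(feet) > 1:
            raise FormatError(f"{path} mixes feet {sorted(feet)}; pass foot=")
        foot = feet.pop() if feet else "left"
    track = LabelTrack(foot=foot, segments=segments)
    track.check_sorted()
    return track


def write_tasks(tasks: Sequence[TaskWindow], path: str | Path) -> None:
    rows = [
        {
            "start_s": t.start_s,
            "end_s": t.end_s,
            "task_name": t.task_name,
            "allowed_activities": "|".join(sorted(t.allowed_activities)),
        }
        for t in tasks
    ]
    pd.DataFrame(
        rows, columns=["start_s", "end_s", "task_name", "allowed_activities"]
    ).to_csv(path, index=False)


def read_tasks(path: str | Path) -> list[TaskWindow]:
    frame = pd.read_csv(path, float_precision='round_trip')
    tasks = []
    for r in frame.to_dict("records"):
        tasks.append(
            TaskWindow(
                float(r["start_s"]),
                float(r["end_s"]),
                str(r["task_name"]),
                frozenset(str(r["allowed_activities"]).split("|")),
            )
        )
    return tasks
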