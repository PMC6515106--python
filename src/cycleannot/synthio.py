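"""Synthetic per-foot IMU and pressure-insole recordings with ground truth.

The generator emulates the structure the detectors key on, not
biomechanics: every swing carries one dominant raised-cosine GZ pulse
peaking at mid-swing, stance onsets produce an AX impact transient plus
a low-amplitude load rumble, and the five pressure channels load in a
heel-to-toe stagger so that the earliest rising edge marks stance onset
and the latest falling edge marks stance end.  The insole series is a
resampled (factor ``insole_ratio``) and delayed (``insole_lag_s``)
transform of the same latent acceleration as the shoe IMU, plus
independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cycleannot.datamodel import (
    LabelTrack,
    Segment,
    TaskWindow,
    TimeSeries,
    fill_gaps,
)

__all__ = [
    "ActivityTemplate",
    "DEFAULT_TEMPLATES",
    "SubjectBundle",
    "SubjectScenario",
    "generate_batch",
    "generate_subject",
]

IMU_RATE_HZ = 200.0
INSOLE_NOMINAL_RATE_HZ = 100.0
N_PRESSURE_CHANNELS = 5

_STAGGER_S = 0.010  # heel-to-toe loading stagger per channel
_RAMP_S = 0.040  # pressure loading/unloading ramp
_IMPACT_AMP = 1.0
_RUMBLE_AMP = 0.30  # stance load rumble on AX (keeps stance out of rest)


@dataclass(frozen=True)
class ActivityTemplate:
    """Waveform parameters for one cyclic activity."""

    activity: str
    stride_time_s: float
    stride_time_cv: float
    swing_fraction: float
    gz_peak_amp: float
    ax_profile: str = "impact"  # "impact" | "smooth"
    pressure_load: float = 1.0

    def __post_init__(self) -> None:
        if not self.stride_time_s > 0:
            raise ValueError("stride_time_s must be positive")
        if not 0.0 < self.swing_fraction < 1.0:
            raise ValueError("swing_fraction must lie strictly in (0, 1)")
        if not 0.0 <= self.stride_time_cv < 1.0:
            raise ValueError("stride_time_cv must lie in [0, 1)")


DEFAULT_TEMPLATES: dict[str, ActivityTemplate] = {
    t.activity: t
    for t in [
        ActivityTemplate("walk", 1.10, 0.03, 0.40, 1.00),
        ActivityTemplate("jog", 0.80, 0.03, 0.50, 1.10),
        ActivityTemplate("run", 0.65, 0.04, 0.55, 1.20),
        ActivityTemplate("stairs", 1.05, 0.04, 0.40, 0.90),
        ActivityTemplate("jump", 0.70, 0.05, 0.60, 1.05),
        ActivityTemplate("hop", 0.65, 0.05, 0.40, 1.00),
        ActivityTemplate("skip", 0.75, 0.04, 0.60, 1.05),
        ActivityTemplate("side_step", 0.90, 0.04, 0.45, 0.90),
        ActivityTemplate("run_on_spot", 0.60, 0.04, 0.50, 1.10),
        ActivityTemplate("cycle", 0.90, 0.03, 0.50, 1.00, "smooth", 0.0),
    ]
}


@dataclass
class SubjectScenario:
    """Recording plan for one synthetic subject."""

    seed: int = 0
    bouts: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("walk", 8, 3.0), ("jog", 8, 3.0)]
    )  # (activity, n_cycles, preceding_rest_s)
    noise_sd: float = 0.10
    insole_ratio: float = 2.0
    insole_lag_s: float = 0.0
    foot_offset_fraction: float = 0.5  # right-foot bout delay, in strides
    trailing_rest_s: float = 3.0

    def __post_init__(self) -> None:
        if not 1.4 <= self.insole_ratio <= 3.3:
            raise ValueError("insole_ratio outside the synchronizer search range")
        for activity, n_cycles, _ in self.bouts:
            if n_cycles < 1:
                raise ValueError(f"bout of {activity} needs at least 1 cycle")


@dataclass
class SubjectBundle:
    imu_left: TimeSeries
    imu_right: TimeSeries
    insole_left: TimeSeries
    insole_right: TimeSeries
    truth: dict[str, LabelTrack]
    tasks: list[TaskWindow]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _schedule_foot(
    scenario: SubjectScenario,
    templates: dict[str, ActivityTemplate],
    foot: str,
    rng: np.random.Generator,
) -> tuple[list[Segment], list[tuple[str, float, float]]]:
    """Per-foot swing/stance schedule plus per-bout (activity, start, end)."""
    segments: list[Segment] = []
    bout_spans: list[tuple[str, float, float]] = []
    cursor = 0.0
    for activity, n_cycles, rest_s in scenario.bouts:
        if activity not in templates:
            raise ValueError(f"no template for activity {activity!r}")
        tpl = templates[activity]
        start = cursor + rest_s
        if foot == "right":
            start += scenario.foot_offset_fraction * tpl.stride_time_s
        t = start
        if activity == "cycle":
            # whole-cycle markers are anchored at the GZ maxima, so the
            # truth segments span peak to peak (n_cycles peaks)
            peaks = []
            for _ in range(n_cycles):
                stride = tpl.stride_time_s * max(
                    0.3, 1.0 + tpl.stride_time_cv * rng.standard_normal()
                )
                peaks.append(t + stride / 2.0)
                t += stride
            segments.extend(
                Segment(a, b, activity, "none", foot)
                for a, b in zip(peaks, peaks[1:])
            )
            bout_spans.append((activity, start, t))
            cursor = t
            continue
        for c in range(n_cycles):
            stride = tpl.stride_time_s * max(
                0.3, 1.0 + tpl.stride_time_cv * rng.standard_normal()
            )
            swing = tpl.swing_fraction * stride
            segments.append(Segment(t, t + swing, activity, "swing", foot))
            t += swing
            if c < n_cycles - 1:  # bouts terminate at final ground contact
                stance = stride - swing
                segments.append(Segment(t, t + stance, activity, "stance", foot))
                t += stance
        bout_spans.append((activity, start, t))
        cursor = t
    return segments, bout_spans


def generate_subject(
    scenario: SubjectScenario,
    templates: dict[str, ActivityTemplate] | None = None,
) -> SubjectBundle:
    """Deterministic synthetic recording for one subject."""
    if templates is None:
        templates = DEFAULT_TEMPLATES
    root = np.random.SeedSequence(scenario.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("left", "right", "noise_left", "noise_right", "insole_left", "insole_right"),
            root.spawn(6),
        )
    }

    schedules = {}
    spans = {}
    for foot in ("left", "right"):
        segs, bout_spans = _schedule_foot(scenario, templates, foot, rngs[foot])
        schedules[foot] = segs
        spans[foot] = bout_spans

    total_end = max(
        (segs[-1].end_s for segs in schedules.values() if segs), default=0.0
    )
    duration = total_end + scenario.trailing_rest_s
    n_imu = int(round(duration * IMU_RATE_HZ))
    t_imu = np.arange(n_imu) / IMU_RATE_HZ

    truth = {}
    imu = {}
    insole = {}
    for foot in ("left", "right"):
        truth[foot] = fill_gaps(
            LabelTrack(foot=foot, segments=schedules[foot]), 0.0, duration
        )
        gz, ax = _render_imu(t_imu, schedules[foot], templates)
        noise = rngs[f"noise_{foot}"]
        imu[foot] = TimeSeries(
            ["GZ", "AX"],
            np.column_stack(
                [
                    gz + scenario.noise_sd * noise.standard_normal(n_imu),
                    ax + scenario.noise_sd * noise.standard_normal(n_imu),
                ]
            ),
            IMU_RATE_HZ,
        )
        insole[foot] = _render_insole(
            scenario, schedules[foot], templates, t_imu, ax, duration,
            rngs[f"insole_{foot}"],
        )

    tasks = _build_tasks(spans["left"], spans["right"], duration)
    return SubjectBundle(
        imu_left=imu["left"],
        imu_right=imu["right"],
        insole_left=insole["left"],
        insole_right=insole["right"],
        truth=truth,
        tasks=tasks,
    )


def _render_imu(
    t: np.ndarray,
    segments: list[Segment],
    templates: dict[str, ActivityTemplate],
) -> tuple[np.ndarray, np.ndarray]:
    gz = np.zeros_like(t)
    ax = np.zeros_like(t)
    rate = IMU_RATE_HZ

    def add_pulse(center: float, width: float, amp: float) -> None:
        # raised-cosine hump peaking at `center`, zero outside +- width/2
        lo = max(int(np.ceil((center - width / 2.0) * rate)), 0)
        hi = min(int(np.ceil((center + width / 2.0) * rate)), t.size)
        if hi > lo:
            tau = t[lo:hi] - center
            gz[lo:hi] += amp * np.cos(np.pi * tau / width) ** 2

    cycle_run: list[Segment] = []
    for k, seg in enumerate(segments + [None]):
        if seg is not None and seg.activity == "cycle":
            cycle_run.append(seg)
            continue
        if cycle_run:
            # whole-cycle markers sit on the GZ maxima: one hump per boundary
            tpl = templates["cycle"]
            peaks = [s.start_s for s in cycle_run] + [cycle_run[-1].end_s]
            # humps narrower than the period: distinct, reasonably sharp maxima
            widths = [
                0.5 * d
                for d in [cycle_run[0].duration_s]
                + [s.duration_s for s in cycle_run]
            ]
            for center, width in zip(peaks, widths):
                add_pulse(center, width, tpl.gz_peak_amp)
            lo = int(np.ceil(cycle_run[0].start_s * rate))
            hi = min(int(np.ceil(cycle_run[-1].end_s * rate)), t.size)
            if hi > lo:
                tau = t[lo:hi] - cycle_run[0].start_s
                period = np.mean([s.duration_s for s in cycle_run])
                ax[lo:hi] += 0.3 * np.sin(2 * np.pi * tau / period)
            # a small hump in every inter-peak valley keeps the bout above
            # the rest-energy floor; its slope vanishes at the cycle
            # boundaries, so the anchor peaks do not move
            for seg2 in cycle_run:
                lo3 = int(np.ceil(seg2.start_s * rate))
                hi3 = min(int(np.ceil(seg2.end_s * rate)), t.size)
                if hi3 > lo3:
                    tau3 = t[lo3:hi3] - seg2.start_s
                    gz[lo3:hi3] += 0.3 * np.sin(np.pi * tau3 / seg2.duration_s) ** 2
            cycle_run = []
        if seg is None:
            break
        tpl = templates[seg.activity]
        lo = int(np.ceil(seg.start_s * rate))
        hi = min(int(np.ceil(seg.end_s * rate)), t.size)
        if hi <= lo:
            continue
        tau = t[lo:hi] - seg.start_s
        dur = seg.duration_s
        if seg.phase == "swing":
            # one dominant mid-swing pulse per cycle
            gz[lo:hi] += tpl.gz_peak_amp * np.sin(np.pi * tau / dur) ** 2
            if tpl.ax_profile == "smooth":
                ax[lo:hi] += 0.3 * np.sin(2 * np.pi * tau / dur)
        elif seg.phase == "stance":
            # impact transient at initial contact + load rumble
            n_impact = min(int(0.12 * rate), hi - lo)
            tau_i = tau[:n_impact]
            ax[lo : lo + n_impact] += (
                _IMPACT_AMP * np.exp(-tau_i / 0.03) * np.cos(2 * np.pi * 25 * tau_i)
            )
            ax[lo:hi] += _RUMBLE_AMP * np.sin(2 * np.pi * 12.0 * tau)
            # low-amplitude foot-rocking oscillation keeps loaded stance
            # distinguishable from quiet standing on the gyro as well
            gz[lo:hi] += 0.25 * np.sin(2 * np.pi * 8.0 * tau)
    return gz, ax


def _pressure_at(
    times: np.ndarray,
    segments: list[Segment],
    templates: dict[str, ActivityTemplate],
) -> np.ndarray:
    """Latent pressure of the 5 staggered channels at arbitrary times."""
    p = np.zeros((times.size, N_PRESSURE_CHANNELS))
    for seg in segments:
        if seg.phase != "stance":
            continue
        load = templates[seg.activity].pressure_load
        if load <= 0:
            continue
        sel = (times > seg.start_s - _RAMP_S) & (times < seg.end_s + _RAMP_S)
        if not sel.any():
            continue
        tau = times[sel]
        for c in range(N_PRESSURE_CHANNELS):
            rise_center = seg.start_s + _STAGGER_S * c
            fall_center = seg.end_s - _STAGGER_S * (N_PRESSURE_CHANNELS - 1 - c)
            rise = _smoothstep((tau - rise_center) / _RAMP_S + 0.5)
            fall = _smoothstep((tau - fall_center) / _RAMP_S + 0.5)
            p[sel, c] += load * rise * (1.0 - fall)
    return p


def _render_insole(
    scenario: SubjectScenario,
    segments: list[Segment],
    templates: dict[str, ActivityTemplate],
    t_imu: np.ndarray,
    latent_ax: np.ndarray,
    duration: float,
    rng: np.random.Generator,
) -> TimeSeries:
    # insole sample i sits at true time lag + i * ratio / imu_rate but is
    # stamped with the nominal insole rate
    period = scenario.insole_ratio / IMU_RATE_HZ
    n = int(np.floor((duration - scenario.insole_lag_s) / period))
    times = scenario.insole_lag_s + np.arange(n) * period
    pressure = _pressure_at(times, segments, templates)
    pressure += 0.02 * rng.standard_normal(pressure.shape)
    ax = np.interp(times, t_imu, latent_ax)
    samples = np.column_stack(
        [
            pressure,
            ax + scenario.noise_sd * rng.standard_normal(n),
            scenario.noise_sd * rng.standard_normal(n),
            scenario.noise_sd * rng.standard_normal(n),
        ]
    )
    names = [f"P{i}" for i in range(N_PRESSURE_CHANNELS)] + ["AX", "AY", "AZ"]
    return TimeSeries(names, samples, INSOLE_NOMINAL_RATE_HZ)


def _build_tasks(
    spans_left: list[tuple[str, float, float]],
    spans_right: list[tuple[str, float, float]],
    duration: float,
) -> list[TaskWindow]:
    """One task window per bout, split midway through the rest gaps."""
    merged = [
        (act, min(a0, b0), max(a1, b1))
        for (act, a0, a1), (_, b0, b1) in zip(spans_left, spans_right)
    ]
    tasks = []
    for i, (activity, start, end) in enumerate(merged):
        lo = 0.0 if i == 0 else (merged[i - 1][2] + start) / 2.0
        hi = duration if i == len(merged) - 1 else (end + merged[i + 1][1]) / 2.0
        tasks.append(
            TaskWindow(
                start_s=lo,
                end_s=hi,
                task_name=f"task{i}_{activity}",
                allowed_activities=frozenset({activity, "rest"}),
            )
        )
    return tasks


def generate_batch(
    n_subjects: int,
    seed: int,
    base_scenario: SubjectScenario | None = None,
    templates: dict[str, ActivityTemplate] | None = None,
) -> list[SubjectBundle]:
    """Deterministic batch of subjects with per-subject template jitter."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_scenario = base_scenario or SubjectScenario()
    templates = templates or DEFAULT_TEMPLATES
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    bundles = []
    for child in children:
        rng = np.random.default_rng(child)
        subject_templates = {
            name: replace(
                tpl,
                stride_time_s=tpl.stride_time_s * rng.uniform(0.9, 1.1),
                swing_fraction=float(
                    np.clip(tpl.swing_fraction + rng.uniform(-0.03, 0.03), 0.2, 0.8)
                ),
                gz_peak_amp=tpl.gz_peak_amp * rng.uniform(0.95, 1.05),
            )
            for name, tpl in templates.items()
        }
        scenario = replace(
            base_scenario, seed=int(rng.integers(0, 2**31 - 1))
        )
        bundles.append(generate_subject(scenario, subject_templates))
    return bundles
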