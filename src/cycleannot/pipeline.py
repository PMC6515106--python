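"""Orchestration: end-to-end annotation of a subject and the batch study.

Ties the stages together in the annotation workflow: edge detection of
the pressure data for the first batch, cycle detectors for phase-less
tasks, and the iteratively trained hierarchical HMM for everything
after, followed by post-processing and event-tolerance evaluation.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np

from cycleannot import edge_detect, preprocess
from cycleannot.config import default_config, merge_config
from cycleannot.cycledet import detect_lce, detect_pd, marks_to_track
from cycleannot.datamodel import (
    LabelTrack,
    Segment,
    TaskWindow,
    TimeSeries,
    fill_gaps,
)
from cycleannot.evaluate import MetricsReport, aggregate_reports, evaluate_tracks
from cycleannot.features import extract_features
from cycleannot.hhmm import HhmmModel, TrainItem, iterative_protocol, predict
from cycleannot.postprocess import enforce_swing_boundaries, merge_consecutive
from cycleannot.synthio import SubjectBundle, SubjectScenario, generate_batch

logger = logging.getLogger(__name__)

__all__ = ["annotate_foot", "run_annotation", "run_iterative_study", "subject_features"]


def subject_features(
    bundle: SubjectBundle, config: dict[str, Any]
) -> dict[str, Any]:
    """Per-person-normalized feature matrices for both feet."""
    fcfg = config["features"]
    out = {}
    for foot, imu in (("left", bundle.imu_left), ("right", bundle.imu_right)):
        fm = extract_features(
            imu.channel("GZ"),
            imu.channel("AX"),
            imu.rate_hz,
            window_s=fcfg["window_s"],
            step_s=fcfg["step_s"],
            t0_s=imu.t0_s,
        )
        fm.frames = preprocess.normalize_per_person(fm.frames)
        out[foot] = fm
    return out


def _task_cyclic_activity(task: TaskWindow) -> str | None:
    cyclic = sorted(task.allowed_activities - {"rest", "sit", "unknown"})
    return cyclic[0] if len(cyclic) == 1 else None


def annotate_foot(
    bundle: SubjectBundle,
    foot: str,
    config: dict[str, Any],
    model: HhmmModel | None = None,
    method: str = "edges",
    cycle_method: str = "pd",
) -> LabelTrack:
    """Annotate one foot with one primary method.

    ``method="edges"`` routes each task to pressure-edge detection,
    except phase-less (cycling) tasks which go to the configured cycle
    detector.  ``method="hhmm"`` decodes the whole recording with the
    trained model under the task restrictions.
    """
    imu: TimeSeries = getattr(bundle, f"imu_{foot}")
    insole: TimeSeries = getattr(bundle, f"insole_{foot}")
    duration = imu.duration_s
    if method == "hhmm":
        if model is None:
            raise ValueError("hhmm method requires a trained model")
        fm = subject_features(bundle, config)[foot]
        track = predict(model, fm, tasks=bundle.tasks, foot=foot)
        return _finalize(track, duration, foot)

    if method != "edges":
        raise ValueError(f"unknown method {method!r}")
    rcfg = config["rest"]
    rest = preprocess.rest_mask(
        imu, window_s=rcfg["window_s"], threshold=rcfg["threshold"],
        channels=tuple(rcfg["channels"]), lowpass_hz=rcfg["lowpass_hz"],
    )
    ecfg = config["edges"]
    pressure_names = [c for c in insole.channel_names if c.startswith("P")]
    pressure = TimeSeries(
        pressure_names,
        np.column_stack([insole.channel(c) for c in pressure_names]),
        insole.rate_hz,
        insole.t0_s,
    )
    pressure = preprocess.lowpass(
        pressure, config["lowpass"]["cutoff_hz"], order=config["lowpass"]["order"]
    )
    pressure = edge_detect.normalize_pressure01(pressure)
    per_channel = [
        edge_detect.detect_channel_edges(pressure, c, ecfg["min_strength"])
        for c in range(len(pressure_names))
    ]
    rules = edge_detect.EdgeRules(
        cluster_s=ecfg["cluster_s"],
        min_stance_s=ecfg["min_stance_s"],
        min_swing_s=ecfg["min_swing_s"],
    )
    stances = edge_detect.aggregate_edges(per_channel, rules)

    gz = imu.channel("GZ")
    gz_peak = np.max(np.abs(gz)) or 1.0
    gz_norm = gz / gz_peak

    segments: list[Segment] = []
    for task in bundle.tasks:
        activity = _task_cyclic_activity(task)
        if activity is None:
            logger.warning("task %s has no unique cyclic activity; skipped", task.task_name)
            continue
        if activity == "cycle":
            pcfg, lcfg = config["pd"], config["lce"]
            if cycle_method == "pd":
                marks = detect_pd(
                    gz_norm, imu.rate_hz,
                    min_distance_s=pcfg["min_distance_s"],
                    min_height=pcfg["min_height"], t0_s=imu.t0_s,
                )
            else:
                marks = detect_lce(
                    gz_norm, imu.rate_hz,
                    noise_threshold=lcfg["noise_threshold"],
                    f_min=lcfg["f_min_hz"], f_max=lcfg["f_max_hz"], t0_s=imu.t0_s,
                )
            task_track = marks_to_track(
                marks, rest, imu.rate_hz, task, t0_s=imu.t0_s, foot=foot
            )
        else:
            task_track = edge_detect.edges_to_track(
                stances, rest, imu.rate_hz, task, t0_s=imu.t0_s, foot=foot
            )
        segments.extend(s for s in task_track.segments if s.activity != "rest")
    track = LabelTrack(foot=foot, segments=sorted(segments, key=lambda s: s.start_s))
    return _finalize(track, duration, foot)


def _finalize(track: LabelTrack, duration: float, foot: str) -> LabelTrack:
    from cycleannot.datamodel import crop_track

    track = crop_track(track, 0.0, duration)
    track = fill_gaps(track, 0.0, duration, activity="rest")
    return enforce_swing_boundaries(merge_consecutive(track))


def run_annotation(
    bundle: SubjectBundle,
    config: dict[str, Any] | None = None,
    model: HhmmModel | None = None,
    method: str = "edges",
    cycle_method: str = "pd",
    reference: dict[str, LabelTrack] | None = None,
) -> dict[str, Any]:
    """Annotate both feet; returns tracks and optional evaluation reports."""
    config = merge_config(default_config(), config or {})
    tracks = {}
    reports = {}
    for foot in ("left", "right"):
        tracks[foot] = annotate_foot(
            bundle, foot, config, model=model, method=method, cycle_method=cycle_method
        )
        if reference is not None:
            reports[foot] = evaluate_tracks(
                tracks[foot], reference[foot],
                tolerance_s=config["eval"]["tolerance_s"],
            )
    out: dict[str, Any] = {"tracks": tracks, "method": method}
    if reference is not None:
        out["reports"] = reports
    return out


def run_iterative_study(
    config: dict[str, Any] | None = None, seed: int | None = None
) -> dict[str, Any]:
    """The batch study: edge detection on batch 1, iterated hHMM after.

    Batch 1 is annotated by pressure-edge detection and its (synthetic)
    manually-corrected reference used to train the first model; every
    later batch is predicted by the previous model, scored against its
    reference, and folded into the training corpus.  All batches are
    also scored on a fixed holdout batch.
    """
    config = merge_config(default_config(), config or {})
    scfg = config["study"]
    if seed is None:
        seed = scfg["seed"]
    n_batches = scfg["n_batches"]
    per_batch = scfg["subjects_per_batch"]
    scenario = SubjectScenario(noise_sd=scfg["noise_sd"])

    seed_rng = np.random.default_rng(seed)
    batch_seeds = seed_rng.integers(0, 2**31 - 1, size=n_batches + 1)
    batches = [
        generate_batch(per_batch, int(s), base_scenario=scenario)
        for s in batch_seeds[:-1]
    ]
    holdout = generate_batch(
        scfg["holdout_subjects"], int(batch_seeds[-1]), base_scenario=scenario
    )

    tolerance = config["eval"]["tolerance_s"]
    # batch 1: edge detection
    edge_reports: list[MetricsReport] = []
    for bundle in batches[0]:
        result = run_annotation(
            bundle, config, method="edges", reference=bundle.truth
        )
        edge_reports.extend(result["reports"].values())
    logger.info("batch 1 (edges): %s", aggregate_reports(edge_reports))

    def to_items(bundle_list: list[SubjectBundle]) -> list[TrainItem]:
        items = []
        for bundle in bundle_list:
            fms = subject_features(bundle, config)
            for foot in ("left", "right"):
                items.append(
                    TrainItem(fms[foot], bundle.truth[foot], tasks=bundle.tasks)
                )
        return items

    train_batches = [to_items(b) for b in batches]
    holdout_items = to_items(holdout)
    hcfg = config["hhmm"]
    feature_dim = train_batches[0][0].features.n_features
    results = iterative_protocol(
        train_batches,
        feature_dim,
        n_iterations=hcfg["n_iterations"],
        holdout=holdout_items,
        components=hcfg["components"],
        em_iterations=hcfg["em_iterations"],
        tolerance_s=tolerance,
        early_stop=hcfg["early_stop"],
        mode=hcfg["training_mode"],
    )

    entries = []
    for res in results:
        batch_reports = edge_reports if res.batch_index == 1 else res.batch_reports
        entries.append(
            {
                "batch": res.batch_index,
                "method": "edges" if res.batch_index == 1 else "hhmm",
                "batch_metrics": aggregate_reports(batch_reports),
                "holdout_metrics": aggregate_reports(res.holdout_reports),
            }
        )
    return {
        "seed": int(seed),
        "n_batches": n_batches,
        "subjects_per_batch": per_batch,
        "entries": entries,
        "final_model": results[-1].model,
    }
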