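"""Hierarchical hidden Markov model for activity/phase segmentation.

The hierarchy (activities contain phases, phases contain internal
states) is flattened into one HMM with a block-structured transition
mask: a left-right chain inside every phase or simple activity, fully
connected block-exit -> block-entry transitions between them.  Simple
activities (sit, rest) carry 3 internal states (initiation,
steady-state, termination); every phase of a cyclic activity carries 4;
the whole-cycle block of cycling carries 4.

Training is semi-supervised: the labels fix which block each frame
belongs to, the alignment to internal states is unsupervised
(segmental Viterbi re-estimation).  Emissions are diagonal-covariance
Gaussian mixtures fitted with a fixed number of EM iterations from a
linear initialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cycleannot.datamodel import (
    LabelTrack,
    Segment,
    TaskWindow,
    PHASELESS_ACTIVITIES,
    SIMPLE_ACTIVITIES,
)
from cycleannot.evaluate import MetricsReport, evaluate_tracks
from cycleannot.features import FeatureMatrix
from cycleannot.postprocess import enforce_swing_boundaries, merge_consecutive

__all__ = [
    "HhmmModel",
    "StateNode",
    "TrainItem",
    "TrainState",
    "build_model",
    "init_emissions",
    "iterative_protocol",
    "load_model",
    "predict",
    "sample_frames",
    "save_model",
    "train",
    "viterbi",
]

LOG_FLOOR = -1e10
_LOG_EPS = -50.0  # score of a structurally forbidden but label-forced jump

N_SIMPLE_STATES = 3
N_PHASE_STATES = 4


@dataclass(frozen=True)
class StateNode:
    activity: str
    phase: str
    internal_index: int


@dataclass
class HhmmModel:
    states: list[StateNode]
    blocks: dict[tuple[str, str], tuple[int, int]]  # key -> (offset, size)
    mask: np.ndarray  # structural transition support, bool (K, K)
    transition: np.ndarray  # row-stochastic on the mask
    start_prob: np.ndarray
    feature_dim: int
    components: int = 1
    weights: np.ndarray | None = None  # (K, M)
    means: np.ndarray | None = None  # (K, M, D)
    covars: np.ndarray | None = None  # (K, M, D)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def activities(self) -> set[str]:
        return {s.activity for s in self.states}

    def block_of(self, activity: str, phase: str) -> tuple[int, int]:
        return self.blocks[(activity, phase)]

    def copy(self) -> "HhmmModel":
        return HhmmModel(
            states=list(self.states),
            blocks=dict(self.blocks),
            mask=self.mask.copy(),
            transition=self.transition.copy(),
            start_prob=self.start_prob.copy(),
            feature_dim=self.feature_dim,
            components=self.components,
            weights=None if self.weights is None else self.weights.copy(),
            means=None if self.means is None else self.means.copy(),
            covars=None if self.covars is None else self.covars.copy(),
        )


@dataclass
class TrainItem:
    """One foot of one subject: features plus its reference labels."""

    features: FeatureMatrix
    track: LabelTrack
    tasks: list[TaskWindow] | None = None


@dataclass
class TrainState:
    model: HhmmModel
    training_corpus: list[TrainItem]
    batch_index: int = 0
    log_likelihood_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _block_plan(activities: set[str]) -> list[tuple[tuple[str, str], int]]:
    plan = []
    for activity in sorted(activities):
        if activity in SIMPLE_ACTIVITIES:
            plan.append(((activity, "none"), N_SIMPLE_STATES))
        elif activity == "cycle":
            plan.append(((activity, "none"), N_PHASE_STATES))
        elif activity == "unknown":
            continue
        else:
            plan.append(((activity, "swing"), N_PHASE_STATES))
            plan.append(((activity, "stance"), N_PHASE_STATES))
    return plan


def build_model(
    activities: set[str], feature_dim: int, components: int = 1
) -> HhmmModel:
    """Untrained model with the structural mask and uniform transitions."""
    if not activities:
        raise ValueError("activity set must be non-empty")
    unknown = set(activities) - {
        "walk", "jog", "run", "stairs", "jump", "hop", "skip",
        "side_step", "run_on_spot", "cycle", "sit", "rest", "unknown",
    }
    if unknown:
        raise ValueError(f"unknown activities {sorted(unknown)}")
    plan = _block_plan(set(activities))
    if not plan:
        raise ValueError("no modelable activities in set")
    states: list[StateNode] = []
    blocks: dict[tuple[str, str], tuple[int, int]] = {}
    for (key, size) in plan:
        blocks[key] = (len(states), size)
        states.extend(StateNode(key[0], key[1], i) for i in range(size))
    k = len(states)
    mask = np.zeros((k, k), dtype=bool)
    entries = []
    for offset, size in blocks.values():
        entries.append(offset)
        for i in range(offset, offset + size):
            mask[i, i] = True  # left-right chain with self-loops
            if i + 1 < offset + size:
                mask[i, i + 1] = True
    for offset, size in blocks.values():
        mask[offset + size - 1, entries] = True  # exit -> every entry
    transition = np.where(mask, 1.0, 0.0)
    transition /= transition.sum(axis=1, keepdims=True)
    start_prob = np.zeros(k)
    start_prob[entries] = 1.0 / len(entries)
    return HhmmModel(
        states=states,
        blocks=blocks,
        mask=mask,
        transition=transition,
        start_prob=start_prob,
        feature_dim=feature_dim,
        components=components,
    )


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


def _fit_diag_gmm(
    x: np.ndarray,
    components: int,
    em_iterations: int,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal-covariance GMM with linear (equal-chunk) initialization."""
    n, d = x.shape
    m = min(components, n)
    # linear init: consecutive equal chunks, one per component
    bounds = np.linspace(0, n, m + 1).astype(int)
    weights = np.array([(b - a) / n for a, b in zip(bounds, bounds[1:])])
    means = np.stack([x[a:b].mean(axis=0) for a, b in zip(bounds, bounds[1:])])
    covars = np.stack(
        [
            np.maximum(x[a:b].var(axis=0), variance_floor)
            for a, b in zip(bounds, bounds[1:])
        ]
    )
    if m == 1:
        return weights, means, covars
    for _ in range(em_iterations):
        logp = _component_logpdf(x, weights, means, covars)  # (n, m)
        log_norm = _logsumexp(logp, axis=1, keepdims=True)
        resp = np.exp(logp - log_norm)
        total = resp.sum(axis=0)
        weights = np.maximum(total, 1e-12)
        weights = weights / weights.sum()
        means = (resp.T @ x) / np.maximum(total[:, None], 1e-12)
        sq = resp.T @ (x**2) / np.maximum(total[:, None], 1e-12)
        covars = np.maximum(sq - means**2, variance_floor)
    if m < components:  # pad degenerate fit up to the requested size
        pad = components - m
        weights = np.concatenate([weights, np.zeros(pad)])
        means = np.concatenate([means, np.repeat(means[-1:], pad, axis=0)])
        covars = np.concatenate([covars, np.repeat(covars[-1:], pad, axis=0)])
    return weights, means, covars


def _component_logpdf(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, covars: np.ndarray
) -> np.ndarray:
    """log(w_m N(x | mu_m, diag sigma2_m)) for every frame and component."""
    log_det = np.log(covars).sum(axis=1)  # (m,)
    diff = x[:, None, :] - means[None, :, :]
    maha = (diff**2 / covars[None, :, :]).sum(axis=2)
    d = x.shape[1]
    with np.errstate(divide="ignore"):
        log_w = np.log(weights)
    return log_w[None, :] - 0.5 * (d * np.log(2 * np.pi) + log_det[None, :] + maha)


def _logsumexp(a: np.ndarray, axis: int, keepdims: bool = False) -> np.ndarray:
    peak = np.max(a, axis=axis, keepdims=True)
    peak = np.where(np.isfinite(peak), peak, 0.0)
    with np.errstate(divide="ignore"):
        out = peak + np.log(np.sum(np.exp(a - peak), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


def emission_logprob(model: HhmmModel, x: np.ndarray) -> np.ndarray:
    """Per-frame, per-state emission log-density, floored at LOG_FLOOR."""
    if model.means is None:
        raise ValueError("emissions not initialized; call init_emissions first")
    if x.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match model ({model.feature_dim})"
        )
    t = x.shape[0]
    k = model.n_states
    out = np.empty((t, k))
    for s in range(k):
        logp = _component_logpdf(x, model.weights[s], model.means[s], model.covars[s])
        out[:, s] = _logsumexp(logp, axis=1)
    return np.maximum(out, LOG_FLOOR)


def _segment_frames(
    features: FeatureMatrix, track: LabelTrack, model: HhmmModel
) -> tuple[list[tuple[tuple[str, str], int, int]], int]:
    """(block key, frame start, frame stop) per labeled segment, plus skip count.

    Frames not covered by any modelable label are skipped.
    """
    times = features.frame_times_s
    spans: list[tuple[tuple[str, str], int, int]] = []
    covered = 0
    for seg in track.segments:
        key = (seg.activity, seg.phase)
        if key not in model.blocks:
            continue
        lo = int(np.searchsorted(times, seg.start_s, side="left"))
        hi = int(np.searchsorted(times, seg.end_s, side="left"))
        if hi > lo:
            spans.append((key, lo, hi))
            covered += hi - lo
    return spans, features.n_frames - covered


def init_emissions(
    model: HhmmModel,
    corpus: list[TrainItem],
    em_iterations: int = 10,
    variance_floor: float = 1e-6,
) -> HhmmModel:
    """Linear-initialization GMM fit of every internal state.

    Each labeled segment is split into equal consecutive parts, one per
    internal state of its block, and every state's mixture is fitted to
    its assigned frames with exactly ``em_iterations`` EM iterations and
    diagonal covariances.
    """
    model = model.copy()
    k, d = model.n_states, model.feature_dim
    assigned: list[list[np.ndarray]] = [[] for _ in range(k)]
    all_frames = []
    for item in corpus:
        x = item.features.frames
        all_frames.append(x)
        spans, _ = _segment_frames(item.features, item.track, model)
        for key, lo, hi in spans:
            offset, size = model.blocks[key]
            bounds = np.linspace(lo, hi, size + 1).astype(int)
            for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
                if b > a:
                    assigned[offset + i].append(x[a:b])
    global_x = np.vstack(all_frames) if all_frames else np.zeros((1, d))
    weights = np.zeros((k, model.components))
    means = np.zeros((k, model.components, d))
    covars = np.ones((k, model.components, d))
    for s in range(k):
        if assigned[s]:
            x = np.vstack(assigned[s])
        else:
            warnings.warn(
                f"state {model.states[s]} has no labeled frames; seeding from "
                "the global feature distribution",
                stacklevel=2,
            )
            x = global_x
        weights[s], means[s], covars[s] = _fit_diag_gmm(
            x, model.components, em_iterations, variance_floor
        )
    model.weights, model.means, model.covars = weights, means, covars
    return model


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def viterbi(
    log_start: np.ndarray, log_trans: np.ndarray, log_b: np.ndarray
) -> tuple[np.ndarray | None, float]:
    """Best state path; ties break toward the lowest state index."""
    t, k = log_b.shape
    if t == 0:
        return np.empty(0, dtype=int), 0.0
    delta = log_start + log_b[0]
    psi = np.zeros((t, k), dtype=int)
    for i in range(1, t):
        scores = delta[:, None] + log_trans
        psi[i] = np.argmax(scores, axis=0)
        delta = scores[psi[i], np.arange(k)] + log_b[i]
    best_end = int(np.argmax(delta))
    best_ll = float(delta[best_end])
    if not np.isfinite(best_ll):
        return None, -np.inf
    path = np.empty(t, dtype=int)
    path[-1] = best_end
    for i in range(t - 1, 0, -1):
        path[i - 1] = psi[i, path[i]]
    return path, best_ll


def _align_segment(
    log_b: np.ndarray, log_trans: np.ndarray, offset: int, size: int
) -> tuple[np.ndarray, float]:
    """Left-right alignment of one labeled segment to its block.

    The path enters at the block's first state; when the segment is long
    enough it must leave from the block's last state (the only state
    with outgoing inter-block transitions).
    """
    t = log_b.shape[0]
    idx = np.arange(offset, offset + size)
    b = log_b[:, idx]
    a = log_trans[np.ix_(idx, idx)]
    delta = np.full(size, -np.inf)
    delta[0] = b[0, 0]
    psi = np.zeros((t, size), dtype=int)
    for i in range(1, t):
        scores = delta[:, None] + a
        psi[i] = np.argmax(scores, axis=0)
        delta = scores[psi[i], np.arange(size)] + b[i]
    end = size - 1 if t >= size and np.isfinite(delta[size - 1]) else int(np.argmax(delta))
    ll = float(delta[end])
    path = np.empty(t, dtype=int)
    path[-1] = end
    for i in range(t - 1, 0, -1):
        path[i - 1] = psi[i, path[i]]
    return path + offset, ll


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _segment_forward_backward(
    log_b: np.ndarray, log_trans: np.ndarray, offset: int, size: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Entry/exit-constrained posteriors for one labeled segment.

    Returns (gamma, xi_sum, log marginal likelihood): gamma is (T, size)
    state posteriors, xi_sum the (size, size) expected transition counts.
    The path is constrained to enter at the block's first state and,
    when the segment is long enough, to leave from its last state.
    """
    t = log_b.shape[0]
    idx = np.arange(offset, offset + size)
    b = log_b[:, idx]
    a = log_trans[np.ix_(idx, idx)]
    alpha = np.full((t, size), -np.inf)
    alpha[0, 0] = b[0, 0]
    for i in range(1, t):
        alpha[i] = _logsumexp(alpha[i - 1][:, None] + a, axis=0) + b[i]
    constrain_exit = t >= size and np.isfinite(alpha[-1, -1])
    beta = np.full((t, size), -np.inf)
    if constrain_exit:
        beta[-1, -1] = 0.0
        ll = alpha[-1, -1]
    else:
        beta[-1] = 0.0
        ll = _logsumexp(alpha[-1], axis=0)
    for i in range(t - 2, -1, -1):
        beta[i] = _logsumexp(a + (b[i + 1] + beta[i + 1])[None, :], axis=1)
    gamma = np.exp(alpha + beta - ll)
    xi_sum = np.zeros((size, size))
    for i in range(t - 1):
        xi = alpha[i][:, None] + a + (b[i + 1] + beta[i + 1])[None, :] - ll
        xi_sum += np.exp(xi)
    return gamma, xi_sum, float(ll)


def train(
    trainstate: TrainState,
    n_iterations: int = 100,
    em_iterations: int = 10,
    variance_floor: float = 1e-6,
    tol_per_frame: float = 1e-6,
    early_stop: bool = True,
    mode: str = "viterbi",
) -> TrainState:
    """Label-constrained iterative re-estimation.

    Each frame's admissible states are the internal states of the block
    named by its label; within that constraint the alignment and the
    parameters are re-estimated iteratively.  ``mode="viterbi"`` uses
    hard segmental alignment (fast, deterministic); ``mode="baum_welch"``
    uses entry/exit-constrained forward-backward posteriors, which is
    more robust against internal states collapsing onto one cluster.
    The recorded per-iteration constrained log-likelihood (best-path or
    marginal, respectively) is non-decreasing up to ``tol_per_frame``.
    Structural transition zeros are preserved.
    """
    if mode not in ("viterbi", "baum_welch"):
        raise ValueError(f"unknown training mode {mode!r}")
    if mode == "baum_welch" and trainstate.model.components != 1:
        raise ValueError("baum_welch training supports single-component emissions")
    model = trainstate.model
    if model.means is None:
        raise ValueError("emissions not initialized; call init_emissions first")
    k, d = model.n_states, model.feature_dim
    items = [
        (item, *_segment_frames(item.features, item.track, model))
        for item in trainstate.training_corpus
    ]
    skipped = sum(n_skip for _, _, n_skip in items)
    if skipped:
        warnings.warn(f"{skipped} frames outside any modelable label; skipped", stacklevel=2)
    n_frames = sum(hi - lo for _, spans, _ in items for _, lo, hi in spans)
    if n_frames == 0:
        raise ValueError("corpus has no labeled frames")

    prev_ll = -np.inf
    for _ in range(n_iterations):
        with np.errstate(divide="ignore"):
            log_trans = np.where(model.mask, np.log(model.transition + 1e-300), -np.inf)
            log_start = np.where(model.start_prob > 0, np.log(model.start_prob + 1e-300), -np.inf)
        counts = np.zeros((k, k))
        sums = np.zeros((k, d))
        sqsums = np.zeros((k, d))
        state_n = np.zeros(k)
        total_ll = 0.0
        for item, spans, _ in items:
            if not spans:
                continue
            log_b = emission_logprob(model, item.features.frames)
            prev_exit: int | None = None
            for key, lo, hi in spans:
                offset, size = model.blocks[key]
                x = item.features.frames[lo:hi]
                if mode == "viterbi":
                    path, ll = _align_segment(log_b[lo:hi], log_trans, offset, size)
                    end_state = int(path[-1])
                else:
                    gamma, xi_sum, ll = _segment_forward_backward(
                        log_b[lo:hi], log_trans, offset, size
                    )
                    end_state = offset + int(np.argmax(gamma[-1]))
                total_ll += ll
                if prev_exit is None:
                    ls = log_start[offset]
                    total_ll += ls if np.isfinite(ls) else _LOG_EPS
                else:
                    lt = log_trans[prev_exit, offset]
                    total_ll += lt if np.isfinite(lt) else _LOG_EPS
                    if model.mask[prev_exit, offset]:
                        counts[prev_exit, offset] += 1
                prev_exit = end_state
                if mode == "viterbi":
                    np.add.at(counts, (path[:-1], path[1:]), 1)
                    np.add.at(sums, path, x)
                    np.add.at(sqsums, path, x**2)
                    np.add.at(state_n, path, 1)
                else:
                    block = slice(offset, offset + size)
                    counts[block, block] += xi_sum
                    sums[block] += gamma.T @ x
                    sqsums[block] += gamma.T @ x**2
                    state_n[block] += gamma.sum(axis=0)
        trainstate.log_likelihood_history.append(total_ll)

        # M-step: transitions (structural zeros preserved, empty rows kept)
        counts *= model.mask
        row = counts.sum(axis=1)
        new_trans = model.transition.copy()
        nz = row > 0
        new_trans[nz] = counts[nz] / row[nz, None]
        new_trans[~model.mask] = 0.0
        model.transition = new_trans
        # emissions (single-component closed form; mixtures re-run EM)
        if model.components == 1:
            seen = state_n > 0
            mu = sums[seen] / state_n[seen, None]
            var = np.maximum(
                sqsums[seen] / state_n[seen, None] - mu**2, variance_floor
            )
            model.means[seen, 0] = mu
            model.covars[seen, 0] = var
            model.weights[seen, 0] = 1.0
        else:
            frames_by_state: list[list[np.ndarray]] = [[] for _ in range(k)]
            for item, spans, _ in items:
                log_b = emission_logprob(model, item.features.frames)
                for key, lo, hi in spans:
                    offset, size = model.blocks[key]
                    path, _ = _align_segment(log_b[lo:hi], log_trans, offset, size)
                    x = item.features.frames[lo:hi]
                    for s in range(offset, offset + size):
                        sel = x[path == s]
                        if sel.size:
                            frames_by_state[s].append(sel)
            for s in range(k):
                if frames_by_state[s]:
                    x = np.vstack(frames_by_state[s])
                    model.weights[s], model.means[s], model.covars[s] = _fit_diag_gmm(
                        x, model.components, em_iterations, variance_floor
                    )

        if early_stop and total_ll - prev_ll < tol_per_frame * n_frames and len(
            trainstate.log_likelihood_history
        ) > 1:
            break
        prev_ll = total_ll
    return trainstate


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    model: HhmmModel,
    features: FeatureMatrix,
    tasks: list[TaskWindow] | None = None,
    foot: str = "left",
    postprocess: bool = True,
) -> LabelTrack:
    """Task-restricted Viterbi decoding to a label track.

    Inside each task window, states of activities outside the window's
    allowed set score -inf (rest stays admissible everywhere); spans not
    covered by any window default to the full activity set.  Consecutive
    frames of equal (activity, phase) collapse into segments.
    """
    x = features.frames
    log_b = emission_logprob(model, x)
    if tasks:
        allowed_masks = _task_state_mask(model, features.frame_times_s, tasks)
        log_b = np.where(allowed_masks, log_b, -np.inf)
    with np.errstate(divide="ignore"):
        log_trans = np.where(model.mask, np.log(model.transition + 1e-300), -np.inf)
        log_start = np.where(model.start_prob > 0, np.log(model.start_prob + 1e-300), -np.inf)
    path, _ = viterbi(log_start, log_trans, log_b)
    if path is None:
        raise RuntimeError("no admissible state path; check task windows")
    times = features.frame_times_s
    step = features.step_s
    segments: list[Segment] = []
    run_start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or _label_of(model, path[i]) != _label_of(model, path[run_start]):
            activity, phase = _label_of(model, path[run_start])
            a = times[run_start] - step / 2.0
            b = times[i - 1] + step / 2.0
            segments.append(Segment(a, b, activity, phase, foot, source="hhmm"))
            run_start = i
    track = LabelTrack(foot=foot, segments=segments)
    if postprocess:
        track = enforce_swing_boundaries(merge_consecutive(track))
    return track


def _label_of(model: HhmmModel, state: int) -> tuple[str, str]:
    node = model.states[state]
    return (node.activity, node.phase)


def _task_state_mask(
    model: HhmmModel, times: np.ndarray, tasks: list[TaskWindow]
) -> np.ndarray:
    """(T, K) admissibility of every state at every frame."""
    k = model.n_states
    state_activity = np.array([s.activity for s in model.states])
    always = np.isin(state_activity, ["rest"])
    out = np.ones((times.size, k), dtype=bool)
    for task in tasks:
        sel = (times >= task.start_s) & (times < task.end_s)
        if not np.any(sel):
            continue
        allowed = np.isin(state_activity, sorted(task.allowed_activities)) | always
        out[sel] &= allowed[None, :]
    return out


# ---------------------------------------------------------------------------
# iterative batch protocol
# ---------------------------------------------------------------------------


@dataclass
class BatchResult:
    batch_index: int
    model: HhmmModel
    batch_reports: list[MetricsReport]
    holdout_reports: list[MetricsReport]


def iterative_protocol(
    batches: list[list[TrainItem]],
    feature_dim: int,
    n_iterations: int = 100,
    holdout: list[TrainItem] | None = None,
    components: int = 1,
    em_iterations: int = 10,
    tolerance_s: float = 0.05,
    early_stop: bool = True,
    mode: str = "viterbi",
) -> list[BatchResult]:
    """Iterative batch training: predict the next batch, then retrain on all.

    The model for batch k >= 2 is warm-started from the previous model
    and trained on all batches up to k; its predictions of batch k are
    scored against that batch's reference before retraining, mirroring
    the annotate-correct-retrain loop.
    """
    if len(batches) < 2:
        raise ValueError("iterative protocol needs at least 2 batches")
    if any(not b for b in batches):
        raise ValueError("empty batch")
    activities = set()
    for batch in list(batches) + ([holdout] if holdout else []):
        for item in batch:
            activities |= {s.activity for s in item.track.segments}
    activities.discard("unknown")

    model = build_model(activities, feature_dim, components=components)
    model = init_emissions(model, batches[0], em_iterations=em_iterations)
    state = TrainState(model=model, training_corpus=list(batches[0]), batch_index=1)
    state = train(
        state, n_iterations=n_iterations, em_iterations=em_iterations,
        early_stop=early_stop, mode=mode,
    )
    results = [
        BatchResult(1, state.model.copy(), [], _score(state.model, holdout, tolerance_s))
    ]
    corpus = list(batches[0])
    for k, batch in enumerate(batches[1:], start=2):
        batch_reports = _score(state.model, batch, tolerance_s)
        corpus = corpus + list(batch)
        state = TrainState(
            model=state.model, training_corpus=corpus, batch_index=k
        )
        state = train(
            state,
            n_iterations=n_iterations,
            em_iterations=em_iterations,
            early_stop=early_stop,
            mode=mode,
        )
        results.append(
            BatchResult(
                k, state.model.copy(), batch_reports, _score(state.model, holdout, tolerance_s)
            )
        )
    return results


def _score(
    model: HhmmModel, items: list[TrainItem] | None, tolerance_s: float
) -> list[MetricsReport]:
    from cycleannot.datamodel import fill_gaps

    if not items:
        return []
    reports = []
    for item in items:
        pred = predict(model, item.features, tasks=item.tasks, foot=item.track.foot)
        lo, hi = item.track.span
        pred = _clip_fill(pred, lo, hi)
        reports.append(evaluate_tracks(pred, item.track, tolerance_s=tolerance_s))
    return reports


def _clip_fill(track: LabelTrack, lo: float, hi: float) -> LabelTrack:
    from cycleannot.datamodel import crop_track, fill_gaps

    track = crop_track(track, lo, hi)
    track = merge_consecutive(fill_gaps(track, lo, hi, activity="rest"))
    return track


# ---------------------------------------------------------------------------
# sampling and persistence
# ---------------------------------------------------------------------------


def sample_frames(
    model: HhmmModel,
    n_frames: int,
    rng: np.random.Generator,
    step_s: float = 0.005,
    foot: str = "left",
) -> tuple[np.ndarray, np.ndarray, LabelTrack]:
    """Draw (states, features, label track) from the model itself."""
    if model.means is None:
        raise ValueError("emissions not initialized")
    k = model.n_states
    states = np.empty(n_frames, dtype=int)
    x = np.empty((n_frames, model.feature_dim))
    s = rng.choice(k, p=model.start_prob)
    for t in range(n_frames):
        states[t] = s
        m = rng.choice(model.components, p=model.weights[s] / model.weights[s].sum())
        x[t] = rng.normal(model.means[s, m], np.sqrt(model.covars[s, m]))
        s = rng.choice(k, p=model.transition[s] / model.transition[s].sum())
    segments = []
    run = 0
    for t in range(1, n_frames + 1):
        if t == n_frames or _label_of(model, states[t]) != _label_of(model, states[run]):
            activity, phase = _label_of(model, states[run])
            segments.append(Segment(run * step_s, t * step_s, activity, phase, foot))
            run = t
    return states, x, LabelTrack(foot=foot, segments=segments)


def save_model(model: HhmmModel, path: str | Path) -> None:
    doc = {
        "states": [
            {"activity": s.activity, "phase": s.phase, "internal_index": s.internal_index}
            for s in model.states
        ],
        "blocks": {f"{a}/{p}": [off, size] for (a, p), (off, size) in model.blocks.items()},
        "mask": model.mask.astype(int).tolist(),
        "transition": model.transition.tolist(),
        "start_prob": model.start_prob.tolist(),
        "feature_dim": model.feature_dim,
        "components": model.components,
        "weights": None if model.weights is None else model.weights.tolist(),
        "means": None if model.means is None else model.means.tolist(),
        "covars": None if model.covars is None else model.covars.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> HhmmModel:
    doc = json.loads(Path(path).read_text())
    return HhmmModel(
        states=[StateNode(**s) for s in doc["states"]],
        blocks={
            (key.split("/")[0], key.split("/")[1]): tuple(val)
            for key, val in doc["blocks"].items()
        },
        mask=np.array(doc["mask"], dtype=bool),
        transition=np.array(doc["transition"]),
        start_prob=np.array(doc["start_prob"]),
        feature_dim=int(doc["feature_dim"]),
        components=int(doc["components"]),
        weights=None if doc["weights"] is None else np.array(doc["weights"]),
        means=None if doc["means"] is None else np.array(doc["means"]),
        covars=None if doc["covars"] is None else np.array(doc["covars"]),
    )
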