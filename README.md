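# cycleannot

Smart annotation of cycle phases (per-foot swing/stance, whole cycles)
in wearable-sensor recordings of cyclic human activities — walking,
jogging, running, stairs, jumping, cycling, and friends.

Manually labeling every gait cycle in hours of sensor data is
infeasible, so this package pre-labels the data so a human only has to
*correct* annotations instead of creating them:

- **Edge detection** — stance onsets/ends from the rising and falling
  edges of the five pressure-insole channels (heel loads first, toe
  unloads last).
- **Iterative hierarchical HMM** — a semi-supervised hHMM over windowed
  gyroscope/accelerometer features (activities → phases → left-right
  internal states), trained in batches: predict the next batch, have it
  corrected, retrain on everything so far.
- **Cycle detectors** — for phase-less activities (cycling), mid-swing
  peak detection (PD) and a local cyclicity estimator (LCE) anchor whole
  cycles at the dominant gyro maxima.
- **Post-processing** — same-label sections are joined and every
  activity bout must open and close with a swing phase; cycle-time
  outliers are flagged for re-inspection.
- **Evaluation** — predicted and reference segmentation points are
  matched one-to-one within a 50 ms tolerance; F1, miss rate, false
  discovery rate, and labeling effort `(FP+FN)/(TP+FN)` are reported
  globally and per activity.
- **Synthetic data** — a deterministic generator produces per-foot IMU
  (GZ/AX at 200 Hz) and insole (5 pressure channels + accelerometer at a
  nominal 100 Hz) recordings with ground-truth label tracks, task
  windows, and a configurable resampling-ratio/lag relation between the
  two sensors, so the whole pipeline is testable end to end without any
  external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric-formula
oracles, matching/Viterbi brute-force equivalence, training soundness,
parameter recovery, the end-to-end batch study); the rest are per-module
unit and property tests.

## CLI

Everything is reachable through one entry point:

```sh
# synthesize two subjects (signals, labels, task windows) into out/
cycleannot synth --subjects 2 --seed 7 --out out/

# pressure-edge annotation of one foot
cycleannot edges --imu out/subject000/imu_left.csv \
    --pressure out/subject000/insole_left.csv \
    --tasks out/subject000/tasks.csv --out pred.csv

# unsupervised cycle annotation (peak detection or local cyclicity)
cycleannot cycles --imu out/subject000/imu_left.csv --method pd --out cycles.csv

# train / predict with the hierarchical HMM
cycleannot train --subject out/subject000/imu_left.csv:out/subject000/labels_left.csv \
    --out model.json
cycleannot predict --model model.json --imu out/subject000/imu_left.csv \
    --tasks out/subject000/tasks.csv --out pred_hmm.csv

# event-based evaluation at 50 ms tolerance
cycleannot evaluate --pred pred.csv --ref out/subject000/labels_left.csv --per-activity

# the full iterative study (edge-detected batch 1, hHMM afterwards)
cycleannot study --seed 1 --out study.json
```

All tunables (filter cutoffs, rest-energy threshold, the 400 ms / 0.5
peak-picking thresholds, the 70 ms / 5 ms feature windowing, HMM
iteration counts, the 1.4–3.3 / 0.001 synchronization grid, the 50 ms
evaluation tolerance, study sizes) live in one YAML-overridable config;
see `cycleannot.config.DEFAULT_CONFIG`.

## Layout

```
src/cycleannot/
  datamodel.py    core types (TimeSeries, Segment, LabelTrack, TaskWindow),
                  label-track algebra, CSV/HDF5/JSON I/O
  synthio.py      synthetic subject/batch generator with ground truth
  preprocess.py   normalization, low-pass, rest detection, insole-IMU sync
  edge_detect.py  pressure-edge stance detection
  features.py     windowed variance/quadratic-fit/raw features
  hhmm.py         hierarchical HMM: build, init, train (viterbi/baum_welch),
                  task-restricted predict, iterative batch protocol
  cycledet.py     peak detection and local cyclicity estimation
  postprocess.py  label rules and outlier flagging
  evaluate.py     tolerance matching and metrics
  pipeline.py     orchestration (annotation routing, batch study)
  cli.py          click command-line interface
```
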