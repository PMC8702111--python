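# larkin

Quantitative measurement of **laryngeal elevation** from per-frame
segmentations of lateral-view videofluoroscopic swallowing study (VFSS)
video.

## Why

Laryngeal elevation protects the airway during the swallowing reflex, and
reduced elevation raises aspiration risk — but the excursion lasts roughly
one second, and routine assessment (visual inspection, palpation) is
subjective. Given per-frame instance segmentations of two structures in a
VFSS clip — the thyroid-cartilage/vocal-fold complex (**TVC**) and the **C1
spinous process** — `larkin` turns them into a calibrated elevation
measurement in millimeters, and provides the evaluation metrics and
synthetic data needed to validate the whole chain without patient data or a
trained network.

## The measurement

For each frame `t`, let `m_TVC(t)` and `m_C1(t)` be the pixel centroids of
the two masks. The analysis uses the *relative* trajectory

    r(t) = m_TVC(t) − m_C1(t)        (pixels; y grows downward)

so camera and head translation cancel (C1 is effectively static during a
swallow). The swallow event is the frame pair `(i, j)`, `i < j`, maximizing
the upward excursion `r_y(i) − r_y(j)` — from the larynx's lowest resting
position to its highest point. Every frame in the selected interval must
have a valid detection, and, when ground truth is available, a TVC
IoU ≥ 0.3 (the validity gate). With per-axis conversion factors
`cf_x, cf_y` (mm/pixel) obtained from a reference segment of known physical
length — e.g. a C3/C4 vertebral-body diagonal measured on the same
patient's MRI — the elevation is

    D = sqrt( (cf_x·Δx)² + (cf_y·Δy)² ),   (Δx, Δy) = r(j) − r(i)

reported together with its pure vertical component `cf_y·|Δy|` and mean and
peak velocities.

Segmentation quality is scored per frame by IoU = |S_m ∩ S_a| / |S_m ∪ S_a|
between manual (`S_m`) and automatic (`S_a`) masks, with a frame counted as
a true positive at IoU ≥ 0.3 (a permissive cutoff: the chain needs the
structure *located*, not perfectly outlined) and per-label recall
TP/(TP+FN). A Welch t-test (or Mann–Whitney U) compares IoU at
elevation-peak frames against the rest. The reference mask loss
`L_mask = −(1/m²) Σ [y·ln ŷ + (1−y)·ln(1−ŷ)]` (default m = 28) is included
for checking mask heads of learned segmenters.

Because no public VFSS segmentation data exist, the `phantom` module
renders synthetic sequences (static C1 blob, TVC blob rising ~1 s with a
raised-cosine profile) with exact ground-truth masks and kinematics, plus
controlled mask degradation to a target IoU, the standard training-time
augmentation recipe, and a classical threshold segmenter standing in for a
learned model at desk scale.

## Worked example

Generate a phantom whose larynx rises 70 px, then measure it at
0.5 mm/pixel (a 2 px ↔ 1 mm reference segment):

```sh
$ larkin phantom --seed 7 --out phantom
INFO larkin: wrote 60 frames + gt.json + truth.json to phantom

$ cat calib.yaml
reference_segments:
- {axis: iso, pixel_length: 2.0, known_mm: 1.0}

$ larkin measure --pred phantom/gt.json --gt phantom/gt.json \
    --calib calib.yaml --out meas
INFO larkin: event frames 0 -> 15: 35.0 mm (vertical 35.0 mm), gate passed
```

`meas/measurement.json` then contains (abridged):

```json
"event": {
  "frame_low": 0, "frame_peak": 15,
  "delta_px": [0.0, -70.0],
  "displacement_mm": 35.0, "vertical_mm": 35.0,
  "gate_passed": true
},
"velocity": {"mean_mm_s": 70.0, "peak_mm_s": 110.6}
```

The event runs from the rest frame (0) to the first frame of the plateau
(15); the 70 px upward excursion at 0.5 mm/px is exactly 35 mm; mean
velocity is 35 mm over 0.5 s. `meas/trajectory.csv` holds the per-frame
relative trajectory (`frame,tvc_x,tvc_y,c1_x,c1_y,rel_x,rel_y,valid`).
`larkin evaluate --gt … --pred …` writes the IoU/recall report for a
prediction set. Library use mirrors the CLI: `generate_phantom`,
`build_track`, `relative_trajectory`, `select_swallow_event`, `gate_event`,
`calibration_from_reference`, `elevation_mm`.

## Scope

The package consumes segmentations; it does not train or ship a neural
network (an adapter producing `FrameAnnotation` objects per frame is the
plug-in point for any learned model). Hyoid-bone kinematics, 3-D motion and
multi-swallow clips are out of scope.
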