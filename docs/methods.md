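# Methods

## Coordinate and pixel conventions

Image convention throughout: 0-based indices, `x` = column increasing
rightward, `y` = row increasing downward, so laryngeal elevation is a
*decrease* in `y`. The pixel at row `r`, column `c` owns the unit square
with center `(c + 0.5, r + 0.5)`. Polygon rasterization sets a pixel iff
its center lies inside the closed polygon under the even-odd rule, with
centers exactly on the boundary counted as inside. This membership rule is
deterministic, checkable against an exhaustive point-in-polygon oracle, and
translation-equivariant under integer shifts. Annotation curves are assumed
simple (non-self-intersecting); for pathological self-intersecting input
the even-odd rule still yields a well-defined, documented result.

## Midpoints and the relative trajectory

"Midpoint" of a structure is its mask centroid — the mean of set-pixel
centers. The centroid is robust to small boundary errors (it moves by
O(boundary error / area)), which matters because predicted masks are noisy
at the contour. A bounding-box-center mode exists behind
`midpoint(..., mode="bbox")` for sensitivity analysis; it is more sensitive
to single stray pixels and is not the default.

When a frame carries several predicted instances of one label, the
instance with the highest confidence wins; ties go to the larger area, then
to first occurrence. Unscored instances rank below scored ones. Ground
truth is restricted to one instance per label per frame.

The trajectory analyzed is `r(t) = m_TVC(t) − m_C1(t)`. Subtracting the C1
midpoint cancels any global translation of the field of view; the
end-to-end tests verify invariance of the final measurement under a global
integer shift of all masks.

## Swallow-event selection and gating

The event is the valid-frame pair `(i, j)`, `i < j`, maximizing
`r_y(i) − r_y(j)`; ties break toward the smallest `i`, then smallest `j`.
This "largest upward excursion" reading operationalizes selecting the
frames with the longest trajectory of the relative y coordinate, and is
consistent with one rise per swallow. A non-positive maximum (the larynx
never rises) is reported as *no event* rather than an error, since flat or
descending clips are legitimate inputs. The implementation is a single
left-to-right scan tracking the earliest prefix maximum; tests pin it to
the exhaustive O(n²) pair search.

The gate requires every frame of `[i, j]` to have both structures detected
and — when ground truth is supplied — TVC IoU ≥ 0.3. The threshold is
inclusive (≥) everywhere for internal consistency between the TP criterion
and the gate. Frames with missing detections inside the interval fail the
gate; they are never interpolated (interpolation would invent kinematics
exactly where the detector is least trustworthy). An ungated event can
still be measured with `force=True`, and the CLI reports it with
`gate_passed: false` and suppresses velocities.

No temporal smoothing is applied by default; the raw trajectory is what is
measured. (A moving-median would bias the peak frame at plateau edges.)

## Calibration and displacement

Conversion factors are mm-per-pixel per axis, `cf = known_mm /
pixel_length`, from reference segments such as C3/C4 vertebral-body
diagonals measured on the same patient's MRI; one segment applies
isotropically, two give independent `cf_x`/`cf_y`. The displacement is the
two-axis calibrated Euclidean norm of `Δr` between the event frames; the
pure vertical component is always reported alongside, so both readings of
"elevation" are available. Mean velocity divides displacement by the
interval duration; peak velocity is the largest single-frame-step
calibrated displacement times the frame rate.

## Evaluation metrics

IoU is a pure pixel-count ratio; both-empty input is an error rather than a
silent 0 or 1. Recall at threshold 0.3 counts, per label, only frames that
carry ground truth for that label; predictions on gt-free frames are
tallied as false positives but excluded from recall (a recall-only
evaluation). Mean IoU is reported both with missed frames as 0
(`iou_mean`, the default headline — its range naturally starts at 0) and
excluding them (`iou_mean_detected`); SDs use ddof = 1.

The peak-vs-lower comparison takes the peak-frame set as an explicit
argument (how wide a "peak" window should be is a study-design choice, not
a property of the data), excludes missing-IoU frames, and defaults to
Welch's two-sample t-test with Mann–Whitney U selectable. Constant groups
make the t statistic degenerate; the p-value is omitted when the test
returns NaN and should be read with suspicion whenever within-group
variance is numerically zero.

`mask_bce_loss` is the reference mean binary cross-entropy over the m×m
mask grid (natural log, probabilities clamped to `[ε, 1−ε]`, ε = 1e-7);
the caller passes the predicted class's probability map. Its analytic
anchors: ln 2 at p ≡ 0.5 for any target, ≈ ε at p = y.

## Phantom design

The phantom exists to give the pipeline inputs with *exactly known*
kinematics. Geometry is elliptical, not anatomical: the downstream math
consumes only masks and centroids, so shape realism contributes nothing to
correctness. The TVC center follows `y(t) = y_rest − A·g(t)` with `g` a
raised-cosine rise (15 frames), hold (5), raised-cosine fall (15) — about
1.2 s at 30 fps, matching the ~1 s swallowing reflex — with default
amplitude A = 70 px in a 640×480, 60-frame clip. Intensities are 30
(background) and 180 (structures); Gaussian pixel noise (sd 10) is added
and then Gaussian blur (σ 1) applied, emulating the low contrast and
smoothing of fluoroscopy. Ground-truth masks are the exact pre-noise
elliptical supports. The true event is (frame 0, first plateau frame).

What the phantom does **not** emulate: anatomical contours and their
deformation, laryngeal tilt, bolus contrast moving through the field,
occlusion of the TVC by the closing vestibule at the peak (the mechanism
that degrades real segmentations exactly where the measurement needs them),
and observer variability in manual curves. Passing tests therefore
demonstrate correctness of the measurement chain given segmentations of a
stated quality — not that any particular segmenter reaches that quality on
patient video.

`degrade_mask` manufactures predictions of controlled quality: shift,
dilate or erode by a magnitude found by monotone search until the IoU with
the original lands within ±0.05 of the target. Shifts try directions in a
seeded order because the first step along a direction bounds that
direction's granularity; for the nested morphological modes a final
fractional step toggles a seeded subset of the boundary ring between two
whole iterations, making the area ratio — and hence the IoU — exact to one
pixel. Erosion can exhaust a small mask before reaching the target; that is
an error, not a silent approximation.

Augmentation applies flip → rotate → scale → shift → optional blur (a fixed
order, since the draws commute in distribution but not pixel-exactly), with
default ranges ±30°, 0.8–1.2, ±10 % per dimension and flip probability 0.5.
Images are warped bilinearly, masks nearest-neighbour to stay binary, both
with the identical transform; identity draws short-circuit the warp so a
no-op is bit-exact.

The threshold segmenter binarizes at the midpoint of the two intensities,
keeps 8-connected components above a minimum area, assigns the component
whose centroid falls in a configured search box to C1 and the largest
remaining one to the TVC, scoring by normalized mean intensity. It is a
classical baseline playing the detector's role in end-to-end tests; any
learned model can replace it through the same frame-in /
`FrameAnnotation`-out interface.

## Numerical choices and degenerate inputs

- IoU of two empty masks, midpoint of an empty mask, event selection with
  < 2 valid frames, zero-length velocity intervals and non-positive
  calibration inputs all raise typed errors (`DataError` subclasses); the
  CLI maps them to exit code 3 (usage errors exit 2).
- Annotation JSON serialization is deterministic (sorted frames and labels,
  stable float repr): equal sets produce byte-identical files. Raster-only
  masks serialize as COCO-style uncompressed column-major RLE so raster
  round-trips are exact; polygonal masks keep their vertices verbatim.
- All stochastic operations (phantom rendering, degradation, augmentation)
  draw from a single explicit seed and are byte-reproducible.
- Problem sizes in the test and acceptance runs — 60-frame 640×480
  phantoms, 532-frame contingencies on 96×96 canvases, 1000/500-case oracle
  sweeps — were chosen so each check completes in seconds while exercising
  the full code path; canvas size does not enter any measured quantity
  beyond centroid discretization (< 0.5 px).

## Known limitations

- Two-dimensional only: out-of-plane motion projects onto the lateral view.
- One swallow event per clip; multi-swallow segmentation is out of scope.
- The centroid midpoint cannot express laryngeal tilt (rotation about a
  still centroid reads as zero elevation).
- Calibration accuracy is bounded by the reference-segment measurement;
  errors propagate linearly into the mm result.
- Whether "elevation" should be the two-axis displacement or its vertical
  component is a reporting choice; both are emitted, the Euclidean norm as
  the headline.
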