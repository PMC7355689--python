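# Methods

`surgtrack` implements a complete tracking-by-detection pipeline for
robotic-surgery video and the downstream quantitative skill assessment,
together with a synthetic scene and cohort simulator that makes every
stage testable without clinical video. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not establish.

## Pipeline model

The pipeline runs, per frame: detection → non-maximum suppression →
Kalman/Hungarian tracking → cascaded re-identification → indicator
recognition → tip localization → metric calibration → indicator gating →
motion metrics.

**Detections are class-free.** A detector reports instrument foreground
only (box, box-local mask, confidence in [0, 1]); partially visible
instruments are not distinguishable by type, so identity is assigned
entirely by tracking and re-identification. Two providers are included: a
ground-truth-backed oracle with a parametric corruption model (per-axis
Gaussian box jitter, misses, Poisson false positives, merged detections
under occlusion) and a classical HSV-threshold/connected-component
segmenter for rendered frames. External detections can be supplied as
JSON-lines with run-length-encoded masks (row-major, runs alternate
0-value and 1-value starting with the 0-run).

**NMS** is greedy in descending confidence with deterministic index
tie-breaks. Overlap is measured as *mask* IOU when masks are available and
box IOU otherwise: two crossing elongated instruments routinely share more
than half of their hull boxes while sharing almost no pixels, and box-IOU
suppression would delete one of them.

**Tracker.** A constant-velocity Kalman filter over
(cx, cy, aspect, h, and their velocities), with process and measurement
noise scaled to the box's characteristic size √(w·h). The usual
pedestrian-tracking convention scales noise to box height alone; the
height of a rigid instrument pivoting about its entry port collapses as
the shaft passes through horizontal (observed aspect excursions 2 → 11 → 4
within ~0.6 s), which makes height a poor size proxy here. For the same
reason the association gate uses the predicted *centre* only (squared
Mahalanobis distance in (cx, cy), chi-square 0.95 quantile at 2 dof,
5.9915); the full 4-D distance is computed and exposed but not used for
gating. Association runs as a matching cascade over track age (most
recently updated first) with combined cost
`0.02·(motion/gate) + 0.98·(appearance cosine distance)`, followed by an
IOU-only pass (gate 0.3) in two stages: confirmed tracks unmatched for
exactly one frame first, then tentative tracks — so a momentarily gated
confirmed track is not robbed of its detection by the hypothesis it just
spawned. Assignments solve the Hungarian problem
(`scipy.optimize.linear_sum_assignment`).

Track lifecycle: tentative → confirmed after 3 consecutive hits,
confirmed → lost after 30 unmatched frames, lost → deleted after 60; a
lost track that re-associates is restored. At most **three** tracks may be
confirmed at once — a surgical view shows at most three instruments — and
a confirmation blocked by the cap is granted as soon as a slot frees.
Confirmed tracks emit their trajectories retrospectively over their full
history including the tentative phase, so a stably tracked instrument has
no warm-up gap in its trajectory.

**Re-identification.** The appearance descriptor is classical: over a 3×3
grid of the box, an 8 hue × 4 saturation colour histogram plus a 9-bin
gradient-orientation histogram per cell, each cell L2-normalized and the
whole vector L2-normalized (369 dimensions). When the detection mask is
available the histograms are restricted to foreground pixels; a thin
diagonal shaft occupies a small fraction of its hull box and background
otherwise dominates (inter-identity cosine distances collapse from ~0.8
to ~0.35 without masking). Any stronger embedding with unit-norm output
drops in behind the same interface.

The cascade keeps an offline *gallery* of up to 50 exemplars per identity
(FIFO, at most 3 identities), fed only from high-confidence detections
whose mask overlaps no other detection. Stage 1 ranks identities by
minimum cosine distance to the query. When stage 1 predicts an identity
*change*, stage 2 fits an online bag-of-visual-words model on the previous
10 frames: dense 8×8 patches (stride 4) with colour-mean + gradient-mean
features, a k-means vocabulary (k = 32, seeded, capped iterations), and
per-identity word histograms compared by cosine similarity. The online
vote is accepted only if it names one of the two candidates (incumbent or
stage-1 proposal); otherwise the incumbent is kept. Appearance ties
(cosine distance within 0.02) retain the incumbent — motion continuity
wins when appearance is uninformative. No identity is ever assigned to two
concurrent confirmed tracks; conflicts resolve by match distance, the
loser taking its next-best identity.

**Indicators.** Console overlays (left-arm, right-arm, camera-arm glyphs)
are recognized by normalized cross-correlation template matching inside
fixed anchor regions; presence means score ≥ 0.8. Gating marks trajectory
samples invalid-for-motion during camera motion (screen motion is not hand
motion) and while the instrument's arm is inactive; positions are never
altered, only flags. Camera-motion frames are excluded from displacement
but counted toward laparoscopy-usage duration.

**Tips and calibration.** The tip of a border-contacting mask is the mask
pixel farthest from the centroid of its border-contact pixels; for an
interior mask it is the extreme pixel along the major principal axis on
the thinner end (end widths compared within windows covering 15% of the
axis range — the tapered tip holds few pixels, so pixel-quantile windows
would dilute it with shaft). Ties break toward smaller y, then x. Shaft
width is the median mask extent perpendicular to the major axis, sampled
over the central shaft (10th–60th percentile of the axial coordinate,
clear of the tip taper), and requires elongation ≥ 2. Calibration uses the
known 8 mm shaft diameter: mm/px = 8 / width_px, measured once on the
first qualifying frame and held for the video; zoom changes during a video
are a known error source of this scheme. Tracking-accuracy evaluation
converts both predicted and ground-truth trajectories with the scene's
known calibration so that calibration error is assessed separately from
tracking error.

## Motion metrics

Nine metrics per operation, computed from gated, calibrated trajectories:

| metric | definition | units |
|---|---|---|
| time to completion | analyzed span / fps | s |
| instruments out of view | maximal intervals in which an active arm has no instrument in view | count |
| instrument collisions | overlap-onset events between two instruments' masks (boxes as fallback) | count |
| economy of motion | Σ‖p_{t+1} − p_t‖ over consecutive valid-motion samples, summed over instruments | mm |
| average speed | economy of motion ÷ time in motion | mm/s |
| number of movements | maximal runs of smoothed speed (5-sample moving average) above 2 mm/s lasting ≥ 0.2 s | count |
| economic factor | mean over movement episodes of net displacement ÷ episode path length | – |
| instrument changes | membership changes of the active-instrument set (arm swaps) | count |
| laparoscopy usage | count and total duration of maximal camera-motion intervals | count, s |

"Time in motion" for average speed is the duration of valid samples whose
smoothed speed exceeds the movement threshold; this follows the
metric-vector invariant `average_speed × moving_time ≤ economy_of_motion`
and keeps average speed from collapsing onto the time-normalized economy
column (they would otherwise be identical after normalization). A video
with no motion at all has average speed 0. Collisions are counted as
pair-onset events, not overlap frames. The "economic factor" is nowhere
given a formula in the surgical-metrics literature we follow; the
displacement-to-path-length straightness ratio is this package's stated
interpretation. Out-of-view is counted as events; the duration is also
available.

**Normalization** is two-stage: (1) every duration-dependent metric is
divided by its video's completion time (counts become rates, path length
becomes mm/s; completion time itself and the intensive metrics pass
through); (2) each column is z-scored across the fitted cohort. The
transform is stored (JSON) and re-applicable to new subjects.
Zero-variance columns standardize to zeros with a warning.

## Skill model

Three families: multinomial logistic regression, Gaussian-kernel SVM
(tuned over C ∈ {0.1, 1, 10, 100}) and a Gini random forest (tuned over
n_trees ∈ {50, 100, 200, 500} × depth ∈ {2, 3, 5, ∞}), all selected by
5-fold cross-validated accuracy with a hard cap of 500 candidate
evaluations. Class imbalance is corrected by SMOTE — each synthetic point
lies on the segment between a minority sample and one of its k = 5
nearest same-class neighbours — applied **inside each training fold
only**; oversampling before splitting would leak interpolants of
validation points into training. The final model refits on all training
data (SMOTE-balanced). Feature importance is the forest's normalized mean
Gini impurity decrease. Labels use the fixed order
novice < skilled < expert for confusion-matrix layout.

## The simulators

**Scene simulator.** Instruments are flat-shaded capsules of configurable
width (default 12 px) ending in a tapered wedge (length 2× width), pivoting
about fixed entry ports just outside the left/right image border; tips
follow shape-preserving (PCHIP) interpolations of waypoints. Pixel grid is
0-based, origin top-left, boxes half-open. The ground-truth tip label is
the rendered distal apex pixel (farthest mask pixel from the border-contact
centroid, the same geometric definition the tip detector implements); a
test pins this label to within 3.5 px of the continuous wedge apex.
Occlusion events steer one instrument's tip smoothly (~1 s cosine ramp)
past the other's tip so the shaft bodies genuinely cross; exits remove an
instrument from view for a scheduled interval; camera events translate the
whole scene (background pans, instruments shift) and display the
camera-arm glyph. Same-side instruments keep disjoint working bands and
separated ports, as hands do — without this, two shafts can drift into
near-coincident lines that no detector could separate. Appearance is a
per-instrument hue with longitudinal stripes; the background is smoothed
seeded noise over a tissue-toned base. All randomness flows from one seed;
scenes are byte-reproducible.

The default study scene for end-to-end checks is 500 frames at 23 fps,
480×360 px, three instruments, three crossings, one exit per instrument
and one camera pan. On such scenes at zero detection noise the pipeline
must reproduce ground truth exactly: tip RMSE 0 mm, AUC 1 at 1/2/5 mm,
Pearson 1 per axis, zero identity switches, event counts equal and
continuous metrics within 2%.

**Skill-cohort simulator.** Each subject is one simulated operation: two
instruments alternating pauses and wandering movement episodes inside a
120×90 mm workspace (5 Hz sampling), with out-of-view excursions,
steered collision approaches, arm swaps (a third identity taking over the
right arm) and camera-motion intervals injected at class-conditional
Poisson rates. Class-conditional parameters (mean ± between-subject sd)
default to: duration 300/240/200 s, moving speed 4.0/4.5/5.0 mm/s,
path inefficiency 1.7/1.45/1.2, duty cycle 0.70/0.45/0.30, out-of-view
4/2/0.7, collisions 3/1.5/0.5, arm swaps 3/2/1 and camera use 4/3/2 per
video for novice/skilled/expert. These effect sizes are free parameters of
the simulation, chosen once so the classes are separable but overlapping;
the dominant separator is the economy-of-motion rate (path per unit time
falls with skill as the duty cycle drops and paths straighten).
A second parameter set (`economy_dominant_class_params`) flattens every
other difference and varies the duty cycle only, for injected-effect
recovery checks of the importance analysis. Configuration validation
enforces the ordering expert ≤ skilled ≤ novice in inefficiency,
out-of-view and collision rates.

**What the synthetic experiments do not show.** The simulator has rigid
straight instruments, no tissue deformation or specularity, no motion
blur, exact masks (or parametrically corrupted ones), and glyphs rendered
pixel-identically to their templates. Passing the zero-noise criteria
therefore certifies the *logic* of the pipeline — association, identity
maintenance, gating, geometry, bookkeeping — not performance on clinical
video, where segmentation error dominates. The noise model covers the
first-order failure modes (jitter, misses, false positives, merged masks
under occlusion) but not correlated appearance drift or gradual zoom.
Likewise the cohort generator realizes the *stated* class differences; it
cannot validate that real surgeons differ this way.

## Numerical choices and degenerate inputs

- Association costs are gated to a large sentinel (1e5); gated matches are
  removed after assignment. Confidence ties in NMS break by input index.
- Kalman extrapolation clamps aspect ≥ 1e-3 and height ≥ 1 px so coasting
  tracks keep valid boxes.
- The detection-AUC ROC is traced by sweeping the confidence threshold
  with TPR = TP/(TP+FN) and FPR = FP/#FP, padded to (1, max TPR) when
  there are no false positives; with everything correct and nothing missed
  the area is exactly 1. Monotonicity in the tolerance holds when errors
  are consistently confidence-ranked (it is not a theorem for arbitrary
  confidence/label patterns).
- Ground-truth comparison runs at 2 samples per second by default
  (stride = round(fps/2)), the cadence at which real videos are hand
  labelled; full-rate comparison is a flag.
- Empty masks, empty galleries, vocabularies larger than the patch count,
  zero-variance correlation inputs and misaligned frame ranges raise
  `ValueError` with specific messages rather than propagating NaNs.
- Problem sizes used by the built-in studies: 500-frame end-to-end scenes;
  10,000 compared tip samples for the jitter calibration; 40 re-ID events
  (20 re-entries, 20 crossings); 52-subject cohorts split 40 train /
  12 test (4 per class); 20 seeded runs for the importance study.

## Known limitations

- Monocular geometry: no depth; out-of-plane motion is invisible, exactly
  as for the 2-D tip benchmarks the evaluation mirrors.
- Calibration is per-video and breaks under zoom changes mid-video.
- The arm-to-identity mapping is inferred from each instrument's entry
  side; consoles that do not constrain entry sides would need the mapping
  supplied.
- The identity cap of three is structural; a fourth instrument would be
  tracked only after one of the three is deleted.
- Re-ID accuracy depends on instruments being visually distinguishable;
  identical instruments are disambiguated only by motion continuity.
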