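# surgtrack

Multi-instrument tracking and quantitative surgical-skill assessment from
endoscopic video.

Rating a surgeon's technical skill today means an expert watching hours of
video and filling in a rubric (OSATS, GEARS). Most of what those rubrics
score is visible in how the instrument *tips* move: how far they travel,
how fast, how straight, how often they leave the view or collide.
`surgtrack` turns a robotic-surgery video into exactly those numbers, and
those numbers into a novice / skilled / expert prediction.

The toolkit is aimed at surgical data-science groups who have per-frame
instrument detections (from any segmentation model, or from the built-in
classical segmenter) and want the downstream machinery: identity-stable
tracking, tip trajectories in millimetres, the nine motion metrics and a
tuned classifier — plus a synthetic scene simulator that provides exact
ground truth for validating every stage.

## The method

**Tracking by detection.** Per-frame detections (box + mask + confidence,
class-free) are linked into tracks by a constant-velocity Kalman filter
over (cx, cy, a, h), a matching cascade combining appearance cosine
distance with a Mahalanobis-gated motion distance, and Hungarian
assignment; at most three tracks can be confirmed at once, because a
robotic view shows at most three instruments.

**Cascaded re-identification.** Instrument identity survives exits and
crossings through two stages: an offline gallery of appearance exemplars
ranked by cosine distance (rank-1 CMC is the headline accuracy), and —
whenever the gallery predicts an identity *change* — an online
bag-of-visual-words model trained on the previous 10 frames that must
second the change, otherwise the incumbent identity is kept.

**Tips and millimetres.** The tip is located geometrically from the mask
(the distal apex of the shaft), and pixel motion is converted to
millimetres through the known 8 mm shaft diameter measured in pixels on
the first usable frame:  mm/px = 8 / width_px.

**Indicator gating.** Fixed-position console overlays are recognized by
template matching: arm-status glyphs say which of the (at most two) arms
are actually driven, and the camera-arm glyph marks laparoscope motion.
Displacement during camera motion or on inactive arms never counts as
hand motion.

**Nine motion metrics** per operation — time to completion, instruments
out of view, instrument collisions, economy of motion (total tip path,
mm), average speed (mm/s), number of movements, economic factor
(movement straightness), instrument changes, laparoscopy usage — are
normalized to operation time and then z-scored, and feed a linear /
Gaussian-SVM / random-forest classifier tuned by 5-fold cross-validation
with SMOTE balancing inside the training folds.

## Worked example

Simulate a 200-frame two-instrument scene (one crossing, two exits, one
camera pan), run the full pipeline on oracle detections at zero noise, and
score it against the scene's ground truth:

```python
from surgtrack.scene import Scene, default_scene_config
from surgtrack.pipeline import PipelineConfig, run_pipeline, evaluate_against_gt
from surgtrack.tips import Calibration

cfg = default_scene_config(n_frames=200, n_instruments=2, seed=7)
scene = Scene(cfg)
res = run_pipeline(
    scene,
    PipelineConfig(calibration_override=Calibration(cfg.shaft_width_px, cfg.shaft_width_mm)),
)
for name, value in res.metrics.as_dict().items():
    print(f"{name:24s} {value:10.3f}")
rep = evaluate_against_gt(res, scene.ground_truth)
print("tip RMSE (mm):", rep.rmse_mm, " AUC@1/2/5mm:", [rep.auc_at[t] for t in (1.0, 2.0, 5.0)])
print("identity switches:", rep.identity_switches, " compared samples:", rep.n_compared_samples)
```

prints

```
time_to_completion            8.696
instruments_out_of_view       2.000
instrument_collisions         1.000
economy_of_motion           778.509
average_speed                48.657
number_of_movements           4.000
economic_factor               0.633
instrument_changes            0.000
laparoscopy_duration          0.435
laparoscopy_count             1.000
tip RMSE (mm): 0.0  AUC@1/2/5mm: [1.0, 1.0, 1.0]
identity switches: 0  compared samples: 32
```

Both instruments travelled 778.5 mm of tip path in an 8.7 s clip (the
simulator moves instruments briskly), moving at 48.7 mm/s while in
motion, in 4 discrete movements of straightness 0.63; each instrument
left the view once while its arm was active, the scheduled crossing was
counted as 1 collision, and the single camera pan lasted 0.43 s. Against
ground truth the recovered tips are exact: RMSE 0 mm, AUC 1 at every
tolerance, no identity switches.

The same stages are available from the shell:

```
surgtrack simulate --n-frames 200 --seed 7 --out scene/
surgtrack track --scene scene/ --out out/
surgtrack metrics --scene scene/ --out metrics.csv
surgtrack skill-train --metrics metrics.csv --labels labels.csv --model random_forest --out model.bin
surgtrack skill-predict --model model.bin --metrics new.csv
surgtrack evaluate --scene scene/ --out eval.json
```

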