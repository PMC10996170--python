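# pfmus

Automatic evaluation of pelvic-floor-muscle (PFM) contractions from
transabdominal B-mode bladder-ultrasound video.

## The problem

Pelvic floor muscle training (PFMT) is the first-line conservative
treatment for urinary incontinence, but most patients cannot tell
whether they are contracting the right muscles. In a transverse
transabdominal ultrasound view the urine-filled bladder appears as a
dark (anechoic) region, and a *correct* PFM contraction elevates the
bladder base (the inferior wall moves cranially), while a *failed*
contraction — straining, breathing, probe wobble — moves the whole
bladder rigidly instead. `pfmus` implements the full analysis chain
that turns self-recorded bladder videos into a four-class judgment per
contraction attempt (`undeterminable`, `correct`, `failure`, `none`):

1. **synth_us** — a seeded generator of synthetic bladder-ultrasound
   recordings with event logs (contract/rest call times), per-attempt
   class labels, and exact ground-truth geometry. Class-specific motion
   models: raised-cosine inferior-wall elevation for `correct`,
   rigid translation plus breathing oscillation for `failure`, a static
   bladder for `none`, and occlusion dropout that defeats segmentation
   for `undeterminable`.
2. **preprocess** — trims recordings into per-contraction clips around
   each contract/rest call pair, and segments the bladder per frame
   (speckle-smoothed automatic threshold → largest dark component →
   sub-pixel boundary). Failure is explicit, never a degenerate contour.
3. **landmarks** — five landmarks per frame: the endpoints **Left**,
   **Right** of the maximum-length diameter of the contour, its
   midpoint **Center**, and the wall crossings **Top**, **Bottom** of
   the vertical line through the Center. Landmark x/y-coordinates are
   sampled every 10th frame of the 24 fps video (2.4 Hz).
4. **features** — per clip: the bladder-area surrogate
   `|Right_x − Left_x| · |Bottom_y − Top_y|` (a urine-volume proxy),
   the bladder-base elevation `max(Bottom_y) − min(Bottom_y)`, and a
   fixed catalogue of 19 time-series features (moments, change
   statistics, peak counts, DFT magnitudes `|Σ_j (x_j − x̄) e^{−2πi jk/N}|`)
   per coordinate channel. Feature columns containing missing values
   are excluded dataset-wide.
5. **classify** — 70/30 stratified split, 5-fold cross-validated model
   comparison ranked by accuracy (gradient boosting, random forest, and
   a multinomial-logistic reference), exhaustive grid-search tuning,
   held-out evaluation with one-vs-rest confusion-matrix metrics
   (recall `TP/(TP+FN)`, precision `TP/(TP+FP)`, `F1 = 2PR/(P+R)`,
   macro-averaged; one-vs-rest macro AUC), and top-10 split-gain
   feature importances.
6. **pipeline** — one-seed orchestration of the whole experiment with
   persisted intermediates, plus a `pfmus` CLI
   (`simulate`, `preprocess`, `landmarks`, `featurize`, `train`,
   `evaluate`, `all`).

## Worked example

```python
from pfmus import ExperimentConfig, SimulationConfig, run_experiment

config = ExperimentConfig(
    simulation=SimulationConfig(n_contractions=4),
    n_recordings=24,          # 96 contraction clips
    k_folds=5,
    seed=42,
)
report = run_experiment(config, "pfmus_demo")
```

prints (via the snippet in `scripts/`-style reporting):

```
chosen model : random_forest_ensemble {'n_estimators': 200, 'max_depth': None}
accuracy     : 0.966
macro AUC    : 0.972
macro recall : 0.958
confusion (rows=true, cols=pred, order=undet/correct/failure/none):
[[5 0 0 1]
 [0 8 0 0]
 [0 0 6 0]
 [0 0 0 9]]
top-5 feature importances:
  Bottom_y__variance                              0.1
  Area__range                                     0.1
  Bottom_y__range                                 0.1
```

96 synthetic clips are simulated, segmented and featurized; the model
comparison selects a tree ensemble, tunes it by grid search, and the
held-out set (29 clips) is classified with 96.6% accuracy. One
`undeterminable` clip whose sampled frames happened to be readable is
mistaken for `none` — exactly the confusion the missing-data design
predicts. The importance ranking is dominated by `Bottom_y` features:
bladder-base motion is what separates a correct contraction, matching
the clinical rationale. The same run from a shell:

```bash
pfmus all --seed 42 --out pfmus_demo
```

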