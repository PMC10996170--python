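# Methods

## Coordinate and label conventions

Images use the raster convention: origin top-left, x rightward, y
downward, 0-based pixel indices. "Elevation" of the bladder base is
therefore a *decrease* in the Bottom landmark's y. All in-scope
features (ranges, moments of differences, mean-removed spectra) are
invariant to the vertical orientation, so no result depends on this
choice. The four contraction classes are, in fixed order:
`undeterminable`, `correct`, `failure`, `none`.

## Synthetic recording model

Each recording is `n_contractions` cycles of `contraction_s` seconds of
contraction followed by `rest_s` seconds of rest, at `fps` frames/s.
The resting bladder is an ellipse with half-widths `semi_axis_x`,
`semi_axis_y` centred in the frame; varying the semi-axes across
recordings (±15% by default) emulates different urine volumes.

Within each contraction interval `[t0, t1]` the activation is a
raised-cosine bump `s(t) = ½(1 − cos 2π(t−t0)/(t1−t0))` — smooth,
compactly supported, peaking mid-interval; no specific kinematic
profile is claimed beyond that.

* `correct`: the lower boundary moves up by
  `base_amplitude_px · s(t) · max(sin θ, 0)` (θ the ellipse parameter),
  so the Bottom landmark moves by the full amplitude, the deformation
  is continuous around the wall, and the upper boundary is static.
* `failure`: the whole contour translates down by
  `translation_amplitude_px · s(t)` and oscillates horizontally as
  `translation_amplitude_px · sin(2π·breathing_freq_hz·t)` — rigid
  motion from straining and breathing, with no differential base
  motion. The single amplitude knob serves both components.
* `none`: static.
* `undeterminable`: static geometry, but each frame is occluded with
  probability `dropout_prob` by a bright band covering the bladder, so
  segmentation fails. This class is defined operationally as
  "unreadable", not by a distinct motion model.

Rendering: pixels inside the contour are near-dark (anechoic lumen,
level 25), the background is bright (level 160) with multiplicative
speckle `I·(1+n)`, `n ~ N(0, speckle_var)`. Levels leave headroom so
speckle rarely saturates 255 and the intensity histogram stays bimodal.
Isotropic vertex jitter (std `jitter_px`) models boundary noise.
Ground truth carries the rendered (jittered) contours and the
noise-free landmark trajectories from the closed-form motion model.

Defaults (the package's study conditions, chosen once): 128×128 frames,
24 fps, 4 cycles of 3 s + 3 s, semi-axes 30×18 px, base amplitude
10 px, translation 8 px, breathing 0.25 Hz, jitter 0.3 px,
`speckle_var` 0.02, `dropout_prob` 0.6. The default experiment is 60
recordings (240 clips), balanced class mix, two recordings per
simulated participant. Real bladder-base displacement in pixels depends
on probe depth and scanner settings; these amplitudes are free
parameters of the simulator, not calibrated to any population.

What the generator deliberately omits: ultrasound wave physics, probe
geometry and fan-shaped fields of view, 3-D anatomy, acoustic shadows,
tissue layers, and operator variability. Passing tests therefore show
that the analysis chain recovers the class structure *it encodes* —
differential base motion vs. rigid motion vs. unreadability — not that
it would reach the same numbers on clinical recordings.

## Preprocessing

Clips are `[contract call, rest call]` windows padded by 0.5 s per side
(clamped to the recording), so onset and release motion around the
calls is retained; frame indices are `round(t·fps)`.

Segmentation: Gaussian speckle smoothing (σ = 1.5 px) → Otsu threshold
→ dark mask → morphological closing (disk r = 2) → largest connected
component (≥ 1% of the frame) → boundary traced as the iso-contour of
the *smoothed image* at the threshold level. The smoothing step matters:
a variance-based threshold on raw speckle is unreliable when the dark
region is a small fraction of the frame. The iso-contour gives
sub-pixel boundaries (the level crossing of a blurred step sits on the
true edge), where tracing the binary mask would dilate every extent by
half a pixel per side and bias the area surrogate by several percent.
Two guards reject frames without a genuinely dark region (minimum
contrast 20 intensity levels; mean dark/bright ratio ≤ 0.5), which is
how occluded frames fail. Failure is always an explicit status — never
a zero-area contour — so missingness propagates cleanly.

## Landmarks

The maximum diameter is computed by exhaustive search over all contour
vertex pairs (the contours here have ≤ a few hundred vertices; an
all-pairs distance matrix is fast and trivially correct). Left is the
endpoint with smaller x (smaller y on a tie); ties between equally long
chords go to the lexicographically smallest (left, right) pair. Top and
Bottom are the global min-/max-y crossings of the vertical line through
the Center with the contour's edges, by linear interpolation along each
edge — a concave wall may cross more than twice, hence global extremes.
A frame whose landmarks cannot be computed becomes a missing sample,
never an aborted clip. Stride sampling starts at the clip's first frame
(stride 10 at 24 fps → 2.4 Hz).

## Feature catalogue

A fixed, versioned catalogue (`pfmus-catalogue-1.0`; 19 features per
channel) replaces open-ended automatic feature generation, for
reproducibility and testability: mean, minimum, maximum, median,
standard deviation, variance, range, mean absolute change, count above
mean, lag-1 autocorrelation, linear trend slope (per second),
number of peaks with support 1 and 3, |DFT coefficients| k = 1..4 of
the mean-removed series, dominant frequency (argmax bin × rate / N),
and spectral energy Σ|X_k|²/N. Channels: the 10 landmark coordinates
plus the Area surrogate; `base_elevation` is a per-clip scalar.

Missing-value semantics: moment-type features use the observed samples
in temporal order (the trend slope uses their true sample times);
spectral features require a gap-free series of ≥ 4 samples, since a DFT
on a gapped sampling grid is ill-defined. Clips with zero observed
samples are dropped as rows (logged); afterwards any feature *column*
containing a missing value anywhere in the dataset is excluded —
exclusion is per-feature, not per-clip, so `undeterminable` clips stay
in the table as labelled rows while their sparse sampling drives the
column exclusion. In the default 4-class experiment this removes the
spectral and sequential columns (210 → ~110 features) and the
classifier works on the robust moment features.

## Classification protocol

70/30 split (test size `round(n·0.3)`), stratified by class; a
participant-grouped split is available because clip-level splitting
leaks participant identity across sides, but the default mirrors
clip-level practice. 5-fold stratified CV compares gradient boosting
(LightGBM), random forest, and a multinomial-logistic reference
(standardized inputs); models are ranked by mean fold accuracy and the
best tree ensemble is grid-search tuned (exhaustive, mean CV accuracy,
ties to the first-listed combination) and refitted on all training
data. Metrics come from the 4×4 confusion matrix one-vs-rest:
per-class TP/FP/FN/TN, recall, precision, F1 = 2PR/(P+R); macro
averages are unweighted class means; 0/0 ratios are reported as 0 and
flagged. AUC is one-vs-rest per class from predicted probabilities,
macro-averaged over classes present in the evaluation set (absent
classes excluded with a warning). Importances use the split-gain
convention, descending, ties alphabetical.

The model roster is three algorithms, configurable — a wider zoo adds
nothing at desk scale. Seeds: one global experiment seed derives
per-stage seeds by fixed offsets, so stages are independently
reproducible; all estimators run single-threaded for determinism.

## Importance-probe setting

When classes are separated by a large margin, greedy boosting puts all
split gain on one of many equally informative correlated features and
the rest of the top-10 fills with zero-gain ties — the ranking then
says nothing about feature *structure*. The importance probe (used by
the acceptance script and the structure test) therefore fits the
boosting model with `colsample_bytree = 0.5`: per-tree feature
subsampling decorrelates gain attribution and spreads it across the
informative family, the same reason random-forest importances are
preferred for correlated features. This setting is used only for the
importance analysis, never for the accuracy protocol.

## Numerical choices and degenerate inputs

* Otsu on a near-constant frame is meaningless → explicit contrast
  guard, frame fails segmentation.
* `number_of_peaks(n)` requires a sample strictly greater than its n
  neighbours on both sides; boundary samples cannot qualify.
* `abs_fft_coefficient(k)` is missing when k exceeds N/2.
* Lag-1 autocorrelation of a constant series is undefined → missing.
* An empty hyperparameter grid, a class smaller than k in CV, a class
  absent from the training split, and a feature table with no
  surviving columns all raise immediately with remediation hints.
* Problem sizes (240-clip default experiment, 30-recording probes,
  96×96 test fixtures) are chosen so the full chain runs comfortably on
  a single CPU; geometry is resolution-independent, so small frames
  lose no generality.

## Known limitations

* The segmenter is a stand-in adequate for the synthetic appearance
  model; it has no claim to robustness on clinical images.
* The generator's class geometry is idealised; `undeterminable` is
  modelled purely as unreadability, so any real-world motion signature
  of undeterminable clips is out of reach.
* Near-ceiling accuracy on the default conditions reflects the
  generator's high signal-to-noise ratio, not expected clinical
  performance.
* The feature catalogue is a compact, documented subset of what
  open-ended extractors produce; counts are not comparable to
  library-generated feature sets.
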