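# Methods

This note records the models implemented by `stripgan`, the assumptions
behind them, the defaults that matter, and the design choices made where
the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Strip simulator (`stripsim`)

The simulator is the package's study fixture: it emulates photographs of
lateral-flow strips at five analyte levels (0, 0.25, 0.5, 0.75, 1.0
μg/mL) grouped into blank / low / high classes, 0 ⇔ blank,
{0.25, 0.5} ⇔ low, {0.75, 1.0} ⇔ high.

A strip is rendered as background color minus two tinted bands, times a
lighting ramp, plus noise, clipped to [0, 1]:

* **Geometry.** Control line centered at 30% of image height, test line
  at 60%, band thickness 4% of height (`band_frac`). Real strip geometry
  varies by cassette; fixed fractions make line cropping deterministic
  and give the simulator exact ground-truth line rows for testing the
  auto-detector. `TOY_PROFILE` raises the thickness to 15% so bands
  remain at least one pixel row in 16×16 renders.
* **Band contrast.** The test-line contrast follows a saturating binding
  curve, {0: 0, 0.25: 0.35, 0.5: 0.50, 0.75: 0.65, 1.0: 0.80}, with
  ±15% multiplicative per-strip jitter; the control line always develops
  (contrast 0.85 ± 7.5%). The curve's shape (steep early, flattening
  toward 1 μg/mL) mimics immunoassay dose–response; its exact values are
  a package choice.
* **Lighting.** A multiplicative linear ramp of amplitude ±15% oriented
  at a per-strip uniform angle — the simplest model that makes
  illumination a class-independent nuisance variable. It is a stand-in;
  no claim is made about any specific capture rig.
* **Noise.** I.i.d. Gaussian per pixel (default sd 0.02), then clip;
  Student-t(3) noise is available as a profile option for heavier tails.
* **Determinism.** Identical parameters and seed give bit-identical
  pixels; datasets are fully reproducible from one seed.

What the simulator does **not** capture: membrane texture, perspective
and camera optics, glare, background clutter, batch-to-batch reagent
variation. Passing tests therefore demonstrate that the pipeline's
mechanics work and that its orderings (e.g. mixed beats sparse-real) hold
on data with this structure — not that any particular accuracy carries
over to real photographs.

Default render size is 3×660×50, the standardized raw strip resolution
used by the preprocessing chain; test profiles render smaller images for
speed. The renderer accepts any size down to 16×8 so that the 16×16 toy
profiles used by the GAN and experiment modules can be rendered directly.

## Preprocessing (`preprocess`)

The standardization chain is 3×H×W → tight edge crop resized to 3×660×50
→ symmetric zero padding to 3×660×660 (content columns 305–354) → a crop
spanning the two detected line rows, resized to 3×128×128. Decisions:

* Foreground for the edge crop is any pixel with channel-mean > 0.05
  (strips are bright on dark backgrounds); an empty mask raises a
  segmentation error.
* Line auto-detection takes the two most prominent minima (prominence
  ≥ 0.05) of the Gaussian-smoothed row-mean intensity profile, computed
  over content columns only. Fewer than two minima (e.g. a blank strip
  with only a control line) raises an error carrying the profile.
* The crop window extends past each line by 20% of the inter-line
  distance (configurable).
* Rotation augmentation uses bilinear interpolation about the image
  center with zero fill, matching the zero-padding convention; the
  schedule k·step for k = 0..N−1 requires step to divide 360° exactly
  (3.6° → 100 images per input). Rotation is applied to the final
  128×128 (or toy-size) image, not the raw strip — the alternative order
  is equally defensible; this one keeps the augmented dataset's shape
  contract trivial. The batched sampler `rotate_batch` is unit-tested
  against `skimage.transform.rotate` and exists so that full-revolution
  schedules over thousands of images stream in seconds.

## Direct self-attention (`attention`)

The block computes Q = W_f x, K = W_g x, V = W_v x with C→C 1×1
convolutions, contracts Q and K over channels into one score per spatial
position, applies a max-subtracted softmax over all positions to get a
single map M ∈ R^{H×W}, and outputs y = γ·(H·W·M ⊙ V) + x.

Design notes:

* The channel contraction is the only realization consistent with both
  "no reshape/transpose of the feature space" and "an intuitive attention
  map with spatial information": a full position-by-position affinity
  matrix cannot be formed without flattening. The classical flattened
  formulation is retained as `SAGANAttention` for ablation.
* The H·W factor keeps the attended output on the scale of V: under a
  uniform map M = 1/(H·W), the output is exactly V.
* γ starts at exactly 0, making a fresh block a bit-exact identity; the
  residual lets attention fade in at the rate training finds useful.
  Softmax normalization is asserted to 1e-6.
* Inside the critic, weight clipping (below) crushes W_f/W_g magnitudes,
  so critic attention maps stay near-uniform at toy scale; the
  generator's attention (not clipped) is where map structure appears.

## GAN (`gan`)

* **Losses.** critic: mean(fake) − mean(real); generator: −mean(fake).
  No logarithms, no sigmoid on the critic output.
* **Optimization.** RMSProp for both networks; after every critic update
  all critic weights are clipped to [−clip_value, clip_value]. Defaults
  clip 0.01, 5 critic steps per generator step, learning rate 5e-5 — the
  canonical values for weight-clipped Wasserstein training; all
  configurable.
* **Generator.** A U-Net over a noise-seeded 16×16 canvas: dense
  projection → two stride-2 encoder convolutions → decoder with skip
  connections, the attention block at the deepest decoder scale (8×8),
  extra upsampling blocks for sizes beyond 16, a 1×1 head and a sigmoid
  to bound pixels to [0, 1]. "Fixed boundary conditions" are realized as
  zero-padded convolutions throughout. Depth/width and the attention
  insertion point are package decisions exposed in `GANConfig`.
* **Class conditioning.** One unconditional generator per class label
  (three models): QC and mixing need class-labeled synthetic images, and
  per-class models are the simplest construction that provides them.
* **Monitor.** The loss history records, at initialization and
  periodically, the exact empirical 1-Wasserstein distance between the
  band-contrast marginals of (up to 256) real images and a generated
  batch — a scalar view of distribution recovery that the tests assert
  decreases over toy training (3-seed majority).
* **Toy profile.** `TOY_GAN`: 16×16 images, 8 base channels, 32-dim
  noise, 200 generator updates, learning rate 2e-4. The raised learning
  rate is part of the toy profile because the full-scale default (5e-5)
  moves too slowly to reach the data distribution within 200 updates at
  this width; the training loop itself is identical at any scale.
* Divergence (non-finite loss) aborts with the history attached.

## Quality control (`qc`)

SSIM uses Gaussian-weighted 11×11 windows (σ = 1.5), the canonical
stability constants at data range 1, averaged over channels (window
shrinks to fit images below 11 pixels). The average hash maps the
channel-mean grayscale to √bits×√bits (anti-aliased), thresholds at the
mean, and compares by Hamming distance.

The filter is greedy in input order: reject iff SSIM > ssim_max **or**
Hamming < hamming_min against any already-accepted image. Defaults
ssim_max = 0.95, hamming_min = 4 on 64-bit hashes — conservative dedup
aimed at exact and near-exact copies. Comparison is intra-synthetic by
default; a `reference` pool adds cross-checking against real images.
Both measures are evaluated for every pair by default so the accepted
set provably contains no violating pair; the `ssim_prefilter` flag skips
SSIM when the hash distance is ≥ 2·hamming_min, trading that exactness
for speed on large pools.

## Datasets (`datasets`)

Mixing supports two framings: **ratio mode** (subsample the over-supplied
pool, class-balanced and seeded, until |real|/total equals the requested
real fraction) and **absolute-count mode** (exact per-pool counts, for
sparse-real compositions such as 300 real + 2700 synthetic). Hold-out
splits are stratified by class (80:20 default) via seeded
`train_test_split`; stratification keeps toy-scale class balance
meaningful. Label schemes: three-class (blank/low/high), binary
(negative/positive), and five-level (one label per concentration).
Undefined requests (missing classes, counts exceeding pools, classes
with fewer than two records) raise errors rather than degrading.

## Classifier and evaluation (`classify`)

The training recipe is fixed across architectures: batch 32, Adam at
1e-4, cross-entropy, 100 epochs, 128×128×3 inputs (all configurable);
the best-validation-accuracy checkpoint is retained. The default
`tiny_cnn` (three conv blocks, global average pooling, linear head) is
deliberately small so toy runs finish in seconds; the larger mobile
architectures are registry names that raise a clear "not provided"
error. The toy profile `TOY_TRAIN` uses 16×16 inputs, 8 epochs and
learning rate 3e-3 — with ~60–100 Adam updates the full-scale rate has
not converged, while 3e-3 reliably solves the band-contrast task.

Metrics: one-vs-rest reduction per class from the confusion matrix
(TP = cm[k,k], FN = row remainder, FP = column remainder, TN = rest).
Zero-denominator ratios are reported as NaN, never 0 — silently
reporting 0 would be indistinguishable from genuinely poor performance.
ROC is one-vs-rest with a threshold sweep over unique scores and
trapezoidal AUC; degenerate label sets set an `undefined` flag. t-SNE is
an export-only diagnostic (no assertions on cluster shape beyond a
sanity property on well-separated blobs).

A known data quirk reproduced in the tests: the 30-strip worked example
(ten strips per class, two low-concentration strips misread as high)
gives accuracy 28/30 = 93.33%, low sensitivity 0.80 and high specificity
0.90. Published per-class tables for this scenario sometimes arrange
these numbers differently (e.g. high SEN 0.90 / low SPE 0.80), which is
arithmetically inconsistent with the described errors; the package
follows the scenario as described.

## Experiment grid (`experiment`)

`run_experiment` executes simulate → per-class GAN training → generation
(oversampled ×1.5 so the pool survives QC) → QC → composition → 80:20
split → classifier training → evaluation on an independently simulated
test fixture, for every (composition × size) cell. Every stage is seeded
from the spec with fixed offsets; trained generators are cached on disk
keyed by a hash of the stage parameters and seed, so re-running an
identical spec skips GAN training and reproduces the consolidated CSV
byte for byte. A failing cell records its error and the grid continues.

`augmentation_only_baseline` builds the no-GAN comparator (real pool
plus mirrored copies; the pool doubles per flip axis) and emits the same
row schema.

Problem sizes throughout the test suite and acceptance checks are the
package's toy profile: 16×16 strips, 100 real images per class, 100–150
synthetic images per class, 200 GAN updates per class, 8 classifier
epochs, with a 120-image independent test fixture. These sizes are
chosen so the complete grid is a minutes-scale, single-CPU computation
while preserving the pipeline's orderings.

## Known limitations

* The autodiff engine is float64/CPU and sized for toy-scale work; there
  is no gradient-penalty variant, spectral normalization, FID scoring,
  conditional generator, or multi-scale attention.
* Simulator realism limits are listed above; absolute accuracies on the
  simulator say nothing quantitative about real phone photos.
* The QC thresholds are heuristics for near-duplicate removal, not
  perceptual quality scores.
* Stochastic training properties (monitor decrease, attention-map
  concentration, end-to-end accuracy orderings) are asserted as
  majorities over three seeded runs, not as certainties.
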