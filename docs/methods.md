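# Methods

## Problem and model

The target task is binary, balanced classification of pears (healthy vs
woolliness-response disease) from two synchronised modalities: a
228-band near-infrared reflectance spectrum (900–1700 nm) and an RGB
photograph of the fruit.  The pipeline is a two-branch, feature-level
fusion design:

1. **Spectral branch.** Raw per-band luminance `I` is calibrated
   against a white reference `W` and dark reference `B`,
   `R = (I − B)/(W − B)`, and the five scans of each region are
   averaged elementwise.  Reflectance is stored as a dimensionless
   fraction throughout (percentages are display-only), which removes a
   whole class of silent 100× scale bugs between branches.  No scatter
   correction or derivative preprocessing is applied; the design
   philosophy is end-to-end: raw averaged spectra go straight into a
   one-hidden-layer network (ReLU hidden, sigmoid output for the binary
   decision, Adam, Glorot-uniform initialisation).  The hidden width is
   the only architectural knob, swept over 10…100 in steps of 10.  The
   post-activation hidden outputs form the spectral feature vector
   `F_b` (length = hidden width); they are non-negative by
   construction.
2. **Image branch.** Six convolutional backbone families are
   re-implemented from their published block patterns (VGG16/19 plain
   conv blocks; ResNet50/101 bottleneck residual stages; Xception
   entry → middle(×k) → exit separable-convolution flows with residual
   shortcuts; DenseNet201 densely connected blocks with halving
   transitions), each ending in a global-average-pool + dense two-class
   head, trained from scratch with softmax cross-entropy and Adam.
   Named tap points expose intermediate activations; a tap activation
   `(H, W, C)` is flattened height-major into a vector of length
   `H·W·C` (`index = (h·W + w)·C + c`).  The order is an arbitrary but
   fixed convention: the fused head is order-agnostic, but fixing it
   makes features bit-reproducible.
3. **Fusion.** `F_f = append(F_a, F_b)` — image features first, exact
   concatenation, no rescaling.  Both branch models are frozen; only a
   single dense layer to two softmax scores is trained on the fused
   vectors (argmax decision).  Freezing matches the extract-then-fuse
   narrative of the reference procedure, makes tap ablations comparable
   (identical branches, only the tap varies), and lets features be
   cached — with deterministic frozen branches, caching and per-epoch
   re-extraction are equivalent.  A `standardize` flag exists on the
   head (per-feature z-scoring) because scale mismatch between branches
   is a known hazard; it is off by default because the reference
   procedure mentions no normalisation.
4. **Evaluation.** 2×2 confusion matrices and accuracy, precision,
   recall, F1.  Averaging is **macro** (each class in turn treated as
   positive, unweighted mean).  The reference tables print only the
   binary formulas without naming an averaging convention, but macro
   averaging is the unique choice that reproduces every reconstructible
   printed value from the published error counts (e.g. precision 0.614
   for the 50/38/34/22 matrix, 0.879 for 72/49/23/0, 0.956 for
   65/72/0/7); weighted averaging coincides only because the classes
   are balanced, and single-class values do not match.  Zero-division
   convention: a class with no predicted positives has precision 0
   unless it also has no actual positives (then 1).  Display rounding
   is half-up to 3 decimals, matching the printed tables.

On any evaluation set with equal class totals, accuracy equals macro
recall exactly.  This balanced-set identity holds for every published
row except one (recall 0.951 printed for the fused deepest-residual-tap
model whose accuracy is 0.917); the reconstruction reports the
identity-consistent value 0.917 and flags the deviation rather than
matching what is almost certainly a typo.

## Synthetic data generator

The original 480-pear dataset is private, so the generator emulates its
*structure*, not its biology.  Defaults are fixed once and are the
conditions under which all statistical properties are tested:

| parameter | default | meaning |
|---|---|---|
| `n_per_class` | 240 | fruits per class (480 total, as in the study; the experiment harness defaults to 100/class for desk-scale runs) |
| `n_bands` / grid | 228, 900–1700 nm | instrument grid |
| `scans_per_region` | 5 | scans averaged per sample |
| `spectral_effect_size` | 0.08 | extra absorption-dip depth (reflectance units) of diseased fruit at 1200/1450 nm |
| `dip_scatter_sd` | 0.35 | per-sample multiplicative variability of each dip depth |
| `scatter_sd` | 0.04 | per-sample global multiplicative scatter |
| `spectral_noise_sd` | 0.01 | additive per-band, per-scan noise |
| `image_size_px` | 128 | generated image side |
| `image_effect_size` | 0.25 | fractional colour shift of diseased skin toward darker yellow |
| `blotches` | on | diseased fruit gets Poisson(2.5) darker blotches near the rim |
| `image_noise_sd` | 10/255 | per-pixel Gaussian noise |

Spectra are a fixed smooth quadratic baseline minus Gaussian absorption
dips; the disease signal lives in the dip depths (water-related bands),
mimicking the physiological account of the disorder (water loss,
mineral deficiency).  The per-dip depth variability is what keeps the
spectral branch away from perfect separation: the class means differ by
`spectral_effect_size` but individual fruits overlap.  Images are a
shaded ellipse on a near-white background; the disease signal is a
colour shift plus rim-concentrated blotches whose count can be zero, so
the image branch is imperfect too.  Both classes consume the random
stream identically (label only scales the class-dependent terms), so
zero effect sizes give literally identical class-conditional
distributions — the null case used to verify that no label information
leaks through the pipeline.

Raw-scan generation inverts the calibration: deterministic instrument
curves `W` (lamp/detector response) and `B` (dark-current drift) map
each noisy reflectance scan to luminance, so calibrate-and-average
recovers the underlying spectrum exactly at zero noise and with
residual sd `spectral_noise_sd/√5` otherwise.

The effect/noise levels were chosen once so that, at defaults, the
pipeline sits in the qualitative regime the fusion design is meant to
demonstrate — both branches clearly better than chance, neither
saturated, fused at least as good as the better branch — and were then
left alone.  What passing tests show is therefore that the *machinery*
(calibration, feature extraction, fusion, metrics) behaves correctly
and that fusion helps when modalities carry partly independent signal;
they say nothing about real pears, real spectra (no instrument drift,
no wavelength miscalibration, no correlated chemical confounds) or real
photographs (no pose, lighting or background variation).

## Scale choices

Training 100+-layer CNNs from scratch in NumPy on a laptop-class CPU is
the binding constraint, so backbones take two reduction knobs that
preserve the shape pattern: `width_scale` (channel multiplier) and
reduced block repeats (`middle_flow_repeats` for the separable-conv
family).  Desk defaults: 64 px input, width 0.25, repeats (2,2,2,2)
for residual nets, (1,1,2,2,2)/(2,2,4,2) for the plain/dense families,
middle flow ×2.  The per-stage spatial halving is untouched (64 px →
32/16/8/4/2 for residual nets), and the full-width ladder
(112/56/28/14/7 at 224 px; 2048-long exit vector) is verified directly
by constructing the full-scale models and running one forward pass.
Experiment-harness defaults use 100 samples per class and ~20 training
epochs; these sizes keep a full seeded run in minutes while leaving the
statistical checks well-powered.

## Numerical and procedural choices

- **Split.** Stratified 7:3 with `round(frac · n_class)` per class:
  480 → 336/144 with 72+72 validation — the only reading consistent
  with the published worked-example counts.  Singleton classes cannot
  be stratified and are alternated across sides (the two-sample edge
  case splits 1/1 rather than erroring).
- **Seeding.** One master seed; every stage derives its own via
  `SeedSequence(master, spawn_key=(stage_counter, k))`, so stages can
  be rerun independently and full runs are bit-reproducible (NumPy
  kernels are deterministic; the generator writes PNGs with fixed
  encoder settings, so even the files are byte-identical).
- **Spectral network training.** Settings the reference procedure never
  states: binary cross-entropy, Adam at 1e-3, up to 200 epochs, batch
  32, early stopping on a 15% validation split with patience 20.
- **Sweep/grid tie-breaks.** Best model by validation accuracy, ties to
  the smaller hidden width (prefer the simpler model).
- **Convolutions.** Computed as k² per-offset matrix products over
  strided slices — no im2col buffers, so full-scale forward passes stay
  within a laptop's memory.  Gradients of every layer are verified
  against central finite differences; forward passes against
  direct-loop oracles.
- **Baseline presets.** Fixed tuned values: PLS-DA 8 components
  (latent-projection regression on a one-hot response, argmax
  decision); SVM C=601, γ=0.15, polynomial kernel; random forest depth
  20, 15 trees, min split 3; AdaBoost and XGBoost both 50 estimators at
  learning rate 1.0.  The boosting presets being identical is an
  anomaly of the published tuning table, preserved as printed.  The
  table's AdaBoost variant/loss options ("SAMME.R", square loss) no
  longer exist in current scikit-learn and are dropped from the preset.
- **Degenerate inputs.** Calibration with `W == B` at any band raises
  naming the band index; empty/ragged scan lists, single-class training
  sets, unknown families/taps, unpaired feature matrices and empty
  fusion inputs all raise early with specific messages.

## Statistical acceptance checks

The properties tested at the default synthetic conditions, each over
five seeds with the median compared (a single chance-level draw on a
60-sample validation set has sd ≈ 0.065, so per-seed bands would fail
by design a few percent of the time; the median is stable):

- zero-effect null: spectral, image and fused validation accuracy all
  in [0.35, 0.65];
- fusion dominance: fused accuracy ≥ max(branch accuracies) − 0.02;
- depth trend: deepest-tap fused accuracy ≥ shallowest-tap − 0.05.

## Known limitations

- The generator is a structural stand-in; none of its distributions are
  calibrated to real pears, and absolute accuracies on synthetic data
  are not comparable to the published real-data tables.
- Backbones train from scratch at reduced scale; no pretrained
  representations, so conclusions about *which* family is best do not
  transfer — only the depth-of-tap and fusion comparisons are meant to.
- Binary, balanced classification only; no multi-class metrics, no
  ROC/AUC, no calibration of fused scores.
- The reference procedure's input resolution and fine-tuning depth are
  unstated; both are configuration knobs here, not fixed constants.
- Why a 90-unit spectral network is best standalone but a 30-unit one
  is best for fusion is unexplained in the source; the harness treats
  the fusion branch width as an experiment input (default 30).
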