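# Methods

## The scoring problem

Abdominal aortic calcification (AAC) on a lateral lumbar or abdominal
radiograph is graded with the Kauppila semi-quantitative system (AAC-24).
The aorta is divided into four segments at the L1–L4 vertebral levels, whose
craniocaudal boundaries sit at the midpoints of the adjacent intervertebral
spaces; each segment's anterior and posterior wall is graded 0–3 by the
calcified length fraction *f* of the segment length:

| grade | rule |
|---|---|
| 0 | no detectable calcification (*f* = 0) |
| 1 | 0 < *f* < 1/3 |
| 2 | 1/3 ≤ *f* ≤ 2/3 |
| 3 | *f* > 2/3 |

The eight grades sum to a total 0–24, categorised as no/mild (0–4),
moderate (5–15) or severe (16–24).  Both boundary fractions (exactly 1/3
and exactly 2/3) belong to grade 2; the rules are read literally, so any
nonzero calcification scores at least 1.

The package automates this score in two learned stages — vertebra L1–L5
segmentation, then CNN regression of the total on an anatomically
standardised crop — and provides the scoring engine itself
(`aacscore.kauppila`) as an exact, mask-based reference oracle.

## Synthetic phantoms

No clinical radiographs ship with the package.  Instead,
`aacscore.phantom` renders 2-D phantoms containing the structures the
method depends on: five stacked rectangular vertebral bodies with
intervertebral gaps, an anterior aortic band, per-segment calcified strips
of *known* length fraction, soft-tissue background, Gaussian noise, and
brightness/contrast/noise strata emulating multicenter acquisition
diversity.  Coordinates follow raster order (row 0 superior, rows increase
inferiorly; half-open boxes).

Design choices and what they mean for interpretation:

* **Strip morphology.**  Real calcification is punctate or arc-shaped;
  the phantom renders one contiguous strip per wall segment, flush with its
  half of the aortic band, starting at the segment's superior boundary
  (random placement is available).  The Kauppila grade depends only on
  craniocaudal covered length, which the strip model preserves exactly, so
  phantom ground truth is analytic.  Passing tests therefore demonstrate
  that the pipeline recovers *calcified length per segment*, not that it
  handles real lesion morphology, overlying bowel gas, or osteophytes.
* **Intensities.**  Bone is rendered brightest, calcification intermediate,
  soft tissue darkest (bone 0.80, calcification 0.62, aortic band 0.36,
  background 0.30 on a 0–1 scale).  No ordering of bone vs calcification is
  required by the method; they only need to be distinct.
* **Grade-band sampling.**  Cohort sampling draws per-segment fractions
  uniformly inside each grade's band with a ±0.033 margin around the 1/3
  and 2/3 boundaries, and strips are at least 1 px long.  With segment spans
  of ≥ 20 rows this guarantees that rasterising a fraction to whole rows
  cannot flip a grade, so generator–scorer agreement measures the scoring
  logic rather than rounding luck.
* **Severity mix.**  The default cohort mix (22.3% no/mild, 64.7%
  moderate, 13.0% severe) mirrors the proportions of a large multicenter
  AAC training cohort (387 : 1,124 : 226).
* **Simulated centers.**  "Centers" are photometric strata only — each
  draws a brightness offset in ±0.05, a contrast factor in 0.85–1.15 and a
  noise σ in 0.01–0.04 — not a physical acquisition model (no beam
  hardening, scatter, or geometry change).  Photometric changes never alter
  masks or ground truth.
* **Geometry jitter.**  Vertebra heights/AP lengths, gaps, and aortic
  offset/width are jittered ±10% per case so the segmenter cannot memorise
  a fixed layout.

## Mask-based scoring conventions

`score_from_masks` projects calcified pixels onto the craniocaudal axis:
the calcified fraction of a (level, wall) segment is the number of distinct
rows within the segment span containing calcified pixels assigned to that
wall, divided by the span length.  Scattered deposits count by the union of
rows, matching the "calcification length" semantics, and making the measure
robust to strip thickness.

Wall assignment splits pixels at a vertical midline through the aortic
band.  The default midline estimate — the centre of the calcification-
bearing column range — is exact whenever both walls bear calcification
somewhere in the image but is ambiguous when only one wall does, so the
midline can be passed explicitly; `phantom.score_sample` passes the
generator's recorded band midline, making the scorer an exact oracle on
phantoms.  Pixels on the midline go to the posterior wall (when the
anterior side is left, "anterior" means strictly smaller column).  Rows of
a deposit overlying a segment boundary are counted in the segment that
contains them, row by row; how human raters resolve such deposits is not
standardised, and this convention is the package's own.

## Segmentation stage

A plain U-Net (`aacscore.segmentation.UNet`): double 3×3 convolution +
batch-norm + ReLU blocks, 2×2 max pooling, nearest-neighbour upsampling
with skip concatenation, 1×1 output convolution over six classes.  Training
minimises 0.5 · soft-Dice (foreground classes) + 0.5 · cross-entropy on
Z-score-normalised intensities, with optional k-fold ensembling by score
averaging before argmax.  Post-processing keeps the largest connected
component per label, so predicted masks always satisfy
one-component-per-label.

Desk-scale defaults and why:

* **Depth 5, channels (8, 16, 32, 64, 64), whole 256×128 images, batch 4.**
  The five vertebra labels differ by *position*, not appearance, so the
  network's receptive field must span the spine column (~220 rows).  A
  depth-4 bottleneck sees only ~60 rows and reliably confuses L2/L3; depth
  5 roughly doubles that and recovers all five labels.
* **Coordinate channels.**  Normalised row/column coordinate input channels
  (on by default) make the position-to-label mapping directly learnable by
  a small network; they can be disabled.
* **Adam (lr 0.003) with polynomial decay `(1 − t/T)^0.9`, 12 epochs.**
  Only the loss is prescribed by the method; Adam converges within the
  package's desk-scale budget where plain SGD needed several times more
  epochs.  SGD with momentum remains selectable.
* **√(inverse-frequency) class weights in the cross-entropy.**  With equal
  weights the rarest foreground label occasionally collapses into
  background early in training (a known soft-Dice failure mode); tempered
  inverse-frequency weighting removes the collapse without destabilising
  the majority classes.
* A full-scale preset (`SegConfig.clinical_preset()`) retains the 9-level
  encoder with channels 32–512, 1,536×1,024 patches, batch 2, five folds.

The ROI-coverage check (`check_roi_coverage`) accepts a mask when all five
labels are present, each is a single component, their superior→inferior
order is correct, and each height is within 0.3–3× the median height.
These criteria (and their bounds) are this package's own operational
definition of "usable for ROI extraction"; they are configurable.

## ROI extraction

The regressor input crop spans, vertically, from the estimated inferior
border of T12 to the inferior border of L5, and horizontally from the
posterior-most vertebral extent to the anterior-most extent extended
anteriorly by 0.75 × the mean anteroposterior vertebral length (to cover
the aorta).  Because only L1–L5 are labelled, the T12 border is estimated
as L1's superior extent minus half the mean intervertebral gap — the
T12–L1 gap resembles the lumbar gaps — and the factor is configurable.
The crop is clamped to the image, Z-score normalised (an all-constant crop
maps to zeros), and bilinearly resized to 500×1,000 (cols×rows) at full
scale or 125×250 at desk scale.  Normalising before resizing is a recorded
package choice; the `Patch` carries its normalisation record and crop
provenance.

## Regression stage

A residual CNN with concurrent spatial-and-channel squeeze-and-excitation
(SCse) attention after every residual block, and a head of batch-norm →
dropout (p = 0.5) → single-output linear layer.  The desk-scale backbone is
one basic block per stage with channels 8/16/32/64 on 125×250 inputs; the
full-scale preset mirrors a 34-layer layout (3/4/6/3 blocks, channels
64/128/256/512) on 500×1,000 inputs.  Models train from scratch — no
pretrained initialisation is bundled — with SGD (momentum 0.9, weight decay
5e-4), mean-squared-error loss, and a linear-warmup + cosine-annealing
schedule: the learning rate rises linearly from base/3 (0.0033) to the base
0.01 over the first 200 iterations, then follows a cosine to a floor of
1e-4, parameterised per iteration and reaching the floor exactly at the
final step.  Validation loss is checked every 10 epochs (5 at desk scale)
with early stopping after 3–4 checks without improvement (the patience is a
package choice; the best-validation parameters are restored).  Desk-scale
training runs 30 epochs at batch 16.

Training-set augmentation is redrawn before every epoch, in fixed order:
brightness ±10% of the patch's intensity range (additive), contrast ±10%
about the mean, Gaussian noise with σ drawn from [0, 10] grey levels of a
255-level range (converted to the patch's own range, so the configuration
is meaningful for Z-scored inputs), shift ±5% of image size, scaling ±5%,
rotation ±30°, all with zero padding and bilinear resampling.  Augmentation
never changes the patch shape or its score label.

For categorical analyses, continuous predictions are clamped to [0, 24],
rounded half-to-even, and classified by the severity tiers; agreement via
ICC and the regression metrics use the raw continuous values, weighted
kappa uses the rounded ones.

All networks run on a small NumPy compute core (`aacscore.nn`) with
explicit, finite-difference-tested backpropagation — convolution via
sliding-window views and GEMM-shaped einsums, batch normalisation with
running statistics, max-pool/upsample/linear/dropout layers, the SCse
block, soft-Dice + cross-entropy and MSE losses, and SGD/Adam optimisers.
Float32 throughout; every initialisation and shuffle is driven by seeded
`numpy` generators, so identical configurations reproduce identical runs.

## Evaluation suite

* MAE, MSE, Spearman's ρ (average ranks on ties), R² = 1 − SS_res/SS_tot
  against the reference mean; with a zero-variance reference, ρ and R² are
  reported NaN and flagged, never fabricated.
* Clinical acceptability: fraction of predictions with |error| strictly
  below 4 (threshold configurable).
* Percentile bootstrap 95% CIs (2.5th/97.5th percentiles over B replicates,
  default 1,000): `resample` mode bootstraps test pairs without retraining;
  `retrain` mode reproduces the full procedure (resample training cases
  with replacement, retrain, predict the fixed test set) via a caller
  closure.  A run aborts if more than 1% of replicates fail.
* ICC(2,1) — two-way random effects, single measure, absolute agreement —
  from the ANOVA mean squares:
  `(MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))`.
* Weighted Cohen's kappa on the full integer scale between the smallest and
  largest observed rating; quadratic disagreement weights by default,
  linear selectable, and the scheme used is always recorded.  Undefined
  (single shared category) is NaN, flagged.
* Severity-stratified one-vs-rest accuracy/sensitivity/specificity/NPV/PPV
  in percent with Wilson score 95% intervals; metrics with zero denominator
  are NaN and flagged.

Cross-checks in the test suite compare ICC against `pingouin` and an
explicit sum-of-squares oracle, and kappa against `scikit-learn` and a
cell-by-cell contingency oracle, to 1e-10.

## Explanation

Gradient-weighted class-activation mapping for the scalar output: channel
weights are the spatial means of the output's gradient at a chosen
convolutional layer (default: the last residual block), the map is the
rectified weighted activation sum, bilinearly upsampled and max-normalised
(an all-zero map stays zero).  `focus_fraction` reports the fraction of the
heatmap's top-decile pixels falling inside the (optionally dilated)
calcification mask mapped through the same crop/resize as the patch.  It is
a computable proxy for reader-study "correct focus" judgments and is not
claimed to reproduce them.

## Pipeline, seeds, and problem sizes

`run_pipeline` executes simulate → segmenter training → ROI extraction
(with predicted masks; coverage failures are logged and dropped) →
regressor training → evaluation → explanation, deriving one seed per stage
from the global seed via `numpy.random.SeedSequence` and logging all of
them; a rerun with the same configuration reproduces the data manifests
byte-for-byte.

The shipped problem sizes — 60-case segmentation cohorts at 256×128,
400-patch regression cohorts at 125×250, 500-phantom consistency checks —
are the package's desk-scale study conditions: large enough for the learned
stages to recover the generator's parameters (held-out Dice ≥ 0.85;
held-out Spearman ρ ≥ 0.8 and MAE ≤ 2.5), small enough to run on one CPU.
Training is stochastic: those two recovery checks are run at fixed seeds,
and typical results carry margin above the thresholds (Dice ≈ 0.89,
ρ ≈ 0.98, MAE ≈ 1.4).

## Known limitations

* The phantom is a geometric stand-in: no projection physics, no lesion
  morphology statistics, no pathology other than calcification (fractured
  or truncated vertebrae are out of scope, as they are exclusion criteria
  for the clinical score).
* Per-segment grades from `score_from_masks` can swap walls (never totals)
  when only one wall bears calcification and no explicit midline is given.
* The desk-scale networks are far smaller than clinical-scale models; their
  recovery results say the implementation works, not how it would perform
  on radiographs.
* DICOM ingest reads pixel data, spacing and laterality only; no modality
  LUT/VOI handling beyond MONOCHROME1 inversion.
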