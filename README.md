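# aacscore

Automated Kauppila scoring of abdominal aortic calcification (AAC) from
lateral lumbar/abdominal radiographs, for researchers building or
validating radiograph-based cardiovascular risk markers.

AAC is a radiological marker of atherosclerosis.  The Kauppila AAC-24
system grades the calcified length fraction *f* of eight aortic wall
segments (anterior/posterior walls at vertebral levels L1–L4, with segment
boundaries at the midpoints of the adjacent intervertebral spaces):

    grade = 0 if f = 0;  1 if f < 1/3;  2 if 1/3 <= f <= 2/3;  3 if f > 2/3

The eight grades sum to a 0–24 total, categorised as no/mild (0–4),
moderate (5–15) or severe (16–24).

The package implements the full automated pipeline in two learned stages —

1. **Segmentation**: a U-Net labels vertebrae L1–L5 on the radiograph,
   with a coverage quality check on the predicted mask;
2. **Regression**: the image is cropped to an anatomically standardised
   patch (inferior T12 border to inferior L5 border, extended anteriorly by
   3/4 of the mean vertebral AP length to cover the aorta; resized to
   500×1,000, or 125×250 at desk scale) and a residual CNN with concurrent
   spatial/channel squeeze-and-excitation attention regresses the
   continuous AAC-24 total (SGD, MSE loss, linear warmup 0.0033→0.01 over
   200 iterations then cosine decay to 1e-4, per-epoch augmentation);

— plus everything around them: the exact Kauppila scoring engine and a
mask-based automatic scorer (`aacscore.kauppila`), a synthetic radiograph
phantom generator with analytic ground truth (`aacscore.phantom`), the full
evaluation suite (MAE/MSE/Spearman/R² with bootstrap CIs, ICC(2,1),
weighted kappa, |error|<4 acceptability, severity-stratified
sensitivity/specificity/NPV/PPV with Wilson CIs; `aacscore.evaluation`),
gradient-weighted activation mapping with a quantitative focus measure
(`aacscore.explain`), and an end-to-end orchestrator with a thin CLI
(`aacscore.pipeline`, `aacscore` command).  The networks run on a small,
gradient-checked NumPy compute core (`aacscore.nn`), so the package has no
deep-learning framework dependency.

No clinical images are included; the phantom generator provides labelled,
licence-free data for every stage (see `docs/methods.md` for what the
phantoms do and do not emulate).

## Worked example

`examples/01_kauppila_scoring.py` builds a phantom with half of the
L1-anterior segment and 90% of the L3-posterior segment calcified, then
scores it back from the rendered masks:

```
calcified fraction 0.0 of a segment -> grade 0
calcified fraction 0.2 of a segment -> grade 1
calcified fraction 0.5 of a segment -> grade 2
calcified fraction 0.8 of a segment -> grade 3

analytic truth: total 5 (moderate)
mask-based score: total 5 (moderate)
  L1 anterior: grade 2
  L3 posterior: grade 3
```

The half-covered segment grades 2, the 90%-covered one grades 3, and the
automatic mask-based scorer recovers the analytic total exactly.

`examples/05_agreement_statistics.py` runs the evaluation suite on a
synthetic rater pair (reference scores plus noise, n = 150):

```
MAE 1.377 (95% CI 1.216-1.560), MSE 3.011, rho 0.969, R2 0.941
clinically acceptable (|error| < 4): 97.3%
ICC(2,1) 0.971; quadratic weighted kappa 0.970
severity confusion matrix (rows = reference):
[[25  3  0]
 [ 4 51  9]
 [ 0  5 53]]
  no_mild: sensitivity 89.3% (95% CI 72.8-96.3)
  moderate: sensitivity 79.7% (95% CI 68.3-87.7)
  severe: sensitivity 91.4% (95% CI 81.4-96.3)
```

A rater within ±2 points of the reference keeps ICC and kappa high while
still flipping some categories near the 4/5 and 15/16 tier boundaries —
exactly what the per-category sensitivities show.

Other examples cover cohort generation (`02`), segmenter training with
held-out Dice (`03`), regressor training plus saliency (`04`), and the full
pipeline (`06`).  The pipeline demo (60/20/20 phantoms, both stages trained
from scratch, ROIs from *predicted* masks) prints:

```
segmenter trained: final val Dice 0.991
test: 20 ROIs kept, 0 dropped by coverage check
{"mae": 1.464, "mse": 3.266, "spearman_rho": 0.985, "r2": 0.943,
 "acceptable_proportion": 0.95}
ICC(2,1): 0.968
```

i.e. on held-out phantoms the automated two-stage system scores within
about 1.5 AAC-24 points of the analytic truth.  The CLI mirrors the
stages:

```bash
aacscore simulate data/ --n-cases 100 --seed 7
aacscore run-all --output-dir pipeline_demo --seed 0
aacscore score case.png --seg-model models/segmenter --reg-model models/regressor
```

## Layout

```
src/aacscore/
  kauppila.py      scoring engine: grades, totals, tiers, segment spans,
                   mask-based scoring
  phantom.py       synthetic radiographs with analytic ground truth
  segmentation.py  U-Net vertebra segmentation + coverage QC
  roi.py           anatomical crop geometry and patch normalisation
  regression.py    residual-attention CNN, augmentation, LR schedule
  evaluation.py    accuracy, bootstrap CIs, ICC, kappa, severity report
  explain.py       gradient-weighted activation maps, focus fraction
  pipeline.py      end-to-end orchestration; cli.py: the `aacscore` command
  nn/              NumPy compute core with explicit backpropagation
```

`docs/methods.md` documents the model assumptions, parameter defaults,
numerical conventions and known limitations.
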