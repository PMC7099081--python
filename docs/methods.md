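# Methods

## Model and training protocol

The model is a Siamese pair of identical convolutional subnetworks with a
single shared parameter store; "both twins" are literally one forward
function, so weight sharing cannot drift. Embeddings are compared with the
Euclidean distance `D_w` and trained with the contrastive loss
`L = (1−Y)·D² + Y·max(0, m−D)²`, margin `m = 2.0`. The loss is zero exactly
when a same-grade pair coincides (`D = 0`) or a different-grade pair is
separated beyond the margin (`D ≥ m`); beyond the margin, dissimilar pairs
contribute nothing, which stabilizes training. Batch reduction is the
arithmetic mean, so the effective learning rate does not depend on batch
size.

Each training epoch draws a fresh balanced sample of image pairs — half
same-grade (Y=0), half different-grade (Y=1), drawn with replacement across
epochs from any patients and timepoints, never pairing a record with itself
(a self-pair has zero gradient and distorts the balance). The validation
pair set is sampled once per run with a fixed seed so that validation losses
are comparable across epochs. Early stopping ends training after
`patience_epochs = 3` consecutive epochs without a new validation-loss
minimum ("improvement" = strictly below the running minimum, with an
optional `min_delta`), and the weights from the minimum-validation-loss
epoch are returned.

Two backbones are provided. The default desk-scale subnetwork is four
stride-2 3×3 convolution blocks (8/16/32/32 channels), global average
pooling, and a linear head to `k_out` embedding dimensions (3 in retina
mode, 5 in knee mode by convention; freely configurable). A deeper variant
with residual blocks (`residual_small`) is available. The layers, backprop,
and the Adam optimizer are implemented in `siamscore.nn` on numpy arrays;
evaluation has no stochastic layers, so embeddings are bit-reproducible
given fixed weights.

### Desk-scale optimization choices

Two protocol parameters differ from the large-backbone reference settings,
both consequences of training a small network *from scratch*:

- **Learning rate 5e-5** (`TrainConfig.desk_scale`). The continuous severity
  signal lives in the *within-grade* spread of embedding distances, which the
  contrastive loss actively destroys at convergence: all same-grade pairs are
  pulled toward distance zero. Severity scoring therefore relies on a
  gently-underfit model — the same regime a large pretrained backbone
  fine-tuned at 5e-6 for a few epochs occupies. Per-epoch scans show the
  severity-rank correlation peaking early and decaying as the validation
  loss keeps improving; 5e-5 keeps a full 15-epoch run inside the high-
  correlation regime while reaching change-detection AUCs above 0.9.
- **`min_epochs = 5`.** From-scratch training shows an early validation-loss
  hump (the loss can rise for 2–3 epochs while features form) that would
  otherwise trip the patience rule immediately and return a degenerate
  majority-class model; pretrained initialization — not shipped here —
  is the usual cure. Stopping is simply not allowed before epoch 5; best-
  checkpoint selection is unaffected.

## Severity scoring

`severity_score` embeds the query and the anchors and returns the median of
the per-anchor Euclidean distances (even-count median = mean of the two
central values; pools of 10 make this case real). Two anchor strategies:

- `random_normal` — 10 grade-0 images drawn uniformly without replacement;
  the deployment protocol, used for change detection and tracking.
- `ranked_least` — the 5 images with the lowest value of a severity-rank
  column; the protocol for severity-rank correlation studies on ranked test
  sets. On synthetic data the latent severity is the stand-in for an expert
  consensus rank.

The severity-recovery analysis uses `ranked_least` over the held-out test
split. This matters: with `random_normal`, anchors are legitimate grade-0
images whose latent severity can sit anywhere below the first grade
threshold, and the rank correlation then varies substantially with the pool
draw (observed 0.69–0.94 on one fixed model) for reasons unrelated to the
model. Anchoring at the least-severe end of the scale removes that variance
and matches how ranked-cohort correlations are computed. Both numbers are
reported by the study pipeline.

`change_delta` scores both visits against the *same* pool instance and
returns score(t2) − score(t1) (positive = worsening; exactly antisymmetric
under swapping visits). `change_pairwise` is the direct embedding distance
(symmetric; directionless). Anchor embeddings are cached per (pool, model
weights); the cache key includes a weight fingerprint so retraining
invalidates it.

## Synthetic cohort

The generator emulates the statistical structure of longitudinal
severity-graded imaging cohorts, not their anatomy. Each imaged unit (an
"eye") carries a latent severity `s ∈ [0,1]`; the ordinal grade is the bin
of `s` under fixed thresholds (default (0.5, 0.8) for 3 grades; boundary
values go to the lower bin). Initial severities are drawn grade-first from
the marginal class weights — default (0.84, 0.13, 0.03), the imbalance of a
real retinopathy screening cohort — then uniformly within the grade's bin.

Appearance is a deterministic function of `(s, unit parameters, visit
noise)`:

- a bright sinusoidal "vessel" confined to an upper band whose tortuosity
  amplitude grows linearly with `s`;
- up to four bright lesion blobs in a lower band, positions fixed per unit,
  whose amplitude, radius, and active count grow monotonically with `s`
  (each lesion fades in over a ramp of 0.25 in `s` so appearance is
  continuous);
- nuisance, independent of `s`: per-unit smooth background texture and a
  global brightness offset (both scaled by `nuisance_level`, default 0.3),
  plus per-visit white noise (σ = 0.015).

The vessel band and lesion band are spatially disjoint by construction, so
the monotone lesion-statistic invariant is well defined and occlusion-map
localization has an unambiguous target.

Trajectories: per visit, severity jumps up by an exponential increment
(mean 0.2) with probability 0.4, and in retina mode may regress with
probability 0.05 (knee mode is monotone non-decreasing, as radiographic
osteoarthritis does not heal); severities are clipped to [0,1]. These rates
make roughly a quarter of the per-unit longitudinal comparisons cross the
normal/abnormal dichotomy, matching the composition of real longitudinal
comparison test sets; smaller progression rates were observed to leave the
40-unit test comparison set with too few (sometimes zero) positive changes
to evaluate at all. Visits per unit follow a configurable distribution
(default 2–4, mean 3, since real screening cohorts image "as clinically
indicated").

Splits are by patient (80/10/10 by default) with largest-remainder rounding
— deterministic and order-free — so no patient appears in two splits.

What the generator does **not** emulate: anatomical realism, rater
disagreement (grades are a deterministic function of latent severity —
see Limitations), acquisition artifacts, or treatment effects. Passing
tests on this cohort demonstrate that the pipeline recovers a monotone
appearance→severity mapping in the presence of irrelevant-but-learnable
nuisance; they do not certify performance on real images.

## Longitudinal evaluation

The longitudinal comparison set uses each unit at most once: all
two-visit combinations are enumerated; if any combination's grade changed,
one changed combination is used (seeded random choice among several);
otherwise any combination is sampled. Binary change under a dichotomy of
the grade scale (retina: {0} vs {1,2}; knee: {0,1} vs {2,3,4}) is 1 iff
the two visits fall on different sides.

For change detection, the `delta` metric feeds |score difference| to the
ROC (binary change detection is directionless; the signed value is kept in
reports), `pairwise` feeds the distance itself. Thresholds come from the
maximum of Youden's J on validation pairs — candidates are midpoints
between consecutive sorted unique scores, ties broken toward the smallest
— and agreement of thresholded predictions with the binary labels is
linear-weighted Cohen's kappa (equal to unweighted kappa for binary
labels; the general linear-weight form supports the multi-class baseline's
agreement reporting). ROC/PR curves and AUCs use the standard threshold
sweep (trapezoidal ROC AUC equals the tie-aware concordance probability;
PR AUC is the step-interpolated average precision). Confidence intervals
are percentile bootstrap over test comparisons (2000 replicates by
default; replicates that lose a class are redrawn).

The conventional baseline is the same backbone with `k_out` = number of
grades, softmax cross-entropy, the same optimizer and stopping protocol,
epochs drawn uniformly from the training split (class-balanced sampling is
available as an option). Its change prediction for a pair is "the
dichotomized argmax grades differ", and it is compared with the Siamese
metrics by kappa.

## Occlusion sensitivity maps

Patches of N×N pixels (defaults: 8 for retina mode, 32 for knee mode;
stride 8) aligned to a grid anchored at the top-left corner are occluded at
the *same* coordinates in both images, each patch replaced by its own mean
(not a cross-image mean). Cell (i, j) of the map stores
`baseline − D_occ`, so regions whose occlusion removes dissimilarity signal
are positive — salient regions are hot. Identical inputs give an exactly
zero map, since synchronized occlusion preserves identity. Grid dimensions
are `⌊(H−N)/stride⌋+1 × ⌊(W−N)/stride⌋+1`; edge remainders are uncovered.
For a single image, one map per anchor is computed and the cellwise median
taken. Rendering upsamples the map to image size, normalizes to the map's
own range, and alpha-blends a colormap over the base image (signed values
by default; an absolute-value toggle exists).

The localization probe renders a low- and a high-severity image of the same
synthetic unit (severity is the only difference) and asks whether the
occlusion map ranks the primary lesion's region in the top quartile of
cells. A "hit" means *some grid cell overlapping the lesion's core disc* is
in the top quartile — region overlap, not the center cell alone, because a
lesion of radius 5–7 px spans 2–4 cells of the stride-8 grid and its mass
frequently concentrates in a neighbor of the cell containing the center.

## Numerical and degenerate-input conventions

- Even-count medians: mean of the two central values (everywhere).
- Pair distance gradient at D→0 is guarded (zero direction vector); the
  Y=0 branch has no singularity (`dL/de = 2·diff` exactly).
- Spearman correlation rejects constant vectors rather than returning NaN.
- Youden thresholding rejects all-equal score sets; `evaluate_change_detection`
  reports a `degenerate` flag (no threshold, no kappa) instead of failing.
- `latent_to_grade` assigns threshold-boundary values to the lower bin.
- Float32 weights and activations for speed; float64 for all distances,
  losses, and statistics; gradient checks run the model in float64.
- Checkpoints are `.npz` archives of weights plus a JSON metadata header
  (format version, architecture spec, margin, preprocessing, seed).

## Problem sizes

The bundled study (`siamscore.pipeline.run_rop_study`, also behind
`scripts/acceptance.py`) uses 200 patients × 2 units × 2–4 visits
(~1200 images, 64×64), 3200 training pairs per epoch for at most 15 epochs,
a 40-unit longitudinal comparison set, 1000–2000 bootstrap replicates, and
10 localization trials; one run takes a few minutes on one CPU. Image size
64×64 (rather than the 224×224 typical of clinical models) keeps that
practical; the method itself is size-agnostic.

## Known limitations

- Grades are a deterministic function of the latent severity, so the
  multi-class baseline faces none of the label noise that caps classifier
  agreement on real cohorts; on some cohort seeds it reaches kappa ≈ 1 on
  the 40-pair comparison set, a ceiling real graders do not attain. Kappa
  comparisons between the Siamese metrics and the baseline should be read
  with that in mind.
- The |delta| and pairwise change scores respond to *any* grade change,
  including changes entirely within the abnormal side of a dichotomy
  (e.g. grade 1→2); those register as false positives for binary change
  detection by construction. This is intrinsic to distance-based change
  scores, not a bug.
- Underfitting is load-bearing for the continuous severity claim (see
  learning-rate note); training this architecture to convergence improves
  binary change AUC slightly while eroding within-grade severity
  resolution.
- The generator's nuisance model (smooth texture + brightness) is far
  simpler than real patient/technique variation.
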