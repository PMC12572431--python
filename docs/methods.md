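# Methods

`lusemble` implements a semi-supervised, ensemble-based pipeline for
interpreting lung point-of-care ultrasound (POCUS) videos, together
with a synthetic sector-scan phantom generator that stands in for
clinical data.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The label space

Video-level findings form a tree: *normal* lungs show scattering-only
or A-lines (reverberation artifacts of an aerated lung); *indicative*
findings are <3 B-lines (B-negative, not yet proof of pathology) and
the *pathological* group, which splits into the B-positive pattern
(≥3 B-lines or coalescent B-lines) and other pathologies
(consolidation, pleural effusion).  Normal- and pathology-side
findings are mutually exclusive, as are the three B-line findings;
B-lines may coexist with consolidation and effusion.

Eight named label sets pick frontiers of this tree: multi-label sets
mlS1–mlS4 (from five coarse labels down to all seven findings) and
categorical sets cLS1–cLS4 (from binary normal-vs-indicative to a
four-way split).  A label set either contains a high-level node or all
leaves beneath it, never a partial subset; this is what makes the
hierarchy-aware ensemble well-defined.  One naming subtlety: the
*Indicative finding* node covers all five pathology-side findings,
while the *Pathological* label of cLS2/cLS4 covers only the four
proof-of-pathology leaves (its sibling *Non-pathological* holds
<3 B-lines).  Both nodes exist in the tree so every named set resolves
without ambiguity.

## Preprocessing

The scan sector (FOV) of a convex probe is a wedge defined by the
probe's virtual origin (pole), two radii and an opening angle.  The
geometry estimator thresholds per-pixel temporal variance (speckle
makes the sector "alive"; surrounding UI furniture is static), keeps
the largest connected component, fits the two straight flanks by
trimmed least squares (4 rounds, 60th-percentile trim, which discards
the curved outer-arc rows), intersects them for the pole, and takes
radial extents for the radii.  The fit is validated against the active
pixels (≥99 % coverage, ≤10 % area excess) and refuses frames without
a plausible sector.  This estimator is contract-tested against phantom
ground truth (pole within 3 px, opening angle within 1°), not against
any external mask reference.  Geometry can also be supplied through
manifest columns, bypassing estimation.

Videos are masked to the FOV, converted to gray (BT.601 luma when
color), and resized to a square network input by a single uniform
scale with nearest-neighbour interpolation (preserving the intensity
palette and avoiding smoothing) plus centered zero padding; the
geometry moves through the same similarity transform.

## Polar-space augmentation

A-lines and B-lines exist only along the beam direction, so generic
rotations/crops can produce physically impossible frames.  All
geometric augmentation therefore happens in polar coordinates about
the pole: a 1-D radial scale (axial-depth change; the first polar row
is the scaling origin, content cropped at the outer radius, vacated
rows zero-filled), an angular translation (probe rocking), and a
linear contrast gain about a configurable pivot (default mid-intensity
0.5, zeros preserved), followed by resampling back to Cartesian —
which by construction confines content to the FOV — and an optional
horizontal flip about the beam axis.  Training draws: scale ±30 %,
rotation ±10°, contrast gain ±0.25, each spatial transform gated
independently at 50 % and the intensity transform at 15 %.  The weak
policy used for pseudo-label generation always applies scale ±7.5 %
and rotation ±2.5°, flips at 50 %, and never touches contrast.
Parameters are drawn once per clip and shared by all frames.

Numerical choices: the polar grid has one row per pixel of radial span
and one column per pixel of outer-arc length (no information loss at
the finest Cartesian scale); polar↔Cartesian resampling is bilinear
(`scipy.ndimage.map_coordinates`), reserving nearest-neighbour for the
one-off standardization resize; a flip about an off-center pole is
re-masked afterwards so FOV closure stays exact.

## Clips and video-level inference

The classifier consumes 32-frame clips sampled at 8 Hz — a 4 s window
matching a typical respiratory cycle — taken by nearest-source-frame
resampling, with zero frames appended when a video is too short.
Training uses one uniformly random clip per video per epoch; inference
enumerates overlapping clips every 0.5 s from the first frame (only
starts whose full span fits, except the guaranteed first clip) and
averages the per-clip scores into the video-level prediction.

## Network and training

The classifier is an 18-layer residual video network in which every 3D
convolution is factorized into a spatial 1×3×3 convolution, batch
norm, ReLU, and a temporal 3×1×1 convolution ("(2+1)D").  The
intermediate width of each factorized unit equals the unit's output
width — *not* the parameter-matching formula of the original
factorized design — so the model has strictly fewer parameters than
its full-3D counterpart while doubling the rectification count (34
ReLUs vs 17).  Heads are softmax (categorical) or per-class sigmoid
(multi-label); features are globally average-pooled before the linear
classifier; no pretraining.  Each residual block's final batch-norm
scale is zero-initialized so every block starts as the identity — the
standard residual-network trainability device, which at small widths
removes most seed-to-seed variance in held-out accuracy.  A `tiny` variant (widths 8/8/16/32/64,
16×32×32 input, 5×5 stem) is part of the public API for desk-scale
experiments.

The network, its backward pass and the Adam optimizer are implemented
directly on NumPy arrays (im2col or offset-sum convolutions backed by
BLAS matmuls), which is ample for these clip sizes and keeps the
dependency footprint minimal.  Training runs Adam at an initial
learning rate of 1e-3 with cosine decay to zero at the final epoch,
batch size 4, for a configurable number of epochs (the clinical-scale
reference is 100; desk-scale runs use 15–20).  Hard targets are
label-smoothed with ε = 0.1 (multi-label runs; categorical runs leave
ε = 0 since mutual exclusivity already limits label noise).

Losses are reliability-masked cross-entropies: each class c of each
sample carries a bit g_c; the per-sample loss averages only reliable
classes, and samples with all-zero g are dropped from the batch mean
(the normalization is undefined there and upstream selection never
produces them).  For labeled data g ≡ 1 and the losses are the
ordinary binary/categorical cross-entropies.

Determinism: with a fixed seed and single-threaded execution, training
histories and phantom datasets are reproducible bit-for-bit; BLAS
threading may reorder reductions across machines.

## Uncertainty-aware pseudo-labeling (UPS)

A trained model scores every unlabeled video with the video-level
routine, once for the original and once for each of nine
weakly-augmented versions (one augmentation draw per version, shared
by all of its clips).  The original's score is the confidence p; the
per-class *population* standard deviation over all ten scores is the
uncertainty u ("standard deviation of the ten predictions" admits
either estimator; the population form is the default and
configurable).  A class becomes a positive pseudo-label when p > τ_p
and u < k_p, negative when p < τ_n and u < k_n (strict inequalities,
per "higher than"/"lower than"), otherwise indeterminate with g = 0.
Defaults: τ_p = 0.5, τ_n = 0.05, k_p = 0.05, k_n = 0.005.  In
categorical mode the argmax class must qualify as positive, yielding a
fully reliable one-hot sample, else the sample is rejected — the
masked categorical loss has no per-class notion of reliability.

Selected videos join the labeled set and a fresh network is trained
from scratch (round 0 reuses the supervised seed, so a round that
selects nothing reproduces supervised training exactly).  The round
count defaults to 1: self-training makes the model overconfident, and
repeated rounds amplify confirmation bias.

## Hierarchy-aware ensembling

Members trained on different label sets are combined over a target
set.  A member's scores are lifted to the target: verbatim labels are
copied; a high-level target label is aggregated from the member labels
beneath it by *sum* for categorical outputs (softmax mass over
disjoint sub-labels is additive) and by *max* for multi-label outputs
(a high-level finding is as present as its most confident
sub-finding).  The ensemble output is the unweighted mean of lifted
member scores; categorical aggregation conserves total probability
mass exactly.  Special cases: all members on the target set =
classical model repetition; repeated fine-label models lifted to a
coarse set = low-to-high; a mixed frontier = multi-output-to-high-level.

## Evaluation

Average precision is the step-interpolated area under the
precision-recall curve with tied scores collapsed into one group
(deterministic under ties; matches the standard reference
implementation).  F1 is reported per class, macro (unweighted class
mean) and micro (pooled counts); multi-label scores are thresholded at
0.5, categorical predictions by argmax.  Categorical tasks add
balanced accuracy (mean per-class recall) and the multiclass Matthews
correlation coefficient from the confusion matrix.  Splits are
patient-level (80/20 with k-fold assignments over training patients)
so no patient straddles partitions.

## The phantom generator

The phantom emulates the *geometry and artifact topology* of
convex-probe lung ultrasound, not acoustic physics: multiplicative
band-limited speckle; a depth-decaying tissue background; a bright
pleural arc; A-lines as concentric arcs below the pleura spaced by the
skin-to-pleura distance with geometrically decaying brightness;
B-lines as radial rays from the pleura to the outer radius that rock
with breathing (0.25 Hz) and may be transient (absent for part of the
cycle); coalescent B-lines as one wide angular band; consolidation as
an irregular hypoechoic patch below the pleura; effusion as an
anechoic band above a displaced bright interface.  Optional Z-line
hard negatives (rays that stop short of the outer radius) are off by
default.

Study conditions follow the emulated acquisition protocol: durations
3–6 s (shorter excluded), frame rates {25, 30, 60} fps, patients
owning 1–12 videos with labeled/unlabeled status assigned at patient
level (preventing leakage into semi-supervised experiments).  Label
draws respect the exclusivity rules: normal videos carry exactly one
of scattering-only/A-lines; pathological videos carry at most one
B-line finding plus independently drawn consolidation/effusion,
redrawn if empty.  Ray widths (σ 3–4.5°) and lesion extents are chosen
once so that every finding stays resolvable after nearest-neighbour
downsampling to coarse grids (a few degrees of arc ≈ one pixel at
32 px); ray centers are placed on jittered even slots so adjacent rays
never blur together in a time average.  The generator records its own
rendering ground truth (ray angles, per-frame presence) for diagnostic
tests; the learning pipeline never reads it.

### What phantom results do and do not show

Desk-scale runs (64 px renders standardized to 32 px, 3–4 s at 25 fps,
the tiny network, 15–20 epochs, 150–200 videos) demonstrate that the
pipeline's machinery works end to end: the phantom classes are
learnable, video-level inference aggregates correctly, UPS selection
is more precise than naive thresholding, and a semi-supervised round
does not degrade held-out performance.  They say nothing about
clinical accuracy: phantoms lack real speckle statistics, probe/gain
variability, annotation noise and anatomical confounders, and the
class structure is far cleaner than hospital data.  Conversely, the
property-based tests (coordinate mappings, loss oracles, selection
truth tables, ensemble algebra, metric references) are exact and carry
over unchanged.

## Known limitations

- Pure-NumPy training is single-device and desk-scale; clinical-scale
  (100-epoch, 8k-video) training would need a GPU framework behind the
  same module surfaces.
- The geometry estimator assumes a bright sector on a dark background
  with visible straight flanks; linear/phased-array footprints are out
  of scope.
- Media I/O is `.npz` frame stacks; compressed video containers are
  not decoded.
- Pseudo-label calibration is not corrected (temperature scaling etc.
  is deliberately out of scope), which is the main reason the round
  count defaults to 1.
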