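# Methods

## Problem and overall design

Temporal lobe epilepsy (TLE) and Alzheimer's disease (AD) both produce
gray-matter atrophy involving medial-temporal and limbic structures; TLE
additionally shows a lateralized, diffuse extratemporal pattern. The
package implements a slice-level discrimination study on normalized
gray-matter probability maps: individual axial slices are classified as
TLE / AD / healthy control (HC) by a small 2D CNN, model stability is
judged against a shuffled-label null ensemble, and the anatomy driving
the classifier is surfaced by ReLU-3 activation mapping, compared with
classical voxel-based morphometry (VBM).

Because real multi-center MRI cohorts cannot be redistributed, the
package carries a first-class synthetic-data generator that plants the
relevant structure, so every downstream stage is testable end to end.

## Synthetic gray-matter model

A subject's volume is

    GM = baseline * (1 - effect) + age_slope * (age - age_ref) + noise,

clipped to [0, 1].

- **Grid and affine.** Default full grid 113 x 137 x 113, 1 mm
  isotropic, with the midsagittal plane (x = 0) and the z = 0 axial plane
  at index 56. All spatial semantics (slice z-coordinates, sagittal
  mirroring) run through the affine, never through raw indices. The
  desk-scale grid is 32 x 40 x 32; its x-midline sits between indices 15
  and 16 (affine offset -15.5) so the sagittal flip is an exact index
  reversal, while z = 0 stays on a voxel plane (index 16) so integer-mm
  slice extraction works unchanged.
- **Atlas.** A toy, mirror-symmetric parcellation of six paired regions
  (hippocampus, amygdala, thalamus, superior frontal, precuneus, lateral
  occipital) as ellipsoids in grid-relative coordinates; right-hemisphere
  masks are built first and reflected exactly into the left. A real
  anatomical atlas on the same grid can be substituted wherever an
  `AtlasDefinition` is accepted.
- **Atrophy topographies.** Fractional regional GM reduction per
  (group, region, ipsi/contralateral): TLE has a lateralized
  medial-temporal core (hippocampus 35%/12%, amygdala 30%/10%) plus
  milder diffuse extratemporal involvement (thalamus 20%/10%, frontal
  12%/8%, occipital 10%/6%); AD is bilateral medial-temporal
  (hippocampus 30%, amygdala 20%) plus parietal (precuneus 30%). Both
  disease groups also carry a mild whole-brain ("global") reduction
  (TLE 3%, AD 8%) standing in for the diffuse atrophy component, so
  every extracted axial plane carries some class signal — the premise of
  slice-level classification. Region-specific effects override the
  global one inside their region, so a planted effect e yields an ROI
  mean of exactly (1 - e) x baseline in the noiseless case (a test
  invariant).
- **Age effect.** Linear decline, default -0.0015 GM/year about a
  reference age of 50 — about 0.09 probability units over a 60-year
  span, comparable to the planted disease effects, which is what makes
  age a genuine confound given the age-structured cohorts.
- **Demographics.** Cohort sizes and age distributions follow the
  study template: 157 TLE (38.77 +/- 12.44 y), 73 AD (75.71 +/- 8.10 y),
  251 HC from a two-component mixture (150 young 36.75 +/- 12.74, 101
  elderly 73.48 +/- 6.55), sex ratios per group, TLE laterality drawn
  left/right at about 92:65. Ages are truncated at 18 (adult cohorts).
- **Noise.** Per-subject smooth Gaussian random fields: white noise
  convolved to a configurable FWHM (default 8 mm full-scale, 2.5 mm
  desk-scale), rescaled to unit variance and multiplied by the amplitude
  (default 0.05). This mimics residual inter-individual anatomy after
  normalization; it does **not** model scanner/site effects, motion,
  segmentation error, or spatially correlated disease heterogeneity, so
  passing tests demonstrate pipeline correctness, not clinical
  performance.

## Preprocessing

Order: Gaussian smoothing -> gray-matter thresholding -> axial slice
extraction and labeling -> voxel-wise age residualization.

- Smoothing uses sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to
  voxel units via the affine; nearest-edge boundary replication is chosen
  so constants are preserved and brain edges are not darkened.
- Thresholding keeps voxels strictly greater than 0.20 gray-matter
  probability.
- Slice extraction takes one slice per integer-mm axial plane in the
  closed interval [-29, +28] mm (58 planes on the full grid; the
  desk-scale grid uses the scaled interval [-8, +7], 16 planes).
- Age residualization fits per-voxel OLS of GM on age and replaces each
  value with its residual. The fit population is *all* participants by
  default, reproducing the original design; this leaks distributional
  information across the split, and `fit_population="train"` provides
  the leak-free alternative. Residuals are not re-clipped to [0, 1]; the
  residual is the classifier input.

## Classifier

Three convolutional modules (3x3 convolution, stride 1, same padding;
batch normalization; ReLU; 2x2 max pooling with stride 2) with 8, 16 and
32 filters, then two fully connected layers (hidden width 64, output 3)
and a softmax. Filter counts for the first two modules, the pooling
geometry and the hidden width are package choices where the published
description is silent; the third module is fixed at 32 channels by the
feature-visualization layer. A ReLU sits between the two fully connected
layers — without it the hidden layer would be a redundant linear map.

Training: SGD with momentum 0.9, learning rate 0.01, L2 penalty 1e-4 on
weights, minibatch 128, 30 epochs (10 at desk scale), per-epoch
reshuffling, validation accuracy logged every 50 iterations, no early
stopping; the returned model is the last-iteration state. Inputs are
zero-centered by the training-set mean image, recomputed at every fit.
Batch-normalization inference statistics are exponential running
averages collected during training. The implementation is plain numpy
(im2col convolutions with analytic backprop, verified against numeric
gradients); all randomness derives from one integer seed, so a fixed
master seed reproduces bit-identical models and predictions on one
machine.

Numerical conventions: argmax ties break toward the lowest class index;
softmax is computed with max-subtraction; min-max normalization of a
constant map returns all zeros (logged where it matters); metric cells
with 0/0 are defined as 0 with a warning so ensemble aggregation never
propagates NaNs.

## Splits, null model, evaluation

Participants are stratified by group into train/validation/test with
train = round(0.60 N), test = round(0.25 N), validation = remainder
(round = half away from zero); all slices of a subject share one
partition. For a 157-subject group this gives 94/39/24.

The null ensemble permutes *training* labels at the participant level
(slice-level shuffling available by flag); validation and test labels
stay correct, and all metrics are computed against correct test labels.

Per class, one-vs-rest slice counts give accuracy (TP+TN)/total,
precision, recall and F1; macro metrics are unweighted three-class
means — under this reading the published per-class values aggregate
exactly to the published ensemble means. F1 is computed per run and then
averaged across runs. The FDCI between two ensembles is the fraction of
ordered accuracy pairs in which the trained model strictly beats the
shuffled one; ties are not wins.

## Feature visualization and VBM

Activation maps are channel-sums of ReLU-3 (a 32-channel map at 1/8
resolution after three poolings), bilinearly upsampled to the slice grid
— the published reconstruction is in brain space without stating the
resampling, so upsampling-before-normalization is a package choice —
then min-max normalized per datum. Disease activation brains are flat
unweighted means over all (participant datum, model) pairs per
(disease, z) (a two-stage mean is available by flag), then per-slice
min-max renormalized and thresholded at > 0.75. Left-TLE contributions
are mirrored about the affine midline before averaging; AD and HC maps
are never mirrored.

VBM uses classical pooled-variance two-sample t-tests (Welch available
by flag) at every masked voxel, two-tailed p, Bonferroni threshold
alpha/m with alpha = 0.05 over the m masked voxels, zeroing of
non-survivors, min-max normalization of surviving |t| (a single survivor
normalizes to 1) and the same > 0.75 cut. VBM runs on age-residualized
preprocessed volumes by default (flag for raw preprocessed volumes).
Zero-variance voxels get p = 1, never NaN.

## Desk-scale study conditions

The trained-vs-shuffled comparison that the acceptance script and the
acceptance tests recompute uses: reduced grid, 60 subjects per group,
noise amplitude 0.05 (noise FWHM 2.5 mm, smoothing FWHM 3 mm — both
scaled to the reduced grid's smaller physical extent), 10 trained + 10
shuffled models at 10 epochs each. These sizes are the package's
desk-scale choice: the FDCI-of-1 outcome needs only class separability,
and the shuffled-label macro recall concentrates at 1/3 for any
label-independent classifier regardless of ensemble size or class
balance, so both quantities are insensitive to the downscaling.

## Known limitations

- The generator's ellipsoidal toy atlas and piecewise-constant baselines
  are far simpler than cortical anatomy; ROI-rank results on synthetic
  data say nothing about real anatomical localization accuracy.
- The published per-class accuracies on the real cohorts are not
  reproducible here (data not deposited); only arithmetic identities,
  data-independent stochastic targets and property suites are.
- Batch-normalization population statistics are approximated by running
  averages rather than a post-training full-population pass.
- The CNN is CPU-bound numpy; full-scale 100-model ensembles on the
  113 x 137 grid are possible but slow — the desk-scale configuration is
  the supported test path.
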