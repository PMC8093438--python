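# Methods note

This note records the statistical model, the estimators, the synthetic data
generator, and the numerical choices made in the implementation, together with
the limitations of each. Empirical behavior of the pipeline is established by
the test suite (`tests/`) and the acceptance script (`scripts/acceptance.py`);
nothing in this note asserts performance numbers beyond what those compute.

## Problem setting

The input is a cohort of co-registered (spatially normalized) 3D volumes
`x_i ∈ R^(X×Y×Z)` with binary labels `y_i ∈ {0, 1}` and a brain mask defining
the voxel support. The task is subject-level binary classification. Because
the number of voxels far exceeds the number of subjects, the pipeline inserts
a mass-univariate feature-selection step — *t-masking* — between the images
and the classifier.

## Voxel-wise t-map

For every voxel `v` inside the brain mask, the two training groups' smoothed
intensities are compared with a two-sample t statistic. Two modes are
implemented:

- **standard** (default): the pooled-variance two-sample t,
  `|μ0 − μ1| / sqrt(s_p² (1/n0 + 1/n1))`, where `s_p²` is the pooled sample
  variance on `n0 + n1 − 2` degrees of freedom. Under the per-voxel null with
  Gaussian noise this follows the Student t distribution, which is what the
  type-I calibration test checks against.
- **literal**: the plain effect-size-like ratio
  `|μ0 − μ1| / sqrt((σ0² + σ1²)/2)`, i.e. without the `1/n` sample-size
  factor. This mode reproduces a formula that appears in some pipeline
  descriptions; its values are smaller than the standard t by roughly
  `sqrt(n/2)` for balanced groups and it is *not* t-distributed, so fixed
  thresholds are not comparable across modes.

Choices common to both modes:

- Sample standard deviations use the `n − 1` divisor.
- Voxels with zero variance in both groups (e.g. outside every subject's
  support) receive `t = 0` rather than NaN.
- Each training volume is smoothed with an isotropic Gaussian kernel before
  the statistic is computed. The kernel is specified by its full width at
  half maximum (FWHM, default 6 mm); the per-axis sigma in voxels is
  `FWHM / voxel_size / (2 sqrt(2 ln 2))`. Smoothing uses
  `scipy.ndimage.gaussian_filter` with nearest-neighbour boundary handling;
  FWHM 0 disables smoothing exactly.
- **Leakage contract**: the t-map is a function of the *training* subjects of
  a given split only. The experiment driver recomputes it per split
  permutation; validation and test subjects never enter the statistic.

## t-mask

The mask keeps voxels with `t(v) > threshold` (strict inequality, so
threshold 0 reproduces the whole brain only where `t > 0`; the driver treats
threshold 0 as the whole-brain configuration). The mask is applied
*multiplicatively* to every volume of every split: masked-out voxels carry
the value 0 into the classifier, preserving spatial structure for the CNN.
Masks along an increasing threshold grid are nested by construction. The
default sweep grid is 21 equally spaced thresholds on [0, 8].

Two stochastic perturbations probe the robustness of the selection:

- **Gaussian t-map noise**: i.i.d. `N(0, sd²)` (default sd 0.2) added to the
  map inside the brain before thresholding, clipped at 0 because the map is
  an absolute statistic. The clipping slightly biases voxels with `t < ~3 sd`
  upward; the perturbation-statistics test therefore measures the empirical
  sd away from the clip.
- **Bernoulli knockout**: each active mask voxel is independently zeroed with
  probability `p` (default 0.05) after thresholding.

A third control replaces the t-mask entirely with a **random mask** that
keeps each brain voxel with probability `1 − p`, matching a chosen selection
rate without using label information.

## Classifiers

**Dual-stream 3D CNN.** The same masked volume enters two parallel
convolutional streams (two conv blocks each, 2×2×2 max-pooling after each);
their activation maps are concatenated along channels (the *concatenate*
layer), a residual add-block follows, then a trunk of
standard/separable/grouped convolution blocks, and two fully connected blocks
ending in a 4-dimensional feature vector and a single logistic output. Every
conv block is convolution → batch normalization → ELU → (optional) pooling →
dropout. Weights are He-initialized; an L2 penalty (5·10⁻⁵) applies to all
convolutional and fully connected weights; dropout rate is 0.1. The network
is configuration-driven; the `desk` preset (~7.7k parameters, 24³ inputs) is
CPU-trainable in seconds per epoch, and a `mni` preset targets
MNI-sized grids (untested at scale here — see limitations).

Training uses Adam (β₁ 0.9, β₂ 0.999), batch size 6, and the learning-rate
schedule `10⁻³ · 0.3^(epoch/10)` with the exponent taken as a real number
(continuous decay; a stepped variant is available). Early stopping monitors
the validation cross-entropy with patience 10 and restores the weights (and
batch-norm running statistics) of the best epoch.

**Mean-intensity linear baseline.** A logistic regression on a single scalar
feature, the mean intensity over the active mask voxels. It isolates the
contribution of the mask itself from that of learned spatial filters.

## Experimental design

Cohorts are split subject-wise into train/validation/test at (0.6, 0.2, 0.2)
with exact class balance in every subset (fractions must be integral per
class). Each experimental point is repeated over several independent split
permutations (default 5). Metrics are accuracy at the 0.5 probability cutoff
and the ROC AUC (ties counted ½, computed by scikit-learn and cross-checked
against a pair-counting oracle in the tests).

Two aggregations over the (grid point × permutation) table:

- **average cross-validation**: per grid point, the mean test metric across
  permutations, with spread reported as the standard deviation of the mean;
- **classical cross-validation**: the test metric of the single
  permutation/grid point with the best *validation* accuracy (ties broken by
  higher validation AUC, then lower grid value). Test metrics never enter
  the selection.

**Performance enhancement (PE)** is the difference between two accuracies in
percentage points. **Dice** `2|A∩B|/(|A|+|B|)` scores mask overlap against
the planted ground truth (two empty masks score 1 by convention).

## Grad-CAM saliency

Heat-maps are computed at the concatenate layer: per-channel weights are the
spatial mean of the gradient of the scalar target (cross-entropy at a chosen
label, or the raw logit) with respect to the layer's activations; the map is
the rectified channel-weighted activation sum, trilinearly upsampled to the
input grid (`scipy.ndimage.zoom`, order 1) and max-normalized to [0, 1]. The
model runs in inference mode, so maps are deterministic. Localization is
quantified as the ratio of mean heat inside versus outside a reference
region.

## Synthetic phantom generator

Real cohorts of the relevant scale cannot ship with the package, so all
empirical claims are established on phantoms with known ground truth:

- an ellipsoidal brain on a cubic grid (defaults: 32³ voxels of 3 mm,
  semi-axes (13, 11, 10) voxels, ≈ 6000 brain voxels);
- one shared template per cohort: base intensity 1.0 plus a smoothed
  Gaussian random field texture (sd 0.2, FWHM 6 mm), zero outside the brain;
- per-subject i.i.d. Gaussian noise (sd 0.1), optionally smoothed to mimic
  the spatial correlation of registered data (off by default so the t-map's
  null is the textbook Student t);
- four deterministic spheres (≈ 10% of brain voxels; a shared radius is
  solved by bisection) inside which group-1 subjects receive a uniform
  intensity decrement of `effect_size × noise_sd`, so the per-voxel Cohen's d
  equals `effect_size` by construction.

This generator supports quantitative tests: type-I calibration at
`effect_size = 0`, effect-size recovery, Dice recovery of the planted
regions, and a feature-selection benefit experiment at desk scale.

## Numerical choices

- The CNN runs in float32; convolutions are evaluated as a single GEMM over
  an im2col matrix (`numpy.lib.stride_tricks.sliding_window_view`), with the
  backward pass as the transposed GEMM plus a 27-offset scatter-add. Only
  stride-1 'same' convolutions are implemented; downsampling is exclusively
  2×2×2 max-pooling (odd trailing planes are cropped).
- Batch normalization keeps running statistics with momentum 0.9; inference
  uses the running statistics, which makes `predict_proba` deterministic and
  batching-invariant to float32 accuracy (~10⁻⁵ tolerance in tests).
- Per-volume z-normalization uses the population (divide-by-n) standard
  deviation and rejects constant volumes.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; permutation seeds are derived with
  `numpy.random.SeedSequence`, and cohort generation, splitting, training and
  perturbations are bit-reproducible given a seed.

## Limitations

- No registration, segmentation, or bias-field handling is included; volumes
  are assumed co-registered on a common grid, and the phantoms are born
  aligned.
- The phantom noise model (i.i.d. Gaussian, uniform decrement in spherical
  regions) is far simpler than real morphometry; results on phantoms bound
  what the code does, not what it would achieve on clinical data.
- The CNN is a CPU NumPy implementation intended for desk-scale grids; the
  `mni` preset constructs but has not been exercised at MNI scale in
  the test suite, and there is no GPU path.
- Accuracy-based model selection on small validation sets (e.g. 16 subjects
  at desk scale) is noisy; the experiment driver mitigates this only by
  averaging over split permutations.
- The literal t-map mode exists for faithfulness to a published formula; its
  thresholds are not exchangeable with standard-mode thresholds.
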