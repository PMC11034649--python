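# Methods

## Problem setting

Semi-supervised segmentation of 2D grayscale slices: a small labeled set
D^L of (image, mask) pairs and a much larger unlabeled set D^U of images
from disjoint cases, with evaluation on held-out cases. The package
implements a three-stage pipeline that combines the two dominant
semi-supervised mechanisms — consistency regularization under a
student–teacher (mean teacher) structure, and pseudo-label self-training —
so that each repairs the other's weakness: the mean teacher produces
better pseudo-labels than a supervised-only model, and the fixed
pseudo-labels give the student–teacher pair a second, complementary
source of supervision on unlabeled data.

## Model

The backbone is a 2D U-Net: `depth` encoder stages of two conv–BN–ReLU
blocks each, channel width doubling per stage from `base_channels`, 2×2
max pooling between stages, a bottleneck block, and a mirrored decoder
(nearest-neighbour 2× upsampling + 3×3 conv, skip concatenation, double
block), finishing in a 1×1 head and a softmax. The softmax head is a
deliberate choice: the consistency loss is a mean-squared error between
outputs, which is only scale-stable on normalized probabilities, and the
cross-entropy terms consume the same probabilities through their
logarithm (with a 1e-8 clamp so one-hot targets stay finite).
Normalization layers, activations and the upsampling mode are free
choices under the shape and probability contracts; batch normalization
and ReLU are used here.

The network, reverse-mode autodiff and SGD are implemented directly on
NumPy (`plmt._autodiff`, `plmt.nn`): float32 throughout, convolution by
im2col + GEMM, gradients verified against central finite differences in
the test suite. This keeps the package dependency-light and every
numerical step inspectable; the cost is GPU-free throughput, which the
desk-scale problem sizes below are chosen around.

## Training pipeline

**Stage A (mean teacher).** Student and teacher start from identical
seed-derived weights. Each iteration draws a labeled batch and an
unlabeled batch from independent infinite shuffled cyclers (the small
labeled set is revisited many times per pass over D^U), applies a random
dihedral (rot90/flip) augmentation, and computes

    L_total^A = L_sup + lambda_A * lambda_d(t) * L_con

where L_sup is pixel cross-entropy on the labeled batch, and L_con is the
MSE between the student's output on a Gaussian-perturbed copy of the
unlabeled batch (std `student_noise_std`, 0 disables) and the detached
teacher's output on the clean copy. Only the student receives gradient;
after each optimizer step the teacher tracks it by EMA,
theta_T <- d*theta_T + (1-d)*theta_S (buffers included), d = 0.99 by
default (the usual mean-teacher value; the reference description leaves
it unstated). lambda_d(t) = exp(-5 (1 - t/t_max)^2) is the standard
Gaussian warm-up; it multiplies the base weight lambda_A = 0.1 in both
stages (the conventional composition; the alternative readings are noted
as configurable in the loss module).

**Stage B (pseudo-labels).** The final Stage-A student is frozen and
labels every unlabeled image with its pixelwise argmax. Deliberately no
confidence threshold and no pixel exclusion — every image yields exactly
one fixed pseudo-label.

**Stage C (combined re-training).** A fresh student–teacher pair (new
seed-derived init; "from scratch" is read as fresh for both, with the
EMA-from-Stage-A alternative left to configuration) trains under

    L_total^C = L_sup + lambda_C * lambda_d(t) * (alpha*K*L_con + beta*L_pse)

with L_pse the cross-entropy of the student's unlabeled-stream output
against the fixed Stage-B pseudo-labels. (alpha, beta) are trainable
convex weights parameterized by a single unconstrained scalar z through
the logistic function — this enforces alpha + beta = 1 and both positive
exactly and differentiably; z starts at 0 (alpha = beta = 0.5), is
optimized by the same SGD step on the total loss, and is excluded from
weight decay (decay on z would bias the pair toward 0.5 permanently).
The temperature K = 1000 rescales the numerically small consistency MSE
to the magnitude of the pseudo-label cross-entropy so the adaptive pair
arbitrates between comparably sized terms; K = 0 removes the consistency
input bitwise. Gradient flows into z through both the alpha*K*L_con and
beta*L_pse products.

**Optimizer.** SGD, momentum 0.9, weight decay 0.001, initial learning
rate 0.1 under the poly schedule lr0 * (1 - t/t_max)^0.9. One optimizer
step is one iteration; the reference schedule is 36,000 iterations with
12+12 batches at 256×256, the desk-scale profile below uses shorter
schedules at 32×32.

**Baseline degenerations.** `supervised` trains on D^L only; `mt` stops
after Stage A; `self-training` uses a supervised Stage A and a Stage C
without consistency term or teacher. With lambda_A = 0, noise 0 and EMA
decay 0, Stage A's loss trace is bit-identical to the supervised run
under the same seed (separate RNG streams per purpose guarantee the
labeled batch order does not depend on whether the unlabeled stream is
consumed).

## Evaluation metrics

Dice and Jaccard are set overlap scores; per case and foreground class,
pixel counts are pooled over the slices where prediction or ground truth
contains the class, so the identity dice = 2j/(1+j) holds exactly per
report row. Surface distances are computed in-plane per 2D slice, in
pixels: boundary pixels are foreground pixels with a background
4-neighbour (the image border counts as background); HD95 is the 95th
percentile (linear interpolation) and ASD the mean of the pooled
symmetric nearest-distance multiset; slices where either mask is empty
contribute no distances, and a case/class with no valid slice is
recorded as missing and excluded from aggregation with a logged count.
Background is never scored; multi-class masks are scored one-vs-rest.
The implementation (KD-tree nearest neighbour) is tested for exact
agreement with an all-pairs brute-force oracle.

## Synthetic data

The generator emulates normalized medical slices with ambiguous
boundaries: class-dependent intensities, Gaussian blur (sigma 1.2) that
smears the mask boundary, additive Gaussian pixel noise (std 0.8), and
per-case z-score normalization; masks are the exact pre-blur geometry.
The binary task draws one random bright ellipse per slice (single-organ
analog); the three-class task draws a central disc inside an annulus
plus a lateral crescent (the cardiac ventricles/myocardium layout).

Two design choices carry the semi-supervised structure. First, the
foreground contrast is drawn once per case from a wide range
(0.35–1.15 of the nominal class brightness): one or two labeled cases
cannot span that appearance manifold while the unlabeled pool does,
which is the mechanism that gives unlabeled scans value on real data
(scanner and patient variation). Purely i.i.d. pixel noise, by contrast,
is learnable from a handful of labeled slices and leaves semi-supervision
nothing to add. Second, the class-conditional intensity distributions
overlap (per-slice jitter on top of the case contrast), so even a
well-trained pseudo-labeler errs near boundaries and Stage C trains
against imperfect pseudo-labels, as it would in practice. The noise
level was calibrated once so the supervised-only baseline at a 10%
labeled fraction lands in the 0.7–0.9 Dice band, leaving measurable
headroom.

What the generator does not emulate: anatomy-specific shape priors,
3D-consistent structure across slices, intensity inhomogeneity fields,
or class imbalance beyond the configured foreground fraction. Passing
desk-scale tests therefore demonstrates the pipeline's mechanics and
direction of effect, not clinical-grade performance.

## Desk-scale study conditions

The comparison study (`plmt.experiments`, also behind
`scripts/acceptance.py`) uses: 50 cases × 4 slices at 32×32 (200 slices;
10 test cases, 40 training cases of which 4 labeled at the 10%
fraction), the light backbone profile (8 initial channels, 3 stages),
3+3 batches, 1500 iterations per stage, three seeds per configuration.
Many cases with few slices each maximizes the per-case contrast
diversity that carries the semi-supervised signal, and a schedule of
1500 small-batch iterations gives the warm-up-ramped unsupervised terms
a long post-convergence phase in which the supervised gradient is small
— the regime where consistency and pseudo-label supervision do their
work. One full four-mode suite trains four stages per seed (Stage-A
models are shared where pipelines coincide) and completes on a single
CPU core in about five minutes per seed. The larger profiles (16
channels, depth 4, 256×256, 12+12, 36,000 iterations) remain the
configuration defaults for full-scale use.

## Numerical choices and edge cases

- Cross-entropy epsilon 1e-8; BN epsilon 1e-5, running-stat momentum 0.1.
- MSE averages jointly over batch, class and pixel axes (scale-free in
  image size and class count).
- Warm-up exponent read as exp(-5 (1 - t/t_max)^2), the canonical ramp.
- Empty unlabeled set: Stage A falls back to supervised-only with a
  warning. Empty labeled batch, non-finite z, incongruent parameter
  shapes, out-of-range classes: errors.
- Constant-intensity volumes z-score with an sd floor of 1e-8 and a
  warning.
- Mask resizing is nearest-neighbour (no new class values); images are
  bilinear with anti-aliasing.
- Labeled fractions are applied at case level (ceil of fraction × train
  cases), never slice level, to prevent leakage between adjacent slices;
  exact slice tallies therefore vary with the seed.
- All randomness flows from `numpy.random.SeedSequence` children split
  by purpose (init / labeled order / unlabeled order / noise /
  augmentation), making runs bit-reproducible on CPU and the supervised
  degeneration trace-identical.

## Known limitations

- CPU-only throughput: full-scale (256×256, 36k iterations) training is
  possible but slow; the package's empirical claims are desk-scale.
- 2D only; surface distances are in-plane per slice, not 3D, and are
  reported in pixels (no physical spacing).
- The adaptive weight pair is a single logistic scalar; with more than
  two unsupervised losses a softmax parameterization would be needed.
- At short schedules the adaptive weight alpha tends toward the
  pseudo-label term (K·L_con exceeds L_pse while the networks still
  disagree); the reported final alpha makes this visible per run.
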