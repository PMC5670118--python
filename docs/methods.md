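# Methods

This note documents the models, procedures, parameter choices and known
limitations of `texsig`.  Everything quantitative stated here is computed
by the test suite or the scripts in this repository.

## Stimuli

**Phase randomization (SM construction).**  The spectrally matched image
of a source image is built by multiplying the source's 2-D DFT by
`exp(i·φ)` where `φ(k) = θ(k) − θ(−k)` and `θ` is i.i.d. uniform on
(−π, π].  `φ` is exactly antisymmetric, so the product spectrum remains
Hermitian and the inverse transform is real to machine precision; the
amplitude spectrum is preserved bit-for-bit up to rounding (verified to
1e−8 relative).  The DC bin is untouched, so the image mean is preserved.
Self-conjugate Nyquist bins of even-sized images have only a sign degree
of freedom, which is flipped at random; odd image sizes are rejected to
avoid ambiguous Nyquist handling.  No output clipping is applied.

**Structured textures (CM-role stand-in).**  True correlation-matched
synthesis by iterative statistic projection is out of scope; instead a
generative texture model produces images that *contain* the relevant
higher-order dependencies so that phase scrambling destroys them.
Oriented Gabor elements (wavelength 5 px, σ = 2 px) are placed along
smooth contours: a contour starts at a uniform position with a direction
drawn from a von Mises distribution around the family's preferred
orientation, takes 5 steps of 0.9 wavelengths, and bends per step by a
zero-mean normal scaled by the *curvature* knob.  When *scale coupling* is
positive, each element is accompanied by a one-octave-coarser element
(wavelength 10 px) at the same location, orientation and polarity — this
is what creates cross-scale energy correlations.  A Gaussian noise floor
(amplitude 0.08 before normalization) keeps the spectrum broadband.
Element count is `density · (size/wavelength)²`.

Four family knobs (density 0.2–0.7, orientation concentration 0.5–4,
curvature 0.05–0.5, scale coupling 0.3–1.0) are sampled on a Latin
hypercube so families occupy distinct regions of parameter space and a
per-family preference ordering is meaningful; preferred orientations are
spread evenly.

**Stimulus contrast.**  Images are mean-subtracted and normalized to RMS
contrast 0.02.  This value is a deliberate calibration, not a free
nuisance: the sparse-coding penalties (λ = 0.15/0.15/0.1) set an absolute
activation threshold (an atom fires when its residual correlation exceeds
λ/2), so the intensity scale decides whether coding is effectively sparse.
At RMS 0.02 a texture element clears the threshold while the spatially
spread energy of a phase scramble mostly does not — the regime in which
selective units can express a structure preference.  At much higher
contrast every unit fires for everything (codes are dense reconstructions
and the network shows no preference or prefers the scramble); at much
lower contrast the network falls silent.

**Preprocessing.**  `preprocess` reproduces the standard preparation:
resize to a working size (default 128), subtract the per-image mean,
resize to the model input size (default 224).  Resizing is bilinear with
anti-aliasing on downscale; the method is recorded in corpus metadata.
The upsample after mean subtraction leaves a small interpolation residual
in the mean (≲1% of the image s.d.), which is documented behaviour.

## Texture statistics

The statistic groups follow the parametric texture description used in
texture-selectivity work: (1) marginal (pixel skewness and kurtosis only;
mean and variance are removed by preprocessing), (2) spectral (mean energy
per sub-band), (3)/(6) correlations of linear/energy responses across
position offsets, (4)/(7) across adjacent scales, (5) energy correlations
across orientations.  The filter bank is quadrature Gabor pairs (even
member DC-corrected, both unit-norm) on an octave-spaced grid, default 4
scales × 4 orientations; this replaces the steerable pyramid, whose exact
1,104-parameter layout is not reproduced — the grouped structure is what
the downstream analysis uses.  All scales are filtered on the
full-resolution grid, so adjacent-scale maps are position-aligned without
upsampling; this is the same statistic as correlating an upsampled coarse
band, with less interpolation error.  Position offsets are
{−3..3}² \ {0}, de-duplicated by point symmetry (24 offsets).
Correlations are Pearson over all valid pixels after trimming a border
margin of half the largest kernel.  The image must be at least four
envelope σ of the coarsest Gabor on each side.  Constant images yield
zeroed marginals with a degeneracy flag rather than an error, keeping
batch runs alive.

**Transforms and regression.**  Raw statistics are mapped through
`sign(x)·√|x|`, z-scored per column (constant columns dropped and
recorded), and reduced per group by PCA to the smallest component count
covering >90% of the variance; scores are re-standardized.  At desk-scale
pair counts the 90% rule can demand more columns than rows, so the
pipeline caps per-group components at `n_pairs // 12` (inactive at the
reference scale of 1,000 pairs) and records the realized variance
fraction.  The per-pair population modulation of the top layer is fitted
by OLS with intercept; group contributions are decomposed by
averaging-over-orderings (LMG), computed exactly through the subset
identity (cost 2^G; refused above G = 12).  Contributions provably sum to
the full-model R², asserted to 1e−8.

## SHMAX

The network alternates sparse-coding and max-pooling layers grouped into
big layers.  Coding solves the nonnegative lasso per patch (patch-wise
independent coding, matching the per-patch objective; convolutional
coding with shared reconstruction is not used).  The solver is cyclic
coordinate descent, batched across patches; stopping combines a
coefficient-change tolerance with a stationarity (KKT) check, because on
overcomplete dictionaries the coefficient change can stall well before
stationarity.  KKT violations are verified to 1e−6 in the test suite.

Dictionary learning alternates batch coding (warm-started from the
previous codes) with block coordinate descent over columns; each column's
subproblem has a Hessian proportional to the identity, so projecting its
unconstrained minimizer onto the unit ball is the exact constrained
minimizer and the outer objective is monotone non-increasing (asserted).
Atoms are initialized from randomly drawn patches rescaled to unit norm —
the constraint boundary — because small-norm atoms never clear the soft
threshold and would stay dead.  Atoms whose codes are all zero are left
untouched (preserving monotonicity) rather than re-seeded.  Training
stops early when the relative objective change drops below 1e−6.

**Desk-scale architecture.**  Default: three big layers, coding kernels
7/5/3 with strides 2/1/1, each of the first two followed by 2×2 stride-2
max pooling, M = (24, 32, 48) atoms, λ = (0.15, 0.15, 0.1), trained on
64-px images with 150 random patches per image per layer and up to 15
outer iterations.  The five-big-layer, 224-px reference configuration is
reachable through `NetworkSpec`/`ExperimentConfig` but is not required by
any test.  The final big layer omits pooling (its maps are already small;
a big layer's response is its final maps either way).  Training images
are structured textures from the same families as the evaluation corpus
but disjoint image draws — the stand-in for training on an independent
natural-image corpus.  Training on the evaluation pairs themselves is
avoided because a small top layer can then memorize individual training
maps as atoms, which reverses the preference (a familiar stimulus gets a
compact code, an unfamiliar scramble a distributed one).

**Geometry.**  Receptive fields follow the standard recursion
`rf_l = rf_{l−1} + (k_l − 1)·Π strides below`; unit counts use floor
division with the configured paddings.  The two-path control splits a big
layer's filters into sets b and c: c keeps the baseline kernel, b's
kernel is enlarged by exactly the upper big layer's RF gain divided by
the input jump, so that the upper layer's set a (running on the c path)
satisfies rf(a) = rf(b) > rf(c) identically; symmetric padding on the b
path makes both paths' map sizes equal at the merge, and a parallel set d
(upper layer on the b path) completes the architecture for subsequent
layers.  Infeasible arithmetic (odd kernel enlargement, non-divisible RF
gain) is rejected with the offending numbers.

## Metrics and statistics

"Did not respond" means exactly zero — the rectifier/nonnegative coding
produces hard zeros; an epsilon threshold is available but defaults to 0.
Per-family PMI restricts the pairs to one family but keeps all
non-excluded units.  Population sparseness is summarized by the mean over
stimuli.  Units that respond to some stimuli but to neither member of any
pair have no valid pairs and are excluded and counted.

**Ranking distance.**  Natural logarithm.  The choice is empirically
forced: under the uniform-permutation-pair null at n = 25, only the
natural log reproduces the reported p-values (≈0.0002/0.0037/0.0019 at
RD 11.01/13.99/13.24); base-10 distances put those observations near the
null's center.  Terms are summed with exact (compensated) summation so
the symmetry axiom holds to the last bit.  The permutation test counts
null distances *strictly smaller* than the observed value, with no
continuity correction, and reports the binomial Monte-Carlo standard
error.

**Random-sampling t-test.**  Per repetition, `n_sample` (default 100)
units are drawn without replacement, independently per group; a standard
t-test (one-tailed unpaired by default) runs per draw and the p-values
are averaged over `reps` (default 500) repetitions.  Note a calibration
subtlety: the averaged p concentrates near the p-value of the realized
full-group difference, so its sampling spread across *group* draws is
wide; null-calibration tests therefore average over independent group
draws as well.

**Per-unit randomization test.**  Default null: each pair's CM/SM labels
are swapped independently with probability 1/2 (equivalently, a random
±1 signing of the per-pair indices), preserving pair structure; a
global-relabel variant (permute all 2·n_pairs labels, re-pair in order)
is available because the verbal description of label shuffling is
ambiguous.  p is the fraction of the null strictly larger than the
observed index; p < 0.05 flags a significantly positive unit.  Type-I
error is verified to lie in [0.04, 0.06] on exchangeable synthetic units.
Edge case: a unit with *identical* CM and SM responses has a degenerate
pair-swap null (all zeros) and p = 0 under the strict inequality; the
global variant handles it (p ≈ 0.5).  With continuous responses the
degenerate case has probability zero.

## Synthetic response generator

CM responses of unit u are Gamma(shape 2) with mean `scale·(1 + m_u)`,
SM responses with mean `scale·(1 − m_u)`; zeros are imposed by
independent thinning at the unit's non-firing probability, so the
non-firing fraction equals the configured probability in expectation.
Scales are log-normal across units.  Note `E[(a−b)/(a+b)] ≠ m` exactly
for gamma pairs; recovery tests compare against Monte-Carlo oracles of
the ratio statistic (and of the plug-in sparseness estimator, which
carries an O(1/n) bias at finite stimulus counts).  The tornado generator
draws the modulation band half-width as `mod_spread + coupling·q_u` and
folds a `skew_weight` fraction of draws to the positive side, reproducing
the widening, positively skewed sparseness-modulation scatter of trained
hierarchies.

What the generator does *not* emulate: correlations between units,
response dynamics, and measurement noise.  Passing recovery tests shows
the estimators and tests are correct and calibrated on data satisfying
their assumptions; it does not validate the gamma family against real
recordings.

## Problem sizes

Test-suite experiments run at deliberately small scale, chosen as the
smallest sizes at which each claim is stable: stimulus corpora of 4–25
families × 4–40 images at 64 px, networks with 16–48 atoms per layer,
10-seed repetitions for the qualitative signature, 1e6 permutation pairs
for the ranking-distance null, 2,000 units for test calibration.  The
reference-scale settings (25 × 40 corpus at 128/224 px, five big layers,
10⁴ randomization shuffles) are all reachable through configuration.

## Known limitations

- The CM stand-in shares the *kinds* of higher-order structure of
  correlation-matched textures, not the exact statistic values of any
  natural texture family; printed correlations that depend on the original
  image corpus are reproduced qualitatively (orderings, signs), not
  numerically.
- The qualitative signature at desk scale lives in a contrast window
  (see *Stimulus contrast*); this mirrors the dependence of the real
  effect on response sparseness, but it means the default generator
  contrast is part of the experimental design.
- The bottom big layer's PMI is slightly negative at desk scale, rather
  than near zero: with only three layers the threshold asymmetry between
  heavy-tailed structured responses and Gaussian scramble responses is
  not yet compensated by learned selectivity.  The layer-over-layer
  *increase* — the claim under study — is robust (10/10 training seeds in
  the acceptance suite).
- Supervised CNN baselines (ImageNet-trained AlexNet/VggNet variants) and
  the sparseness-regularized CNN loss are out of scope; SHMAX is the only
  trained model family.
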