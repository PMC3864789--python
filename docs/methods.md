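# Methods

`neovessel` detects retinal neovascularization — the growth of fine,
tortuous new vessels that marks proliferative diabetic retinopathy — in
color fundus photographs. Detection is image-level: each photograph is
reduced to a fixed 75-value descriptor, a supervised clustering step
compresses the descriptor, a small family of logistic models with
pairwise interactions is ranked by AICc, and the model-averaged
probability is thresholded on the ROC curve. This note records the
model choices, defaults and their rationale, the numerical decisions,
and what the built-in synthetic data can and cannot show.

## Preprocessing

All analysis runs on the green channel: the red channel of fundus
photographs is typically near saturation and the blue channel carries
little vascular contrast. Because the decorrelation stretch needs all
three channels, it is applied to the RGB image *before* green
extraction. The chain is:

1. **Decorrelation stretch.** The 3x3 channel covariance is whitened
   (symmetric eigendecomposition) and all channels are rescaled to a
   common spread, exaggerating hue differences and lifting faint
   microvasculature. Channels with no variance pass through unchanged.
2. **Hybrid median filter** (window 5): each pixel becomes the median
   of {median of the plus-shaped neighborhood, median of the X-shaped
   neighborhood, the pixel itself}. Removes impulse noise while
   preserving thin lines and corners; edges use reflection padding.
3. **Illumination correction** (disc radius 30 px): a background
   surface estimated by grayscale opening with a disc wider than any
   vessel is subtracted, and the mean background level is added back so
   a flat image passes through unchanged and the range stays in [0, 1].
4. **Dual-tree complex wavelet denoising** (4 levels, soft threshold at
   3 sigma). Two orthogonal `db6` trees — tree b uses the time-reversed
   filters and a one-sample-delayed input — give four 2-D row/column
   tree combinations that are merged into oriented complex subbands.
   Complex magnitudes are soft-thresholded at `threshold` times the
   robust noise scale (median absolute coefficient of the finest level
   / 0.6745), then each tree is inverted exactly (periodization mode)
   and the four reconstructions are averaged. With threshold 0 the
   transform reconstructs the input to machine precision. The filter
   pair is an approximate, not a designed, Hilbert pair: shift
   invariance is only approximate, which affects denoising quality but
   not invertibility.
5. **Contrast normalization.** The 1st-99th percentile range is
   stretched to [0, 1], removing residual per-image brightness and
   contrast differences before texture quantization.
6. **Vessel response and segmentation.** Vessels are dark and locally
   linear, so the response is the orientation-maximum bottom-hat
   (closing minus image) over line structuring elements (length 9 px at
   12 orientations; elements at theta >= 90 degrees are exact rotations
   of their partners, making the response equivariant under 90-degree
   image rotation). The response is hysteresis-thresholded (high = Otsu
   of the nonzero response, low = 0.5 x high) and components under
   30 px are dropped.

Defaults are sized for roughly 1000-px photographs.
`PreprocessConfig.for_small_images()` adapts them to ~200-px imagery
(line length 11, shrinkage 1.5 sigma, hysteresis low 0.3 x high, 20-px
size filter); the synthetic study uses these settings, under which the
segmented mask recovers >= 80 % of ground-truth vessel pixels.

## The 75-feature descriptor

**Statistical texture (17).** Images are quantized uniformly to 8 gray
levels. The co-occurrence matrix averages symmetric counts at the four
unit offsets and yields energy, entropy (bits), contrast, homogeneity,
four moments of the |i-j| distribution (mean, SD, standardized skewness
and kurtosis), correlation, dissimilarity, inverse difference momentum,
and maximum probability. Homogeneity and inverse difference momentum
coincide in their classical forms; IDM here normalizes the squared
index difference by the squared level count so the two stay distinct.
The run-length matrix is computed at 0/45/90/135 degrees and gives
short- and long-run emphasis, gray-level and run-length non-uniformity,
and run percentage, each averaged over the four directions.

**Higher-order spectra (50).** For each of ten angles (0 to 162 degrees
in 18-degree steps — 180 duplicates 0) the mean-subtracted image is
Radon-projected to a 1-D signal, zero-padded to a power of two. The
bispectrum B(f1,f2) = E[X(f1)X(f2)X*(f1+f2)] is estimated by the direct
method (Hann-windowed segments of length nfft = 256 with 50 % overlap,
triple products averaged across segments) and summarized over the
principal domain 0 <= f2 <= f1, f1+f2 <= 1 (Nyquist units) by five
statistics: mean magnitude, entropies of the normalized magnitude and
of its second and third powers, and the entropy of the phase histogram
(64 equal bins on (-pi, pi]); natural logarithms throughout. Averaging
over segments suppresses the bispectrum of Gaussian noise, so the
statistics respond to non-Gaussian, quadratically phase-coupled
structure such as dense vessel nets. An all-zero bispectrum (constant
image) reports zeros by convention.

**Fractal (8).** Box counting on the binary vessel mask at dyadic box
sizes from 2 px to a quarter of the short side (larger boxes carry
finite-size bias) gives `fd_box`. The radially averaged 2-D power
spectrum of the grayscale image, fitted in log-log between 4
cycles/image and half the Nyquist frequency, gives `ffd_slope` and
`ffd_intercept`; a constant image reports slope 0 with a finite
sentinel intercept (-50). The multifractal spectrum of the grayscale
measure is estimated by box-counting moments for q in [-5, 5] (step
0.5): tau(q) from the partition-sum scaling, the Hoelder exponent
alpha(q) from the moment (Chhabra–Jensen) estimator, and
f(alpha) = q alpha - tau. Empty boxes are excluded before
exponentiation so negative q stay finite, and q values whose alpha
regression falls below R^2 = 0.9 are dropped before extracting the
five reported parameters: alpha_min, alpha_max, alpha at q = 0 (local)
and f(alpha_min), f(alpha_max) (global). The grayscale measure is the
default; a mask-based measure is available via
`multifractal_spectrum(mask.astype(float))`.

## Dimension reduction (supervised clustering)

`PeloraReducer` grows up to K = 5 clusters greedily on standardized
features. A cluster's representative is the mean of its sign-adjusted
members; candidates (feature, sign) are scored by the ridge-penalized
logistic deviance of the labels on all current representatives
(penalty 0.01 n, IRLS). A candidate joins only if it improves the
criterion by more than 2 ln(number of candidates) — the chi-square(1)
Bonferroni level, which keeps chance admissions rare on pure-noise
tables — or if it ties the criterion exactly, the signature of a
duplicated measurement. The penalized likelihood keeps the criterion
stable under the strong class imbalance of screening cohorts
(about 1 positive per 4 controls here, 27/110 in real archives).

## Model selection and multimodel inference

The cluster representatives enter an exhaustive logistic-model search:
every subset of main effects and, optionally, of their pairwise
interactions, under marginality (an interaction requires both mains).
With 5 representatives this is 1,450 models; beyond 20 candidate terms
a seeded genetic search (population 100, 200 generations) replaces
enumeration. Higher-order interactions are excluded. Models are ranked
by AICc = AIC + 2k(k+1)/(n-k-1); a model with n <= k+1 is inadmissible.
Quasi-separated fits fall back to a light ridge and are flagged.

Selection uncertainty is handled by stratified bootstrap (B = 200 by
default; stratification preserves the minority class). Each replicate
re-fits the top 20 models and computes Akaike weights
exp(-delta/2)/sum; the smoothed weight of a model is its across-
replicate mean weight. Coefficients are model-averaged with absent
terms counted as zero; the reported variance is the sum of the
within-model part (weighted mean squared standard error) and the
between-model part (weighted dispersion of the per-model estimates).

## Evaluation

Scores are weight-averaged predicted probabilities. AUC is the
Mann-Whitney concordance statistic (ties half), with the Hanley-McNeil
standard error. The operating point defaults to the Youden-optimal
threshold. Because apparent metrics flatter any selected model, the
evaluation module reports both resubstitution and stratified 5-fold
cross-validated metrics; in cross-validation the entire chain
(clustering, enumeration, averaging) is refit inside each fold.

## Synthetic data: what it emulates and what it does not

The generator renders a bright orange textured circular field of view,
a recursive branching tree of dark vessels (trunk width 3-4 px,
thinning by 25 % per branching, depth 5-6), low-frequency value-noise
texture, a linear illumination ramp, and Gaussian pixel noise, at a
default size of 192 px — a desk-scale stand-in for 960-1536 px
photographs, with all pixel-unit parameters scaled accordingly.
Positive images add a neovascular tuft: ~220 x density short
Brownian-walk strokes of width 1.1 px inside a disc of radius 12 % of
the image width, placed centrally within the field of view. These
lesion values were chosen so that the tuft is unambiguous, the way
florid neovascularization is to a grader, and so that the premise that
new vessels raise the fractal dimension of the vessel pattern holds
measurably at this scale (matched-pair ground-truth masks differ by
+0.11 in box-counting FD on average).

Background streams are seeded independently of the tuft stream, so a
positive image and its tuft-free twin are pixel-identical outside the
lesion: a classifier can only learn the lesion. Per-image parameters
are jittered across a cohort (branches 5-6, depth 5-6, width 3-4 px,
ramp 0.05-0.25, noise 0.01-0.03, positive tuft density 0.7-1.0).

What passing tests do *not* show: the synthetic images contain no
optic disc, fovea, exudates, hemorrhages, laser scars or camera
vignetting beyond a linear ramp; lesion appearance is geometrically
idealized; and class separation is by construction cleaner than in
MESSIDOR/DIARETDB0-style archives. Results on synthetic cohorts
validate the machinery, not clinical performance.

## Numerical choices and degenerate inputs

- All intermediate images are float64 in [0, 1]; quantization happens
  only inside GLCM/RLM binning.
- Constant images: zero bottom-hat, unchanged by filtering and
  illumination correction, all-zero HOS block, FFD sentinel intercept.
- GLCM correlation of a one-level image is reported as 1; moment
  skewness/kurtosis of a zero-spread difference distribution as 0.
- Box-counting and multifractal fits use plain least squares on
  dyadic sizes; box-grid alignment makes `fd_box` rotation-invariant
  only to about 0.01.
- Akaike weights are computed after subtracting the minimum AICc
  (shift-invariant, overflow-safe); infinite AICc gets weight 0.
- Bootstrap replicates that lose a class are redrawn (at most 10 B
  attempts) and counted.
- Every stochastic component (generator, bootstrap, genetic search,
  cross-validation splits) takes an explicit seed; a fixed seed
  reproduces results bit for bit.

## Problem sizes used in the shipped studies

The synthetic study cohort is 30 positive / 120 negative images of
192 px; model-recovery simulations use n = 300 with 50 replicates and
B = 200 bootstrap replicates; known-fractal checks use 243-256 px
sets and a 5-level multiplicative cascade. These sizes make the full
suite and the acceptance run complete in a few minutes on one CPU
while leaving every estimator in its asymptotically meaningful regime.

## Known limitations

- The bispectral entropy definitions follow the standard normalized
  forms of the HOS-screening literature; other conventions exist.
- The mapping of "three local / two global" multifractal parameters to
  (alpha_min, alpha_max, alpha_0, f(alpha_min), f(alpha_max)) is one
  defensible choice among several and is configurable.
- The dual-tree filters are not a designed q-shift pair; directional
  selectivity is coarser than a reference implementation's.
- Pelora-style clustering is greedy; it does not revisit assignments
  and offers no optimality guarantee.
- With 5 clusters the exhaustive search is exact, but AICc ties near
  the top can reorder under bootstrap; interpret single "best models"
  through the smoothed weights, not in isolation.
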