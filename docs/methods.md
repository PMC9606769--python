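# Methods

`sipscape` implements an analysis chain from experimental aesthetics: how the
objective, formal statistics of abstract images relate to the aesthetic
judgments they elicit.  This note records the models, the conventions chosen
where the problem left the design open, and what the synthetic study does and
does not establish about real data.

## Random-phase stimulus synthesis

A random-phase image has a prescribed rotationally averaged power spectrum,
`power(f) ∝ f^α`, and i.i.d. uniform phases, so it carries texture but no
recognisable content.  The synthesis sets the Fourier **amplitude** to
`f^(α/2)` (power is amplitude squared), draws one uniform phase field over the
full frequency grid, and takes the real part of the inverse FFT — equivalent
to Hermitian-symmetrising the spectrum, which rescales expected power
uniformly across frequencies and therefore leaves the slope α untouched.
Conventions:

- The DC term is zeroed before inversion (the `f = 0` power law is
  undefined); the result is linearly min–max rescaled to `[0, 1]`.  Affine
  intensity maps do not move the measured slope, so the rescale is harmless.
- Colored stimuli place three independent syntheses of the same α in R, G
  and B.  Channel sub-streams are the three children of
  `SeedSequence(seed)`, so one master seed reproduces the image exactly and
  channels are uncorrelated *in expectation*.  At steep slopes a single
  256-px realisation has few effective degrees of freedom, so individual
  channel correlations of ±0.3 are normal; they average out over seeds.

**Slope estimation.** RGB is reduced to Rec. 709 luminance; the 2-D power
spectrum is averaged over 30 log-spaced radial annuli; a least-squares line
is fit to log₁₀(mean power) against log₁₀(geometric-mean frequency) over a
default window of (10, size/4) cycles/image.  The window avoids DC leakage
at the bottom and the anisotropic spectrum corners at the top; both window
and bin count are configurable because no standard protocol exists.  Across
α ∈ {−5 … 0} the estimator recovers the set slope with bias ≈ 0.02 and
seed-to-seed s.d. ≈ 0.03 at 512 px (the acceptance suite checks ±0.15).

## Statistical image properties (SIPs)

All SIPs are computed after bilinear resampling to a fixed square working
resolution (default 800 px; tests run at 64–256 px), which makes them
independent of the stored image size.  Two low-level conventions apply
throughout:

- **Gradients** are central differences with periodic (wrap) boundaries.
  This makes an image tiled in register with the pyramid grid *exactly*
  self-similar and keeps the rotation/mirror symmetries of the definitions
  exact; the price is a spurious seam response on the ≈0.5 % of pixels at
  the border of non-periodic images.
- **Colour gradients** are taken per CIELab channel after scaling L to a
  0–255 span (a and b already span ≈255 units); the channel with the largest
  magnitude supplies both magnitude and unsigned orientation (mod 180°).

The measures:

- **Complexity** — mean of the max-channel gradient magnitude (0–255
  scale).  Exactly 0 for constant images.
- **PHOG self-similarity** — magnitude-weighted orientation histograms
  (16 bins over 0–180°) on a spatial pyramid; the value is the median over
  the 64 level-3 cells of the histogram-intersection kernel
  `Σ min(hᵢ, gᵢ)` between the (L1-normalised) cell histogram and the
  whole-image histogram.  **Anisotropy** is the s.d. of the level-3 bin
  strengths, rescaled by the one-hot maximum `√(B−1)/B` so a one-orientation
  image scores 1.
- **Edge-orientation entropies** — oriented edge strength is the maximal
  |response| over 24 first-derivative-of-Gaussian orientations (σ = 1 px,
  realised as projections of the Gaussian gradient, to which the rotated
  filters are algebraically identical).  Non-maximum suppression in a
  3-px Chebyshev radius keeps one edge per neighbourhood, a floor of 1e-12
  of the peak strength discards round-off responses in flat regions, and
  the 10 000 strongest pixels survive.  If suppression leaves fewer pixels
  than orientation bins — steep-slope stimuli are that smooth — the
  classical strongest-pixels rule (no suppression) is used instead.
  First-order entropy: Shannon entropy of the strength-weighted orientation
  histogram / log 24.  Second-order: pairs are binned by distance into 20
  log-spaced bins; per bin, the entropy of the histogram of *unsigned
  circular* orientation differences (0–90°; the signed difference would
  depend on enumeration order), weighted by strength products, normalised
  by log 24; the mean over populated bins is reported.  Pairs are
  enumerated exhaustively up to 10⁶ and subsampled with a seeded RNG above
  that (the subsample agrees with full enumeration to < 0.02).
- **Filter-bank variances P_a(k), P_f(k)** — responses of a deterministic
  bank of 50 zero-mean, unit-norm kernels (8 orientations × 3 frequencies ×
  even/odd Gabor phases on luminance, plus two difference-of-Gaussian
  kernels on the R−G and B−(R+G)/2 opponent planes).  The bank stands in
  for first-layer CNN filters: the analysis exercises the *structure* of
  the measures, and the bank is pluggable for externally supplied kernels.
  Convolution is circular (FFT); rectified maps are max-pooled onto a k×k
  grid, k ∈ {2, 4, 8, 16, 30}.  P_a(k) = population variance over all
  k²·50 entries (inverse richness); P_f(k) = median over filters of the
  per-filter variance (variability).  Exactly 0 on constant images.
- **Colour statistics** — CIELab channel means (standard scales) and HSV
  means; the hue mean is circular (reported in degrees).  Entropies from
  256-bin histograms in bits; hue bins wrap.
- **Mirror symmetry (lr/ud)** — PHOG histograms on a 4×4 cell grid of one
  half versus the pixel-mirrored opposite half (mirroring in pixel space
  reflects orientations automatically); per-cell histogram intersections
  averaged, then the two axes averaged.  Whether the original measure was
  gradient- or CNN-feature-based is not documented; the PHOG-based
  definition is this package's convention.
- **Fourier slope** — the estimator above at the working resolution.

Every measure is checked against an independent brute-force implementation
(explicit pixel loops, explicit rotated kernels, explicit wrap-padded
sliding windows, exhaustive pair loops) to 1e-6 (1e-2 for the second-order
entropy).

## Predictor selection

Three steps reduce a candidate SIP set for regression:

1. **Best-subset search**: for every model size the `n_best = 10` subsets
   with the highest adjusted R² (`1 − (1−R²)(n−1)/(n−p−1)`) are retained —
   exhaustively while `C(p, s)` is within the enumeration cap, otherwise by
   a branch-and-bound that prunes a partial subset when even adjoining its
   whole remaining pool cannot beat the current 10th-best RSS.  Ties break
   lexicographically so both routes return identical lists.
2. **Robustness cut**: the visual "appears in many models" judgment is
   operationalised as the total appearance count across all retained
   models of all three rating dimensions, ties broken by the best
   single-model adjusted R²; the top 12 survive.
3. **Collinearity pruning**: while any surviving pair has Spearman
   |ρ| > 0.6, the member of the worst pair with the lower robustness count
   is dropped (ties: lower |ρ| to the response, then the alphabetically
   later name); an audit log records every drop.

A PCA reference model (OLS on the leading principal components of the
standardized candidate set) provides the explained-variance yardstick the
reduced model is compared against.

## Rating analyses

Regressions are fit on **per-image mean ratings** with predictors and
response z-scored, so coefficients are standardized β\* (bands: weak < 0.2 ≤
moderate < 0.5 ≤ strong) and each p-value is the partial t-test in the full
model.  Group comparisons use the tie-corrected Kruskal–Wallis test with
Dunn's post-test
(`z = (R̄ᵢ − R̄ⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)]`),
Holm-adjusted over all pairs by default (Bonferroni switchable) with the
four-level star convention.  Slope-preference profiles are quadratic
least-squares fits of mean rating against set slope (inverted-U ⇔ negative
quadratic coefficient, vertex −b/2c) plus the group test across slope
levels.  Inter-rating correlations are Spearman ρ between dimension pairs,
pooled over per-image means or within each participant (≥ 5 common images).

## Sweet-spot distances

A reference corpus is summarised by its per-SIP **median** (the centre the
distances are taken to) and the ordinary sample covariance about the mean,
ridge-regularised by 1e-8·mean(diag) when near-singular.  The squared
Mahalanobis distance `D² = (x−c)ᵀΣ⁻¹(x−c)` is affine-invariant, so no
standardization is applied; with the median centre the invariance holds
coordinatewise (the componentwise median is not equivariant under general
linear maps — tested accordingly).  The distance subspace defaults to the
SIPs whose distributions differ significantly (Kruskal–Wallis) between the
test set and the reference, mirroring the study's rule; Gaussian calibration
(D² ~ χ²_p) is verified by simulation.  Negative Spearman correlations
between D² and ratings mean images closer to the reference are preferred.

## Participant clustering

Participants are described either by (ρ_PH, ρ_PI, ρ_HI) or by their
z-scored 18-feature slope-preference profile (z-scoring is this package's
choice; it prevents scale dominance).  K-means (k-means++, 25 restarts)
runs over k = 1…8; elbow, silhouette and gap (uniform bounding-box
reference, 50 seeded draws) are always reported.  The **elbow is taken on
log-WSS**: the raw-WSS second difference saturates at the first large drop
and, on five-archetype benchmark data, always chose k = 2 (ARI 0.33),
while the log-scale kink identifies k = 5 in every seed — the silhouette
agrees.  The chosen k follows the elbow but is demoted until every cluster
has more than three members.

## The synthetic study

The generator emulates the study design: 40 raters; 6 set slopes × 25
random-phase images of which each rater sees 5 per slope (a cyclic balanced
incomplete design giving exactly 8 ratings per image); 150 "pseudo-painting"
collages rated by everyone; three dimensions.  Ratings follow

```
rating = clip01[ 0.5 + s·(Σⱼ β_dj·z(SIPⱼ) + slope-term + offset_p + ε) ]
```

with trial noise ε ~ N(0, 0.3²), participant offsets N(0, 0.2²) and a scale
s = 0.12 compressing the standardized latent into the click scale
(standardized regression is affine-invariant, so s does not move β\*; it
only keeps clipping rare).  Default loadings have row sums of squares
≈ 0.55–0.65, matching explained variances in the 50–69 % range.  Rater
archetypes: half inverted-U (peak −2.5), 20 % increasing, 20 % decreasing,
10 % with the Interesting loadings flipped against Harmonious
(anticorrelated group).  The recorded ground-truth β\* are the *implied
standardized coefficients* β/sd(per-image mean latent) — the quantity a
standardized regression on per-image means estimates — so noiseless runs
recover them exactly and default runs to MAE < 0.1 with ≈ 95 % CI coverage.

Pseudo-paintings are dead-leaves-style collages: sharp-rimmed elliptical
discs with a power-law size distribution, painted over one another until
2.5 image areas are covered.  The characteristic `patch_scale` steers the
size-distribution exponent (coarser mixtures ⇒ steeper spectral slope, the
classic occlusion account of natural-image spectra); `hue_spread` moves hue
entropy monotonically below the saturation point of the hue circle.  The
collages are built only to *span SIP space*; they claim no artistic
validity, carry no semantic content, and have narrower slope ranges than
real style-transferred paintings.  Passing tests therefore demonstrate that
the pipeline recovers planted structure of the assumed (linear,
Gaussian-noise) rating model — not that real ratings follow that model.

Fast surrogates (`sample_sip_table`, `sample_inter_rating_vectors`) draw
SIP-like feature tables and archetype correlation vectors directly for
calibration batteries that need hundreds of replicates; image-based runs
use 64–256 px working sizes (the study display resolution of 800 px is the
default for real analyses).

## Numerical choices and limitations

- Variances are population (ddof 0); histogram intersections operate on
  L1-normalised histograms, with all-zero histograms contributing 0.
- Empty pair-distance bins are skipped (not counted as zero entropy).
- Covariance ridge, KMeans restarts, gap-statistic reference draws and the
  pair-subsampling RNG are all seeded; two runs from one seed are
  byte-identical.
- The filter bank is a stand-in with the documented structure, not trained
  CNN weights; absolute P_a/P_f values are bank-dependent even though their
  comparative use is not.
- Only the 20 SIPs named in the analysis are implemented; the wider
  supplementary set is out of scope, and `compute_sip_table` is the hook
  for adding more columns.
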