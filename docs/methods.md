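# Methods

## Spectrum model and conventions

A spectrum is a vector of absorbance values on a strictly increasing
wavenumber grid in cm⁻¹. The default working grid spans 4000–400 cm⁻¹ at
2 cm⁻¹ point spacing (1801 points) — the conventional digitization for a
4 cm⁻¹ optical resolution — and is configurable. Wavenumbers are stored
ascending; the descending presentation customary in spectroscopy is left to
plotting code, and all operations are defined on the internal order.
Spectral windows are inclusive on both ends, matching the habit of quoting
exact endpoint wavenumbers; the default analysis windows are 3751–2749 cm⁻¹
(C–H/O–H stretch region) and 1800–599 cm⁻¹ (fingerprint region), processed
high-wavenumber window first. Resampling between grids is linear
interpolation and refuses to extrapolate.

## Synthetic fingerprint generator

The generator stands in for root spectra that are not publicly available.
It emulates the *structure* of such data, not any particular instrument:

* **Line shape.** Bands are Gaussian. Nothing in the emulated data
  constrains the line shape, so the simplest model preserving position,
  width and height semantics is used (no Lorentzian/Voigt tails).
* **Species profiles.** Each of the eight study species has a baseline
  (0.02 AU) plus common bands (3330, 2921 cm⁻¹, and 1030 cm⁻¹ — always the
  tallest, amplitude 0.90–1.10 AU, tallest in the weeds), a family template
  (Poaceae: 1160, 1370, 898 cm⁻¹; Chenopodiaceae: 1100, 1320, 1740 cm⁻¹) so
  that within-family spectra are mutually closer than cross-family ones,
  and the species-specific fingerprint bands at their reported positions
  (maize 1572; barnyard grass 1637; barley 1510, 815; wheat 1510, 1420;
  sugar beet 1621, 1416; common lambsquarters 1516, 1240 cm⁻¹). Amplitudes
  are design choices (0.08–0.40 AU) fixed so the qualitative relative-
  height relations hold: blackgrass elevated over wheat in 1800–1200 cm⁻¹,
  and barley/wild oat sharing peak *positions* while differing only in
  height — deliberately the hardest pair, as it was in the glasshouse data.
* **Noise model.** Four seeded sources: per-peak multiplicative amplitude
  jitter (CV 0.05 for dried segments, 0.02 for ground material —
  homogenization averages local tissue composition), a global intensity
  scale (SD 0.10, emulating sample thickness/crystal contact), a random
  baseline offset and tilt (SD 0.01 AU), and additive white noise
  (SD 0.002 AU). All default values are fixed package-wide conditions, not
  per-analysis dials; a single integer seed fixes the whole stream, and
  changing only the seed changes only the noise, never the noise-free
  signal.
* **Preparation states.** `dried_segment` is the peak model as given.
  `ground` uses the lower amplitude jitter. `fresh_segment` superimposes
  broad water bands — O–H stretch at 3300 cm⁻¹ (width 150) and the H–O–H
  bend at 1640 cm⁻¹ (width 40), at 6× and 5× the tallest dry band — and
  additionally attenuates the family/species fingerprint bands to 0.3× to
  model how the water signal conceals the compositional bands, not merely
  sits on top of them. (Superposition alone is largely undone by the first
  derivative, which suppresses broad bands; concealment is the physical
  mechanism and is what makes fresh material genuinely indiscriminable.)
  Segment positions (basis/middle/tip) accept configurable amplitude
  modifiers, including an optional tip-convergence factor that shrinks
  species-specific bands at root tips, where surface chemistry is most
  alike across species.
* **Mixtures.** Beer–Lambert additivity: the noise-free part of a mixture
  spectrum is the mass-fraction-weighted sum of the noise-free pure-species
  spectra; scale, drift and additive noise are applied to the mixed
  spectrum. Linearity in the fractions is verified against a summation
  oracle. The two-species calibration design is the 5%-step dilution series
  (21 compositions); the three-species design draws n compositions
  uniformly from the simplex by seeded rejection sampling within per-species
  bounds (defaults 15–80% maize, 1.5–79% wild oat, 0.5–20% barnyard grass),
  because the original 21 compositions were never listed. n is exposed
  because the original sample count is reported inconsistently (21 vs 23).

What passing tests on this generator show: that the *pipeline* —
preprocessing, Ward statistics, PLS calibration and validation — behaves
correctly on data with the stated spectral structure. What they cannot
show: performance on real instruments (ATR penetration-depth effects,
scatter, atmospheric lines, detector drift and nonlinear matrix effects are
all out of scope).

## Preprocessing

* **First derivative.** Savitzky–Golay, default window 9 points and
  polynomial order 2, with the filter's derivative divided by the grid
  spacing to give a true d/d(wavenumber) in AU·cm. The smoothing width is a
  convention of the (non-public) instrument software; 9 points at 2 cm⁻¹
  spacing is a standard choice and both parameters are configurable. Edges
  are handled by evaluating the edge window's fitted polynomial (no
  zero-padding, so no fabricated edge features). A uniform grid is
  required.
* **Vector normalization.** Subtract the mean intensity, then divide by the
  Euclidean norm of the centered spectrum. Idempotent, and invariant to
  affine intensity changes — exactly the scale and baseline terms the noise
  model injects. Constant spectra are rejected as degenerate.
* **Offset correction.** Shift so the minimum is exactly zero. Idempotent.
* **Pipeline.** Steps are applied per sample in the configured order, then
  the windows are extracted. The default for clustering is first derivative
  → vector normalization; offset correction is available but not in the
  default chain, since the analyses that were actually clustered used the
  two-step treatment while the methods text also lists offset correction —
  an ambiguity resolved here in favour of the per-analysis captions.
  Normalization runs over the full recorded range before windowing (the
  window choice then cannot alter the normalization); `window_first`
  flips the order for sensitivity analysis.

## Ward clustering and heterogeneity

Agglomeration minimizes the growth of total within-cluster sum of squares
(Ward). The implementation keeps squared Euclidean distances and applies
the Lance–Williams update

D(r,i) = [ (nₚ+nᵢ)·D(p,i) + (q→ likewise) − nᵢ·D(p,q) ] / (nₚ+n_q+nᵢ),

merging the pair with the smallest updated squared distance; ties break
toward the smallest node-id pair, making results order-stable. Merge
heights are the fused pair's D value, which equals exactly twice the
sum-of-squares growth — a brute-force oracle that recomputes that growth
for every candidate pair at every step is the ground truth in the tests,
and scipy's Ward implementation (whose heights are the square roots of
these) serves as an independent cross-check. The published heterogeneity
equation for this update is typographically corrupted in its source and is
not algebraically well-formed; the standard Ward recurrence over the same
symbols is the implemented reading. Because the height *scaling* of the
original software is proprietary, absolute merge heights are not comparable
across implementations: only ratios, purity and topology are contractual
outputs here.

Reported statistics: per-species intraspecific heterogeneity (height of
the lowest node covering all the species' leaves), interspecific
heterogeneity (height of the lowest node covering both species), the
inter/intra ratio rounded half-away-from-zero to one decimal (the rounding
consistent with all four published multipliers), a purity flag (each
species' covering node contains no foreign leaf), and the k-cluster
separation percentage: a leaf counts as separated iff its cluster is
species-pure *and* its species occupies exactly one cluster. Species with
a single sample get intra = 0 and are flagged rather than rejected.
Dendrograms export to Newick with branch lengths equal to parent-minus-child
height differences.

## PLS quantification

Composition (percent, rows closed to 100) is regressed on preprocessed
spectra with centered, unscaled NIPALS PLS (scikit-learn's
`PLSRegression` backs the fit; spectra entering the model are already
vector-normalized, so no variance scaling). All species are fitted jointly
in one multivariate model; with closed compositions this makes predictions
sum to 100 and, for two species, forces mirrored errors (equal RMSE,
opposite bias) — a structural property the tests assert.

Leave-one-out cross-validation refits the model n times, each time
predicting the held-out sample; RMSECV per species is assembled over all
folds, and the component count minimizing the mean RMSECV is selected, ties
resolved toward fewer components. Counts exceeding the effective rank of
some training fold are scored as infinitely bad rather than aborting the
search. `optimize_model` extends the same criterion over a grid of
preprocessing specs. External validation applies a frozen model to a
disjoint test set and reports prediction-context metrics plus the
least-squares line of predicted on true values.

Conventions: RMSE uses the plain 1/n mean in every context (no
degrees-of-freedom correction); the reference SD in RPD uses the n−1 sample
variance; predictions are not clipped to [0, 100] nor renormalized (over-
and under-shoot at the range ends is diagnostic), though both are available
as options. The published tables for this kind of model do not state their
denominator conventions, so exact reproduction of third-party table values
is not a goal; the RPD class boundaries (3/5/10) are.

## Numerical choices and degenerate inputs

* Rounding of heterogeneity ratios: half-away-from-zero via decimal
  arithmetic, one decimal place.
* Ward tie-break: smallest (left, right) node-id pair; permutation of
  input order changes neither heights nor any k-partition.
* Constant spectra: rejected by vector normalization (zero norm); offset
  correction and derivatives handle them fine.
* Mixture fractions must be in [0,1] and sum to 1 within 1e-9.
* Rejection sampling of three-species designs has an explicit try budget
  (default 10⁶) and fails loudly if the bounds make the acceptance region
  too small.
* Newick branch lengths are serialized at 12 significant digits; root-to-
  leaf path sums are reproducible to ~1e-6 of the root height.

## Problem sizes

The default analyses are sized for a desk machine: discrimination uses
6 replicates × 2 species × 4 pairs = 48 spectra of 1801 points
(~1100 retained features), and quantification 21 mixtures × 3 replicates
= 63 spectra with leave-one-out selection over 10 component counts. The
full test suite and the acceptance script each run in seconds on one CPU.

## Known limitations

* The generator is additive and noise-stationary: no scatter artifacts,
  no atmospheric compensation residuals, no instrument drift over time,
  no ATR penetration-depth dependence on wavenumber.
* Absolute dendrogram heights depend on the squared-distance scaling
  convention and are not comparable to other software's heights.
* PLS assumes linear mixing; strongly interacting components (chemical
  shifts on mixing) are outside the model.
* The three-species design is a random stand-in for an unpublished
  composition list; conclusions about that specific design transfer only
  statistically.
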