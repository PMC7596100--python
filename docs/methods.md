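# Methods

`infilstat` quantifies immune-cell infiltration in tumour tissue from 2-D
point patterns of cell centroids. It has three layers: spatial statistics
computed from a point pattern, a synthetic two-compartment tissue generator
labelled by an infiltration ratio, and maximum-likelihood inference of that
ratio from the statistics. This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Spatial statistics

All coordinates are in millimetres inside a rectangular observation window,
by default the 1.5 mm × 1.5 mm region-of-interest (ROI) tile; 20 μm = 0.02 mm
is roughly one macrophage diameter. Four statistics are computed on a
uniform radius grid (default bin width `dr` = 0.01 mm, maximum radius
0.75 mm = half the window side; bin *i* covers `(i·dr − dr/2, i·dr + dr/2]`,
ties to the upper bin):

* **Pair correlation function** g(r): for each point, the number of other
  points in the annulus around it divided by the expected count under
  complete spatial randomness (CSR); averaged over points. The CSR
  expectation is the global intensity n/|W| times the annulus–window
  intersection area, computed in closed form for rectangles (per-quadrant
  circle–rectangle integrals). This area-based edge correction is unbiased
  under CSR by construction and is verified in the tests against adaptive
  numerical quadrature. g ≡ 1 under CSR; g > 1 indicates clustering at that
  scale, g < 1 inhibition (here the hard core forces g = 0 below 0.02 mm).
* **Nearest-neighbour distance CDF** G(r): empirical CDF of each point's
  distance to its closest neighbour. No edge correction (plain empirical
  definition).
* **Spherical contact / empty-space CDF** F(r): empirical CDF of distances
  from uniformly random reference locations to the nearest pattern point.
  The number of reference points equals the pattern size so F and G have
  equal denominators. F is therefore a stochastic statistic; the reference
  seed is recorded with every feature row. Tests can inject explicit
  reference points.
* **J-function** J(r) = (1 − G)/(1 − F), defined while F(r) < 1; J ≡ 1
  under CSR, J < 1 indicates clustering, J > 1 dispersal.

Three scalar features summarise the curves: `g_max = max g` (peak clustering
intensity), `F_max` = the largest observed empty-space distance (radius of
the largest "immune desert"; equivalently the smallest r with F(r) = 1,
taken from the raw reference distances rather than the grid), and
`J_min = min J`, clamped to [0, 1] (since J(0) = 1 and J ≥ 0, values above
1 at the minimum can only be grid artefacts). The J minimum is searched
over radii where the tail estimate 1 − F(r) rests on at least 10 reference
points. Close to F_max the ECDF ratio (1 − G)/(1 − F) is a ratio of counts
of extreme order statistics with unbounded relative noise; without the
restriction J_min acquires a point mass at exactly 0 for a quarter to a
half of all patterns at every infiltration level (whenever the largest
nearest-neighbour distance loses the race against the largest void
radius), destroying its value as a clustering descriptor and its
approximate normality across an ensemble. Patterns with fewer than two
points raise explicit errors;
empirically the statistics are unstable below ~150 cells/mm², which is why
the generator truncates densities there.

## Synthetic tissue generator

The generator emulates a cohort of CD68+ macrophage patterns in
head-and-neck tumour ROIs. Its defaults are the study conditions, not
free dials:

* **Geometry.** A zero-mean stationary Gaussian random field with Gaussian
  correlation exp(−π²r²/(2l²)) is synthesised spectrally (FFT, 256² grid)
  and thresholded at 0; the positive excursion set is the tumour-nest
  compartment. The π² scaling makes the mean chord length of the excursion
  set equal to the nest length scale *l* (Rice's zero-crossing formula), so
  *l* is literally the mean nest width. A draw is accepted only if each
  compartment covers ≥ 25% of the window; the tumour area fraction
  otherwise varies freely between draws, which is the dominant source of
  between-pattern feature variance at fixed parameters. Masks are periodic
  in construction; at the accepted *l* range (0.1–0.75 mm per pattern,
  uniform) the wrap-around correlation is a second-order effect absorbed by
  the geometry variability.
* **Counts.** The overall density d is drawn from Normal(333, 170) cells/mm²
  truncated below at 150 (the empirical cohort distribution), giving
  N = round(d·|W|) points. The infiltration ratio ρ = d_t/d_s (nest density
  over stroma density, ρ ∈ [0, 0.5] for training) fixes per-compartment
  quotas n_t = round(N·ρ·A_t/(ρ·A_t + A_s)), n_s = N − n_t.
* **Placement.** Candidates are uniform over the whole window and accepted
  iff their compartment's quota is unfilled and they are ≥ 0.02 mm from
  every accepted point (one global hard core across compartments). The
  sequential acceptance loop uses a spatial hash (cell size = exclusion
  radius) compiled with numba. Failure handling: a compartment whose quota
  would exceed 45% hard-core disc coverage (near the ~55% random
  sequential adsorption jamming limit) is rejected up front; a stalled fill
  (proposal budget or 10,000 consecutive rejections) raises an error.
  Failed draws are resampled with a fresh (d, l, geometry) sub-seed, so the
  realised ensemble slightly under-represents the extreme corner of high
  density inside a small compartment — a physically absurd crowding regime.
* **Ensembles.** Training: every ρ on the grid {0, 0.02, …, 0.5} with a
  configurable number of repetitions (the full-scale design uses ≥ 1200;
  the shipped validation experiments use 200 per ρ, which bounds the Monte
  Carlo error of per-ρ feature means well below the fitted-curve residuals
  while keeping a full run in minutes on one CPU). Validation: ρ uniform on
  [0, 0.5]. All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning, so manifests and coordinates are
  bit-reproducible.

What the generator does **not** emulate: staining artefacts, tissue folds,
anisotropic or branching stromal architecture, cell-size variation (the
hard core is a single diameter), and multi-type interactions. Passing the
validation experiments therefore shows that the inference machinery
recovers the generator's own infiltration parameter — a well-posedness and
calibration statement — not that ρ estimated on real tissue equals any
particular biological quantity.

## Feature model and inference

At fixed ρ the features (g_max, F_max, J_min) are approximately normal
across patterns. Per feature, the per-ρ means and SDs over the training
ensemble are fitted by least squares with the three-parameter family
a·e^(−bρ) + c, giving smooth μ(ρ) and σ(ρ) for every ρ ∈ [0, 0.5],
including off-grid values. The monotone μ curves make single-statistic
estimates monotone in the observed feature. The cross-feature correlation
C(ρ) is estimated empirically at each training ρ (Pearson, nearest grid
point used off-grid) and combined with the fitted SDs into
Σ(ρ) = D(ρ)·C(ρ)·D(ρ).

The log-likelihood of an observation x for a subset of k features is the
multivariate normal form

    ln L(ρ) = −½ ( ln|Σ(ρ)| + (x − μ(ρ))ᵀ Σ(ρ)⁻¹ (x − μ(ρ)) + k ln 2π ),

reducing to the univariate formula for k = 1. The estimate η is the argmax
of ln L over a dense grid on [0, 0.5] (step 0.002; ties resolve to the
smallest ρ), equivalent to the lookup-table formulation but simpler to
reason about; the 95% confidence interval is the Wilks profile set
{ρ : ln L(ρ) ≥ ln L(η) − ½·χ²₀.₉₅,₁}, reported as its min/max and truncated
to [0, 0.5]. Estimates near the boundaries therefore have short intervals
by construction.

Numerical safeguards, each of which matters in practice:

* **SD floor.** σ(ρ) is floored at 5% of its peak over [0, 0.5]. At ρ = 0
  the feature J_min is degenerate (full exclusion makes it exactly 0 for
  almost every pattern), so its fitted SD curve can touch or cross zero;
  an unfloored σ would assign essentially infinite precision to one
  feature near the boundary and distort every subset containing it. The
  floor caps the precision gain of the Gaussian surrogate at twenty-fold.
* **Degenerate correlation.** A constant feature column at a grid point
  makes the Pearson correlation undefined; during training the matrix from
  the nearest non-degenerate grid point is substituted (with a warning).
  Near-singular matrices are repaired by an eigenvalue floor and
  re-normalised to unit diagonal.
* **Weak identifiability of the exponential fit.** On near-linear data the
  family a·e^(−bρ) + c is only jointly identified (a·b fixed while
  |a|, |c| → ∞). The fit is multi-started over decay rates, and fits whose
  residual is within 0.1% of the best are resolved by parsimony (smallest
  |a| + |c|). The J_min asymptote in particular is weakly identified on
  ρ ≤ 0.5 and should be read as a curve, not a parameter.
* **SD fit fallback.** If the exponential SD fit fails to converge, the
  empirical SDs are interpolated piecewise-linearly (warning logged).

## Validation metrics

R² is computed about the identity line ρ = η: R² = 1 − Σ(η−ρ)²/Σ(ρ−ρ̄)²,
so a perfect estimator scores 1, predicting the ensemble mean scores 0,
and negative values are possible and reported. Mean 95% CI width is
averaged per feature subset. The seven subsets of {g_max, F_max, J_min}
are labelled g, F, J, gF, gJ, FJ, gFJ.

## Known limitations

* The pair-correlation edge correction assumes a rectangular window.
* F_max (and hence J's domain) is Monte Carlo noisy at the single-pattern
  level; downstream analyses should carry the recorded reference seed.
* The Gaussian surrogate for the feature distributions is poor exactly at
  ρ = 0 (J_min is a point mass); the SD floor makes the likelihood usable
  there but the resulting intervals at the boundary are approximate.
* The GRF kernel and threshold rule are one concrete realisation of a
  "two-compartment tissue with nest scale l"; other constructions with the
  same chord statistics would shift the absolute feature curves somewhat.
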