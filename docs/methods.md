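# Methods

## The model

Habitat selection is estimated at the scale of 10-minute movement steps.
A step runs between consecutive regularly spaced fixes; each observed step
is matched with available steps drawn from the bird's own *tentative*
movement kernel — a gamma distribution for step length and a von Mises
distribution with mean 0 for turn angle, both fitted by maximum likelihood
to that bird's observed steps. Within each stratum (1 observed + n_avail
available steps) the probability that the observed step was the one taken
is the conditional-logit form exp(x_usedᵀβ)/Σ_j exp(x_jᵀβ), and β is
estimated by maximizing the stratified partial log-likelihood. Covariates
are evaluated at the step's end point: wetland class (treatment-coded
against other tidal) and time-specific water depth (tide height at the
step's end time minus cell elevation, a cell-average quantity on the 10 m
grid). The candidate set holds seven nested models, from wetland-only and
depth-only up to the full wetland × (depth + depth²) interaction, compared
by AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n the number of strata.

Fitting is per bird. Pooled random-effects conditional models are out of
scope; between-bird variation is reported by comparing per-bird estimates.

### Estimation details

* Newton–Raphson with analytic score and observed information,
  step-halving on any likelihood decrease; convergence when the relative
  change in ℓ is < 1e-9 and the maximum |score| < 1e-6; at most 100
  iterations. The covariance is the inverse observed information at the
  optimum. Per-stratum log-sum-exp centering keeps the weights finite for
  any β.
* Separation. Two detectors mark a fit non-converged: (i) any |β̂| > 15
  during iteration (odds ratios beyond e¹⁵ are numerically meaningless
  here), and (ii) a sign-constant design column with zero mass on every
  used step but positive mass among availables — then the likelihood is
  monotone in that coefficient and the MLE is at −∞. Detector (ii) is
  exactly the situation of a bird that never uses shellfish while its
  availability domain contains it; such birds are excluded from pooled
  reporting, as they must be in field data.
* Columns that are constant within every stratum are unidentifiable (the
  partial likelihood is invariant to stratum-constant shifts) and are
  flagged.
* Zero step lengths are replaced by half the minimum positive length
  before the gamma fit; the von Mises concentration solves
  I₁(κ)/I₀(κ) = mean(cos a) by bracketed root-finding, capped at κ = 500
  for near-degenerate samples; κ = 0 is returned when mean(cos a) ≤ 0.
* Depth window. Selection analysis is restricted to depths in [−0.5, 1] m:
  members outside the window are removed; a stratum whose observed member
  leaves the window, or with no surviving available member, is dropped.
  Because the conditional-logit family is closed under restriction of the
  choice set, windowing both sides leaves β estimable without correction.
* Movement adjustment. The behavior model augments the full habitat model
  with step length and ln(step length), each interacted with the wetland
  class at the step's *start*. Beyond describing movement differences,
  these terms absorb misfit of the tentative step-length kernel (which is
  estimated from selection-contaminated observed steps): the gamma family
  is an exponential family in (L, ln L), so the likelihood ratio between
  the true and tentative gamma lies exactly in the span of those columns.
  The analogous correction for the turn-angle kernel is a cos(turn angle)
  column (the von Mises family is exponential in cos a), available as the
  ``angle`` term; the fully adjusted model (habitat + step-length terms +
  cos turn angle) is what parameter-recovery checks read habitat
  coefficients from, the standard de-biasing device in step-selection
  practice. The fitted step-length coefficients also
  yield the selection-corrected kernel per start wetland:
  k′ = k + β_ln(sl), 1/θ′ = 1/θ − β_sl (error if the corrected rate is
  not positive). Turn-angle corrections are deliberately not applied.
* log-RSS. For wetland w at depth d, log-RSS(w, d) = x(w,d)ᵀβ − x(ref,d)ᵀβ
  with pointwise Wald bands from the delta method (c′β ± z √(cᵀΣc)).
  Profile-likelihood bands are not implemented.

### ODBA

Static acceleration per axis is the arithmetic mean over the whole 6-s,
10 Hz burst; ODBA is the sum over the three axes of the summed absolute
deviations from the axis mean — a per-burst total in raw acceleration
units, not a per-sample average. Bursts shorter than the nominal 60
samples are processed but flagged; bursts under 10 samples are rejected.
ODBA records enter the behavior analysis at the native 5-min interval,
filtered by the same daylight/accuracy/speed rules as fixes but *not* by
the depth window.

### The ODBA mixed model

odba ~ wetland with a random intercept per bird, fitted by maximum
likelihood (not REML, because the interest is the fixed effects). The
variance ratio λ = σ²_b/σ²_e is profiled: at fixed λ the GLS fixed
effects and σ̂²_e are closed-form via per-group shrinkage
(I + λJ)⁻¹ = I − λ/(1+n_iλ)·J, so the deviance is one-dimensional in λ
and is minimized on a coarse log-grid (including the λ = 0 boundary)
followed by golden-section refinement. The wetland model is compared to
the intercept-only model by a 3-df likelihood-ratio test.
Per-coefficient profile-likelihood CIs solve
profiled-deviance difference = χ²₁(0.95) by bracketed root-finding, with
a Wald fallback (logged) if a side fails. A single bird, or one
observation per bird (σ²_b and σ²_e confounded), is rejected rather than
silently fitted.

## Environmental engine

* All geometry is assumed pre-projected to one planar metric CRS; the
  package never reprojects. GeoJSON layers declaring a geographic CRS are
  rejected.
* Rasterization assigns each 10 m cell the class covering its center,
  with precedence shellfish > eelgrass > base; eelgrass is buffered by
  5 m, shellfish line features by 1 m, and the merged shellfish shape by a
  further 1 m to close interior gaps.
* The elevation surface takes the DEM at and above 0 m MLLW and the
  bathymetry below (LiDAR does not resolve the submerged bed); vertical
  datums are treated as equal.
* Tide interpolation is shape-preserving piecewise cubic (PCHIP) through
  the hourly knots, exact at knots and never overshooting the bracketing
  knots. Its worst-case half-hour error on a 0.9 m-amplitude semidiurnal
  sinusoid is 0.027 m — two orders below tidal amplitude but larger than a
  non-monotone cubic spline's 0.0015 m; monotonicity was kept because
  overshoot at hourly spacing would create spurious local extremes of the
  depth covariate. Subordinate-station corrections are additive offsets in
  time and height applied to the knots before interpolation (NOAA
  ratio-style corrections are not implemented).
* Daylight is solar elevation ≥ 0° from a standard low-precision solar
  ephemeris at the configured site latitude/longitude (a twilight
  threshold can be configured instead).

## The synthetic generator

The generator is the package's ground truth, emulating a ~1.2 × 1.2 km
tidal embayment at 10 m resolution:

* **Landscape** — a cross-bay elevation ramp (−2.2 to +2.2 m MLLW) with
  smoothed noise and a channel incision; marsh occupies the highest
  elevation band (~21 % of cells), eelgrass forms patches in the low
  intertidal (~36 %), shellfish infrastructure sits in a narrow band
  strictly inside the eelgrass elevation range (~2 %), the rest is
  unvegetated flats (~41 %). Fractions follow the configured targets to
  within a few cells.
* **Tide** — hourly sum of two sinusoids (periods 12.42 h and 25.82 h,
  amplitudes 0.8 and 0.5 m) around a 1.0 m mean: a mixed semidiurnal
  regime whose range spans the intertidal.
* **Movers** — at each 10-min step the end point is drawn *exactly* from
  the continuous target density kernel(s)·exp(x(s)ᵀβ) by rejection
  sampling: proposals come from the current wetland's kernel (truncated at
  its 1−10⁻⁶ quantile radius, ~0.8 km), are rejected off-grid, and are
  accepted with probability exp(score − bound), where the bound is the
  per-class quadratic's maximum over the locally reachable depth interval.
  An earlier softmax-over-K-candidates implementation was replaced because
  its O(1/K) flattening of the choice density biased recovered
  coefficients by several percent even at K = 500.
  Timestamps are confined to daytime windows (48 fixes per day from 16:00
  UTC, June onward at the site's longitude) so the daylight filter is
  exercised but not destructive; accuracy ≈ 3 m and speeds < 1 m s⁻¹ keep
  the other filters clean.
* **Generating truth (defaults)** — kernel gamma(k = 2, θ = 50 m) ×
  von Mises(κ = 0.5); selection β: wetland mains +0.75 (eelgrass), +1.5
  (shellfish), −1.0 (marsh); depth +1.0, depth² −1.0 (optimum 0.5 m on the
  flats); interactions eelgrass +1.1/−2.0, shellfish +0.9/−2.0, marsh
  −1.0/+0.5 — every class's depth optimum sits at wadeable depths
  (0.1–0.5 m), shellfish and eelgrass are the most sharply depth-dependent,
  and the class-specific shapes are strong enough that the full interaction
  model is AICc-identifiable from single birds, the regime the real system
  exhibits. The shellfish main effect is calibrated so converged birds use
  shellfish for a few percent of steps despite its 2 % areal share,
  standing in for the spatial clustering of real aquaculture within
  foraging ranges, which the generator does not model.
* **Bursts** — per fix, 60 tri-axial samples of Gaussian noise around
  random static offsets, scaled so the expected ODBA equals the wetland
  mean (600/750/700/300 raw units for flats/eelgrass/shellfish/marsh) plus
  a per-bird N(0, 80²) offset plus N(0, 200²) burst noise, truncated at 0.
  The exact normal identity E Σ|x−x̄| = 3n·a·√(2(n−1)/(πn)) maps a target
  ODBA to the noise scale a.

What the generator does **not** emulate: GPS position error driving
step-length inflation, home-range or memory behavior, roosting bouts in
marsh, prey fields, spatially clustered aquaculture, or harmonic tidal
structure beyond two constituents. Passing recovery tests therefore show
the estimator is correct under its own model assumptions at realistic
sizes — not that field estimates are unbiased under these unmodelled
features.

## Problem sizes and calibration checks

The recovery experiment simulates 7 birds × 2000 steps per replicate
(≈ 1300 strata per bird after windowing) and re-estimates with
n_avail = 10; in at least 18 of 20 replicates the replicate's pipeline
estimate lies within 3 Monte-Carlo standard deviations of every
generating coefficient and the full model wins the per-replicate
summed-AICc comparison, while roughly a fifth to a quarter of bird-fits
end in separation and are excluded — the same phenomenon (and similar
proportion) as the field study's excluded birds. Diagnostics behind this
design: the per-stratum score of the estimating equation evaluated at the
generating coefficients is mean-zero (checked over ~60 000 strata), and
the rejection sampler's single-step choice law matches a brute-force
discretized target (χ² goodness-of-fit p ≈ 0.74 at 40 000 draws). Type-I error of the 3-df LRT is measured on 500
null replicates of 7 birds × 150 ODBA records (0.03–0.07 at α = 0.05),
and Wald CI coverage on 500 replicates of 200 exchangeable strata
(93–97 %). The acceptance script reruns these at 12 replicates for the
recovery block.

## Known limitations

* Per-bird estimates of rare-class interactions (shellfish × depth²) are
  heavy-tailed at realistic shellfish availability; pooled summaries
  should use the movement-adjusted fits and treat single-bird shellfish
  curves with caution.
* The corrected step-length kernel for shellfish starts is limited by the
  same scarcity (sampling SE ≈ 20 % of the mean at 2000 strata).
* Wald RSS bands, not profile; additive (not ratio) subordinate-station
  tide corrections; no datum transformations.
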