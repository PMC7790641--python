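# Methods

## The model

A community at sampling point *i* is the set of herbivore species whose
ranges cover it. Each species carries an ordinal hypsodonty score
h ∈ {1, 2, 3} (brachydont, mesodont, hypsodont; hypselodont taxa are
scored 3). The community metrics are the arithmetic mean *x_i* and sample
standard deviation *s_i* of member scores, one occurrence per species.
The response is *y_i* = ln(annual precipitation in mm); the natural-log
transform symmetrizes the right-skewed precipitation distribution.
Communities with fewer than five scored species are excluded before any
fitting — small assemblages give unstable trait moments — and every
exclusion is counted in a filter report.

Sample SD uses the n−1 denominator. This is a deliberate choice where
either convention is defensible: communities are treated as samples of the
regional species pool, and n−1 matches mainstream statistical defaults.
With ordinal scores in {1,2,3}, x ∈ [1, 3] and s ∈ [0, √(n/(n−1))];
both bounds are asserted as property tests.

## The four estimators

**Linear.** OLS of *y* on *x* with intercept. The slope standard error is
retained for parameter-recovery checks. Constant *x* is an error
(undefined slope), not a degenerate fit.

**Cubic polynomial.** Degree-3 OLS of *y* on *x*. The normal equations on
raw powers of x ∈ [1,3] are poorly conditioned, so the fit runs on numpy's
scaled domain ([-1, 1]) and coefficients are converted back to the raw
power basis for reporting; both bases are serialized. The degree is fixed
at three — the model the framework compares, not a tuning knob. Because a
cubic on a bounded interval has a floor, the model records its minimum
achievable prediction over the fitted range (computed exactly from the
derivative's real roots plus endpoints, and cross-checked against a
10,000-point grid search in tests): communities more hypsodont than the
argmin cannot receive lower estimates, an intrinsic bias of this method in
arid settings.

**k-nearest neighbor.** `round(0.2 n)` calibration records are drawn
uniformly without replacement (seeded) and stored; a query returns the
unweighted mean *y* of the k = 15 nearest training records by Euclidean
distance. The 20% training fraction and k = 15 are the published
calibration settings of the hypsodonty–precipitation framework and are
kept as defaults, configurable. Distance is computed on *x* only by
default (`mean_only`); a `mean_sd` 2-D space is available. Neighbor search
is a stable argsort, which makes the tie rule part of the contract: ties
at the k-th distance resolve by ascending training-record index. The
estimate is the plain neighbor mean — no distance weighting — the simplest
reading where the method description names none. Anomaly evaluation uses
all calibration points by default (training points included); a
`knn_holdout_only` switch restricts evaluation to the held-out 80%.

**Maximum-likelihood trait-space binning.** Equal-width 25 × 25 bin edges
span [min, max] of calibration *x* and *s*; bins are half-open [lo, hi)
with the last bin closed, so every calibration record lands in exactly one
bin. Each occupied bin stores the most likely precipitation for that trait
composition. The likelihood model is not prescribed by the framework's
description, so the default is the simplest defensible one: member *y*
values are modeled as normal, whose MLE for the location is the member
mean. A `hist_mode` switch instead returns the center of the fullest cell
of a 10-bin histogram of member values (degenerate single-value bins
return that value). Queries outside the edge envelope or in an unoccupied
bin return NaN — a typed missing value, not an exception — because
nonanalog communities are an expected outcome that the paleo stage counts
by age class.

## Evaluation

Modern anomalies are observed − estimated log precipitation. For any OLS
fit with intercept evaluated on its own calibration data, the mean anomaly
is identically zero; the suite asserts this to 1e-8 and it anchors the
two-decimal 0.00 means the regression methods report. Correlations are
pairwise-complete Pearson r with two-sided p (missing ML points are
dropped per pair, never imputed; a pair with under 3 complete records or a
constant series is an error). The ANOVA is one-way fixed-effects on
anomaly by method, missing excluded per group, with sums of squares formed
explicitly so that zero within-group variance yields F = ∞ (p = 0)
deterministically and identical group means yield F = 0; p-values come
from the F survival function and are reported at machine precision, never
thresholded. df_between is the number of methods minus one; df_within is
total non-missing anomalies minus the number of methods, so it reflects
method-specific missingness.

## Fossil application

Fossil sites carry their own per-taxon scores; repeated occurrences of a
taxon are collapsed to one before computing metrics, and a site with fewer
than five distinct species fails the inclusion rule. Each site gets four
estimates; ML refusals are counted by age class. The GCM reference for a
glacial site is the average of the two glacial model values, averaged on
the mm scale and then log-transformed (the stated procedure averages
precipitation values; a `log_then_mean` switch is provided), and for an
interglacial site the single interglacial value. Paleo anomalies are
GCM − estimate on the log scale — the reverse of the modern direction —
since the question is whether climate models sit above or below the
faunal estimate. `age_match=force_glacial` compares every site (typically
the interglacial ones) against the glacial reference, the cross-comparison
used to ask whether interglacial faunas look glacial.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
North American biogeography. Species ranges are discs on a planar grid:
the simplest mechanism producing spatially autocorrelated, overlapping
communities analogous to sampling expert range polygons on an equidistant
point grid. Log precipitation is generated from the community mean trait,
`y = intercept + slope·x + N(0, noise_sd)`, which makes the
trait–environment signal exact and parameter recovery sharply testable;
with `noise_sd = 0` the linear estimator must return the generating line
to 1e-8. Defaults, chosen once: 40 × 40 grid (~1,400 retained points after
the richness filter) and 60 species — large enough to populate over a
hundred of the 625 trait-space bins, small enough for seconds-scale
tests; trait probabilities (0.3, 0.3, 0.4) giving mixed communities with a
hypsodont lean; mean range radius 10 cells (mean richness ≈ 11, so the
five-species floor bites but does not dominate); generating intercept
12.25 log mm and slope −3.34 log mm per trait unit — the empirical
modern-calibration line, so synthetic estimates live on a realistic
scale; noise_sd 0.3 log mm, enough to make R² < 1 without drowning the
gradient.

What the generator does **not** emulate: environmental noise is white
(the framework's description gives no trait-independent spatial
autocorrelation of precipitation to copy), ranges are circular and
climate-independent, and there is no megafaunal extinction bias. Passing
tests therefore demonstrate correctness of the computation and the
estimators' contracts, not predictive skill on real rasters.

Fossil sites are resampled whole from calibration communities, which
guarantees in-space sites land in occupied bins under any bin count.
Nonanalog sites (default 9 of 43, with 31 of 43 glacial — the composition
of the real case study) are constructed extreme compositions (uniform
score-1 or score-3 assemblages, balanced 1/3 mixtures) kept only if their
(mean, SD) falls strictly outside the calibration envelope, so the
ML-missing set is exactly the constructed set. Synthetic GCM values derive
from the landscape truth: the model class matching a site's own age class
is generated at the true value (two glacial models ±0.15 log mm apart,
noise SD 0.05), the mismatched class offset by −0.4 log mm. The offset
makes age-matched comparison closer than deliberate mismatching by
construction — a structural analogue of the glacial/interglacial alignment
question, not an empirical claim about it.

## Numerical and interface choices

All randomness flows from one integer seed through named per-stage
substreams (`SeedSequence([seed, stage])`); reruns are byte-identical.
CSV is the interchange format, written with full round-trip float
precision and read back with pandas' round-trip parser; fitted models
serialize to JSON with explicit nulls for unoccupied bins, and a
load-save round trip reproduces predictions bit-identically. Raster point
extraction supports the plain-text ESRI ASCII grid (nearest cell, no
interpolation; out-of-bounds points and nodata cells are errors, never
silently passed through). Unknown species, non-positive precipitation,
conflicting duplicate trait scores, and unclassifiable age classes are
hard errors naming the offending record; nothing is imputed or silently
dropped. Regression and kNN estimators extrapolate beyond the fitted
trait range without error (models record their fitted range so callers
can flag extrapolation); only the ML grid refuses.

## Limitations

The printed-scale headline statistics of the real North American analysis
(anomaly ranges, the correlation matrix values, R² ≈ 0.4) depend on
WorldClim rasters, NatureServe ranges and Paleobiology Database
occurrences that this package deliberately does not download; synthetic
runs reproduce the structure (zero-mean OLS anomalies, positive
inter-method correlations, ANOVA layout, ML coverage failures), not those
values. k = 15 is taken as given rather than re-derived by
cross-validation; regression-tree estimation and spatial-autocorrelation
corrections are out of scope.
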