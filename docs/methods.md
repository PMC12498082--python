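# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a maintainer would need to reproduce results
exactly.

## Species response curves and elevational optima

Occurrence records are Bernoulli observations per (locality, species); the
probability of presence along elevation is modelled with the five classical
HOF shapes, products of logistic terms on elevation standardized to [0, 1]
(standardization conditions the optimizer; all reported quantities are
back-transformed to metres).  The ceiling M is fixed at 1 — with binary
data M is not identifiable jointly with the intercept parameter `a`, which
absorbs prevalence.  The model set stops at the classical five shapes; the
extended shapes some implementations add (bimodal variants) are out of
scope.

Each model is fitted by maximizing the Bernoulli log-likelihood with
analytic gradients and L-BFGS-B from a deterministic grid of starting
points (`a ∈ {−2, 0, 2}`, `b ∈ {±5, ±20}`, `c` mirrored from `a`), plus a
warm start from the best simpler model.  The warm starts guarantee the
maximized log-likelihoods respect the nesting of the hierarchy
(V ≥ IV ≥ II ≥ I and III ≥ II) up to optimizer tolerance, which the test
suite asserts at 1e-6.

**Model choice.**  Among the five fits, the selected model is the one with
the fewest parameters whose AIC lies within 2 units of the minimum
(hierarchy order I → V breaks parameter-count ties; `aic_margin=0` gives
the strict lowest-AIC rule).  The margin matters: under a strict AIC rule a
spurious one-parameter likelihood gain on featureless data exceeds the
penalty with probability P(χ²₁ > 2) ≈ 0.16, so roughly one flat species in
six would be assigned a structured curve.  Two AIC units is the
conventional "equivalent support" band, and the same band is used
everywhere else in the pipeline for near-tie reporting, so model choice and
reporting share one notion of equivalence.

**Optimum.**  Model IV's optimum is the stationarity point
`x* = (c − a)/(2b)`; model V's is a 1-m grid argmax refined by
golden-section; monotone fits (II/III) attain their supremum at a gradient
edge, which is returned with a `boundary` flag; model I has no optimum.
Optima are clipped to the observed span (flagged when clipping occurs).
Range limits are the outermost elevations where the predicted response
falls to `threshold_frac` (default 0.05) of the peak, located by grid scan
plus bisection; the 5% criterion is an assumption of this package — the
literature rarely states one — and is configurable.

Records per species must number at least 30 with both presences and
absences; all-present/all-absent profiles return a flagged flat fit rather
than an error, since they carry no gradient information.

## Phylogenetic regression

The residual covariance across species is σ²·V(λ): V(λ) keeps the Brownian
diagonal of the tree covariance C (C_ij = root-to-MRCA shared path length)
and multiplies off-diagonals by λ.  β̂ is generalized least squares at each
λ; σ² is profiled analytically; λ̂ maximizes the profile likelihood via a
21-point grid plus golden-section refinement in the bracketing interval,
with both endpoints evaluated explicitly so boundary optima are reported as
exactly 0 or 1.  ML (not REML) is used throughout because AIC comparisons
across different fixed-effect sets require ML.  The AIC parameter count k
includes every regression coefficient plus λ and σ², so ΔAIC ledgers are
self-consistent across designs of different size.

R² is defined on the λ̂-whitened scale against the intercept-only GLS at
the *same* λ̂, and adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p the
number of non-intercept coefficients (indicator columns each count).  Other
R² conventions exist for PGLS; published adjusted-R² values computed under
a different convention will differ slightly.

Standard errors are t-based with n − p − 1 error degrees of freedom at the
fitted λ̂; λ uncertainty is not propagated.  At small n (tens of species)
this makes tests on predictors that are themselves strongly phylogenetically
clustered (e.g. a habitat label that splits the tree into two clades)
anti-conservative; the test suite demonstrates calibration for predictors
that are not confounded with tree structure.

Categorical predictors are expanded to reference-coded indicators, the
reference level being the alphabetically first (growth form: `A`, annuals);
coefficients are contrasts against that level.

When the tree is ultrametric (constant diag C), V(λ) shares C's
eigenvectors, so the λ search reuses one eigendecomposition and whitening
is a diagonal rescale; non-ultrametric trees take a Cholesky factorization
per λ.  The two paths are algebraically identical.

## Sequential category selection

Within a category, all 2^m subsets of its predictors are fitted (plus the
carried covariates, which candidate designs never drop), λ re-estimated by
ML in every design.  The winner is the smallest subset (ties broken
lexicographically) within 2 AIC units of the enumeration minimum — the
same equivalence band as above; a predictor that only distinguishes models
of equivalent support has not demonstrated influence on the optimum and is
not carried forward.  The enumeration minimum is reported separately
(`min_aic`) and is what the brute-force oracle test checks.  Growth form
enters and leaves as a single block of indicator columns with one
importance value, because it is one named predictor.

Importance of a selected predictor is the best AIC over *all* enumerated
designs excluding it, minus the minimum AIC (a re-search, not a drop-one
refit; `importance_mode="drop_one"` gives the simpler variant).  Re-search
importance is never negative by construction.  Near-ties (ΔAIC < 2 vs the
minimum) are recorded so traits masked by collinearity remain visible.

Stages run morphology → anatomy → physiology; stage t's covariates are the
union of earlier winners, refitted jointly (their coefficients stay free).
Complete cases are taken per stage over that stage's candidates plus
covariates, so n can differ between stages and is recorded.  The cumulative
adjusted-R² sequence is reported per stage and is not forced monotone.

## Screening, transforms, contrasts

Single-predictor scans fit one PGLS per trait per habitat pool with the
optimum as response.  Right-skewed predictors (sample skewness > 1) are
natural-log transformed when strictly positive, square-root transformed
when nonnegative with zeros; before a log transform, exact zeros are
replaced by half of the second-smallest distinct value.  Every applied
transform and substitution is recorded in the scan output.  The transform
map is configurable per trait (YAML), the heuristic being only a default.

Holm–Bonferroni step-down control is applied within one family per habitat
column (and one for the contrast column): sort p ascending, reject while
p(i) ≤ α/(m − i + 1).  Direction arrows accompany a slope only when its raw
p < α.  Growth form's scan p-value is an overall F-type block test against
the intercept-only model, both models whitened at the *null* model's ML λ;
evaluating F at the full model's λ̂ instead is anti-conservative because
that λ̂ is chosen to flatter the block (measured: raw null rate 0.11
instead of 0.05 at n ≈ 36).

Habitat contrasts default to PGLS of the trait on a steppe/alpine
indicator (a phylogenetic two-group contrast); a Welch two-sample variant
is offered for sensitivity and both label their method in the output.  The
printed P-values of the published 310-species table are frozen in
`elevtrait.screen.PUBLISHED_TABLE` as a worked decision-replay example; "<0.0001"
entries are replayed at their stated bound, which is conservative.

## Phylogenetic PCA

The ordination eigendecomposes the evolutionary covariance: trait
deviations from the GLS ancestral mean, whitened by V(λ̂)⁻¹, with λ̂ fitted
by multivariate ML under a matrix-normal model (R and the ancestral mean
profiled out).  Correlation mode is the default because the variables mix
units (cm, %, ‰, years, m); covariance mode is available and flagged in the
output.  Scores are the (GLS-centered, optionally standardized) data
projected on the eigenvectors; because centering is phylogenetic, the
arithmetic grand mean of the scores is at the origin only when λ̂ = 0.
Component signs follow a fixed convention (largest-magnitude loading made
positive).  Growth-form centroids are passive: plain mean scores per
category on the first two components, computed after the ordination.

## Synthetic data: what it emulates and what it does not

Defaults mirror the emulated survey: 310 species split 169 steppe / 141
alpine, a 2,650–6,150 m gradient, uniform locality elevations (4,062 by
default; the analysis scripts use 2,000 to keep the full chain under a few
minutes), symmetric HOF-IV presence curves with peak probability 0.8 and
400 m half-width at half-maximum, traits evolved at λ = 0.5 with unit
Brownian rate, and trait effects Height −12 m/cm, storage tissue +8 m/%,
δ13C +60 m/‰ over a 300 m optimum noise floor.  The default intercept
(5,950 m) is chosen so the *mean* optimum sits mid-gradient given those
effects and the default trait means — the optimum model is linear in raw
traits, and δ13C is ≈ −27‰ — yielding optima spanning roughly
2,900–5,700 m; custom effect maps should come with a matching intercept.
Out-of-gradient optima are clipped and the affected species logged, never
silently.

Trees are pure-birth (Yule) crown trees rescaled to unit height, hence
ultrametric.  Percent traits are generated on a logit scale, positive
traits on a log scale, so table invariants hold by construction.  Growth
form thresholds a latent Brownian trait at empirical septiles, so the
categories carry phylogenetic signal; the bin→label order is fixed but
arbitrary.  Habitat is assigned by optimum rank so the configured pool
sizes are met exactly (a fixed split elevation is available instead); how
the original survey assigned its pools is not recorded, so this rule is a
stand-in.

Not emulated: spatial autocorrelation among localities, abundance (counts),
climate covariates, detection error, trait measurement error, and
correlated trait evolution (traits are independent deviations on a shared
tree).  Passing recovery tests therefore demonstrates correctness of the
estimators under the generating model, not robustness to these real-data
features.

## Numerical conventions

- Elevations are physical metres throughout; any binning is display-only.
- Species labels are matched exactly after whitespace→underscore
  normalization; no fuzzy matching, and species absent from the tree are a
  validation failure, not grafted.
- One master seed per simulation config; per-stage child seeds derive from
  it via `numpy.random.SeedSequence`, making every output table
  byte-reproducible.
- Probabilities inside HOF likelihoods are clipped to [1e-10, 1−1e-10];
  λ profile tolerance 1e-7; subset/model ties broken by parameter count
  then lexicographic/hierarchy order, deterministically.
- Fit reports carry flags rather than silent fixes (`degenerate`,
  `boundary`, `optimum_at_boundary`, `adj_r2_undefined`, clipping logs).

## Known limitations

- λ uncertainty is not propagated into coefficient tests (see above).
- The HOF stage assumes independent Bernoulli records; localities are
  neither weighted nor binned, and repeat visits would violate the
  assumption.
- Range limits depend on the configurable 5%-of-peak criterion.
- The published table's adjusted-R² staircase cannot be recomputed without
  the original species-level data, which are not deposited in a public
  archive; the pipeline accepts such data as plain CSV/Newick inputs
  should they become available.
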