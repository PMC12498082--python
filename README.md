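# elevtrait

Which functional traits decide how high up a mountain a plant species lives?
`elevtrait` is a Python pipeline for answering that question from two kinds
of field data: floristic presence/absence records along an elevation
gradient, and a species × trait table with a phylogeny.  It was built around
the trait–elevation analysis of the Ladakh (NW Himalaya) flora — 310 herb
and shrub species, 17 morphological / anatomical / physiological traits,
a 2,650–6,150 m gradient split into dry steppe and cold alpine habitat
pools — and is aimed at comparative plant ecologists who want that style of
analysis as tested, scriptable code.

The pipeline has four statistical stages, each exposed as a library module:

1. **Elevational optima** (`elevtrait.hof`).  Each species' occurrence
   probability along elevation is fitted with the Huisman–Olff–Fresco (HOF)
   hierarchy of response curves, built from products of logistic terms
   (`I` flat, `II` monotone, `III` plateau, `IV` symmetric unimodal,
   `V` skewed), e.g. model IV:

   `y(x) = M / [(1 + e^(a+bx)) (1 + e^(c−bx))]`

   fitted by Bernoulli maximum likelihood with multi-start L-BFGS-B.  The
   curve shape is chosen by AIC (simplest model within 2 AIC units of the
   best), and the species' *elevational optimum* is the point of maximum
   response — in closed form `x* = (c − a) / 2b` for model IV.

2. **Phylogenetic regression** (`elevtrait.pgls`).  Interspecific variation
   in optima is modelled by GLS with residual covariance
   `σ² V(λ)`, where `V(λ)` is the Brownian tree covariance with
   off-diagonals scaled by Pagel's λ ∈ [0, 1], and λ is estimated by
   maximum likelihood (golden-section on the profile likelihood with
   explicit endpoint checks).

3. **Sequential trait-category selection** (`elevtrait.selection`).
   Predictors are searched exhaustively *within* each category in order —
   morphology (height, growth form) → anatomy (bark/xylem, longevity,
   mechanical and storage tissue, ring width) → physiology (leaf/root
   nutrients, δ13C, δ15N, carbohydrates) — each stage carrying the previous
   winners as covariates.  A predictor's importance is the AIC penalty when
   it is omitted (re-searched over all subsets without it); subsets within
   ΔAIC < 2 of the best are reported as near-ties.

4. **Screening and ordination** (`elevtrait.screen`, `elevtrait.ppca`).
   Single-predictor PGLS scans per habitat with Holm–Bonferroni family-wise
   control and skewness-driven √/log transforms (zeros replaced by half the
   second-smallest value before logs), phylogenetic two-group habitat
   contrasts, and a phylogenetic PCA of traits plus optima/minima/maxima
   with growth forms passively projected as centroids.

A synthetic-data module (`elevtrait.simulate`) generates Yule phylogenies,
λ-structured traits, true optima with known trait effects, and HOF-IV
occurrence records, so every stage is validated by parameter recovery.

## Worked example

The `analysis/` scripts run the whole chain on a synthetic survey at the
study conditions (310 species, 169 steppe / 141 alpine, 2,000 localities):

```bash
python analysis/01_simulate.py     # tree + traits + occurrences
python analysis/02_optima.py       # HOF fits per species
python analysis/03_screen.py       # Holm scans + habitat contrasts
python analysis/04_selection.py    # sequential category selection
python analysis/05_ppca.py         # phylogenetic PCA
```

`02_optima.py` prints, for the default seed:

```
fitted 310 species; model choices: {'IV': 295, 'V': 12, 'II': 3}
optimum recovery: median |error| 10 m, 90th pct 30 m (310 species ...)
```

— almost every species is assigned a unimodal curve and the estimated
optimum sits within a few metres of the generator's truth.  The selection
stage then prints a per-habitat ledger, e.g. for the steppe pool:

```
[morphology] best subset: Height  (n=169, 4 designs, lambda=0.188, adjR2=41.76%, +41.76%)
    dAIC when Height omitted: 90.28
[anatomy]    best subset: Storage tissue  (... adjR2=54.51%, +12.75%)
[physiology] best subset: LCC, RPC, d13C  (... adjR2=60.11%, +5.60%)
```

reading: plant height alone explains 41.8% of optimum variance (dropping it
costs 90 AIC units), storage tissue adds 12.7 points, and the physiology
stage adds δ13C and root phosphorus — exactly the planted simulation
effects (Height −12 m/cm, storage tissue +8 m/%, δ13C +60 m/‰), with the
near-tie lists showing which correlated traits could stand in for them.

The same stages are available as a CLI
(`elevtrait simulate|optima|select|scan|pca|run`) for use on real CSV/Newick
inputs; `elevtrait run --config pipeline.yaml` executes everything and
stamps each artifact with a config hash.

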