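# Methods

This note documents the models implemented in `floralint`, their
assumptions, the defaults and why, what the synthetic-data generator does
and does not emulate, and the numerical and design choices that were
genuinely open.

## Integration index

For one species, `T` traits measured on `N` individual flowers (all in
mm, strictly positive), the index is the variance of the eigenvalues of
the `T × T` Pearson correlation matrix. Conventions:

- **Sample variance (divisor `T − 1`).** Under this convention perfectly
  collinear traits give `Var(λ) = T` exactly, so "percent of maximum" is
  `100 · INT / T`. The population-variance convention would cap the index
  at `T − 1` instead; it is not offered.
- **Bias correction.** `(T − 1)/N` is subtracted. The exact expectation of
  the raw index for independent Gaussian traits is `T/(N − 1)` (each
  squared off-diagonal correlation has mean `1/(N − 1)`), so the corrected
  index retains a small positive remainder `(T + N − 1)/(N(N − 1))` —
  0.043 at `T = 8, N = 30`, about 15% of the uncorrected bias. The
  correction is applied as conventionally written; the remainder is a
  property of that convention, verified by simulation in the test suite.
  Negative corrected values are reported as-is and flagged, not floored:
  flooring would bias exactly this calibration.
- **Bootstrap.** Percentile CI (2.5/97.5) over `n_boot = 5000` resamples
  of flowers. Resamples that make a trait constant (correlation
  undefined) are redrawn and counted. Species differ "significantly" when
  their 95% CIs do not overlap; both the CI method and this rule are the
  package's choice of convention and are stated in the output.
- Constant trait columns are an error, never silently dropped; `N < 3` or
  `T < 2` are errors.

Divergence statistics: PCA of the pooled individuals on standardized
columns (divisor `N − 1`; each component's sign fixed so its
largest-magnitude loading is positive), one-way ANOVA per trait with
`(k − 1, N_total − k)` df, Bonferroni across the `T` traits
(`min(1, p·T)`), and Tukey HSD letters built by insert-and-absorb with
ties broken by species-label order.

## Composite proboscis length

The per-period visitation rate of a guild is `visits / open_flowers`; the
guild rate `VFᵢ` is by default the **mean of per-period rates over all of
the species' observation periods**, periods without visits contributing
zero. The pooled alternative (`Σ visits / Σ flower-periods`) is available
by flag; the default was chosen because the rate's unit,
visits · flower⁻¹ · period⁻¹, reads as a per-period quantity. The
assemblage rate is `VFₙ = Σ VFᵢ`, which makes
`PLa = Σ PLᵢ VFᵢ / VFₙ` a weighted mean — hence the tested invariants:
`min PLᵢ ≤ PLa ≤ max PLᵢ`, invariance to rescaling all rates, and unit
equivariance in mm. `VFₙ = 0` is an explicit error (PLa undefined), and
guilds with `VFᵢ = 0` stay in the assemblage count but contribute nothing.

## PGLS

Tip covariances: Brownian motion `C_ij = ` shared root-to-MRCA path
length; Pagel's λ multiplies the BM off-diagonals by `λ ∈ [0, 1]`; the
Ornstein–Uhlenbeck structure is the stationary form
`corr_ij = exp(−α d_ij)` with `d_ij` the patristic distance — the
structure behind the standard GLS correlation option in comparative
practice, not the non-stationary rooted variant. Branch lengths are
required input; trees with zero total depth fail positive-definiteness
and are reported as such.

Estimation is ML throughout (one criterion keeps the AIC table coherent
across models with identical fixed effects):

- `b̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` via Cholesky whitening;
  `σ̂² = rᵀV⁻¹r / n`; `logLik = −½[n ln(2πσ̂²) + ln|V| + n]`.
- Standard errors rescale the ML variance by `n/(n − p)`; t tests use
  `n − p` df, **not** reduced for the estimated structural parameter,
  mirroring common comparative-methods practice.
- λ is profiled over `[0, 1]` by bounded scalar search (tolerance 1e-8,
  endpoints checked explicitly); α over `ln α ∈ [−10, 10]`. Boundary
  optima are flagged on the fit, not raised.
- `AIC = −2 logLik + 2(p + 1 + [structural parameter estimated])`. Ties
  under 1e-6 go to the simpler model (BM < PL < OU).
- Residuals numerically at roundoff level (σ̂² below 1e-12 of the
  response scale) mark the fit degenerate rather than producing spurious
  likelihoods.

The integration screen regresses INT on each predictor **alone**
(intercept + one slope) to avoid overparametrizing an 11-species
regression, and reports the non-phylogenetic OLS fit alongside every
PGLS fit rather than guessing a switching rule between the two.

## Piecewise SEM

A path model is a DAG plus unordered correlated-error pairs between
non-adjacent vertices; an edge and a correlated error may not share a
pair. The d-separation basis set takes every vertex pair that is
(a) non-adjacent, (b) not a correlated-error pair and (c) not two
exogenous vertices (exogenous variables are free to covary, the standard
piecewise convention, noted in the log), conditioning on the union of the
two parent sets. The regression response of a claim is the vertex later
in topological order when one descends from the other; otherwise the
vertex with the larger parent-set overlap with the conditioning set, ties
by label. Each claim is tested by PGLS under the evolutionary model
selected for the response's structural equation.

`C = −2 Σ ln pᵢ ~ χ²_{2k}`; a model passes when the global p exceeds 0.05
and no single claim falls below 0.05. `K` counts intercepts, slopes and
one parameter per correlated-error pair — residual variances are not
counted, giving the smallest parameter set consistent with
`AIC = C + 2K`. Correlated errors are assessed as correlations of the
fitted equations' residuals (centred raw values for vertices without an
equation) with a t test, reported separately and never entering `C`.

**Calibration caveat.** Fisher's C treats claim p-values as independent.
Individual claims are exactly calibrated here (uniform p under the true
model; mean C equals 2k in simulation), but when the generative truth has
strong cross-equation residual correlations (ρ = 0.7) the overlapping
claims become dependent and the global test is anticonservative: ~9%
rejection at nominal 5% (50 tips). With independent equation residuals
the measured rate is 5%. This is a property of the method, shared by the
standard piecewise approach; the type-I calibration experiment therefore
uses the independent-residual setting, and results under strong
correlated errors should lean on the per-claim tests.

**Candidate family.** The built-in family sends the pollinator predictor
to every non-empty subset of the three functional modules — accessibility
(corolla tube), efficiency (stigma height), attractiveness (upper lip,
with the lower lip attached by a fixed upper↔lower correlated error) —
crossed with inter-module cascade toggles (tube→stigma, stigma→upper,
tube→upper) and filtered to DAGs in which every module is reachable from
the predictor; the tube↔stigma correlated error is dropped from models
containing a directed tube→stigma edge. This yields 21 distinct valid
models. Reachability matters: it guarantees no module trait is ever
exogenous, so a genuinely missing predictor path always has a testable
claim. A user-supplied family file (`A -> B`, `A ~~ B`, `# name:` blocks)
overrides the built-in family entirely.

Fitting level is species means (one row per tip). Standardized
coefficients are `b · sd(x)/sd(y)` with raw sample sds; R² is the squared
Pearson correlation between fitted and observed values — GLS has no
unique R², so the convention is printed with the report.

## Synthetic data

The generator emulates the study design at its native scale, with ground
truth returned for every quantity:

- **Tree.** Yule (pure birth, unit rate), written directly: lineages
  split uniformly at exponential waiting times, an exponential tail after
  the last split keeps all terminal branches positive, and the crown
  depth is rescaled to 1. Ultrametric and deterministic under the seed.
- **Predictor.** PLa is exp(Brownian motion) min–max rescaled to
  2.45–41.15 mm on the log scale, so every replicate spans the study
  system's 16.8-fold proboscis range while staying positive.
- **Structural equations.** tube = 5 + 0.207·PLa + e₁,
  stigma = 5 + 1.765·PLa + e₂, upper = 5 + 0.232·stigma + e₃,
  lower = 10 + e₄, with residuals Brownian on the tree (λ_true = 1 by
  default, λ-transformable), residual sds (1.5, 3, 2, 3) mm, and planted
  correlations corr(e₁,e₂) = corr(e₃,e₄) = 0.7. The upper–lower
  association is carried entirely by the residual correlation (an
  optional direct lower-on-upper coefficient defaults to 0) so that the
  generating model satisfies its own d-separation claims. The four traits
  outside the causal core evolve as independent lognormal Brownian
  motions at realistic mm scales. Trait means are floored at 0.5 mm
  (counted; rare at the default noise levels).
- **Flowers.** 30 per species, multivariate normal around the species
  mean with sd = cv·mean (cv = 0.08) and an equicorrelation matrix whose
  level rises with log PLa from 0.3 to 0.62 — so percent INT runs from
  roughly 8% to 35% across the pollinator gradient, matching the spread a
  field study of this kind reports. Non-positive draws are redrawn and
  counted.
- **Pollinators.** Five guilds (2.45, 5.6, 7.4, 9.8, 41.15 mm); a
  log-scale Gaussian matching kernel between guild proboscis length and
  the species' planted PLa allocates a total expected rate of 0.5
  visits · flower⁻¹ · period⁻¹; visits are Poisson given 3–12 open
  flowers over 30 periods; 20 specimens per guild, normal with 5% cv,
  truncated positive.

What the generator does **not** emulate: observation-period weather and
phenology structure, pollinator behavioural sequences, measurement error
correlated within observers, non-Gaussian trait distributions, and any
attempt to reproduce the real species' trait values numerically.
Passing recovery tests therefore show the estimators work when their
distributional assumptions hold at field sample sizes — not that the
original field data satisfy those assumptions.

## Experiment sizes

The calibration and recovery experiments (in `floralint.experiments`)
use: 500 independent-trait datasets for the correction calibration;
500 datasets × 50 tips for d-separation type-I; 200 replicates × 100 tips
for path-coefficient recovery; 100 seeds × 100 tips for model recovery
against the 7-model family (the true structure plus six distortions that
keep all modules reachable and neither nest nor d-separate identically to
it). These sizes give Monte-Carlo standard errors comfortably below the
decision margins while keeping a full run of the reproduction script
under a minute on one CPU.

## Known limitations

- OU is the stationary correlation form only; no rooted non-stationary
  OU, no measurement-error models, no Blomberg's K, no multi-predictor
  PGLS screen.
- The piecewise global test inherits Fisher's independence assumption
  (see calibration caveat above).
- Species-level fitting treats species means as exact; an 11-species
  regression has little power against moderate slopes, which is visible
  in the pipeline's screen at preset scale.
- λ is clamped to [0, 1]; estimates at the boundary are flagged rather
  than extended beyond it.
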