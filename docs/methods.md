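# Methods

## The model

`thermalsteps` analyses temperature-dependent habitat selection with a
step-selection function (SSF). The movement path of a GPS-collared animal is
decomposed into *steps* — straight segments between consecutive fixes at a
near-constant interval (8 h by default). Each observed ("used") step is
matched with M available steps (default M = 10) that begin at the same fix
and time but end where the animal *could* have gone, with step lengths and
turning angles drawn from the animal's own movement kernel. One used step
plus its M available steps form a *stratum*.

Selection is modelled by conditional logistic regression (CLR) on the
matched strata: with covariates x measured at each candidate endpoint, the
conditional likelihood is

    L(beta) = prod_s  exp(beta' x_used,s) / sum_{j in s} exp(beta' x_j,s).

Anything constant within a stratum cancels from this ratio. Ambient
temperature is constant within a stratum by construction (it is indexed by
the stratum's shared start time), so it is **never a main effect**; it can
only modulate selection through interactions, which is exactly the
scientific question: does selection for thermal cover strengthen as
temperature rises?

Three model families are compared per population-sex partition:

1. **base** — habitat main effects only (percent canopy, distance to water,
   elevation, solar radiation index);
2. **linear interaction** — a habitat covariate multiplied by temperature;
3. **spline interaction** — the covariate multiplied by each column of a
   natural cubic spline basis of temperature with df = 2 or 3 columns,
   allowing a nonlinear (e.g. saturating or sign-switching) thermal
   response. df is deliberately capped at 3 to keep the nonlinearity from
   overfitting; the cap can be overridden explicitly.

### Natural spline basis

The basis is the standard restricted cubic spline construction: a cubic
B-spline design on df + 1 knots (boundary knots at the 2.5th/97.5th
percentiles of stratum temperatures, interior knots at equally spaced
quantiles), projected onto the null space of the two second-derivative
constraints at the boundary knots, with the intercept column removed. The
basis is linear beyond its boundary knots; evaluation outside them uses the
first-order expansion at the nearest boundary knot, and downstream curve
tables flag such rows as extrapolated. Tests verify the basis spans exactly
the same function space as an independently coded truncated-power natural
basis.

### Inference

The conditional likelihood is concave; `fit_clr` maximizes it by
Newton-Raphson with analytic gradient and Hessian and step-halving,
declaring convergence when max |score| < 1e-8 or the relative log-likelihood
change is below 1e-10 (max 100 iterations). Strata with no within-stratum
covariate variation contribute nothing and are dropped with a logged count.
Complete separation (a covariate whose used value is the strict extreme in
every stratum) gives a monotone likelihood; it is detected, reported, and
the fit is flagged non-converged rather than returning runaway coefficients.

Steps within an animal-summer are serially dependent (each stratum's start
is the previous stratum's used endpoint). Rather than random effects, the
variance is corrected with a GEE-style cluster-robust sandwich,
A⁻¹ B A⁻¹, where A is the observed information and B sums outer products of
within-cluster score sums over *animal-year* clusters. The sandwich is
reliable from roughly 20 independent clusters and comfortable from 30; fits
warn below those marks. No small-sample cluster correction is applied by
default (with ~30 equally sized clusters the G/(G−1) factor moves SEs by
under 2%).

### Model comparison and validation

Fit is compared by the quasi-likelihood under independence criterion,
QIC = −2·loglik + 2·trace(A·V_robust); when the robust and naive covariances
coincide the penalty is exactly 2p and QIC is AIC. Predictive ability is
assessed by leave-one-animal-out cross-validation: refit without one animal,
score every member of its strata by exp(beta'x), pool all scored points into
10 equal-frequency bins, and Spearman-correlate bin rank with the count of
used points per bin (a Boyce-style statistic, invariant to monotone
transforms of the score). The mean correlation over folds (also reported
x100 as a percentage) summarizes each variant; the best model has the
lowest QIC and highest LOOCV, and disagreement between the two rules is
reported, not resolved.

A caveat discovered and documented here: because the bins pool points
across strata, temperature-driven shifts in *whole-stratum* score levels add
between-stratum noise to the statistic. A model whose interaction term is
real but whose time-averaged effect is mimicked by a static main effect can
therefore validate no better than the static model, even while QIC strongly
prefers it. The interaction's predictive value shows cleanly when the
time-averaged effect carries little signal (see the power study below).

## Covariates

* **Percent canopy** (0-100): thermal cover. Nearest-cell sampling, no
  interpolation — canopy is an area summary, and endpoint uncertainty is of
  cell-size order anyway.
* **Distance to water** (m): exact Euclidean distance transform of the
  water mask (cell-center to cell-center), not a chamfer approximation.
* **Elevation** (m), and **slope/aspect** by Horn's eight-neighbour method
  (edge cells use edge replication; any nodata in a 3x3 window voids the
  cell).
* **Solar radiation index** (dimensionless): daily mean, over an
  equinoctial day with unit solar constant, of the cosine of the solar
  incidence angle on the tilted surface, zero when the sun is below the
  flat horizon or behind the surface. Closed form via the equivalent
  rotation (C = cosS·cosL − sinS·sinL·cosA, D = sinS·sinA, incidence =
  sqrt(C²+D²)·cos(h+atan2(D,C))); a flat surface at latitude L gets
  cos(L)/π. Tests verify it against hour-angle quadrature of the raw solar
  geometry to 1e-6. The time-resolved variant is out of scope: nothing
  time-varying is interacted with SRI.
* **Ambient temperature** (°C): attached per stratum at the start-fix time
  (configurable), one value copied to all members.

Covariates are standardized by **dividing by twice their SD** computed over
all rows (used and available pooled — the only choice that puts both halves
of the design on one scale). Centering is off by default: the rule is a pure
division, and an additive shift would cancel from the conditional likelihood
anyway. Pairs with Pearson |r| > 0.70 are screened; an explicit priority
order (canopy > distance-to-water > elevation > SRI, reflecting their
ecological primacy for thermoregulation) decides which member survives, and
a conflicted covariate missing from the order is an error, never a silent
guess. Since Pearson r is scale-invariant, screening before or after
standardization is equivalent.

## The synthetic study system

Real moose telemetry of this kind is access-restricted, so the package
ships a generator with known truth instead of data.

* **Landscape**: Gaussian-smoothed white noise fields (smoothing scale 4
  pixels, 30 m cells). Canopy is a logistic rescale to [0, 100] (mean 40%),
  water an independent field thresholded at the quantile matching the
  target water fraction (5%), elevation a third field scaled to 120 m
  relief. Stationary, isotropic, tunable autocorrelation — and nothing
  else; no geographic realism is claimed.
* **Temperature**: one regional series shared by all animals (emulating a
  gridded reanalysis product): mean 13 °C, 24-h sinusoid of amplitude 6 °C,
  Gaussian noise SD 2.5 °C — a plausible boreal summer at 8-h fixes.
* **Movement and selection**: a correlated random walk with gamma step
  lengths (shape 1.8, scale 220 m) and von Mises turning angles (κ = 0.6).
  At each step, `n_candidates` = 50 endpoints are proposed from that kernel
  and one is chosen with probability ∝ exp(beta'x) — the generative inverse
  of the SSF. Proposals leaving the raster are redrawn (the analogue of
  study-area containment); with 50 candidates the chosen endpoint's
  distribution approximates the continuous SSF density to O(1/K).
* **True coefficients** (on the generator scale: each covariate divided by
  twice its landscape SD): canopy −0.7, distance-to-water −0.5, elevation
  +0.3, SRI −0.3, plus canopy x spline(temperature, df=2) terms (+2.5,
  −1.5). This reproduces the sign structure characteristic of thermal SSFs
  in heat-sensitive ungulates: a negative static canopy term with positive
  warm-end spline terms, i.e. canopy is avoided when cool and sought when
  hot.

What the generator does *not* emulate — GPS error, fix failure, habitat-
dependent movement speed, inter-animal interaction, temperature gradients
across the landscape — bounds what green tests mean: they validate the
estimator and pipeline logic under the stated model, not robustness to
field-data pathologies.

## Simulation studies (`thermalsteps.experiments`)

Problem sizes were chosen to make Monte-Carlo noise small relative to the
effects measured while staying desk-scale; all are deterministic functions
of their seed.

* **CLR oracle** (25 instances, ≤ 2 parameters, ≤ 5 strata): Newton fit vs.
  exhaustive shrinking-grid maximization of an independently coded
  likelihood; agreement is ~1e-6, asserted < 1e-4.
* **Recovery** (200 replicates of 30 animals x 150 steps, M = 10, 600x600
  world): refits the generating spline model and measures per-coefficient
  relative bias (< 10% asserted; observed ≲ 5%) and robust-Wald 95% CI
  coverage (asserted within [90, 98]%). Two deliberate design choices make
  this a clean test of the *estimator*: availability is drawn from the
  generator's own movement-kernel family, and coefficients are compared on
  the generator's scale (its divisors and spline knots), so kernel
  estimation error and scale re-estimation cannot masquerade as estimator
  bias. The large world keeps boundary trimming of strata below ~6%.
* **QIC behaviour** (50 replicates per scenario, 12 animals x 80 steps):
  under a strong three-segment thermal response the generating spline(df=3)
  variant should attain the lowest QIC (≥ 80% asserted). The interaction
  scenario is given genuine df=3 structure because when the truth is df=2,
  the df=3 variant wins small-margin ties at the irreducible ~16% rate of
  one-extra-parameter noise (P(chi²₁ > 2)) — a property of AIC-type rules,
  not of this implementation. Under a no-interaction truth the base model
  stays within 2p of the minimum QIC (≥ 80% asserted).
* **LOOCV behaviour**: null calibration (all-zero selection, 50 folds,
  |mean rho| ≤ 0.15) and power (30 replicates, 10 animals): the spline
  variant out-validates the base model when the interaction carries the
  predictive signal (canopy main effect set to cancel the mean thermal
  response; see the pooling caveat above). Asserted ≥ 70%, observed ~97%.
* **Pipeline determinism**: the packaged fixture (8 animals, 150x150 world,
  120 steps each, two populations x two sexes) is generated and analysed
  twice under one seed; all CSVs must be byte-identical and stage counts
  must reconcile (strata = annotated + dropped). The fixture's movement
  scale (gamma 1.6 x 110 m) is kept small relative to its 4.5 km world so
  tracks rarely meet the boundary. The fixture is regenerated from its
  recorded seed rather than stored; regeneration is itself a tested
  contract.

The fixture partitions hold only two animals each, so the demo outputs in
`analysis/` are illustrative; the statistically validated claims are the
experiment studies above.

## Numerical and degenerate-input choices

* Random streams derive from `numpy.random.SeedSequence` with fixed tags;
  per-animal and per-partition substreams mean adding an animal never
  perturbs another's draws.
* Angles are mathematical (CCW-positive, atan2(dy, dx)), wrapped to
  (−π, π]; turning angles are undefined for the first step of a burst and
  such steps anchor no stratum. Inputs must be projected; coordinates that
  fit in degree ranges are rejected.
* Fix aggregation is greedy forward thinning: keep a fix when its gap from
  the last kept fix reaches target·(1−tol); a gap above target·(1+tol)
  starts a new burst (tol = 0.25 keeps "near 8 h").
* Movement kernels are per-animal; raw resampling (lengths and angles
  independent) is the default, a parametric gamma/von Mises option exists.
  Fewer than 20 usable steps is an error naming the animal.
* A stratum with any member off any raster is dropped whole (counted),
  keeping the table fully annotated.
* Standardization uses the sample SD (ddof = 1). A constant covariate is an
  error naming the column.
* Spearman values within 1e-12 of ±1 are snapped to ±1 (a perfectly
  monotone rank profile is exactly ±1; only float fuzz says otherwise).
* Wald p-values are two-sided normal.

## Known limitations

* The conditional likelihood treats availability draws as exact; kernel
  misspecification on real data (e.g. selection-contaminated empirical
  kernels) biases coefficients slightly toward zero — visible as the ~2-5%
  attenuation in the recovery study when availability is re-estimated.
* The pooled-bin LOOCV statistic undervalues interaction models whose
  time-averaged effect is mimicked by a main effect (discussed above).
* No GPS-error filtering, no mixed-effects SSF, no time-varying
  coefficients, no map rendering or data-download clients.
* The SRI is the daily-average equinoctial form; absolute values are on a
  unit-solar-constant scale and only relative contrasts are meaningful.
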