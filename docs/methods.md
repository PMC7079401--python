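# Methods

`stressproc` implements a stress-process analysis of antenatal depression
screening data: psychometric scoring, descriptive contingency analysis,
cluster-aware variable screening, and a covariance-structure (SEM) stage
that decomposes the standardized effect of each stressor on a latent
depression factor into direct and mediated components.  Because the kind
of survey it targets rarely deposits raw records, the package also ships a
calibrated synthetic-cohort generator so that every stage is exercised and
tested end to end.

## The model

Participants are pregnant women in their second or third trimester,
sampled within kebeles (urban districts).  The stress-process framework
(Pearlin) orders the variables causally:

* **Stressors** (exogenous, binary): adequate food access, unplanned
  pregnancy, fear of giving birth, history of a common mental disorder.
  They are freely correlated.
* **Mediating resources** (observed ordinal scores treated as
  continuous): marital agreement (1–4), partner support (1–5) and social
  support (OSSS-3 total, 3–14), arranged as a chain
  marital agreement → partner support → social support, each fed by
  selected stressors.
* **Outcome**: a latent depression factor measured by three parcels of
  the ten EPDS items (fixed assignment {1,4,9}, {6,7,8}, {2,3,5,10};
  parcel score = item sum, so parcels always add up to the EPDS total).

In RAM form the model is a directed-path matrix `A` (loadings and
structural coefficients), a symmetric matrix `S` (exogenous covariances
and residual variances) and a filter `F` over observed rows, with implied
covariance `Σ(θ) = F (I−A)⁻¹ S (I−A)⁻ᵀ Fᵀ`.  The packaged default has 10
observed variables, 33 free parameters and 22 degrees of freedom.  The
latent is identified by fixing the first parcel loading to 1; a
fixed-latent-variance rule is available.  The exact mediation topology is
not uniquely recoverable from a published effect table; the default
(social support purely direct; marital agreement and partner support
carrying the indirect mass; food access feeding both marital agreement
and social support) reproduces the published decomposition pattern, and
any alternative recursive topology can be supplied as a YAML model file.

## Estimation and robust fit

Estimation minimizes the normal-theory discrepancy
`F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` by BFGS with an analytic gradient.
Start values are fixed (free loadings 0.5, structural paths 0, variances
at half the sample variances, free covariances at half the sample
covariances) so fits are deterministic.  Convergence requires an
infinity-norm gradient below 1e−3 after an optimization run with target
tolerances 1e−9 (discrepancy change) and 1e−6 (gradient).  Standard
errors invert the numerically differentiated information of
`(n−1)/2·F_ML` (central differences, step 1e−5 per parameter scale).
`χ²_ML = (n−1)·F_ML`, and all indices use the same `(n−1)` convention.
Heywood cases (negative residual variances) are reported on the fit, not
constrained away; a bound-constrained L-BFGS-B retry is available.

Ordinal Likert items make the parcels non-normal, so the test of fit uses
the Satorra–Bentler scaling: with `Γ̂` the fourth-order moment matrix of
the centered second moments, `W = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D`, and
`U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW`, the factor is `c = tr(UΓ̂)/df` and
`χ²_SB = χ²_ML / c`.  Under multivariate normality `c → 1`; the test
suite checks this limit, a closed-form two-variable case, and that the
scaled test's type-I error stays near nominal over 200 normal replicates.

Fit indices: RMSEA `√(max(χ²−df,0)/(df(n−1)))`, CFI and TLI against the
independence baseline (all covariances fixed 0), SRMR in the correlation
metric including the diagonal, and a determinant-based coefficient of
determination over the endogenous observed block.  Because published
reports often leave unstated whether indices are scaled, both ML and
SB-scaled variants are emitted (`*_sb`).

Standardization multiplies each coefficient by the implied SD of its
source over that of its target.  For a recursive standardized structural
matrix `B`, total effects are `(I−B)⁻¹ − I` (the finite path-product
sum), direct effects are the entries of `B` into the outcome, indirect
effects the difference; `total = direct + indirect` is an identity, and
standard errors come from a first-order delta method through a
numerically differentiated effect map.

## Scales

EPDS items are scored 0–3 toward distress (the CSV reader can apply the
standard direction key, items 3 and 5–10 reversed).  Totals of 12–16
screen positive ("possible depression"); 17+ triggers exclusion from
analysis with referral; a total of 13+ or any endorsement of the
self-harm item triggers referral.  The analysis cutoff (12) and referral
threshold (13) are deliberately separate settings because the source
protocol uses both.  OSSS-3 totals 3–14 with "poor" support below 9.
PCI-4 totals 0–12 with no cutoff.  The MUAC rule set preserves the
published labels verbatim ("printed": 18–22 normal, 22.5–31 underweight)
behind a named, swappable table because those labels invert common field
practice; values in (22, 22.5) are unassigned by the printed rule and
classify as out of range.  Cronbach's alpha uses population
(divide-by-n) variances throughout so oracle tests match exactly.

Missing item responses reject the record: the analysis is complete-case
by design and no imputation is attempted.

## Descriptive and screening stages

Contingency tables use Pearson's chi-square without continuity
correction, switching to an exact conditional (Fisher) test whenever any
expected cell count is below 5 — the rule the descriptive tables state.
The exact test enumerates 2×c tables under the fixed-margins
multivariate hypergeometric null and sums the probabilities of tables no
more probable than the observed one (tie tolerance 1e−12); larger tables
signal fallback to Pearson.  Prevalence uses the Clopper–Pearson exact
interval (beta-quantile form), which reproduces printed intervals where
the normal approximation does not.  The two-proportion sample-size
helper implements the Fleiss formula with continuity correction and
unequal allocation, with the effect interpretable as a risk ratio
(default) or an absolute difference, plus a separate attrition-inflation
helper.

Variable screening fits linear random-intercept models by maximum
likelihood (not REML, since fixed effects are compared): for a given
variance ratio the GLS coefficients and residual variance are closed
form, leaving a one-dimensional profiled likelihood optimized by bounded
search, with the boundary (zero cluster variance, i.e. OLS) checked
explicitly.  Wald normal p-values are used with no small-sample df
correction.  The screening outcome is the continuous EPDS score
(configurable); a two-stage rule keeps candidates at bivariate p < 0.05
and reports those still below 0.05 in one multivariable model.  The
protocol's wording gestures at odds ratios, but the model it names is
linear mixed-effects; the linear model is what is implemented.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
records.  Per subject it draws, in causal order: a kebele and its
intercept; four correlated stressors by thresholding a latent normal at
the printed marginal prevalences (food difficulty 4.2%, untimed 13.4%,
unintended 1.8%, fear of birth 21.3%, CMD history 6.9%; latent
exchangeable correlation 0.15); mediator propensities as linear functions
of the standardized upstream variables plus Gaussian noise, discretized
at the quantile cut-points of the printed category marginals; the latent
depression propensity from the structural equation; ten EPDS items (and
three OSSS items) by thresholding loading-weighted propensities; and
independent sociodemographic covariates matching the descriptive-table
marginals.  All draws flow through one seeded PCG64 stream.

Calibration has two layers, both frozen into the packaged defaults and
reproducible with `scripts/calibrate_generator.py`:

* `structural_paths` solves the inverse decomposition problem so the
  implied direct/indirect/total effects equal the published table (the
  underdetermined food-access split resolved toward the minimum-norm
  solution).
* `generator_paths` are the simulation-scale coefficients.  Discretizing
  a mediator attenuates every fitted coefficient into it, so the
  generator coefficients are iteratively adjusted until *fitting the
  model to large generated cohorts* returns the standardized targets;
  residual noise SDs are re-solved each pass to keep propensities
  unit-variance.  The latent's residual variance follows from the
  unit-variance constraint given the calibrated explained variance
  (≈0.36, consistent with the reported R² ≈ 0.35), with the cluster
  variance inside the budget.
* EPDS thresholds and loadings are solved semi-analytically (exact
  conditional convolution of the item-total distribution over a quantile
  grid of the latent) so that P(total ≥ 12) = 0.069 and alpha = 0.74 on
  the generated cohort, with the median total at 4.

Two deliberate design choices matter for interpretation.  First, the six
kebele effects are a fixed quantile profile of the configured SD (0.1),
randomly permuted across kebeles: with so few clusters a fresh normal
draw would shift each cohort's latent location and spread, moving tail
rates (the screening prevalence) by several times the subject-level
noise; the quantile profile keeps the marginal mixture identical across
seeds while preserving within-cohort clustering for the screening stage.
Second, the 6.9% target is applied to the EPDS ≥ 12 rate of the full
generated cohort; the source survey reports 6.9% as the 12–16 share of
its post-exclusion sample, and the two readings cannot hold at once
(its own pre-exclusion counts imply a ≥12 rate above 9%).  The full-cohort
reading is the one the generator is calibrated to.

What the generator does *not* emulate: the covariates are independent of
the stress process (real education or income gradients in depression are
absent), all EPDS items share one threshold set (so the self-harm item is
endorsed as often as any other, inflating the referral count relative to
a real clinic), the stressor cross-correlations are a modeling choice
(only marginals are printed), and there is no missing-data mechanism.
Passing tests therefore show the pipeline recovers a known generating
process of the right shape — not that it would be unbiased on the
original records.

## Problem sizes used by the checks

The packaged checks run at the study's own scale where that is cheap and
at reduced scale elsewhere: parameter recovery uses 100 replicates of
n = 916 (a single fit takes ~50 ms); robust-statistic calibration uses
200 normal replicates at n = 916 and a single n = 5,000 sample for the
normal-theory limit; the generator's measurement targets are checked on
one cohort of n = 50,000 against the binomial sampling band.

## Known limitations

* Mediators are modeled as continuous observed scores; no
  polychoric/WLSMV estimation for ordinal indicators.
* One latent variable; no multi-group, longitudinal or missing-data SEM.
* The exact final path topology of the source analysis is not printed;
  the default is one member of the equivalence class consistent with the
  published decomposition.
* The published sample-size figure (n = 809) is not reproducible from
  its stated inputs under any reading of the effect ("difference of
  1.5"); the Fleiss implementation is validated against an independent
  power calculation instead.
* Several printed descriptive p-values are not reproducible from their
  own printed counts; the test suite validates the test statistics
  against enumeration and closed-form oracles, not against those values.
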