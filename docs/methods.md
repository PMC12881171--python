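# Methods

This note documents the statistical procedures implemented in `agelaw`,
the defaults and conventions chosen where the design was genuinely open,
and what the synthetic-data checks do and do not establish.

## Data model and filtering

An observation is one registry × age-bin cell: incidence per 100,000
person-years, optionally with the raw case count and person-years. Bins
are closed-open exact-age intervals `[lower, upper)`; the regression
abscissa is always the bin midpoint `(lower+upper)/2`, with no within-bin
integration. The "dataset-1-like" adult grid used throughout the tests is
`[25,30) … [55,60)` (midpoints 27.5 … 57.5 years).

Before any fit, three inclusion rules apply (each can be toggled):

- adult-only: drop bins whose lower bound is below 18 years (a bin
  straddling 18 is dropped — the conservative reading);
- non-zero incidence: a zero rate is a finite-sampling artefact that maps
  to −∞ on the log scale;
- bounded bins only: an open-ended "80+" group has no midpoint.

Pooling registries requires an identical bin grid and sums cases and
person-years per bin, recomputing the rate. When only extracted rates are
available, a person-years-weighted mean (or, with an explicit override, a
plain mean) is allowed and marked approximate in the provenance.

## Curve fits

All fits are unweighted OLS of `ln(incidence)` (natural log; base-10 is
display only and leaves every R² unchanged) on `ln t` (log-log / power
law) or `t` (semi-log / exponential), optionally with a squared term to
probe curvature. Multi-registry, non-pooled data are stacked into one
unweighted point set; registry structure is handled only by the
hierarchical models. The reported Gaussian log-likelihood uses the ML
variance `rss/n`, so that `exp(Δloglik)` between two fits of the same
response equals `((1−R²₀)/(1−R²₁))^(n/2)` exactly. Degenerate responses
(zero variance of `ln I`) define R² = 0 and skip curvature
classification. Reported R² values round half away from zero.

The curvature verdict comes from the sign of the fitted quadratic
coefficient, with "linear" declared when its magnitude is below 1e−8 or
when dropping it changes R² by less than 1e−4.

Leave-one-out R² is `1 − PRESS/TSS` with each point predicted by the fit
on the remaining points; it needs `degree + 2` points (the minimal
subfits are then exact interpolants).

Fit results also carry classical and HC3 heteroscedasticity-consistent
standard errors. Recovery checks against the generator use the HC3
interval: Poisson noise on log-incidence has variance ≈ 1/cases, which
varies by an order of magnitude across adult bins, and the classical
homoscedastic interval undercovers (~89% instead of 95%) in exactly that
regime.

## Bayes factors

The encompassing model is `ln I = β₁ t + β₂ ln t + β₃ + ε`,
`ε ~ N(0, σ²)`. H1 (exponential) keeps `t`, H0 (power law) keeps `ln t`;
with a uniform model prior over the two single-predictor models the
posterior odds equal the Bayes factor, computed as the ratio of the two
against-null JZS factors.

For a p-predictor sub-model vs the intercept-only null under the
Zellner–Siow setup (Cauchy, scale r, on standardized coefficients;
Jeffreys on σ²):

    BF = E_g[ (1+g)^((n−1−p)/2) · (1+g(1−R²))^(−(n−1)/2) ],
    g ~ InverseGamma(1/2, n r²/2).

The expectation is computed by adaptive quadrature on u = ln g over
[−300, 300] at relative tolerance 1e−8; an independent Monte-Carlo
estimator over the same mixture acts as the numerical oracle (agreement
well under 1%). The formula depends on the data only through R², which
makes the factor invariant to affine rescaling of the response and
positive rescaling of the predictor; explicit standardization is
therefore unnecessary and not performed. The default scale is 0.354; the
robustness sweep covers {0.01, 0.354, 1, 10, 10³, 10⁵}.

The ML-ratio approximation `exp(loglik₁ − loglik₀)` is reported alongside
as the flat-prior reference. Note the exact wide-scale limit of the JZS
*ratio* is `((1−R²₀)/(1−R²₁))^((n−1)/2)` — exponent (n−1)/2, not the ML
ratio's n/2 — so the JZS factor approaches the ML ratio from below and
the ML ratio overstates the evidence, most visibly at small n.

Evidence grades follow the standard scale (anecdotal < 3 ≤ moderate < 10
≤ strong < 30 ≤ very strong < 100 ≤ extreme, boundaries taking the lower
category, values < 1 graded on the reciprocal). A perfect semi-log fit
yields an infinite factor, returned flagged rather than raised.

## Hierarchical models

The mixed models add registry-level random intercepts and slopes (on the
same abscissa as the fixed slope) with an unstructured 2×2 covariance,
estimated by full ML — never REML — so log-likelihoods are comparable
across the two abscissa transforms; their likelihood ratio is the
hierarchical Bayes factor. Estimation is delegated to statsmodels
`MixedLM` with optimizer fallbacks (lbfgs → bfgs → powell, best
log-likelihood kept). The abscissa is centered internally (random
intercept/slope designs on raw adult ages are badly conditioned); the
maximized likelihood is invariant under this reparametrization and fixed
effects are reported on the original axis.

Random-effect predictions (BLUPs) are computed directly from the
estimated covariance; a covariance at the boundary (between-registry
variance ≈ 0 is legitimate) is floored to the nearest positive-definite
matrix and the fit flagged degenerate instead of failing. The
hierarchical R² is *conditional*: the squared correlation between
observed and fitted `ln I` including predicted random effects — a
declared choice, since several hierarchical R² definitions exist.
Hierarchical LOO refits without each point and re-predicts that
registry's random effects from its remaining points; a registry reduced
below two points falls back to fixed effects only.

## Acceleration window and sensitivity

Both candidate curves have positive first and second derivatives, so the
comparison is fair only where incidence accelerates. The window starts at
the youngest retained bin and extends while the second divided difference
of incidence (linear scale, bin midpoints; divided differences handle
non-uniform grids) is strictly positive; an exactly-zero difference
terminates the window (conservative: avoids inflating the exponential's
advantage). No smoothing is applied by default — pooling is the intended
smoother — with an optional 3-point median filter for noisy single
registries. The reported bound is the **upper edge** of the last included
bin (the within-bin location of the change is unidentified; the edge is
the defensible outer statement). Sensitivity scans recompute ΔR²
(semi-log minus log-log) over nested windows, lowering the final age or
raising the initial age, with a 4-point minimum per window.

## Synthetic data

The generator emulates multi-registry, age-binned rates with Poisson
sampling noise: per bin, `cases ~ Poisson(I(midpoint)/10⁵ ·
person_years)` under the rare-disease approximation (no depletion), with
incidence recomputed from sampled counts. Defaults are calibrated to the
motivating setting: b = 0.117/yr, amplitude a_e = 0.032 per 10⁵, five
registries at 2×10⁶ person-years per 5-year bin → ≈6,000 expected pooled
cases on the adult grid; the power-law default (k = 5, a_m ≈ 2×10⁻⁶) is
calibrated to the same case total. Between-registry heterogeneity applies
jointly Gaussian offsets to the log-intercept and to the slope of the
truth family's own linear scale (b, or k−1), mirroring the hierarchical
model structure; for the multistep family only intercept heterogeneity is
defined.

The mechanistic cohort simulator draws each onset age as the sum of k
independent exponential waiting times and bins onsets over exact
person-years at risk (censoring at onset). Its expected hazard is the
hypoexponential hazard, computed in `expected_incidence` via a matrix
exponential of the transient-state generator (no special-casing of
repeated rates); the Erlang closed form serves as an independent oracle
in tests.

What the generator does **not** emulate: cohort/period effects, competing
mortality, registry quality differences, graphical-extraction error, and
incidence decline at the highest ages (peak-shaped fixtures for the
window diagnostics are constructed explicitly). Passing tests therefore
demonstrate correctness of the machinery under the stated sampling model,
not robustness to those real-data features.

## Problem sizes and numerical choices in the test suite

Simulation-based checks use: 100 replicates for slope-recovery coverage
(95% HC3 interval, ≥93/100 expected), 200 replicates per truth for
model-selection direction at the ≈6,000-case design, 10⁷ Monte-Carlo
draws × 20 instances for the JZS oracle, 10⁵ onsets for the
Kolmogorov–Smirnov check of the Erlang onset distribution, and 10⁷
subjects for the mechanistic cohort. Mixed-model recovery properties use
30–50 replicates of 9–20 registries. Quadrature tolerance is 1e−8
(relative); likelihood-ratio form agreement is enforced at 1e−8;
fractional-polynomial likelihood ties (within 1e−10) break toward the
smaller |x| with a warning.

## Known limitations

- The Armitage–Doll power-law slope k−1 is exact only in the limit of
  vanishing cumulative risk. Over ages 27–57 the log-log slope of the
  k-step equal-rate hazard is ≈ (k−1) − λ·⟨dt/d ln t⟩ ≈ 5 − 40λ for
  k = 6, so any step rate large enough to produce appreciable case counts
  in a finite cohort also visibly depresses the slope: at λ = 0.01/yr a
  10⁷-subject cohort yields only a few hundred onsets and a slope
  centred near 4.7 with Monte-Carlo spread ≈0.6. A simulated cohort of
  realistic size therefore cannot pin the slope at 5 ± 0.2; the analytic
  expected-hazard check at λ = 0.002/yr (slope 4.92, fractional-polynomial
  optimum 0.0) is the attainable statement of mechanistic consistency.
- The JZS quadrature assumes R² < 1; exact fits return flagged infinities.
- Unweighted OLS ignores the differing precision of bins (by design, to
  mirror the simple-regression convention); Poisson-likelihood GLMs and
  case-count weighting are deliberate non-goals.
- The hierarchical optimizer can flag non-convergence on near-degenerate
  random-effects structures; results carry `converged`/`degenerate` flags
  rather than silently failing.
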