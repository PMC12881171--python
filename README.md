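# agelaw

Does an age-specific incidence curve rise as a **power law** — the
signature predicted by the Armitage–Doll multistep model of pathogenesis —
or as an **exponential function**, which is associated with continuous
accumulation of damage and is incompatible with that model?

`agelaw` is a Python library for epidemiologists and modellers who want to
ask that question rigorously of registry data (or of simulated data). It
was built around the ALS/cancer use case — multi-registry, age-binned
incidence per 100,000 person-years — but nothing in it is disease-specific.

## The comparison

Two curves of equal complexity are pitted against each other:

- power law: `I(t) = a_m · t^(k−1)`, linear in log-log coordinates,
  `ln I = ln a_m + (k−1) ln t`; under the Armitage–Doll model `k` is the
  number of rare, irreversible, ordered pathogenic steps;
- exponential: `I(t) = a_e · e^(b·t)`, linear in semi-log coordinates,
  `ln I = ln a_e + b·t`, with `b` the per-year acceleration rate.

The machinery:

- **OLS fits** of `ln I` on `ln t` and on `t` (plus quadratic curvature
  probes and leave-one-out cross-validation);
- **Bayes factors** from the encompassing regression
  `ln I = β₁ t + β₂ ln t + β₃ + ε`: the Jeffreys–Zellner–Siow prior
  (Cauchy scale 0.354 on the standardized slope, Jeffreys on σ²) gives
  `BF₁₀ = BF(t vs null) / BF(ln t vs null)` by one-dimensional quadrature
  over the g-mixture, with a prior-scale robustness sweep and the
  maximum-likelihood-ratio `((1−R²₀)/(1−R²₁))^(n/2)` as the wide-prior
  reference;
- **fractional polynomials** `ln I = β̃₁ t^(x) + β̃₂` for x ∈ [−2, 2]
  (x = 0 meaning ln t): the best exponent is ~0 for a power law, ~1 for an
  exponential;
- **hierarchical mixed-effects models** with registry-level random
  intercepts and slopes on never-pooled data, compared by ML likelihood
  ratio;
- **acceleration diagnostics**: both candidate curves accelerate with age,
  so the comparison is restricted to the leading age window with positive
  second differences of incidence; sensitivity scans vary the window
  bounds;
- a **synthetic-data generator** (Poisson registry sampling with optional
  between-registry heterogeneity) and a **mechanistic multistep cohort
  simulator** (onset age = sum of k exponential waiting times, exact
  person-years at risk), so every stage is testable without any external
  data.

## Worked example

`examples/06_full_pipeline.py` simulates five heterogeneous registries
under an exponential truth (b = 0.117/yr, ≈6,000 pooled cases), pools
them, picks the acceleration window and runs every comparison:

```
acceleration window: ages < 60 (7 bins)
R^2 log-log  = 0.993
R^2 semi-log = 0.995
Delta R^2    = +0.0025
JZS BF10     = 2.28 [anecdotal]
ML-ratio BF10= 4.28
fracpoly x_opt = +0.6
hierarchical BF10 = 3.48
```

Read: both curves fit well (R² > 0.99 — expected, the two shapes are
visually close), but the semi-log fit is consistently better; every Bayes
factor is above 1, i.e. the evidence points at the exponential, as it
should for this generating truth. At a single ~6,000-case design the
evidence per replicate is modest (anecdotal-to-moderate); it concentrates
with more points and more registries. The other `examples/` scripts show
each capability in isolation (fits, Bayes factors, fractional polynomials,
hierarchical models, the multistep cohort).

A thin CLI mirrors the library: `agelaw simulate|fit|compare|hier|
sensitivity|run` (see `agelaw --help`).

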