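# Methods

`oncorisk` implements, end to end, the statistical workflow used to validate
a QRISK3-style 10-year cardiovascular risk score in 1-year cancer survivors
and to test whether cancer-survivorship variables qualify for inclusion in
such a score.  Because the linked primary-care/hospital/registry data behind
the original analysis are not publicly available, the package pairs the
analysis machinery with a synthetic matched-cohort generator whose hazard
structure is fully known, so every stage can be checked against ground
truth.

## The scoring model

A sex-specific proportional-hazards score: for subject *i*,

    risk_10y(i) = 1 − S0(10) ^ exp(lp_i)

where `S0(10)` is the 10-year baseline survival and the linear predictor is

    lp_i = Σ_k β_k (x_ik − m_k) + Σ_k γ_k (x_ik − m_k)(a_i − m_a)

over fractional-polynomial (FP) transformed predictor components `x_ik`
centred at cohort means `m_k`, with age-interaction products against the
centred first FP age component `a_i`.  FP conventions are Royston–Altman:
power `p ≠ 0` gives `u^p`, `p = 0` gives `ln u`, and a repeated power
`(p, p)` gives `(u^p, u^p ln u)` — hence `(0, 0)` gives `(ln u, (ln u)²)`.

The engine is entirely coefficient-set driven (YAML schema in
`oncorisk.scoring`): no published constants are hard-coded, and any
published or refitted model can be supplied.  Missing values among the six
substitutable predictors (smoking, BMI, ethnicity, SBP, SBP standard
deviation, total:HDL cholesterol ratio) are filled from configured
substitution values; the defaults are the synthetic cohort's approximate
means.  Deprivation enters as a single ordinal score on the twentile number
(1..20) rather than 19 indicator columns; this keeps replicate-heavy Cox
fits tractable and is a standard treatment of an ordered group variable.

## The synthetic cohort

Each matched set holds one cancer survivor (index = 1 year after diagnosis)
and 1–5 cancer-free controls of the same sex within ±3 years of age
(practice matching is represented only by the set identifier; the analysis
models, like the score's own derivation, ignore the matching).  Defaults:
58% female, ages N(62.7, 12.5) truncated to 25–84, twenty cancer sites with
plausible UK frequencies and sex restrictions, independent predictor
marginals (the joint predictor distribution of real primary-care data is
not emulated), and MCAR missingness at rates of the order seen in routine
records (blood-test-derived variables missing most often).  A
covariate-dependent missingness option exists for imputation stress tests.

Event generation: CVD times are inverse-transform draws from an exponential
baseline hazard multiplied by `exp(lp + cancer increment)`, where the
baseline rate is derived from the generating coefficient set's `S0(10)`
(`h0 = −ln S0(10)/10`) so the generator and the scorer can never disagree
about the baseline.  Site-specific true log-hazard increments default to
~ln 1.12 for most solid tumours and larger values (up to ~ln 1.45) for
haematological, lung and bladder cancers.  Non-CVD death (0.02/py, ×1.8 in
survivors, reflecting excess post-cancer mortality) and loss to follow-up
(0.07/py) are independent exponential processes; follow-up is truncated at
10 years.  The earliest of {CVD, death, censoring, horizon} terminates
follow-up.  Because all processes are continuous, event-time ties have
measure zero.

What passing tests on this generator do *not* show: performance under
correlated predictors, non-proportional hazards, informative censoring,
coding/linkage error, or missingness mechanisms tied to unobserved values —
all present in real records.

Eligibility filters mirror the score's target population: age 25–84 at
index (inclusive), no prior cardiovascular disease, fewer than two statin
prescriptions in the prior year, and (controls only) ≥2 years of pre-index
registration.  Overlapping exclusions are double counted and flagged as
such in the report.

## Validation

* **Cumulative incidence** is computed both as the Kaplan–Meier complement
  with deaths censored (the convention under which the score was derived)
  and as the Aalen–Johansen cause-specific cumulative incidence with death
  competing.  The latter is never above the former on the same data; the
  gap widens where mortality is high — the package reproduces this
  qualitative divergence in high-risk survivors.
* **Calibration** compares mean predicted risk with the naïve Kaplan–Meier
  observed risk at 10 years per decile of predicted risk.  Decile edges are
  empirical quantiles; ties at an edge fall to the lower bin; a horizon
  beyond the last observed time is flagged and the last estimate used.
* **Discrimination** is Harrell's C over comparable pairs (the member with
  the strictly smaller observed time must have had the event; time ties are
  not comparable; score ties count one half), computed on a seeded simple
  random 10% subsample without replacement, as in the original analysis
  (the pair count is quadratic in n).  With `sample_fraction=1` the result
  is deterministic and seed-free.  Age-banded C statistics (25–59, 60–84)
  filter the same subsample rather than redrawing per band.

## Derivation and the inclusion rule

Per sex stratum, with administrative censoring at 10 years applied first:

1. **Multiple imputation** (m = 5 by default) by chained equations.  Each
   imputation model contains every analysis predictor component,
   explicitly constructed age-interaction product columns, the
   Nelson–Aalen cumulative hazard at the subject's exit time
   (`Σ d_i/n_i`), and the CVD event indicator.  Continuous targets use
   Bayesian linear-regression draws — σ² from the scaled inverse-χ²
   posterior, coefficients from their conditional normal, then a residual
   draw — so between-imputation variance is non-degenerate; skewed
   variables (BMI, cholesterol ratio, SBP standard deviation, a
   configurable set) are imputed on the log scale; categorical targets
   (smoking, ethnicity) use a multinomial logistic draw fitted on a
   bootstrap resample.  Imputed values are clipped to the observed support
   so FP transforms stay defined.  Derived analysis columns are recomputed
   from the imputed raw values after each draw (products enter the
   imputation models as constructed columns; they are not imputed as
   free-standing variables).  Predictive-mean matching is not implemented.
   With no missing data the step returns m identical copies.
2. **Cox fits** via partial-likelihood maximisation (lifelines; Efron tie
   correction — inert here since simulated times are continuous), on a
   design matrix centred at the stratum's observed-data means shared
   across imputations, with candidate cancer columns (binary; solid vs
   haematological; or 20 site indicators) each carrying an age
   interaction.
3. **Rubin's rules**: pooled estimate = mean; total variance
   `T = W + (1 + 1/m) B`; two-sided Wald P from `β̄/√T` with
   Barnard–Rubin degrees of freedom (reducing to the normal reference as
   B → 0 or df → ∞); 95% CI `exp(β̄ ± 1.96 √T)`.
4. **HR at the mean age**: because every column (including the age
   component in the products) is mean-centred, interaction contributions
   vanish at the mean age and the candidate's main coefficient is directly
   its log HR there.
5. **Inclusion rule**: a candidate qualifies iff its independent HR is
   strictly below 0.90 or strictly above 1.10 *and* P < 0.01.

Imputation is run once per sex with the binary survivorship indicator in
the model and the completed datasets are reused across cancer encodings,
mirroring a derivation in which the imputation replicates the base score
once before candidate variables are added.

A site level is estimated only with ≥10 carriers and ≥5 events in the
stratum; sparser levels (including zero-event levels) are reported as
inestimable rather than risking monotone-likelihood fits, never silently
dropped.  Whether every site indicator should carry its own age
interaction is an open design point; the package gives each estimable site
indicator one interaction with the first age component.

## Numerical choices and problem sizes

* Risks are computed as `−expm1(exp(lp)·ln S0)`; no overflow for |lp| ≤ 20.
* Imputation regressions are ridge-stabilised at 1e−8 on the Gram matrix.
* A global seed drives a `SeedSequence` that spawns per-stage sub-seeds;
  identical configuration and seed reproduce every output table
  byte-for-byte.
* Default simulation scale in the analysis scripts and the acceptance
  script is 3 000 matched sets (~13 000 eligible subjects) — a
  deliberately desk-scale analogue of the ~495 000-person study, chosen so
  the full pipeline runs in about a minute.  Monte-Carlo studies in the
  test suite use 100–200 replicates at 300–600 matched sets with tolerance
  bands derived from the binomial error of each design.  At this scale
  site-specific hazard ratios carry wide confidence intervals and few site
  decisions fire — the same sparsity caveat the original analysis reports
  for its site-specific models.

## Known limitations

* Predictors are generated independently, so imputation gains over
  complete-case analysis are modest (they come mainly from retaining rows,
  not from cross-predictor information).
* No Fine–Gray competing-risks regression; the competing-risks view is
  descriptive (Aalen–Johansen) only.
* The practice level of the matching is not modelled (no clustering or
  frailty), matching the unmatched-analysis convention of the score's own
  derivation.
* Heart failure and venous thromboembolism outcomes are out of scope; the
  event of interest is the combined coronary heart and cerebrovascular
  disease endpoint only.
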