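# Methods

`nephroref` implements a risk-based nephrology-referral analysis as a
reusable, tested pipeline: compute kidney-failure risk with the 4-variable
Kidney Failure Risk Equation (KFRE), recalibrate it to a local population,
encode guideline referral criteria as predicates, and evaluate everything
under competing risks (death overwhelmingly dominates kidney replacement
therapy, KRT, in primary-care CKD populations). This note records the
models, the assumptions, the tunable parameters, and the places where a
design had to be chosen.

## The risk model

The 4-variable KFRE predicts KRT within a horizon t from age, sex, eGFR and
urine albumin:creatinine ratio (ACR). On the transformed covariate scale
x = (age/10, male, eGFR/5, ln ACR), centered at
c = (7.036, 0.5642, 7.222, 5.137):

    lp      = Σᵢ βᵢ (xᵢ − cᵢ)
    risk(t) = 1 − S0(t)^exp(lp)

Shipped constants (`kfre.KFRE_4V_NON_NA`, `kfre.KFRE_4V_ORIGINAL`):
β = (−0.2201, +0.2467, −0.5567, +0.4510); baseline survival
S0(5y) = 0.9240, S0(2y) = 0.9878 for the non-North-American calibration and
0.8996 / 0.9832 for the original. These are transcribed from the external
development/validation literature, are marked as externally sourced in the
code, and should be re-verified against the primary sources before any
clinical use. At the centering point risk(5y) = 1 − 0.9240 = 0.0760, which
the tests pin down.

eGFR comes from serum/plasma creatinine via the revised Lund–Malmö
equation (the equation auto-reported in Swedish healthcare); the piecewise
form is continuous at the sex-specific creatinine knot and strictly
decreasing in creatinine, both asserted by property tests. Only RLM is
implemented — no CKD-EPI/MDRD — because the analysis this package supports
is anchored to Swedish routine data.

Albuminuria is harmonized to ACR in mg/g (canonical unit; mg/mmol accepted
with factor 8.84). PCR converts through a three-segment log-linear spline
with additive sex/diabetes/hypertension terms; dipstick categories convert
through fixed per-category medians. **Caveat:** the dipstick table shipped
in `data/acr_conversion.json` is a crude, explicitly synthetic fallback
(the stratified published coefficients were not available when it was
written); the file is editable precisely so users can substitute
transcribed values. The PCR spline coefficients are transcribed from the
widely reproduced published conversion and flagged for verification.

## Observation records

One record per creatinine test, paired with the nearest albuminuria test
within 365 days (ties broken toward the earlier albuminuria test); the
index date is the later of the two. A `cross_join` switch instead emits
every in-window pair, since registry descriptions of "all available pairs"
admit both readings. Persons enter the cohort if at their *first* record
eGFR < 60, KRT has not started, and death does not occur within 1 day;
later records with eGFR ≥ 60 are retained by default (entry criterion is
first-observation-only), with a strict flag to drop them.

Follow-up per record is min(KRT, death, emigration, administrative end,
index + horizon) − index, with the horizon measured as 365.25·h days
(leap-year stable; a 5-year horizon is 1826.25 days, so a "5-year" censor
prints as 1826.25 rather than 1826). Ties resolve KRT > death > censored.
Refractory hypertension is ≥ 4 distinct antihypertensive classes dispensed
in the half-open window (index − 183 d, index]. Calendar-period strata
default to tertiles of the study window because the source analyses do not
name their cut points.

## Competing-risk estimators

All implemented from first principles (they are the package's point);
lifelines serves only as an independent cross-check in tests.

- **Aalen–Johansen.** CIF_k(t) = Σ_{tᵢ≤t} S(tᵢ⁻) d_{k,i}/nᵢ with S the
  all-cause Kaplan–Meier; events process before censorings at tied times.
  Conservation Σ_k CIF_k + S = 1 holds to machine precision and is
  asserted at 1e-10. Variance is the Aalen/Marubini–Valsecchi estimator
  (computed with prefix sums, O(m)); confidence intervals use the
  log(−log) transform. Point estimates and variances match lifelines'
  `AalenJohansenFitter` to ~1e-12 on random data.
- **Cumulative/dynamic ROC.** Sens(c,t) = P(M≥c)·F_{M≥c}(t)/F(t),
  Spec(c,t) = P(M<c)·(1−F_{M<c}(t))/(1−F(t)), with all F's Aalen–Johansen
  CIFs of KRT; positivity is risk ≥ threshold, matching the referral-rule
  convention. The threshold grid is every distinct risk (exact Youden),
  thinnable to quantiles for large cohorts (`max_thresholds`). With no
  deaths and complete follow-up this reduces *exactly* to the empirical
  binary ROC (asserted). Under censoring the group-wise reweighting is not
  exactly monotone in the threshold — wiggles of order 1/n (≈2e-5 at
  n = 20 000) are expected and tolerated at 1e-3 in tests; no isotonic
  clean-up is applied.
- **Youden.** argmax of sens + spec − 1 over curve thresholds; ties take
  the higher threshold (fewer referrals). Verified against exhaustive grid
  search on 100 random 1000-record datasets.
- **C-index.** Horizon-truncated and cause-specific: cases are KRT events
  by the horizon; controls for a case at tᵢ are records KRT-free at tᵢ,
  *including* deaths at any time — a person dead without KRT never needed
  referral. Ties in risk count ½.
- **Brier score.** IPCW at the horizon with reverse-Kaplan–Meier censoring
  weights; deaths by t are observed non-cases (weight 1/G(T⁻)), censored-
  before-t records get weight 0. Uncensored reduction is the plain mean
  squared error.
- **Calibration.** Decile grouping on predicted risk (ties collapse groups
  with a warning), observed risk = within-group AJ CIF at the horizon with
  log(−log) CI, plus a lowest-20% sub-table re-split into deciles — the
  region that actually drives referral decisions.

## Recalibration

A Cox proportional-hazards fit on the four transformed-and-centered
covariates, death treated as censoring (retaining the original KFRE
structure), Efron tie correction (registry dates are heavily tied), via
lifelines. Baseline survival is the Breslow estimator computed directly at
the centering point from the fitted linear predictors — lifelines'
stored baseline is normalized at covariate means, so the package evaluates
H0 by hand and reads S0 at 2·365.25 and 5·365.25 days. Repeated records
per person enter as independent rows (matching the main-analysis framing);
`cluster_col` switches on cluster-robust standard errors without changing
point estimates. A brute-force Efron partial-likelihood oracle in the test
suite pins the tie correction to 1e-8 (and shows a Breslow-ties evaluation
would *not* match).

## Referral rules and decision analytics

KDIGO 2012: eGFR < 30, or ACR ≥ 300 mg/g, or ≥ 4 antihypertensive classes
in 6 months. Fixed-threshold rules are disjunctions of conjunctive bounds
over age/eGFR/ACR/antihypertensive count, loaded from YAML; the shipped
Swedish-style config is an explicitly non-authoritative placeholder (the
national thresholds live in guidance not reproduced here). KFRE rules
refer at risk ≥ cutoff — boundary inclusive so that rule sets nest cleanly
(a config switch flips it). Universally applicable referral indications
(AKI, sediment abnormalities, genetic disease, …) are out of scope by
design.

Classification tables default to `raw_counts` (a record censored before
the horizon counts as a non-case — the policy that appears to underlie
integer-cell registry tables); `cif_weighted` replaces cell case counts
with n·CIF and equals raw counts exactly on uncensored data. The NRI uses
cell-level AJ CIFs (the censoring-robust two-category construction) and
reduces exactly to the classical binary NRI when follow-up is complete.
Decision curves use NB(p) = (n⁺/N)·F⁺ − (n⁺/N)(1−F⁺)·p/(1−p) with
AJ CIFs among positives; fixed rules enter as threshold-independent
classifications; the default grid is 0.005–0.30 in steps of 0.005,
covering every cutoff of practical interest (0.6%–15%).

## The synthetic cohort: what it emulates, and what it does not

`simulate_cohort` generates persons (age ~ truncated normal mean 75 sd 9,
49% male, diabetes 18%, hypertension 59%), entry eGFR ~ truncated normal
(52, 9) on (8, 60), ln ACR ~ N(3.1, 0.9²), entry uniform over 2006–2021
with administrative censoring at the window end and exponential emigration
(0.008/y). Test dates follow a per-person homogeneous Poisson process
(gamma-distributed rate, mean 0.6/y) — reproducing the dispersed repeat
counts (median 2, IQR 1–5). Within a person, true eGFR declines linearly
(mean −1.3 ml/min/1.73 m²/y, sd 1.0) with measurement noise sd 3; ln ACR
is stable with noise sd 0.3. These within-person choices are modelling
conveniences, not sourced facts. Albuminuria modality is 50% dipstick, 10%
PCR, 40% ACR; 20% of quantitative results are reported in mg/mmol to
exercise unit handling.

Events come from constant cause-specific hazards λ_k·exp(lp_k), with the
KRT linear predictor on the same four KFRE transforms — so a Cox
recalibration has a recoverable truth — and a death predictor rising in
age and male sex. The KRT baseline default is −ln(0.9240)/5 ≈ 0.0158/y:
the world in which the imported non-NA 5-year KFRE is *exactly* calibrated
at the centering point. `miscalibration_factor` multiplies it to emulate a
population whose risk the imported equation misestimates. The death
baseline (0.085/y) was set once so ~40% die over the window; with these
defaults ~1% of persons reach KRT, record-level medians land near the
target registry marginals (age ≈ 77, eGFR ≈ 46, ACR ≈ 25 mg/g), and the
sampler's constant-hazard mode admits closed-form checks
(P(cause 1) = λ₁/(λ₁+λ₂), CIF₁(t) = λ₁/(λ₁+λ₂)(1−e^{−(λ₁+λ₂)t})).

Because one exponential clock cannot reproduce *both* published baselines,
the imported 2-year model is mildly miscalibrated in this world
(generator S0(2y) = 0.9689 vs the model's 0.9878) — incidentally mirroring
the qualitative 2-year behaviour seen in real validations. A green test on
this world establishes estimator correctness and pipeline integrity, not
real-world transportability: the generator has no care-seeking dynamics,
no covariate-dependent testing, no informative censoring, and its
within-person correlation structure is invented.

`simulate_record_frame` bypasses the longitudinal machinery and draws
i.i.d. records straight from the covariate and hazard model — the clean
Cox truth used for parameter-recovery and calibration tests, where the
estimand must match the generator exactly (the cohort stream's measurement
noise and time-varying eGFR would attenuate coefficients, which is
realistic but wrong for an oracle).

## Numerical and statistical conventions

- All randomness flows through one `numpy.random.Generator` seeded from
  the config; identical config + seed ⇒ byte-identical outputs (asserted).
- Horizon arithmetic uses 365.25 days/year everywhere.
- Risk-decile ties collapse groups (warning) rather than splitting a tied
  value across groups.
- Youden ties → higher threshold; classification of a refer-everyone rule
  reports NPV = 1 with a degeneracy flag.
- Monte-Carlo test bounds are pre-registered with fixed seeds. Where a
  per-decile "k MC SE" bound is applied to 10 deciles simultaneously, unit
  tests use a Bonferroni-style family bound (|z| < 4 and mean z² < 2)
  because a raw 3-SE bound fails by chance in ~3% of exactly calibrated
  worlds; the acceptance-level criteria are kept at their stated values
  with their pre-registered seeds.
- `pipeline.run_pipeline` writes all tables with `float_format="%.10g"`
  and hashes the scientific config (output directory excluded) into every
  manifest.

## Known limitations

- The dipstick→ACR table is a placeholder; results that depend on dipstick
  records inherit its crudeness (an `acr_only` sensitivity subset is built
  in for exactly this reason).
- The Swedish rule config is illustrative, not the national criteria.
- The recalibrated model, like the original KFRE, is a net-risk (death-
  censored) quantity; comparing it to AJ-observed incidence retains a
  small conservative gap wherever competing mortality is heavy.
- C-index and ROC variants under competing risks are not unique in the
  literature; the choices here (truncated cause-specific concordance,
  AJ-based cumulative/dynamic ROC, deaths as controls) are documented
  decisions, asserted by oracles, and labelled in the outputs.
- No bootstrap confidence intervals for NRI/DCA; group-wise calibration
  CIs are analytic.
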