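# Methods

This note documents the statistical models, conventions and numerical
choices behind `policymatch`, and what the synthetic-data validation does
and does not establish.

## Study frame

All computation lives on a quarterly state panel. The default window is
2007Q1–2018Q4 (48 quarters, 144 months); quarters are indexed 0..47 from
the window start and days 0..4382 for claim-level arithmetic
(`policymatch.quarters.QuarterWindow`).

## Claims-derived misuse indicators

Six patient-level indicators are measured per quarter and aggregated to
state × quarter proportions:

| indicator | patient-quarter rule |
|---|---|
| `p_any_opioid` | ≥1 opioid fill in the quarter |
| `p_oud_overdose` | ≥1 OUD or overdose diagnosis in the quarter |
| `p_mme90` | ≥1 day in the quarter with total daily MME ≥ 90 |
| `p_doctor_shopping` | some 90-day window ending in the quarter holds fills from ≥4 unique prescribers **and** ≥4 unique pharmacies |
| `p_overlap` | ≥1 day in the quarter covered by two distinct opioid fills |
| `p_mat` | ≥1 medication-assisted-treatment fill in the quarter |

Conventions, all configurable via `IndicatorConfig`:

* **Daily MME.** A fill contributes
  `strength_per_unit × (quantity / days_supply) × mme_factor` to every day
  of the inclusive supply interval `[fill_date, fill_date + days_supply − 1]`
  (a 1-day supply covers exactly its fill date); concurrent fills sum.
  The high-dose threshold is **≥ 90** mg morphine equivalent
  (`mme_threshold`); the comparison convention matters only on the exact
  boundary.
* **Doctor shopping.** "Within 90 days" is a rolling span, not a calendar
  bin. Windows are anchored at claim dates (the window ending at each fill
  is inspected), which detects every violating span; the flag lands in the
  quarter containing the window end. Fills missing a prescriber or pharmacy
  id are ignored for this indicator and logged.
* **Quarter attribution.** Every flag is attributed to the quarter
  containing the violating day / window end / fill, matching outcome
  measurement per quarter.
* **Exclusions and denominators.** Patients with any cancer or
  palliative-care diagnosis are removed from numerators and denominators.
  `p_any_opioid` uses all eligible enrollees. The other five indicators
  restrict numerator eligibility to patients with ≥1 opioid fill during the
  window; their denominator defaults to all eligible enrollees
  (`subset_denominator="enrollees"`), the reading consistent with using
  total enrollees as denominators throughout, with `"ever_opioid"`
  available because the alternative reading is also defensible.
* **Code map.** Diagnosis categories come from a small packaged ICD-9/10
  prefix map (`policymatch.icd.DIAGNOSIS_CODE_MAP`): F11/304.0/305.5 → OUD,
  T40/965.0/E850.1 → overdose, C00–C96/140–208 → cancer, Z51.5/V66.7 →
  palliative. It is a documented stand-in for a full claims code list and
  is swappable via `IndicatorConfig.code_map`. MAT is identified by drug
  class (buprenorphine-based agents and naltrexone); methadone is excluded
  by default because it is frequently prescribed as an analgesic, and
  `methadone_as_mat=True` adds it back for sensitivity runs.
* **Degenerate cells.** A zero denominator yields a missing proportion
  (never 0), logged.

## Overdose mortality

A death is a drug-overdose death iff its underlying cause is in
X40–X44 (unintentional), X60–X64 (suicide), X85 (homicide) or Y10–Y14
(undetermined intent). Such a death counts under `all_drug` and under one
category per distinct contributing code T40.1–T40.6 (heroin; natural and
semisynthetic opioids; methadone; synthetic opioids excluding methadone;
cocaine; other/unspecified). Categories deliberately overlap — a
polysubstance death counts in every involved category — so category counts
need not sum to `all_drug`. T40.0 (opium) maps to no specific category;
the death still counts under `all_drug`. Malformed code strings cause the
record to be skipped with a log entry.

`recover_monthly_counts` implements the exact subtraction identity
`count(m) = total − total_excluding_m` for reconstructing monthly series
from an aggregate-only interface (144 leave-one-month-out totals for a
12-year window); it raises on any leave-one-out total exceeding the grand
total. An arbitrary excluded-month mask is supported simply by omitting
those months from the input map. Mortality outcomes are quarterly rates
per 300 million people: `quarterly count × 3e8 / state population`.

## Treatment panels

A policy effective in any month of quarter q is treated as active from q
onward (`activation="enactment_quarter"`; `"next_quarter"` available since
the enactment-quarter convention is not the only defensible one).
Treatment is absorbing — no repeal — so flags are monotone non-decreasing
and cumulative adoption counts only grow. Medicaid expansion is carried as
a covariate/condition flag, not an analysed treatment (it can be promoted
to a treatment for sensitivity runs simply by listing it as a policy).

## Panel-matching estimator

For each policy and each state switching 0→1 at quarter t:

1. **Matched set.** Controls are states with the identical treatment
   history over `[t−L, t−1]` (L = 4 quarters by default — one year of
   matching history) that remain untreated at t. Events with t < L are
   skipped (insufficient pre-period); events with no eligible control are
   reported but excluded from estimation.
2. **Lead-wise control hygiene.** At lead F the contrast uses only controls
   still untreated at t+F; their weights are renormalised. This keeps the
   comparison clean of the controls' own later treatment response (and is
   what makes the noise-free injected-effect check exact at every lead). A
   set whose controls are all contaminated at some lead drops out at that
   lead only, as does a set whose t+F runs past the window.
3. **Refinement weights.** Default `method="cbps"`: a pooled
   covariate-balancing propensity score over treated and control
   unit-quarters — logistic scores whose coefficients solve the
   just-identified ATT balance moments (odds-weighted control covariate
   means equal treated means) — with control weights proportional to the
   fitted odds, renormalised within each matched set. Features are the
   covariates at t−1 plus L pre-treatment outcome lags (the lags implement
   matching on pre-treatment trends; `condition_on_pre_outcomes=False`
   disables them), z-scored for conditioning. Alternatives: `"entropy"`
   (within-set minimum-KL weights solving the balance moments exactly when
   the treated point lies in the control hull), `"ipw"` (plain logistic),
   `"nn"` (Mahalanobis J-nearest with lexicographic tie-break for
   determinism), `"uniform"`. Separation or degenerate designs fall back to
   uniform weights with a warning; non-finite odds never propagate.
4. **Effect and uncertainty.** The lead-F ATT is the equal-weighted average
   over matched sets of
   `[Y_tr(t+F) − Y_tr(t−1)] − Σ_c w_c [Y_c(t+F) − Y_c(t−1)]`, F = 0..12
   (lead 0 is the adoption quarter itself; both conventions about when
   effects may start are visible since the full profile is reported).
   Confidence intervals come from a block bootstrap that resamples whole
   state trajectories with replacement (states are the independent units)
   and recomputes matching, refinement and estimation inside each
   replicate; percentile intervals, B = 1000 by default (500 in the
   pipeline, 200 in the large validation studies). Replicates with no
   matched sets contribute missing draws and are counted.

## Pooling across leads

`pool_random_effects` fits the standard random-effects model
`y_f = μ + u_f + e_f`, `u_f ~ N(0, τ²)`, `e_f ~ N(0, se_f²)` with τ² by
REML (bounded scalar optimisation of the restricted likelihood, default) or
DerSimonian–Laird, inverse-variance weights `w_f = 1/(se_f² + τ̂²)` and a
Wald 95% CI. Missing leads reduce k rather than being imputed. Degenerate
all-zero SEs return the simple mean with a zero-width CI and a warning.
An association is *negative* iff the pooled mean is < 0 (a mean of exactly
0 is labelled positive, a documented tie-break) and *significant* iff the
CI excludes 0, giving the four shading labels of the policy × outcome grid.

**Dependence-aware CI.** The 13 lead estimates from one panel share
matched sets and baseline quarters, so their sampling errors are strongly
positively correlated and the independent-leads Wald interval materially
understates pooled uncertainty (in a null simulation it flagged ~47% of
policy–outcome pairs). The pipeline therefore defaults to
`meta.pool_with_draws`: τ² and the weights come from the random-effects
model exactly as above, but the CI is the percentile interval of the
weighted mean applied to each block-bootstrap replicate of the lead
profile, which inherits the between-state resampling dependence. The Wald
interval remains available (`pooling.ci="wald"`).

## Synthetic data generator

The generator defines the validation conditions; its defaults are the
study frame (50 states, 48 quarters, 2007 start).

* **Adoption** is a per-quarter hazard process per (state, policy), default
  0.02/quarter, giving ≈62% adoption by the window end — most, but not
  all, states adopt, so never-treated controls exist throughout. Adoption
  is absorbing and independent of outcomes and covariates.
* **Panel outcomes** follow
  `baseline + intercept_s + common trend·q + slope_s·q +
  Σ schedule[q − adoption_q] + N(0, noise_sd²)` with intercept sd 1,
  pre-trend slope sd 0.02/quarter and noise sd 1 by default — parallel
  trends in expectation plus a lagged injected effect starting at lead 0.
  Effect schedules give leads 0..F_max and plateau at their last value.
* **Claim streams** draw a fixed enrollee roster per state (the enrollment
  structure of the source data is not public; a fixed roster is the
  assumption), an any-opioid fill probability of 0.12 per patient-quarter
  shifted additively by active supply-policy schedules (realised targets
  are stored for binomial-error checks), fills with realistic
  supply/strength/conversion-factor combinations kept below 90 daily MME,
  planted high-dose regimens (95–150 MME) at a policy-modulated rate,
  planted doctor-shoppers (4 prescribers × 4 pharmacies inside one 90-day
  span), natural refill overlap, MAT/methadone fills, OUD/overdose
  diagnoses (ICD-9 before 2015-10, ICD-10 after) and a ~2% cancer/palliative
  cohort that downstream code must exclude.
* **Deaths** are record-level: per state-month-cause Poisson counts with
  mean `(base rate + active harm-reduction schedules) × population / 3e8 / 3`,
  each record carrying a random overdose underlying code, the cause's
  T-code, and a second T-code for a 10% polysubstance share.
* **Reproducibility.** Each component (policies, outcomes, covariates,
  claims, deaths) draws from its own `numpy` Generator seeded as
  `[master_seed, component_id]`, so changing one component's parameters
  never perturbs another's draws, and seeded runs are bit-reproducible.

What the generator does **not** emulate: enrollment churn and coverage
spells, geographic spillover between states, correlated adoption of
different policies within a state, outcome-dependent (endogenous) policy
adoption, drug-level NDC detail, and coding drift beyond the single
ICD-9→10 switch date. Passing validation therefore shows the estimation
chain is internally correct and calibrated under its stated assumptions —
not that those assumptions hold in real claims or vital-statistics data.

## Validation studies (`policymatch.validation`)

Problem sizes are desk-scale, single-CPU choices:

* **Dual-route agreement** — matched sets and per-set DiD on random panels
  up to 6 states × 12 quarters versus exhaustive enumeration; all six
  indicators on a ~500-patient, 3-state cohort versus a literal per-patient
  per-day reimplementation (`policymatch.reference`). Agreement is exact.
* **Closed forms** — the two-unit/two-period reduction equals the textbook
  DiD; τ² = 0 pooling equals the fixed-effect inverse-variance mean; the
  two-study DL τ² equals `(Q − (k−1))/C` by hand.
* **Parameter recovery** — a ramp schedule (0 → −1 over 13 leads) injected
  at the default panel conditions, 500 replicates, uniform set weights
  (appropriate because adoption is covariate-independent here): per-lead
  `|mean − truth|` is reported in Monte-Carlo-SE units, plus the
  correlation of the mean profile with the truth. Note the per-lead
  2·MCSE bound across 13 correlated leads is a noisy joint check: for a
  perfectly unbiased estimator the max per-lead deviation exceeds 2 MCSE in
  a sizeable fraction of study repetitions; a 3000-replicate diagnostic
  bounds any true bias below 0.01 outcome units.
* **Null calibration** — zero injected effect, 300 replicates at B = 200:
  coverage of the mid-profile (lead-4) bootstrap CI and the pooled
  classifier's false-flag rate.
* **Sign-grid reproduction** — full pipeline on a 40-state bundle with a
  supply policy injected negatively into the any-opioid and high-dose fill
  probabilities and a harm-reduction policy injected positively into
  heroin/synthetic death rates (magnitudes of a few hundred deaths per
  300M per quarter, the scale such policy effects are reported on). The
  claims→indicators→match→pool and deaths→rates→match→pool paths must
  label injected cells with the correct significant sign and leave
  non-injected cells non-significant.

## Known limitations

* No spillover between states or between policies; each policy is
  evaluated marginally against its own clean-control pool.
* The estimator consumes binary absorbing treatments; repeal, dosage and
  continuous-strength variants are out of scope.
* Matching quality with CBPS refinement is only as good as the pooled
  propensity model; with one treated unit per set and many features the
  fit can be degenerate, in which case weights fall back to uniform (with
  a warning) rather than failing.
* The leave-one-month-out recovery assumes the aggregate source is
  internally consistent; inconsistent totals raise rather than being
  reconciled.
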