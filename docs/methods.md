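# Methods

This note records the statistical model behind each stage of `cvburden`,
the defaults and why they were chosen, the numerical choices that make
results reproducible, and what the synthetic-data tests do and do not
establish about real cohort data.

## Data model

A pooled dataset holds one row per participant: cohort id, sex, baseline
age (≥ 20 years), baseline exposures in canonical units (BMI kg/m², SBP
mmHg, FPG/TC/non-HDL mmol/L), follow-up time in years, and 0/1 indicators
for fatal and non-fatal cardiovascular events at the end of follow-up.
Unit conversion happens once at pooling: cholesterol mg/dL ÷ 38.67,
glucose mg/dL ÷ 18.016, blood pressure kPa × 7.50062; unknown unit labels
are hard errors naming the column.  Rows violating the invariants
(age < 20, non-positive follow-up) are dropped and counted in a pooling
report rather than silently fixed.

Incidence is modelled on *attained age*.  Follow-up is split into the
half-open ten-year bands [35, 45), …, [75, 85), [85, ∞) in exact
fractional years; person-time before 35 is discarded.  The event sits in
the band containing the exit age; when the exit age falls exactly on a
band edge — a measure-zero case for continuous data — the event is
attached to the last segment with positive person-time, so event and
person-time conservation are exact.  The `age_at_risk` covariate of a
segment is the midpoint of the sub-interval the participant actually
occupies, a documented choice where "age at risk" alone underdetermines
the construction.

Crude rates use the exact Poisson (Garwood) interval on the event count
(`chi²` quantiles at 2k and 2k+2 degrees of freedom), scaled by
person-years.  At the event counts involved (hundreds to thousands) the
exact and normal-approximation intervals are near-indistinguishable; the
exact interval also behaves correctly at very small counts.

## Synthetic cohorts

The generator emulates a pooled set of Latin American and Caribbean
prospective cohorts.  Defaults follow the pooled cohort profile such data
show: exposure means/SDs BMI 27.2 (4.8) kg/m², SBP 131 (22.1) mmHg, FPG
5.5 (1.9) mmol/L, TC 5.3 (1.3) mmol/L, non-HDL 4.2 (1.3) mmol/L; 83.7%
women; entry ages uniform on 25-70 (mean ≈ 47.5); administrative
censoring at 8.9 years; a 0.54 fatal fraction among events; roughly a
third of cohorts carrying a repeat-measurement protocol.

Two generative details matter for the downstream statistics:

* **Variance split.**  Each exposure's total SD is divided into
  between-person and within-person components so that the implied
  attenuation `λ = σ²_b/(σ²_b + σ²_w)` reproduces the conventional
  correction factors for these risk factors (1.10 BMI, 1.50 SBP, 1.53
  FPG, 1.75 TC, 1.85 non-HDL).  The person's *usual* level drives the
  hazard; the baseline measurement and every repeat add independent
  within-person noise.  Regression-dilution behaviour is therefore known
  exactly by construction.
* **Hazard.**  Event times are drawn from a piecewise-constant
  attained-age hazard (defaults rising from 3·10⁻⁵/py at 20-34 to
  2·10⁻²/py at 85+, giving an overall crude rate on the order of
  100-160 per 100,000 person-years) scaled per person by
  `exp(u_cohort + 0.4·male + Σ β·(usual − mean))`, with cohort
  intercepts `u ~ N(0, 0.3²)`.  Sampling inverts the cumulative hazard
  against a unit-exponential draw, so the generator's age structure
  matches the piecewise-constant model fitted downstream.

True log RRs per canonical unit default to 0.06 (BMI), 0.02 (SBP), 0.12
(FPG), 0.18 (TC), 0.22 (non-HDL) — the order of magnitude large cohort
poolings report at middle age.  Exposure draws are normal with
physiologic floors enforced by re-sampling (BMI > 10, SBP > 60, …),
keeping moments near-nominal while avoiding impossible values.
Missingness is applied in two layers, protocol-level first (a sampled
subset of cohorts never measures a variable; defaults make BMI ~10%
missing and the biomarkers 55-70% at the cohort level) and then
completely-at-random within cohorts (5%).  All randomness derives from
one integer seed through fixed named sub-streams.

What the generator does **not** emulate: correlation between risk
factors, competing risks, loss to follow-up other than administrative
censoring, time-varying usual levels (no drift, so attenuation does not
grow with the measurement gap), calendar-period effects, and
non-random (differential) missingness.  Passing tests therefore
establish internal statistical correctness — unbiasedness, calibration,
conservation — under these idealised conditions, not robustness to the
messier features of real cohort data.

## Multiple imputation and Rubin's rules

Missing exposures are imputed by chained equations with predictive mean
matching (statsmodels' `MICEData`; k = 5 donors, 10 cycles between
successive imputed datasets, m = 50 by default).  Each incomplete
exposure is regressed on the other exposures, sex, baseline age, cohort
indicators, the event indicator and log follow-up time — the standard
predictor set for imputation compatible with a person-time outcome
model.  PMM only ever imputes observed values, so it cannot produce
physiologically impossible exposures and is robust to skewness.
Variables missing for *every* record cannot be imputed and are excluded
with a logged warning.  A complete-case mode is available as a
sensitivity path in the pipeline.  The imputation model treats cohort as
fixed indicators, not as a random effect; with many small cohorts this
can slightly understate between-cohort uncertainty in imputed values.

Per-imputation estimates `(β̂_j, se_j)` are pooled as
`β̄ = mean(β̂_j)`, `W = mean(se²_j)`, `B = var(β̂_j)` (sample variance),
`T = W + (1 + 1/m)B`, with reference t degrees of freedom
`(m−1)(1 + W/((1+1/m)B))²` and infinite df when B = 0.  With no missing
data the stack contains identical copies and pooling reproduces the
complete-data fit exactly.

## Regression dilution

The regression-dilution ratio is estimated by the MacMahon grouped
method: pairs are grouped into baseline quintiles (configurable), and
the RDR is the least-squares slope of the repeat group means on the
baseline group means.  When several repeats exist, the first repeat at
least one year after baseline is used, avoiding short-interval
correlated error.  Per-cohort RDRs are pooled by pair-count-weighted
mean (a pooled-pairs mode is also provided, since either reading of
"pooling across cohorts" is defensible).  The correction multiplies the
log RR *and its SE* by `1/RDR`, treating the factor as fixed — the
conventional presentation, which keeps corrected CI widths proportional
on the log scale and ignores the (second-order) sampling error of the
factor itself.

## Age-band incidence models

For one band, segment counts are Poisson with

    log E[y_i] = log t_i + β0 + β x_i + γ1 male_i + γ2 (age_i − mid) + u_c(i),
    u_c ~ N(0, σ_u²) independent across cohorts.

The marginal likelihood integrates `u` out per cohort.  Because a
cohort's contribution depends on `u` only through its total events
`Y_c` and scale `S_c = Σ_i exp(η_i)`, the integrand's mode solves
`Y_c − S_c e^u − u/σ² = 0` with closed Newton updates, and adaptive
Gauss–Hermite quadrature (7 points by default) recentres the nodes at
that mode with the local curvature.  The five parameters (four fixed
effects on an internally centred exposure plus log σ_u) are optimised by
BFGS with a Nelder–Mead polish, to a gradient tolerance of 1e-8;
standard errors come from the observed information via central finite
differences.  When σ̂_u collapses toward zero the log-σ direction is
flat, so the covariance falls back to the fixed-effect block with the
random effect pinned at zero.  `fix_sigma=0` fits the degenerate model
with the same code path and agrees with an ordinary Poisson GLM to
1e-6; the full fit agrees with lme4's `glmer` (nAGQ = 7) to ~1% on
shared test data.  Bands with no events are skipped with a logged
reason; a constant exposure column raises a degenerate-design error;
non-converged fits are flagged and excluded from pooling, and a band
where every imputation failed is *absent* from the RR table, never
reported as zero.

RR assembly Rubin-pools the per-imputation β̂s, applies the dilution
factor, and exponentiates at a configurable display increment (defaults
5 kg/m², 10 mmHg, 1 mmol/L); the per-canonical-unit log RR remains the
stored primitive because displayed increments are a presentation
convention.  CIs use the Rubin t quantile.  Sub-regional RRs reuse the
identical machinery on cohort strata, skipping strata with fewer than
two cohorts.

## Comparative risk assessment

Band log RRs are placed at band midpoints (40, 50, 60, 70, 80, and 90
for the open-ended 85+ band), interpolated linearly in log RR across
age, evaluated at 5-year group midpoints (a+2.5; 90 for 85+), and
extrapolated flat beyond the outermost midpoints.  SEs are interpolated
the same way.  Ages 20-34 therefore carry the youngest band's RR — the
one self-consistent completion when burden is computed from age 20 but
RRs are estimable only from 35.  Evaluating at a band midpoint
reproduces that band's input exactly.

The PAF uses the mean-shift counterfactual: with a log-linear RR and the
exposure distribution shifted down by `Δ = max(0, μ_current − μ_optimal)`
with unchanged spread, the distribution cancels in the ratio of expected
risks and `PAF = 1 − exp(−βΔ)` is exact (not an approximation); the
package carries a quadrature cross-check (`paf_numeric`) used by the
tests at 1e-6.  Default optimal levels are the conventional
theoretical-minimum-risk values BMI 21 kg/m², SBP 115 mmHg, TC 3.8
mmol/L, non-HDL 2.6 mmol/L; FPG has no population mean-level surface in
this framework and is excluded from the burden stage.  The same RRs are
used for both sexes; exposures and deaths stay sex-specific.

The chain propagates whatever the models estimate: a band log RR that
comes out negative by sampling error yields a negative PAF and negative
attributable deaths in the strata it covers, and aggregates can then
fall below zero.  No truncation at zero is applied — clamping individual
strata would bias every aggregate upward — so burden summaries for age
ranges the cohort data barely inform (notably 75+, which inherits the
flat-extrapolated oldest band) should be read together with their
credible intervals, which straddle zero in exactly these situations.

Attributable deaths are `PAF × deaths` per country × sex × 5-year
stratum; strata mismatches between the PAF and deaths tables are hard
errors.  Crude rates divide by adult population × 10⁵.  Sub-regional
rates are recomputed from summed deaths and populations, which equals
the population-weighted mean of country rates.  "Premature" means ages
20-69, "all ages" 20+, and the premature-to-all-ages ratio is their
percentage quotient (undefined on a zero denominator).

Credible intervals draw each 5-year log RR independently from
`N(point, se)` (1,000 draws by default) and recompute the whole
PAF → deaths → aggregation chain per draw; intervals are the 2.5th and
97.5th percentiles, deterministic given the seed.  Only RR uncertainty
is propagated — exposure-surface and death-count uncertainty are not —
and independence across age groups ignores the positive correlation the
interpolation induces, so aggregated intervals are, if anything,
slightly narrow.  The point estimate always lies inside its interval.

## Problem sizes in the test suite

The statistical tests choose sizes where the Monte-Carlo error of the
check is well below the tolerance asserted: dilution recovery at 10,000
pairs (factor within 1.5 ± 0.05), effect-size recovery over 100
replicates of 20 cohorts × 2,000 participants (corrected 95% CI covers
the truth in ≥ 90), null-rate agreement within 3 Poisson SEs at ≥ 50,000
person-years, imputation recovery at 5,000 rows with 30% missingness,
and exact (1e-6 to 1e-12) assertions for the deterministic identities:
person-time/event conservation, attributable-death conservation,
interpolation fixed points, Rubin's rules, and the PAF closed form.

## Known limitations

* No competing risks and no late entry other than baseline age; no
  calendar-period dimension.
* The dilution model is static: no decay of the usual-level correlation
  with the measurement gap, so the correction factor is treated as
  age- and gap-invariant.
* The imputation model is single-level (cohort as fixed indicators).
* Burden credible intervals propagate RR uncertainty only.
* The random-intercept model assumes a normal cohort effect; with very
  few cohorts σ_u is weakly identified and the fit may legitimately
  report a boundary (σ_u ≈ 0) solution.
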