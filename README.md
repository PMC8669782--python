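# cvburden

Pooled-cohort cardiovascular relative risks and attributable mortality
burden for Latin America and the Caribbean style analyses.

`cvburden` implements the analytic chain used to quantify how much of a
region's cardiovascular mortality is attributable to non-optimal
cardio-metabolic risk factors (body mass index, systolic blood pressure,
fasting plasma glucose, total and non-HDL cholesterol), when the evidence
base is a pool of heterogeneous prospective cohorts:

1. **Pooling & person-time** — harmonise participant tables to canonical
   units, split each participant's follow-up into attained-age bands
   (35-44 … 85+) with exact person-time, and compute crude event rates
   with exact Poisson (Garwood) intervals.
2. **Missing data** — multiple imputation of unmeasured exposures by
   chained equations with predictive mean matching, and Rubin's rules for
   pooling per-imputation model estimates.
3. **Regression dilution** — correction factors `1/λ` estimated from
   repeat measurements by the MacMahon grouped-quantile method, where
   `λ = σ²_between / (σ²_between + σ²_within)` is the attenuation of a
   one-off baseline measurement.
4. **Incidence models** — per age band, a Poisson random-intercept model

       log E[y] = log t + β·x + γ₁·sex + γ₂·(age − mid) + u_cohort,
       u_cohort ~ N(0, σ²_u),

   fitted by marginal maximum likelihood with adaptive Gauss–Hermite
   quadrature; `exp(β · increment)` after dilution correction is the
   age-specific incidence rate ratio for "usual" exposure.
5. **Comparative risk assessment** — interpolate log RRs to 5-year age
   groups, form population attributable fractions against optimal
   (theoretical-minimum-risk) mean levels,

       PAF = 1 − exp(−β · max(0, μ_current − μ_optimal)),

   multiply by CVD deaths per country × sex × age stratum, aggregate to
   countries and sub-regions, and propagate RR uncertainty by Monte Carlo
   into 95% credible intervals, including premature (ages 20-69) versus
   all-ages (20+) summaries.

Because participant-level cohort data of this kind cannot be
redistributed, the package ships a first-class synthetic-cohort generator
(`cvburden.synthetic`) with known ground truth — cohort-level baseline
rate heterogeneity, between/within-person exposure variability,
log-linear effects on a piecewise-constant age hazard, administrative
censoring, and protocol-level plus completely-at-random missingness — so
the entire pipeline is testable end to end.  A published regional table
of attributable cardiovascular deaths (LAC, 2019) is included as a
reference fixture for the burden arithmetic.

## Worked example

```python
import numpy as np
import cvburden as cb

# 1. simulate a pooled multi-cohort study with a known usual-SBP effect
cfg = cb.SimulationConfig(
    n_cohorts=20, n_per_cohort=2000, seed=1,
    age_range=(45.0, 62.0), followup_years=8.0,
    true_log_rr={"sbp": np.log(1.02)},
    exposures={"sbp": cb.ExposureSpec(131.0, 22.1 * np.sqrt(2/3),
                                      22.1 * np.sqrt(1/3), "mmHg", 60.0)},
    baseline_rate_by_age={35.0: 1.5e-3},
    missing=cb.MissingSpec({}, 0.0), repeat_cohort_fraction=0.5,
)
cohorts = cb.generate_cohorts(cfg)

# 2. crude event rate with exact Poisson CI
rate = cb.crude_rate(int(cohorts.participants["event_fatal"].sum()),
                     float(cohorts.participants["followup_time"].sum()))
print(f"crude fatal rate {rate.rate:.0f} (95% CI {rate.ci_low:.0f}-{rate.ci_high:.0f}) per 100,000 py")

# 3. regression-dilution correction from the repeat measurements
pairs = cb.build_pairs(cohorts.participants, cohorts.repeats, "sbp")
factor = cb.estimate_correction_factor(pairs)
print(f"dilution: rdr {factor.rdr:.3f}, correction factor {factor.factor:.2f} ({factor.n_pairs} pairs)")

# 4. age-at-risk expansion and the random-intercept Poisson fit
segments = cb.lexis_expand(cohorts.participants, bands=((35.0, np.inf),))
fit = cb.fit_poisson_random_intercept(segments, "sbp", band=(35.0, np.inf))
beta, se = cb.apply_correction(fit.beta, fit.se, factor)
print(f"corrected RR per 10 mmHg usual SBP: {np.exp(10*beta):.2f} "
      f"(95% CI {np.exp(10*(beta-1.96*se)):.2f}-{np.exp(10*(beta+1.96*se)):.2f})")

# 5. published-table arithmetic: premature-to-all-ages ratio
table = cb.load_lac_burden_2019().set_index(["subregion", "sex", "risk_factor", "age_scope"])
prem = table.loc[("Andean Latin America", "men", "BMI", "premature"), "estimate"]
tot = table.loc[("Andean Latin America", "men", "BMI", "all_ages"), "estimate"]
print(f"Andean men, BMI: premature-to-all-ages ratio {cb.premature_ratio(prem, tot):.2f}%")
```

Output:

```
crude fatal rate 100 (95% CI 90-112) per 100,000 py
dilution: rdr 0.674, correction factor 1.48 (19880 pairs)
corrected RR per 10 mmHg usual SBP: 1.16 (95% CI 1.08-1.25)
Andean men, BMI: premature-to-all-ages ratio 80.60%
```

The simulated truth here is RR 1.02 per mmHg, i.e. `1.02¹⁰ ≈ 1.22` per
10 mmHg of usual SBP: the baseline-exposure fit is attenuated by within-
person variability, and the estimated MacMahon factor (truth 1.50)
de-attenuates it so that the corrected interval covers the truth.  The
final line recomputes a published premature-to-all-ages percentage from
its printed premature and all-ages death counts.

## Command line

Every stage is a subcommand over CSV/YAML files:

```sh
cvburden simulate --seed 1 --outdir run/cohorts
cvburden dilute --participants run/cohorts/participants.csv \
                --repeats run/cohorts/repeats.csv --out run/factors.csv
cvburden impute --pooled run/cohorts/participants.csv -m 50 --seed 1 --outdir run/imputed
cvburden fit --imputed-dir run/imputed --risk-factor sbp --out run/rr.csv
cvburden burden --rr run/rr.csv --exposure surface.csv --deaths deaths.csv \
                --seed 1 --outdir run/burden
cvburden run --config config.yaml   # full pipeline with a manifest
```

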