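"""Synthetic multi-cohort generator with known ground truth.

The generator emulates a pooled set of prospective cohorts of the kind used
for cardio-metabolic risk factor analyses in Latin America and the
Caribbean: cohort-level heterogeneity in baseline event rates, between- and
within-person exposure variability (so regression-dilution behaviour is
known by construction), log-linear exposure effects on a piecewise-constant
age-specific hazard, administrative censoring, and two-layer missingness
(whole variables unmeasured in a subset of cohorts, then missing completely
at random within cohorts).

Every random quantity derives from one integer seed through fixed named
sub-streams, so stage-level reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .riskfactors import RISK_FACTORS


@dataclass(frozen=True)
class ExposureSpec:
    """Generative description of one risk factor.

    ``sd_between`` is the SD of the person-level "usual" exposure;
    ``sd_within`` the SD of independent measurement-occasion noise.  The
    regression-dilution ratio implied by the pair is
    ``sd_between² / (sd_between² + sd_within²)``.
    """

    mean: float
    sd_between: float
    sd_within: float
    unit: str
    floor: float = -np.inf


def _default_exposures() -> dict[str, ExposureSpec]:
    # Population means/SDs follow the pooled LAC cohort profile (BMI 27.2
    # kg/m² SD 4.8, SBP 131 mmHg SD 22.1, FPG 5.5 mmol/L SD 1.9, TC 5.3
    # mmol/L SD 1.3, non-HDL 4.2 mmol/L SD 1.3).  The between/within split
    # of each total SD reproduces the regression-dilution correction
    # factors reported for those cohorts (1.10, 1.50, 1.53, 1.75, 1.85):
    # lambda = 1/factor, sd_between = sd_total * sqrt(lambda).
    totals = {"bmi": (27.2, 4.8, 1.10), "sbp": (131.0, 22.1, 1.50),
              "fpg": (5.5, 1.9, 1.53), "tc": (5.3, 1.3, 1.75),
              "non_hdl": (4.2, 1.3, 1.85)}
    out = {}
    for key, (mean, sd, factor) in totals.items():
        lam = 1.0 / factor
        rf = RISK_FACTORS[key]
        out[key] = ExposureSpec(
            mean=mean,
            sd_between=sd * np.sqrt(lam),
            sd_within=sd * np.sqrt(1.0 - lam),
            unit=rf.unit,
            floor=rf.floor,
        )
    return out


def _default_log_rr() -> dict[str, float]:
    # Log incidence-rate ratios per canonical unit of usual exposure, in
    # the range reported by large cohort poolings (e.g. roughly RR 1.5-2
    # per 20 mmHg usual SBP at middle age).
    return {"bmi": 0.06, "sbp": 0.02, "fpg": 0.12, "tc": 0.18, "non_hdl": 0.22}


def _default_baseline_rates() -> dict[float, float]:
    # CVD event rates per person-year by attained-age band (events rise
    # steeply with age; the overall crude rate in the default population is
    # on the order of 100-150 per 100,000 person-years).
    return {20.0: 3e-5, 35.0: 1.5e-4, 45.0: 4e-4, 55.0: 1.2e-3,
            65.0: 3e-3, 75.0: 8e-3, 85.0: 2e-2}


@dataclass(frozen=True)
class MissingSpec:
    """Two-layer missingness: a cohort may not measure a variable at all
    (protocol-level), then individual values go missing at random."""

    cohort_unmeasured_prob: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.10, "sbp": 0.55, "fpg": 0.65,
                                 "tc": 0.60, "non_hdl": 0.70}
    )
    mcar_rate: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    n_cohorts: int = 20
    n_per_cohort: int = 2000
    age_range: tuple[float, float] = (25.0, 70.0)
    sex_fraction_female: float = 0.837
    exposures: dict[str, ExposureSpec] = field(default_factory=_default_exposures)
    true_log_rr: dict[str, float] = field(default_factory=_default_log_rr)
    baseline_rate_by_age: dict[float, float] = field(default_factory=_default_baseline_rates)
    cohort_intercept_sd: float = 0.3
    sex_log_rr_male: float = 0.4
    followup_years: float = 8.9
    repeat_measure_times: tuple[float, ...] = (3.0,)
    repeat_cohort_fraction: float = 0.32
    fatal_fraction: float = 0.54
    missing: MissingSpec = field(default_factory=MissingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts <= 0:
            raise ValueError("n_cohorts must be positive")
        if self.n_per_cohort <= 0:
            raise ValueError("n_per_cohort must be positive")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must be in [0, 1]")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.cohort_intercept_sd < 0:
            raise ValueError("cohort_intercept_sd must be >= 0")
        if not 0.0 <= self.fatal_fraction <= 1.0:
            raise ValueError("fatal_fraction must be in [0, 1]")
        if not 0.0 <= self.repeat_cohort_fraction <= 1.0:
            raise ValueError("repeat_cohort_fraction must be in [0, 1]")
        for key, spec in self.exposures.items():
            if spec.sd_between < 0:
                raise ValueError(f"sd_between for {key!r} must be >= 0")
            if spec.sd_within < 0:
                raise ValueError(f"sd_within for {key!r} must be >= 0")
        for age, rate in self.baseline_rate_by_age.items():
            if rate <= 0:
                raise ValueError(f"baseline rate at age {age} must be positive")
        if not 0.0 <= self.missing.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must be in [0, 1]")
        for key, p in self.missing.cohort_unmeasured_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cohort_unmeasured_prob for {key!r} must be in [0, 1]")


@dataclass
class SyntheticCohortSet:
    """A generated multi-cohort dataset plus everything needed to score
    downstream estimates against the truth."""

    participants: pd.DataFrame     # observed data after missingness
    repeats: pd.DataFrame          # long (participant_id, cohort_id, time, risk_factor, value)
    complete: pd.DataFrame         # observed data before missingness was applied
    true_exposures: pd.DataFrame   # person-level usual exposures
    cohort_intercepts: pd.Series   # realized cohort log-rate random effects
    truth: SimulationConfig


_STREAMS = {
    "intercepts": 1, "sex": 2, "age": 3, "true_exposure": 4,
    "measurement": 5, "event": 6, "fatal": 7, "missing_cohort": 8,
    "missing_mcar": 9, "repeat_cohorts": 10,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    """Normal draws with re-sampling below the floor (keeps moments close
    to nominal for floors several SDs out)."""
    x = rng.normal(mean, sd, size)
    if sd == 0 or not np.isfinite(floor):
        return np.maximum(x, floor) if np.isfinite(floor) else x
    for _ in range(100):
        bad = x < floor
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(x, floor)


def _piecewise_event_times(
    entry_age: np.ndarray,
    horizon: float,
    multiplier: np.ndarray,
    rate_by_age: dict[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw event times under a piecewise-constant age-specific hazard
    scaled per person, censored administratively at ``horizon`` years.

    Returns (followup_time, event_indicator).
    """
    edges = np.array(sorted(rate_by_age))
    rates = np.array([rate_by_age[a] for a in edges])
    # ages below the first configured band use the first band's rate
    lower = np.concatenate([[0.0], edges[1:]])
    upper = np.concatenate([edges[1:], [np.inf]])
    n = len(entry_age)
    target = rng.exponential(1.0, n) / multiplier  # baseline cum-hazard at event
    consumed = np.zeros(n)
    event = np.zeros(n, dtype=bool)
    t_event = np.full(n, horizon)
    exit_age = entry_age + horizon
    for k in range(len(rates)):
        seg_lo = np.maximum(entry_age, lower[k])
        seg_hi = np.minimum(exit_age, upper[k])
        dur = np.maximum(seg_hi - seg_lo, 0.0)
        h = rates[k] * dur
        hit = ~event & (dur > 0) & (target < consumed + h)
        t_event = np.where(
            hit, seg_lo + (target - consumed) / rates[k] - entry_age, t_event
        )
        event |= hit
        consumed += h
    return t_event, event


def generate_cohorts(config: SimulationConfig) -> SyntheticCohortSet:
    """Generate a multi-cohort dataset under ``config``.

    True ("usual") exposures are drawn per person from the between-person
    distribution; the baseline measurement and every scheduled repeat add
    independent within-person noise.  Event times follow a
    piecewise-constant attained-age hazard scaled by
    ``exp(cohort intercept + sex effect + Σ β · (true exposure − mean))``,
    censored at the administrative horizon.  Fatal vs non-fatal labels are
    independent Bernoulli draws at event time.
    """
    cfg = config
    n = cfg.n_cohorts * cfg.n_per_cohort
    cohort_ids = np.repeat([f"cohort_{i:02d}" for i in range(cfg.n_cohorts)], cfg.n_per_cohort)

    intercepts = _rng(cfg.seed, "intercepts").normal(0.0, cfg.cohort_intercept_sd, cfg.n_cohorts)
    u = np.repeat(intercepts, cfg.n_per_cohort)

    female = _rng(cfg.seed, "sex").random(n) < cfg.sex_fraction_female
    age0 = _rng(cfg.seed, "age").uniform(cfg.age_range[0], cfg.age_range[1], n)

    rng_true = _rng(cfg.seed, "true_exposure")
    rng_meas = _rng(cfg.seed, "measurement")
    true_vals, obs_vals = {}, {}
    log_mult = u + cfg.sex_log_rr_male * (~female)
    for key, spec in cfg.exposures.items():
        tv = _truncated_normal(rng_true, spec.mean, spec.sd_between, spec.floor, n)
        true_vals[key] = tv
        obs_vals[key] = tv + rng_meas.normal(0.0, spec.sd_within, n)
        log_mult = log_mult + cfg.true_log_rr.get(key, 0.0) * (tv - spec.mean)

    followup, event = _piecewise_event_times(
        age0, cfg.followup_years, np.exp(log_mult),
        cfg.baseline_rate_by_age, _rng(cfg.seed, "event"),
    )
    fatal = event & (_rng(cfg.seed, "fatal").random(n) < cfg.fatal_fraction)

    participants = pd.DataFrame(
        {
            "participant_id": [f"p{i:07d}" for i in range(n)],
            "cohort_id": cohort_ids,
            "sex": np.where(female, "female", "male"),
            "age_baseline": age0,
            **{k: obs_vals[k] for k in cfg.exposures},
            "followup_time": followup,
            "event_fatal": fatal.astype(int),
            "event_nonfatal": (event & ~fatal).astype(int),
        }
    )
    true_exposures = pd.DataFrame(
        {"participant_id": participants["participant_id"], **true_vals}
    )

    # repeat measurements, in the subset of cohorts with a repeat protocol
    rng_rep = _rng(cfg.seed, "repeat_cohorts")
    n_rep_cohorts = int(round(cfg.repeat_cohort_fraction * cfg.n_cohorts))
    rep_cohorts = set(
        np.array(sorted(set(cohort_ids)))[
            rng_rep.permutation(cfg.n_cohorts)[:n_rep_cohorts]
        ]
    )
    rep_rows = []
    in_rep = participants["cohort_id"].isin(rep_cohorts).to_numpy()
    for t_meas in cfg.repeat_measure_times:
        alive = participants["followup_time"].to_numpy() >= t_meas
        m = in_rep & alive
        for key, spec in cfg.exposures.items():
            vals = true_vals[key][m] + rng_meas.normal(0.0, spec.sd_within, int(m.sum()))
            rep_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": participants["participant_id"].to_numpy()[m],
                        "cohort_id": participants["cohort_id"].to_numpy()[m],
                        "time": t_meas,
                        "risk_factor": key,
                        "value": vals,
                    }
                )
            )
    repeats = (
        pd.concat(rep_rows, ignore_index=True)
        if rep_rows
        else pd.DataFrame(columns=["participant_id", "cohort_id", "time", "risk_factor", "value"])
    )

    complete = participants.copy()

    # cohort-level unmeasured variables, then within-cohort MCAR
    rng_mc = _rng(cfg.seed, "missing_cohort")
    rng_mcar = _rng(cfg.seed, "missing_mcar")
    unmeasured: dict[str, set[str]] = {}
    all_cohorts = sorted(set(cohort_ids))
    for key in cfg.exposures:
        p = cfg.missing.cohort_unmeasured_prob.get(key, 0.0)
        drop = {c for c in all_cohorts if rng_mc.random() < p}
        unmeasured[key] = drop
        mask = participants["cohort_id"].isin(drop).to_numpy()
        mask |= rng_mcar.random(n) < cfg.missing.mcar_rate
        participants.loc[mask, key] = np.nan
    if len(repeats):
        drop_mask = np.zeros(len(repeats), dtype=bool)
        for key, drop in unmeasured.items():
            drop_mask |= (repeats["risk_factor"] == key).to_numpy() & repeats[
                "cohort_id"
            ].isin(drop).to_numpy()
        repeats = repeats.loc[~drop_mask].reset_index(drop=True)

    return SyntheticCohortSet(
        participants=participants,
        repeats=repeats,
        complete=complete,
        true_exposures=true_exposures,
        cohort_intercepts=pd.Series(intercepts, index=all_cohorts, name="intercept"),
        truth=cfg,
    )


def write_cohort_set(cohorts: SyntheticCohortSet, outdir) -> None:
    """Write participants/repeats CSVs plus a YAML truth sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts.participants.to_csv(out / "participants.csv", index=False)
    cohorts.repeats.to_csv(out / "repeats.csv", index=False)
    def plain(obj):
        if isinstance(obj, dict):
            return {plain(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.str_):
            return str(obj)
        return obj

    truth = dataclasses.asdict(cohorts.truth)
    truth["exposures"] = {k: dataclasses.asdict(v) for k, v in cohorts.truth.exposures.items()}
    truth["cohort_intercepts"] = dict(cohorts.cohort_intercepts.items())
    truth = plain(truth)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, default_flow_style=False)


# ---------------------------------------------------------------------------
# synthetic country-level inputs for the burden stage


def synthetic_exposure_surface(
    countries: list[str], seed: int = 0, sexes: tuple[str, str] = ("female", "male")
) -> pd.DataFrame:
    """Country × sex × 5-year-age mean exposure levels with plausible age
    gradients (e.g. SBP rising ~0.5 mmHg/year of age from a country-specific
    young-adult level)."""
    from .burden import FIVE_YEAR_GROUPS, group_midpoint

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    base = {"bmi": (26.0, 1.2, 0.02), "sbp": (118.0, 4.0, 0.45),
            "tc": (4.6, 0.25, 0.012), "non_hdl": (3.5, 0.25, 0.012)}
    rows = []
    for country in countries:
        offsets = {k: rng.normal(0, s) for k, (_, s, _) in base.items()}
        for sex in sexes:
            for grp in FIVE_YEAR_GROUPS:
                mid = group_midpoint(grp)
                for key, (level, _, slope) in base.items():
                    val = level + offsets[key] + slope * (mid - 20.0)
                    val += 0.5 if (sex == "male" and key == "sbp") else 0.0
                    rows.append((country, sex, grp, key, val))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "risk_factor", "mean_level"])


def synthetic_mortality_table(
    countries: list[str], seed: int = 0, sexes: tuple[str, str] = ("female", "male")
) -> pd.DataFrame:
    """Country × sex × 5-year-age CVD deaths and population, with a
    Gompertz-like rise of CVD mortality with age over a declining adult
    population pyramid."""
    from .burden import FIVE_YEAR_GROUPS, group_midpoint

    rng = np.random.default_rng(np.random.SeedSequence([seed, 102]))
    rows = []
    for country in countries:
        adult_pop = rng.uniform(5e5, 3e7)
        for sex in sexes:
            weights = np.array(
                [np.exp(-0.03 * (group_midpoint(g) - 20.0)) for g in FIVE_YEAR_GROUPS]
            )
            pops = adult_pop / 2.0 * weights / weights.sum()
            for grp, pop in zip(FIVE_YEAR_GROUPS, pops):
                mid = group_midpoint(grp)
                rate = 3e-5 * np.exp(0.085 * (mid - 20.0))  # per person-year
                rate *= 1.25 if sex == "male" else 1.0
                deaths = rng.poisson(rate * pop)
                rows.append((country, sex, grp, int(deaths), float(pop)))
    return pd.DataFrame(rows, columns=["country", "sex", "age_group", "deaths", "population"])
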