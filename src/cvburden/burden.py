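"""Comparative risk assessment: PAFs, attributable deaths, rates, ratios.

Age-band relative risks are interpolated to 5-year age groups (linear in
log RR across band midpoints, flat beyond the outermost midpoints).  For
each country × sex × age stratum the population attributable fraction
against an optimal (theoretical-minimum-risk) mean exposure is

    PAF = 1 - exp(-beta * max(0, mean_current - mean_optimal)),

which for a log-linear RR under a pure shift of the population mean (the
spread unchanged) is exactly the distributional PAF — the exposure
distribution cancels in the ratio of expected risks.  Attributable deaths
are PAF × CVD deaths per stratum; crude rates divide by adult population;
credible intervals propagate RR uncertainty by Monte Carlo.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import integrate

logger = logging.getLogger(__name__)


def _pctl(arr, q):
    arr = np.asarray(arr, dtype=float)
    if not np.isfinite(arr).any():
        return math.nan
    return float(np.nanpercentile(arr, q))


#: 5-year age groups from 20 to 85+ (labels "20-24" … "80-84", "85+").
FIVE_YEAR_STARTS = tuple(range(20, 90, 5))
FIVE_YEAR_GROUPS = tuple(
    f"{a}+" if a == 85 else f"{a}-{a + 4}" for a in FIVE_YEAR_STARTS
)

#: Conventional theoretical-minimum-risk exposure levels (canonical units).
DEFAULT_OPTIMAL_LEVELS = {"bmi": 21.0, "sbp": 115.0, "tc": 3.8, "non_hdl": 2.6}

PREMATURE_CUTOFF = 70.0


def group_start(group: str) -> float:
    return float(group.rstrip("+").split("-")[0])


def group_midpoint(group: str) -> float:
    """Evaluation age of a 5-year group; the open-ended 85+ group uses 90,
    matching the midpoint convention of the open-ended model band."""
    a = group_start(group)
    return 90.0 if group.endswith("+") else a + 2.5


def _band_mid(band: str) -> float:
    if band.endswith("+"):
        return float(band.rstrip("+")) + 5.0
    a, b = band.split("-")
    return (float(a) + float(b) + 1.0) / 2.0


def interpolate_rr_5y(rr_table: pd.DataFrame) -> pd.DataFrame:
    """Interpolate age-band log RRs onto the 5-year age groups.

    ``rr_table`` needs columns band, log_rr, se (one risk factor; bands
    like "35-44" or "85+").  Log RR is linear in age between band
    midpoints and flat beyond them, so every age group from 20-24 up is
    assigned a value; the same scheme is applied to the SE.
    """
    if rr_table.empty:
        raise ValueError("empty relative-risk table")
    tab = rr_table.copy()
    tab["age_mid"] = tab["band"].map(_band_mid)
    tab = tab.sort_values("age_mid")
    if len(tab) == 1:
        warnings.warn("single age band: using a constant relative-risk surface")
    mids = np.array([group_midpoint(g) for g in FIVE_YEAR_GROUPS])
    log_rr = np.interp(mids, tab["age_mid"], tab["log_rr"])
    se = np.interp(mids, tab["age_mid"], tab["se"])
    out = pd.DataFrame(
        {"age_group": FIVE_YEAR_GROUPS, "log_rr": log_rr, "se": se}
    )
    if "risk_factor" in tab.columns:
        out.insert(0, "risk_factor", tab["risk_factor"].iloc[0])
    return out


def interpolate_log_rr(rr_table: pd.DataFrame, ages) -> np.ndarray:
    """Evaluate the interpolated log-RR surface at arbitrary ages."""
    tab = rr_table.copy()
    tab["age_mid"] = tab["band"].map(_band_mid)
    tab = tab.sort_values("age_mid")
    return np.interp(np.asarray(ages, dtype=float), tab["age_mid"], tab["log_rr"])


# ---------------------------------------------------------------------------
# PAF


def paf(log_rr, mean_current, mean_optimal):
    """Population attributable fraction for a mean shift to the optimal
    level; zero when the current mean is already at or below optimal."""
    delta = np.maximum(0.0, np.asarray(mean_current, float) - np.asarray(mean_optimal, float))
    return 1.0 - np.exp(-np.asarray(log_rr, float) * delta)


def paf_numeric(log_rr: float, mean_current: float, sd: float, mean_optimal: float) -> float:
    """Quadrature cross-check of :func:`paf` for a normal exposure under a
    pure mean shift (spread unchanged)."""
    delta = max(0.0, mean_current - mean_optimal)

    def expected_rr(mu):
        f = lambda x: np.exp(log_rr * x) * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi)
        )
        val, _ = integrate.quad(f, mu - 12 * sd, mu + 12 * sd, limit=200)
        return val

    cur = expected_rr(mean_current)
    cf = expected_rr(mean_current - delta)
    return 1.0 - cf / cur


# ---------------------------------------------------------------------------
# attributable deaths and rates


_STRATA = ["country", "sex", "age_group"]


def attributable_deaths(paf_table: pd.DataFrame, deaths_table: pd.DataFrame) -> pd.DataFrame:
    """Attributable deaths per stratum: PAF × CVD deaths.

    ``paf_table`` has columns country, sex, age_group, risk_factor, paf;
    ``deaths_table`` has country, sex, age_group, deaths (and optionally
    population).  A stratum present in one table but not the other is a
    hard error listing the strata involved.
    """
    left = set(map(tuple, paf_table[_STRATA].drop_duplicates().itertuples(index=False)))
    right = set(map(tuple, deaths_table[_STRATA].drop_duplicates().itertuples(index=False)))
    if left != right:
        missing = sorted(left ^ right)[:20]
        raise ValueError(f"strata mismatch between PAF and deaths tables: {missing}")
    merged = paf_table.merge(deaths_table, on=_STRATA, validate="many_to_one")
    merged["attributable"] = merged["paf"] * merged["deaths"]
    return merged


def crude_attrib_rate(attrib_deaths, population, per: float = 1e5):
    """Crude attributable death rate per ``per`` population."""
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive")
    return np.asarray(attrib_deaths, dtype=float) / population * per


def premature_ratio(premature, all_ages):
    """Premature-to-all-ages percentage: 100 × (deaths at 20-69) / (deaths
    at 20+).  Undefined (NaN) when the all-ages total is zero."""
    premature = np.asarray(premature, dtype=float)
    all_ages = np.asarray(all_ages, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(all_ages == 0, np.nan, 100.0 * premature / all_ages)
    return float(out) if out.ndim == 0 else out


def premature_ratio_table(cells: pd.DataFrame, value: str = "attributable",
                          by=("country", "sex", "risk_factor")) -> pd.DataFrame:
    """Premature (20-69) and all-ages (20+) totals plus their ratio, from
    age-group-level cells."""
    by = list(by)
    cells = cells.copy()
    cells["premature"] = cells["age_group"].map(group_start) < PREMATURE_CUTOFF
    total = cells.groupby(by)[value].sum().rename("all_ages")
    prem = cells.loc[cells["premature"]].groupby(by)[value].sum().rename("premature")
    out = pd.concat([total, prem], axis=1).fillna({"premature": 0.0}).reset_index()
    out["ratio_pct"] = premature_ratio(out["premature"], out["all_ages"])
    return out


def aggregate_subregion(
    country_table: pd.DataFrame,
    subregion_map: dict[str, str],
    value: str = "attributable",
) -> pd.DataFrame:
    """Sum attributable deaths and population within sub-regions and
    recompute the crude rate from the sums (equal to the population-
    weighted mean of country rates)."""
    unmapped = set(country_table["country"].astype(str)) - set(subregion_map)
    if unmapped:
        raise ValueError(f"countries missing from sub-region map: {sorted(unmapped)}")
    tab = country_table.copy()
    tab["subregion"] = tab["country"].astype(str).map(subregion_map)
    keys = ["subregion"] + [
        c for c in ("sex", "risk_factor") if c in tab.columns
    ]
    agg = tab.groupby(keys)[[value, "population"]].sum().reset_index()
    agg["rate_per_100k"] = crude_attrib_rate(agg[value], agg["population"])
    return agg


# ---------------------------------------------------------------------------
# full chain and Monte Carlo intervals


def compute_burden(
    rr_5y: pd.DataFrame,
    exposure_surface: pd.DataFrame,
    deaths_table: pd.DataFrame,
    optimal_levels: dict[str, float] | None = None,
) -> pd.DataFrame:
    """PAF and attributable deaths for every country × sex × age group ×
    risk factor stratum.

    ``rr_5y`` holds risk_factor, age_group, log_rr, se (the same RRs are
    used for both sexes); ``exposure_surface`` holds country, sex,
    age_group, risk_factor, mean_level; ``deaths_table`` holds country,
    sex, age_group, deaths, population.
    """
    optimal_levels = dict(DEFAULT_OPTIMAL_LEVELS if optimal_levels is None else optimal_levels)
    missing_rf = set(exposure_surface["risk_factor"]) - set(optimal_levels)
    if missing_rf:
        raise ValueError(f"no optimal level configured for: {sorted(missing_rf)}")
    surf = exposure_surface.merge(rr_5y, on=["risk_factor", "age_group"], validate="many_to_one")
    surf["paf"] = paf(
        surf["log_rr"], surf["mean_level"], surf["risk_factor"].map(optimal_levels)
    )
    cells = attributable_deaths(
        surf[_STRATA + ["risk_factor", "paf"]], deaths_table
    )
    return cells


def monte_carlo_ci(
    rr_5y: pd.DataFrame,
    exposure_surface: pd.DataFrame,
    deaths_table: pd.DataFrame,
    optimal_levels: dict[str, float] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    subregion_map: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Percentile credible intervals from Monte Carlo draws of the log RRs.

    Each (risk factor, age group) log RR is drawn from Normal(point, se)
    and the whole PAF → attributable-deaths chain is recomputed per draw.
    Returns country-level totals (all ages, premature, ratio) with 2.5th
    and 97.5th percentile bounds, plus sub-region totals when a map is
    given.  Deterministic given ``seed``.
    """
    optimal_levels = dict(DEFAULT_OPTIMAL_LEVELS if optimal_levels is None else optimal_levels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 301]))

    surf = exposure_surface.merge(rr_5y, on=["risk_factor", "age_group"], validate="many_to_one")
    surf = surf.merge(deaths_table, on=_STRATA, validate="many_to_one")
    delta = np.maximum(
        0.0, surf["mean_level"].to_numpy() - surf["risk_factor"].map(optimal_levels).to_numpy()
    )
    deaths = surf["deaths"].to_numpy(float)
    prem = surf["age_group"].map(group_start).to_numpy() < PREMATURE_CUTOFF

    # one normal draw per (risk factor, age group), shared across strata
    rr_key = surf[["risk_factor", "age_group"]].apply(tuple, axis=1)
    uniq = rr_5y[["risk_factor", "age_group"]].apply(tuple, axis=1)
    key_idx = rr_key.map({k: i for i, k in enumerate(uniq)}).to_numpy()
    draws = rng.normal(
        rr_5y["log_rr"].to_numpy()[None, :],
        rr_5y["se"].to_numpy()[None, :],
        size=(n_draws, len(rr_5y)),
    )

    attrib = (1.0 - np.exp(-draws[:, key_idx] * delta[None, :])) * deaths[None, :]

    group_keys = ["country", "sex", "risk_factor"]
    codes, uniques = pd.factorize(surf[group_keys].apply(tuple, axis=1))
    n_groups = len(uniques)

    def group_sums(mat, mask=None):
        w = mat if mask is None else mat * mask[None, :]
        out = np.zeros((mat.shape[0], n_groups))
        np.add.at(out.T, codes, w.T)
        return out

    tot = group_sums(attrib)
    prem_tot = group_sums(attrib, prem.astype(float))

    point = compute_burden(rr_5y, exposure_surface, deaths_table, optimal_levels)
    point_tab = premature_ratio_table(point, by=group_keys)
    point_tab = point_tab.set_index(point_tab[group_keys].apply(tuple, axis=1))

    rows = []
    for g, key in enumerate(uniques):
        pt = point_tab.loc[[key]].iloc[0]
        ratio = np.where(tot[:, g] > 0, 100.0 * prem_tot[:, g] / tot[:, g], np.nan)
        rows.append(
            {
                "country": key[0], "sex": key[1], "risk_factor": key[2],
                "all_ages": pt["all_ages"],
                "all_ages_low": np.percentile(tot[:, g], 2.5),
                "all_ages_high": np.percentile(tot[:, g], 97.5),
                "premature": pt["premature"],
                "premature_low": np.percentile(prem_tot[:, g], 2.5),
                "premature_high": np.percentile(prem_tot[:, g], 97.5),
                "ratio_pct": pt["ratio_pct"],
                "ratio_low": _pctl(ratio, 2.5),
                "ratio_high": _pctl(ratio, 97.5),
            }
        )
    country = pd.DataFrame(rows)
    out = {"country": country}

    if subregion_map is not None:
        unmapped = set(country["country"]) - set(subregion_map)
        if unmapped:
            raise ValueError(f"countries missing from sub-region map: {sorted(unmapped)}")
        sub_codes, sub_uniq = pd.factorize(
            surf["country"].map(subregion_map).astype(str) + "|" + surf["sex"] + "|" + surf["risk_factor"]
        )
        n_sub = len(sub_uniq)
        sub_tot = np.zeros((n_draws, n_sub))
        sub_prem = np.zeros((n_draws, n_sub))
        np.add.at(sub_tot.T, sub_codes, attrib.T)
        np.add.at(sub_prem.T, sub_codes, (attrib * prem[None, :]).T)
        point_attr = point.copy()
        point_attr["subregion"] = point_attr["country"].map(subregion_map)
        sub_point = premature_ratio_table(point_attr, by=["subregion", "sex", "risk_factor"])
        sub_point = sub_point.set_index(
            sub_point["subregion"] + "|" + sub_point["sex"] + "|" + sub_point["risk_factor"]
        )
        sub_rows = []
        for g, key in enumerate(sub_uniq):
            sr, sex, rf = key.split("|")
            pt = sub_point.loc[key]
            ratio = np.where(sub_tot[:, g] > 0, 100.0 * sub_prem[:, g] / sub_tot[:, g], np.nan)
            sub_rows.append(
                {
                    "subregion": sr, "sex": sex, "risk_factor": rf,
                    "all_ages": pt["all_ages"],
                    "all_ages_low": np.percentile(sub_tot[:, g], 2.5),
                    "all_ages_high": np.percentile(sub_tot[:, g], 97.5),
                    "premature": pt["premature"],
                    "premature_low": np.percentile(sub_prem[:, g], 2.5),
                    "premature_high": np.percentile(sub_prem[:, g], 97.5),
                    "ratio_pct": pt["ratio_pct"],
                    "ratio_low": _pctl(ratio, 2.5),
                    "ratio_high": _pctl(ratio, 97.5),
                }
            )
        out["subregion"] = pd.DataFrame(sub_rows)
    return out
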