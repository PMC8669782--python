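"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("cvburden") / "data"


def load_lac_burden_2019() -> pd.DataFrame:
    """Published estimates of cardiovascular deaths in 2019 attributable to
    each cardio-metabolic risk factor in Latin America and the Caribbean,
    by sub-region and sex, with 95% credible intervals.

    One row per (subregion, sex, risk_factor, age_scope) where age_scope is
    ``all_ages`` (20+) or ``premature`` (20-69); columns estimate, lower,
    upper are death counts.
    """
    with resources.as_file(_DATA / "lac_attributable_cvd_deaths_2019.csv") as p:
        return pd.read_csv(p)


def load_lac_premature_ratios_2019() -> pd.DataFrame:
    """Published premature-to-all-ages percentages matching
    :func:`load_lac_burden_2019` (columns ratio, ratio_lower, ratio_upper)."""
    with resources.as_file(_DATA / "lac_premature_ratios_2019.csv") as p:
        return pd.read_csv(p)


def load_correction_factors() -> pd.DataFrame:
    """Regression-dilution correction factors estimated from LAC cohorts
    with repeat measurements (columns risk_factor, factor, n_pairs;
    pair counts were not published and are recorded as 0)."""
    with resources.as_file(_DATA / "correction_factors.csv") as p:
        return pd.read_csv(p)
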