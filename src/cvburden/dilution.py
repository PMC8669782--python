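"""Regression-dilution ratios from repeat measurements (MacMahon method).

A one-off baseline measurement understates the association between
"usual" exposure and outcome because of within-person variability.  With
repeat measurements, the regression-dilution ratio (RDR) is estimated by
grouping participants into baseline quantiles and regressing the group
means of the repeat on the group means of the baseline; the correction
factor 1/RDR multiplies log relative risks (and their SEs) estimated
from the baseline measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionFactor:
    risk_factor: str
    rdr: float
    factor: float
    n_pairs: int
    cohorts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isclose(self.rdr * self.factor, 1.0):
            raise ValueError("factor must be the reciprocal of rdr")


def build_pairs(
    participants: pd.DataFrame,
    repeats: pd.DataFrame,
    risk_factor: str,
    min_gap_years: float = 1.0,
) -> pd.DataFrame:
    """Baseline/repeat value pairs for one risk factor.

    When a participant has several repeats, the first one at least
    ``min_gap_years`` after baseline is used (short gaps share correlated
    measurement error and overstate reproducibility).
    """
    reps = repeats.loc[
        (repeats["risk_factor"] == risk_factor) & (repeats["time"] >= min_gap_years)
    ]
    reps = reps.sort_values("time").drop_duplicates("participant_id", keep="first")
    base = participants[["participant_id", "cohort_id", risk_factor]].rename(
        columns={risk_factor: "baseline"}
    )
    pairs = base.merge(
        reps[["participant_id", "value"]].rename(columns={"value": "repeat"}),
        on="participant_id",
    )
    pairs = pairs.dropna(subset=["baseline", "repeat"])
    pairs["risk_factor"] = risk_factor
    return pairs.reset_index(drop=True)


def macmahon_rdr(baseline, repeat, n_groups: int = 5) -> float:
    """Regression-dilution ratio by the grouped-means (MacMahon) method.

    Pairs are grouped by baseline quantile (quintiles by default); the RDR
    is the least-squares slope of the repeat group means on the baseline
    group means.  With two groups this reduces to the ratio of the ranges
    of the group means.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(repeat, dtype=float)
    if x.shape != y.shape:
        raise ValueError("baseline and repeat must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} pairs for {n_groups} groups")
    if np.ptp(x) == 0:
        raise ValueError("all baseline values identical; dilution slope undefined")
    groups = pd.qcut(x, n_groups, labels=False, duplicates="drop")
    gx = pd.Series(x).groupby(groups).mean().to_numpy()
    gy = pd.Series(y).groupby(groups).mean().to_numpy()
    if len(gx) < 2:
        raise ValueError("baseline distribution too degenerate to form groups")
    slope = np.polyfit(gx, gy, 1)[0]
    return float(slope)


def pool_rdr(per_cohort, risk_factor: str = "") -> CorrectionFactor:
    """Pool per-cohort RDRs as the pair-count-weighted mean.

    ``per_cohort`` is an iterable of (cohort_id, rdr, n_pairs); cohorts
    with zero pairs carry no weight.
    """
    rows = list(per_cohort)
    if not rows:
        raise ValueError("need at least one cohort")
    cohorts = tuple(str(c) for c, _, n in rows if n > 0)
    rdrs = np.array([r for _, r, n in rows if n > 0], dtype=float)
    ns = np.array([n for _, _, n in rows if n > 0], dtype=float)
    if len(rdrs) == 0:
        raise ValueError("no cohort contributed pairs")
    pooled = float(np.average(rdrs, weights=ns))
    return CorrectionFactor(
        risk_factor=risk_factor,
        rdr=pooled,
        factor=1.0 / pooled,
        n_pairs=int(ns.sum()),
        cohorts=cohorts,
    )


def estimate_correction_factor(
    pairs: pd.DataFrame,
    n_groups: int = 5,
    mode: str = "weighted",
) -> CorrectionFactor:
    """Correction factor from a pair table (columns cohort_id, baseline,
    repeat, risk_factor).

    ``mode="weighted"`` estimates an RDR per cohort and pools by pair
    count; ``mode="pooled"`` runs one grouped regression over all pairs.
    """
    rf = str(pairs["risk_factor"].iloc[0]) if len(pairs) else ""
    if mode == "pooled":
        rdr = macmahon_rdr(pairs["baseline"], pairs["repeat"], n_groups)
        return CorrectionFactor(rf, rdr, 1.0 / rdr, len(pairs), tuple(sorted(set(pairs["cohort_id"]))))
    if mode != "weighted":
        raise ValueError(f"unknown mode {mode!r}")
    per_cohort = []
    for cohort, sub in pairs.groupby("cohort_id"):
        if len(sub) < 2 * n_groups:
            logger.warning("cohort %s has too few pairs (%d), skipped", cohort, len(sub))
            continue
        per_cohort.append((cohort, macmahon_rdr(sub["baseline"], sub["repeat"], n_groups), len(sub)))
    return pool_rdr(per_cohort, rf)


def apply_correction(log_rr: float, se: float, factor) -> tuple[float, float]:
    """Scale a log relative risk and its SE by a regression-dilution
    correction factor (the factor is treated as fixed)."""
    f = factor.factor if isinstance(factor, CorrectionFactor) else float(factor)
    if f < 1.0:
        raise ValueError("correction factor must be >= 1")
    return log_rr * f, se * f


def default_correction_factors() -> dict[str, CorrectionFactor]:
    """Packaged correction factors for use when no repeat data are supplied
    (from a pooled LAC cohort analysis of repeat measurements)."""
    from .datasets import load_correction_factors

    table = load_correction_factors()
    return {
        row.risk_factor: CorrectionFactor(
            row.risk_factor, 1.0 / row.factor, row.factor, int(row.n_pairs)
        )
        for row in table.itertuples()
    }
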