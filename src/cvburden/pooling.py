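"""Pooled participant data model, attained-age Lexis expansion, crude rates.

The pooled dataset is a pandas DataFrame with one row per participant:

====================  =======================================================
column                meaning
====================  =======================================================
participant_id        unique within the pooled data
cohort_id             unique cohort label
sex                   "female" / "male"
age_baseline          age at entry, years (>= 20)
bmi, sbp, fpg,        baseline exposures in canonical units (kg/m², mmHg,
tc, non_hdl           mmol/L); NaN where unmeasured
followup_time         years from baseline to event or censoring (> 0)
event_fatal           0/1, fatal cardiovascular event at end of follow-up
event_nonfatal        0/1, non-fatal cardiovascular event at end of follow-up
====================  =======================================================

Incidence is modelled on attained age, so each participant's follow-up is
split into the ten-year age-at-risk bands 35-44 … 75-84, 85+.  Person-time
before age 35 is discarded; bands are half-open ``[a, b)`` in exact
fractional years, so no instant is counted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .riskfactors import EXPOSURE_COLUMNS, KPA_TO_MMHG, MGDL_TO_MMOL, RISK_FACTORS

logger = logging.getLogger(__name__)

#: Attained-age bands used by the age-specific incidence models.
AGE_BANDS: tuple[tuple[float, float], ...] = (
    (35.0, 45.0),
    (45.0, 55.0),
    (55.0, 65.0),
    (65.0, 75.0),
    (75.0, 85.0),
    (85.0, np.inf),
)

MIN_AGE = 20.0


def band_label(band: tuple[float, float]) -> str:
    a, b = band
    return f"{a:.0f}+" if np.isinf(b) else f"{a:.0f}-{b - 1:.0f}"


def band_midpoint(band: tuple[float, float], open_width: float = 10.0) -> float:
    """Midpoint used to centre the age covariate; the open-ended band is
    treated as if it had the same width as the closed ones."""
    a, b = band
    if np.isinf(b):
        return a + open_width / 2.0
    return (a + b) / 2.0


# ---------------------------------------------------------------------------
# pooling


@dataclass
class PoolingReport:
    """Row-level accounting from :func:`pool_cohorts`."""

    n_tables: int = 0
    n_rows: int = 0
    n_invalid: int = 0
    invalid_reasons: dict = field(default_factory=dict)


_CANONICAL_UNITS = {key: rf.unit for key, rf in RISK_FACTORS.items()}


def _convert_column(values: pd.Series, column: str, unit: str) -> pd.Series:
    canonical = _CANONICAL_UNITS[column]
    unit = unit.strip()
    if unit.replace("^", "").replace("²", "2") in (
        canonical.replace("^", ""),
        "kg/m2",
    ) and canonical == "kg/m2":
        return values
    if unit == canonical:
        return values
    if canonical == "mmol/L" and unit.lower() in ("mg/dl", "mg/dL".lower()):
        return values / MGDL_TO_MMOL[column]
    if canonical == "mmHg" and unit.lower() == "kpa":
        return values * KPA_TO_MMHG
    raise ValueError(f"unknown unit {unit!r} for column {column!r}")


def pool_cohorts(
    tables: dict[str, pd.DataFrame],
    unit_maps: dict[str, dict[str, str]] | None = None,
) -> tuple[pd.DataFrame, PoolingReport]:
    """Harmonise and pool participant tables.

    Parameters
    ----------
    tables
        Mapping table name -> participant DataFrame.
    unit_maps
        Mapping table name -> {exposure column: unit label}.  Columns not
        listed are assumed to be in canonical units.

    Returns the pooled DataFrame plus a :class:`PoolingReport`.  Rows that
    violate the participant invariants (age < 20 or non-positive follow-up)
    are dropped and counted; cohort ids are made globally unique by
    prefixing the table name when two tables share a cohort label.
    """
    unit_maps = unit_maps or {}
    report = PoolingReport(n_tables=len(tables))
    seen_cohorts: set[str] = set()
    parts = []
    for name, table in tables.items():
        df = table.copy()
        units = unit_maps.get(name, {})
        for col, unit in units.items():
            if col not in _CANONICAL_UNITS:
                raise ValueError(f"unknown exposure column {col!r} in unit map")
            if col in df.columns:
                df[col] = _convert_column(df[col], col, unit)
        bad_age = df["age_baseline"] < MIN_AGE
        bad_fu = df["followup_time"] <= 0
        n_bad = int((bad_age | bad_fu).sum())
        if n_bad:
            report.invalid_reasons.setdefault(name, {})
            report.invalid_reasons[name]["age_below_20"] = int(bad_age.sum())
            report.invalid_reasons[name]["nonpositive_followup"] = int(bad_fu.sum())
            df = df.loc[~(bad_age | bad_fu)]
        report.n_invalid += n_bad
        clash = set(df["cohort_id"].astype(str)) & seen_cohorts
        if clash:
            df = df.assign(cohort_id=name + ":" + df["cohort_id"].astype(str))
        seen_cohorts |= set(df["cohort_id"].astype(str))
        parts.append(df)
    pooled = pd.concat(parts, ignore_index=True)
    if pooled["participant_id"].duplicated().any():
        # re-key clashing participant ids so the pooled key stays unique
        pooled["participant_id"] = (
            pooled["cohort_id"].astype(str) + ":" + pooled["participant_id"].astype(str)
        )
    report.n_rows = len(pooled)
    return pooled, report


# ---------------------------------------------------------------------------
# Lexis expansion


def lexis_expand(
    participants: pd.DataFrame,
    bands: tuple[tuple[float, float], ...] = AGE_BANDS,
    outcome: str = "fatal",
    carry_columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Split follow-up into attained-age band segments.

    Each band a participant crosses during follow-up (at ages >= the first
    band edge) contributes one segment with its person-time; the event, if
    any, sits in the segment containing the exit age.  An exit age exactly
    on a band edge would fall in a zero-length segment of the next band, so
    the event is attached to the last segment with positive person-time.

    Parameters
    ----------
    participants
        Pooled participant table.
    bands
        Ordered, contiguous half-open bands; the last may be open-ended.
    outcome
        ``"fatal"`` uses ``event_fatal``; ``"combined"`` uses fatal OR
        non-fatal (follow-up is assumed already truncated at first event).
    carry_columns
        Extra columns copied onto every segment (defaults to the exposure
        columns that are present).

    Returns a segment DataFrame with columns participant_id, cohort_id,
    sex, band, entry_age, exit_age, person_time, events, age_at_risk plus
    the carried columns.
    """
    if outcome not in ("fatal", "combined"):
        raise ValueError(f"unknown outcome type {outcome!r}")
    if carry_columns is None:
        carry_columns = tuple(c for c in EXPOSURE_COLUMNS if c in participants.columns)

    lo = float(bands[0][0])
    entry = np.maximum(participants["age_baseline"].to_numpy(float), lo)
    exit_age = (
        participants["age_baseline"].to_numpy(float)
        + participants["followup_time"].to_numpy(float)
    )
    if outcome == "fatal":
        ev = participants["event_fatal"].to_numpy(int)
    else:
        ev = (
            (participants["event_fatal"].to_numpy(int) > 0)
            | (participants["event_nonfatal"].to_numpy(int) > 0)
        ).astype(int)

    keep = exit_age > lo
    base = participants.loc[keep]
    entry, exit_age, ev = entry[keep], exit_age[keep], ev[keep]

    edges = np.array([b[0] for b in bands] + [bands[-1][1]])
    # band containing the exit age (last band catches everything above)
    exit_idx = np.clip(np.searchsorted(edges, exit_age, side="right") - 1, 0, len(bands) - 1)
    # an exit exactly on a band edge leaves zero time in that band: step back
    on_edge = (exit_age == edges[exit_idx]) & (exit_idx > 0)
    exit_idx = np.where(on_edge, exit_idx - 1, exit_idx)

    pieces = []
    for k, (a, b) in enumerate(bands):
        seg_entry = np.clip(entry, a, b)
        seg_exit = np.clip(exit_age, a, b)
        pt = seg_exit - seg_entry
        m = pt > 0
        if not m.any():
            continue
        seg = pd.DataFrame(
            {
                "participant_id": base["participant_id"].to_numpy()[m],
                "cohort_id": base["cohort_id"].to_numpy()[m],
                "sex": base["sex"].to_numpy()[m],
                "band": band_label((a, b)),
                "entry_age": seg_entry[m],
                "exit_age": seg_exit[m],
                "person_time": pt[m],
                "events": (ev[m] * (exit_idx[m] == k)).astype(int),
                "age_at_risk": (seg_entry[m] + seg_exit[m]) / 2.0,
            }
        )
        for c in carry_columns:
            seg[c] = base[c].to_numpy()[m]
        pieces.append(seg)
    if not pieces:
        cols = [
            "participant_id", "cohort_id", "sex", "band", "entry_age",
            "exit_age", "person_time", "events", "age_at_risk", *carry_columns,
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# crude rates


@dataclass(frozen=True)
class CrudeRate:
    events: int
    person_years: float
    rate: float       # per `per` person-years
    ci_low: float
    ci_high: float
    per: float = 1e5


def crude_rate(events: int, person_years: float, per: float = 1e5) -> CrudeRate:
    """Crude event rate with an exact (Garwood) Poisson confidence interval.

    The 95% interval on the count is ``chi2.ppf(.025, 2k)/2`` to
    ``chi2.ppf(.975, 2k+2)/2`` (lower bound 0 when k = 0), scaled by the
    person-years at risk.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    k = int(events)
    lo = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / 2.0
    hi = stats.chi2.ppf(0.975, 2 * k + 2) / 2.0
    scale = per / person_years
    return CrudeRate(k, person_years, k * scale, lo * scale, hi * scale, per)
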