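"""Multiple imputation of missing exposures and Rubin's-rules pooling.

Imputation uses chained equations with predictive mean matching: each
incomplete exposure is regressed on the other exposures, sex, baseline
age, cohort indicators, the event indicator and log follow-up time, and
imputed values are drawn from the k nearest observed donors by predicted
mean.  The chain is run for a fixed number of cycles between successive
imputed datasets.

Per-imputation coefficient estimates are combined with Rubin's rules:
the pooled point is the mean of the m estimates, the total variance is
the mean within-imputation variance plus ``(1 + 1/m)`` times the
between-imputation variance, and the reference t distribution has
``(m - 1) (1 + within / ((1 + 1/m) between))²`` degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

from .riskfactors import EXPOSURE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ImputationStack:
    """m completed copies of the pooled data (observed cells identical
    across copies; only originally-missing cells vary)."""

    datasets: list[pd.DataFrame]
    m: int
    seed: int


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)


def _imputation_frame(data: pd.DataFrame, exposures: tuple[str, ...]) -> pd.DataFrame:
    """Numeric working matrix: exposures + the always-observed predictors."""
    work = data[list(exposures)].copy()
    work["male"] = (data["sex"] == "male").astype(float)
    work["age_baseline"] = data["age_baseline"].astype(float)
    work["log_followup"] = np.log(data["followup_time"].astype(float))
    work["event"] = (
        (data["event_fatal"].astype(int) > 0) | (data["event_nonfatal"].astype(int) > 0)
    ).astype(float)
    cohorts = pd.get_dummies(data["cohort_id"].astype(str), prefix="cohort", drop_first=True)
    return pd.concat([work.reset_index(drop=True), cohorts.astype(float).reset_index(drop=True)], axis=1)


def mi_impute(
    data: pd.DataFrame,
    m: int = 50,
    seed: int = 0,
    exposures: tuple[str, ...] | None = None,
    n_cycles: int = 10,
    k_pmm: int = 5,
) -> ImputationStack:
    """Impute missing exposure values by chained equations with PMM.

    Variables missing for every record cannot be imputed; they are left
    missing and a warning is logged.  Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if exposures is None:
        exposures = tuple(c for c in EXPOSURE_COLUMNS if c in data.columns)

    all_missing = [c for c in exposures if data[c].isna().all()]
    if all_missing:
        logger.warning(
            "variables missing for all records, excluded from imputation: %s",
            ", ".join(all_missing),
        )
    usable = tuple(c for c in exposures if c not in all_missing)
    incomplete = [c for c in usable if data[c].isna().any()]

    if not incomplete:
        return ImputationStack([data.copy() for _ in range(m)], m, seed)

    work = _imputation_frame(data, usable)
    # MICEData draws from numpy's global stream; pin it for reproducibility
    np.random.seed(int(np.random.SeedSequence([seed, 211]).generate_state(1)[0]))
    mice = MICEData(work, k_pmm=k_pmm)

    datasets = []
    for _ in range(m):
        mice.update_all(n_cycles)
        completed = data.copy()
        for col in incomplete:
            completed[col] = mice.data[col].to_numpy()
        datasets.append(completed)
    return ImputationStack(datasets, m, seed)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool m per-imputation estimates and squared SEs with Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have the same length")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules require m >= 2 imputations")
    point = float(est.mean())
    within = float(var.mean())
    # identical estimates have exactly zero between-imputation variance
    between = 0.0 if np.all(est == est[0]) else float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between == 0.0:
        df = math.inf
    else:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    return PooledEstimate(point, within, between, total, df, m)
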