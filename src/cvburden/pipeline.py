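"""End-to-end orchestration of the synthetic pipeline.

``run_pipeline`` executes simulate → pool → dilute → impute → fit →
burden → report on generated cohorts and country tables, persists every
stage's outputs under one directory, and writes a machine-readable
manifest (inputs, seeds, stage file hashes).  Reruns with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .burden import compute_burden, interpolate_rr_5y, monte_carlo_ci, premature_ratio_table
from .dilution import build_pairs, estimate_correction_factor
from .missing import mi_impute
from .models import assemble_rrs, fit_all_bands
from .pooling import crude_rate, lexis_expand
from .riskfactors import RISK_FACTORS
from .synthetic import (
    SimulationConfig,
    generate_cohorts,
    synthetic_exposure_surface,
    synthetic_mortality_table,
    write_cohort_set,
)

logger = logging.getLogger(__name__)

_DEFAULT_COUNTRIES = ["Country A", "Country B", "Country C", "Country D"]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Run the full pipeline from a configuration mapping.

    Required keys: ``seed`` (int), ``outdir`` (path).  Optional keys with
    defaults: n_cohorts 20, n_per_cohort 2000, m_imputations 5,
    risk_factor "sbp", outcome "fatal", n_groups 5, n_draws 1000,
    countries, subregion_map, optimal_levels, complete_case False.

    Returns the manifest dictionary (also written as manifest.json).
    """
    seed = int(cfg["seed"])
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    risk_factor = cfg.get("risk_factor", "sbp")
    outcome = cfg.get("outcome", "fatal")
    m = int(cfg.get("m_imputations", 5))
    countries = cfg.get("countries", _DEFAULT_COUNTRIES)
    subregion_map = cfg.get("subregion_map") or {c: "Region 1" for c in countries}
    complete_case = bool(cfg.get("complete_case", False))

    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _hash_file(p) for p in paths},
        }

    # simulate
    t0 = time.perf_counter()
    sim_cfg = SimulationConfig(
        n_cohorts=int(cfg.get("n_cohorts", 20)),
        n_per_cohort=int(cfg.get("n_per_cohort", 2000)),
        seed=seed,
    )
    cohorts = generate_cohorts(sim_cfg)
    write_cohort_set(cohorts, out / "cohorts")
    record("simulate", t0, sorted((out / "cohorts").glob("*")))

    # crude rate on the pooled data
    t0 = time.perf_counter()
    events = int(cohorts.participants["event_fatal"].sum())
    py = float(cohorts.participants["followup_time"].sum())
    rate = crude_rate(events, py)
    (out / "crude_rate.json").write_text(json.dumps({
        "events": rate.events, "person_years": rate.person_years,
        "rate_per_100k": rate.rate, "ci_low": rate.ci_low, "ci_high": rate.ci_high,
    }, indent=1))
    record("crude_rate", t0, [out / "crude_rate.json"])

    # dilution
    t0 = time.perf_counter()
    pairs = build_pairs(cohorts.participants, cohorts.repeats, risk_factor)
    cf = estimate_correction_factor(pairs, int(cfg.get("n_groups", 5)))
    pd.DataFrame([{"risk_factor": risk_factor, "rdr": cf.rdr, "factor": cf.factor,
                   "n_pairs": cf.n_pairs}]).to_csv(out / "correction_factors.csv", index=False)
    record("dilute", t0, [out / "correction_factors.csv"])

    # impute (or complete-case sensitivity mode)
    t0 = time.perf_counter()
    if complete_case:
        cc = cohorts.participants.dropna(subset=[risk_factor])
        datasets = [cc]
    else:
        stack = mi_impute(cohorts.participants, m=m, seed=seed,
                          exposures=tuple(k for k in RISK_FACTORS
                                          if k in cohorts.participants.columns))
        datasets = stack.datasets
    record("impute", t0, [])

    # fit per imputation
    t0 = time.perf_counter()
    fits = []
    for df in datasets:
        segments = lexis_expand(df.dropna(subset=[risk_factor]), outcome=outcome)
        fits.append(fit_all_bands(segments, risk_factor, outcome=outcome))
    rr_bands = assemble_rrs(fits, cf, RISK_FACTORS[risk_factor].increment)
    rr_bands.to_csv(out / "rr_bands.csv", index=False)
    record("fit", t0, [out / "rr_bands.csv"])

    # burden on synthetic country tables
    t0 = time.perf_counter()
    exposure = synthetic_exposure_surface(countries, seed=seed)
    exposure = exposure.loc[exposure["risk_factor"] == risk_factor].reset_index(drop=True)
    deaths = synthetic_mortality_table(countries, seed=seed)
    rr5 = interpolate_rr_5y(rr_bands.assign(risk_factor=risk_factor))
    cells = compute_burden(rr5, exposure, deaths, cfg.get("optimal_levels"))
    cells.to_csv(out / "burden_cells.csv", index=False)
    summaries = monte_carlo_ci(rr5, exposure, deaths, cfg.get("optimal_levels"),
                               n_draws=int(cfg.get("n_draws", 1000)), seed=seed,
                               subregion_map=subregion_map)
    for name, tab in summaries.items():
        tab.to_csv(out / f"burden_{name}.csv", index=False)
    record("burden", t0,
           [out / "burden_cells.csv"] + [out / f"burden_{n}.csv" for n in summaries])

    # report
    t0 = time.perf_counter()
    ratios = premature_ratio_table(cells)
    ratios.to_csv(out / "premature_ratios.csv", index=False)
    record("report", t0, [out / "premature_ratios.csv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
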