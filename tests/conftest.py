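import numpy as np
import pytest

import cvburden as cb


@pytest.fixture(scope="session")
def small_cohorts():
    """A compact multi-cohort dataset with repeats and missingness."""
    cfg = cb.SimulationConfig(
        n_cohorts=6,
        n_per_cohort=500,
        seed=42,
        missing=cb.MissingSpec({"bmi": 0.1, "sbp": 0.3, "tc": 0.3, "non_hdl": 0.3, "fpg": 0.3}, 0.1),
        repeat_cohort_fraction=0.5,
    )
    return cb.generate_cohorts(cfg)


@pytest.fixture(scope="session")
def single_band_cohorts():
    """Dense single-band data for model fits: entry ages keep everyone in
    35+ for the whole follow-up, constant baseline hazard."""
    cfg = cb.SimulationConfig(
        n_cohorts=8,
        n_per_cohort=800,
        seed=7,
        age_range=(45.0, 62.0),
        followup_years=8.0,
        true_log_rr={"sbp": 0.02},
        exposures={
            "sbp": cb.ExposureSpec(131.0, 22.1 * np.sqrt(2 / 3), 22.1 * np.sqrt(1 / 3), "mmHg", 60.0)
        },
        baseline_rate_by_age={35.0: 2e-3},
        cohort_intercept_sd=0.3,
        missing=cb.MissingSpec({}, 0.0),
        repeat_cohort_fraction=1.0,
    )
    return cb.generate_cohorts(cfg)


@pytest.fixture(scope="session")
def single_band_segments(single_band_cohorts):
    return cb.lexis_expand(single_band_cohorts.participants, bands=((35.0, np.inf),))
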