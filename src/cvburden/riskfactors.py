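"""Registry of the cardio-metabolic risk factors handled by the pipeline.

Canonical units are kg/m² for body mass index, mmHg for systolic blood
pressure, and mmol/L for the blood biomarkers (fasting plasma glucose,
total cholesterol, non-HDL cholesterol).  All modules exchange exposures
in these units; unit conversion happens once, at pooling time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RiskFactor:
    """Static description of one exposure column."""

    key: str              # canonical column name
    display: str          # name used in reports
    unit: str             # canonical unit
    floor: float          # physiologic floor used when simulating
    increment: float      # conventional display increment for relative risks


RISK_FACTORS: dict[str, RiskFactor] = {
    "bmi": RiskFactor("bmi", "BMI", "kg/m2", floor=10.0, increment=5.0),
    "sbp": RiskFactor("sbp", "SBP", "mmHg", floor=60.0, increment=10.0),
    "fpg": RiskFactor("fpg", "FPG", "mmol/L", floor=2.0, increment=1.0),
    "tc": RiskFactor("tc", "TC", "mmol/L", floor=1.5, increment=1.0),
    "non_hdl": RiskFactor("non_hdl", "non-HDL", "mmol/L", floor=0.3, increment=1.0),
}

EXPOSURE_COLUMNS = tuple(RISK_FACTORS)

#: mg/dL -> mmol/L divisors for the biomarkers (molar-mass based).
MGDL_TO_MMOL = {"tc": 38.67, "non_hdl": 38.67, "fpg": 18.016}

#: kPa -> mmHg multiplier.
KPA_TO_MMHG = 7.50062

DISPLAY_TO_KEY = {rf.display: key for key, rf in RISK_FACTORS.items()}
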