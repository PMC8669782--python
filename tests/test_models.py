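"""Age-band Poisson random-intercept model and RR assembly."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cvburden as cb
from cvburden.models import DegenerateDesignError


class TestFitPoissonRandomIntercept:
    def test_degenerate_random_effect_equals_plain_glm(self, single_band_segments):
        """With sigma_u fixed at zero the marginal likelihood is an
        ordinary Poisson regression with offset; estimates must agree with
        an independent GLM fit."""
        seg = single_band_segments
        mine = cb.fit_poisson_random_intercept(seg, "sbp", band=(35.0, np.inf), fix_sigma=0)
        X = pd.DataFrame(
            {
                "const": 1.0,
                "sbp": seg["sbp"],
                "male": (seg["sex"] == "male").astype(float),
                "agec": seg["age_at_risk"] - 40.0,
            }
        )
        glm = sm.GLM(
            seg["events"], X, family=sm.families.Poisson(), offset=np.log(seg["person_time"])
        ).fit()
        assert mine.beta == pytest.approx(glm.params["sbp"], abs=1e-6)
        assert mine.se == pytest.approx(glm.bse["sbp"], abs=1e-6)
        assert mine.coefficients["male"] == pytest.approx(glm.params["male"], abs=1e-6)

    def test_doubling_person_time_shifts_intercept_by_log2(self, single_band_segments):
        seg = single_band_segments
        doubled = seg.assign(person_time=seg["person_time"] * 2)
        f1 = cb.fit_poisson_random_intercept(seg, "sbp", band=(35.0, np.inf))
        f2 = cb.fit_poisson_random_intercept(doubled, "sbp", band=(35.0, np.inf))
        assert f2.beta == pytest.approx(f1.beta, abs=1e-6)
        assert f2.coefficients["intercept"] - f1.coefficients["intercept"] == pytest.approx(
            -math.log(2), abs=1e-5
        )

    def test_constant_exposure_rejected(self, single_band_segments):
        seg = single_band_segments.assign(sbp=130.0)
        with pytest.raises(DegenerateDesignError, match="sbp"):
            cb.fit_poisson_random_intercept(seg, "sbp", band=(35.0, np.inf))

    def test_single_cohort_rejected(self, single_band_segments):
        seg = single_band_segments
        one = seg.loc[seg["cohort_id"] == seg["cohort_id"].iloc[0]]
        with pytest.raises(ValueError, match="cohort"):
            cb.fit_poisson_random_intercept(one, "sbp", band=(35.0, np.inf))

    def test_no_events_rejected(self, single_band_segments):
        seg = single_band_segments.assign(events=0)
        with pytest.raises(ValueError, match="events"):
            cb.fit_poisson_random_intercept(seg, "sbp", band=(35.0, np.inf))

    def test_estimate_near_attenuated_truth(self, single_band_segments, single_band_cohorts):
        """The fit on noisy baseline exposure recovers the attenuated
        slope lambda * beta_true within 3 SE."""
        fit = cb.fit_poisson_random_intercept(
            single_band_segments, "sbp", band=(35.0, np.inf)
        )
        lam = 2.0 / 3.0
        truth = single_band_cohorts.truth.true_log_rr["sbp"]
        assert fit.converged
        assert abs(fit.beta - lam * truth) < 3 * fit.se

    def test_agrees_with_lme4_glmer(self, single_band_segments, tmp_path):
        """Independent cross-check against lme4's adaptive-quadrature
        Poisson GLMM on the same segments."""
        seg = single_band_segments.copy()
        seg["male"] = (seg["sex"] == "male").astype(int)
        seg["agec"] = seg["age_at_risk"] - 40.0
        csv = tmp_path / "seg.csv"
        seg[["events", "sbp", "male", "agec", "person_time", "cohort_id"]].to_csv(
            csv, index=False
        )
        script = f"""
        d <- read.csv("{csv}")
        suppressMessages(library(lme4))
        m <- glmer(events ~ sbp + male + agec + offset(log(person_time)) + (1 | cohort_id),
                   data = d, family = poisson, nAGQ = 7)
        co <- summary(m)$coefficients
        cat(co["sbp", 1], co["sbp", 2], as.numeric(summary(m)$varcor$cohort_id[1]), sep = "\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_beta, r_se, r_var = map(float, out.stdout.split())
        fit = cb.fit_poisson_random_intercept(
            single_band_segments, "sbp", band=(35.0, np.inf)
        )
        assert fit.beta == pytest.approx(r_beta, rel=0.02, abs=1e-4)
        assert fit.se == pytest.approx(r_se, rel=0.05)
        assert fit.sigma_u**2 == pytest.approx(r_var, rel=0.15, abs=5e-3)


class TestAssembleRrs:
    def _fit(self, beta, se, band="45-54", converged=True):
        return cb.ModelFit(
            risk_factor="sbp", band=band, outcome="fatal",
            beta=beta, se=se, converged=converged,
        )

    def test_null_effect_gives_unit_rr(self):
        tab = cb.assemble_rrs([{"45-54": self._fit(0.0, 0.01)}], 1.5, increment=10)
        row = tab.iloc[0]
        assert row["rr"] == pytest.approx(1.0)
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0, rel=1e-9)

    def test_corrected_rr_closed_form(self):
        fits = [{"45-54": self._fit(0.04, 0.01)}, {"45-54": self._fit(0.04, 0.01)}]
        tab = cb.assemble_rrs(fits, 1.5, increment=10)
        assert tab.iloc[0]["rr"] == pytest.approx(math.exp(0.6))

    def test_identity_correction_matches_per_unit_rr(self):
        tab = cb.assemble_rrs([{"45-54": self._fit(0.03, 0.005)}], 1.0, increment=1)
        assert tab.iloc[0]["rr"] == pytest.approx(math.exp(0.03))
        assert not tab.iloc[0]["corrected"]

    def test_failed_band_absent_not_zero(self):
        fits = [{"45-54": self._fit(0.02, 0.01), "55-64": self._fit(0.0, 0.0, converged=False)}]
        tab = cb.assemble_rrs(fits, 1.0)
        assert list(tab["band"]) == ["45-54"]

    def test_rubin_pooling_feeds_t_interval(self):
        fits = [{"45-54": self._fit(0.3, 0.1)}, {"45-54": self._fit(0.5, 0.1)}]
        tab = cb.assemble_rrs(fits, 1.0, increment=1)
        row = tab.iloc[0]
        assert row["log_rr"] == pytest.approx(0.4)
        # within 0.01, between 0.02 -> total (0.01 + 1.5 * 0.02) = 0.04
        assert row["se"] == pytest.approx(math.sqrt(0.04))
        assert row["m"] == 2
        # t interval is wider than the normal one at these few df
        assert row["ci_high"] > math.exp(0.4 + 1.96 * row["se"])


class TestStratifiedRrs:
    def test_single_stratum_matches_unstratified(self, single_band_segments):
        seg = single_band_segments
        strata = {c: "all" for c in seg["cohort_id"].unique()}
        by_stratum = cb.stratified_rrs(
            seg.assign(band="35+"), strata, "sbp", bands=((35.0, np.inf),)
        )
        fits = cb.fit_all_bands(seg.assign(band="35+"), "sbp", bands=((35.0, np.inf),))
        direct = cb.assemble_rrs([fits], 1.0, 1.0)
        assert by_stratum["all"].iloc[0]["rr"] == pytest.approx(direct.iloc[0]["rr"])

    def test_small_stratum_skipped_with_warning(self, single_band_segments):
        seg = single_band_segments
        cohorts = list(seg["cohort_id"].unique())
        strata = {c: "big" for c in cohorts}
        strata[cohorts[0]] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            out = cb.stratified_rrs(
                seg.assign(band="35+"), strata, "sbp", bands=((35.0, np.inf),)
            )
        assert set(out) == {"big"}

    def test_unmapped_cohort_is_error(self, single_band_segments):
        with pytest.raises(ValueError, match="strata"):
            cb.stratified_rrs(single_band_segments, {}, "sbp")
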