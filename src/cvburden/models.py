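"""Age-band-specific Poisson random-intercept incidence models.

For one attained-age band the event count of each person-time segment is
modelled as Poisson with

    log E[y] = log(person_time) + b0 + beta * exposure + g1 * male
               + g2 * (age_at_risk - band midpoint) + u_cohort,

with a cohort-level random intercept ``u ~ Normal(0, sigma_u²)``.  The
marginal likelihood integrates the random intercept out of each cohort's
contribution with adaptive Gauss–Hermite quadrature (the integrand's mode
and curvature have closed Newton updates because the cohort contribution
depends on ``u`` only through the cohort's total events and total
expected-count scale).  Standard errors come from the observed
information at the optimum (central finite differences).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .dilution import CorrectionFactor, apply_correction
from .missing import rubin_pool
from .pooling import AGE_BANDS, band_label, band_midpoint

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    risk_factor: str
    band: str
    outcome: str
    beta: float                  # log-IRR per canonical exposure unit
    se: float
    coefficients: dict = field(default_factory=dict)
    sigma_u: float = 0.0
    converged: bool = False
    loglik: float = math.nan
    n_events: int = 0
    n_cohorts: int = 0
    n_segments: int = 0


class DegenerateDesignError(ValueError):
    pass


def _design(segments: pd.DataFrame, risk_factor: str, center_age: float):
    x = segments[risk_factor].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError(f"exposure column {risk_factor!r} contains missing values; impute first")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"exposure column {risk_factor!r} is constant in this band")
    male = (segments["sex"] == "male").to_numpy(float)
    agec = segments["age_at_risk"].to_numpy(float) - center_age
    X = np.column_stack([np.ones(len(x)), x, male, agec])
    return X


def _nll_factory(X, y, offset, cohort_idx, n_cohorts, quad_points):
    """Negative marginal log-likelihood over (b0, beta, g1, g2, log sigma)."""
    z, w = hermgauss(quad_points)
    logw = np.log(w)
    y_tot = np.bincount(cohort_idx, weights=y, minlength=n_cohorts)
    ylogt = float((y * offset).sum())  # y * log(person_time) part of eta

    def nll(params):
        beta = params[:4]
        sigma = math.exp(params[4])
        eta = offset + X @ beta
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        if not np.isfinite(mu).all():
            return 1e10
        s = np.bincount(cohort_idx, weights=mu, minlength=n_cohorts)
        yxb = float((y * (X @ beta)).sum())
        if sigma < 1e-8:
            # degenerate random effect: plain Poisson likelihood
            return -(ylogt + yxb - s.sum())
        # per-cohort integrand mode: solve Y - s e^u - u/sigma^2 = 0
        u = np.zeros(n_cohorts)
        inv_s2 = 1.0 / sigma**2
        for _ in range(50):
            g = y_tot - s * np.exp(u) - u * inv_s2
            h = -s * np.exp(u) - inv_s2
            step = g / h
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        hess = s * np.exp(u) + inv_s2  # positive curvature at the mode
        scale = np.sqrt(2.0 / hess)
        nodes = u[:, None] + scale[:, None] * z[None, :]
        logf = (
            y_tot[:, None] * nodes
            - s[:, None] * np.exp(nodes)
            - nodes**2 * (0.5 * inv_s2)
            - math.log(sigma)
            - 0.5 * math.log(2.0 * math.pi)
        )
        log_int = special.logsumexp(
            logw[None, :] + z[None, :] ** 2 + logf, axis=1
        ) + np.log(scale)
        ll = ylogt + yxb + log_int.sum()
        return -ll

    return nll


def fit_poisson_random_intercept(
    segments: pd.DataFrame,
    risk_factor: str,
    outcome: str = "fatal",
    band: tuple[float, float] | None = None,
    quad_points: int = 7,
    fix_sigma: float | None = None,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit the random-intercept Poisson model on one band's segments.

    ``segments`` must already be restricted to a single age band (the
    ``events`` column is the response and ``person_time`` the offset).
    ``fix_sigma=0`` fits the degenerate model (ordinary Poisson regression
    with offset) with the same machinery.
    """
    cohorts = pd.Categorical(segments["cohort_id"].astype(str))
    n_cohorts = len(cohorts.categories)
    if n_cohorts < 2 and fix_sigma is None:
        raise ValueError("need segments from at least 2 cohorts")
    y = segments["events"].to_numpy(float)
    if y.sum() < 1:
        raise ValueError("no events in this band")
    if band is None:
        lab = str(segments["band"].iloc[0]) if "band" in segments else ""
        center = float(segments["age_at_risk"].mean())
    else:
        lab = band_label(band)
        center = band_midpoint(band)
    X = _design(segments, risk_factor, center)
    offset = np.log(segments["person_time"].to_numpy(float))
    idx = cohorts.codes.astype(int)

    nll = _nll_factory(X, y, offset, idx, n_cohorts, quad_points)

    # moment-style start: log crude rate for the intercept
    b0 = math.log(y.sum() / segments["person_time"].sum())
    x_mean = X[:, 1].mean()
    start = np.array([b0 - 0.0, 0.0, 0.0, 0.0, math.log(0.3)])
    start[0] = b0
    # centre exposure internally for conditioning, refit intercept afterwards
    Xc = X.copy()
    Xc[:, 1] = X[:, 1] - x_mean
    nll_c = _nll_factory(Xc, y, offset, idx, n_cohorts, quad_points)

    if fix_sigma is not None:
        if fix_sigma != 0:
            raise ValueError("only fix_sigma=0 is supported")

        def nll_fixed(p4):
            return nll_c(np.concatenate([p4, [math.log(1e-12)]]))

        res = optimize.minimize(nll_fixed, start[:4], method="BFGS",
                                options={"gtol": tol, "maxiter": 500})
        params = np.concatenate([res.x, [-np.inf]])
        free = 4
        nll_used = nll_fixed
        xopt = res.x
    else:
        res = optimize.minimize(nll_c, start, method="BFGS",
                                options={"gtol": tol, "maxiter": 500})
        # polish with Nelder-Mead if the gradient path stalled
        if not res.success:
            res2 = optimize.minimize(nll_c, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
            if res2.fun <= res.fun:
                res = res2
        params = res.x
        free = 5
        nll_used = nll_c
        xopt = res.x

    # at a sigma_u ~ 0 boundary the log-sigma direction is flat; fall back
    # to the fixed-effect block with the random effect pinned at zero
    if free == 5 and math.exp(xopt[4]) < 1e-4:
        def nll_beta(p4):
            return nll_c(np.concatenate([p4, [math.log(1e-12)]]))
        cov = _fd_covariance(nll_beta, xopt[:4])
    else:
        cov = _fd_covariance(nll_used, xopt)
    se_beta = math.sqrt(max(cov[1, 1], 0.0)) if cov is not None else math.nan
    converged = bool(np.isfinite(se_beta)) and se_beta > 0 and np.isfinite(res.fun)

    beta_hat = params[1]
    sigma_u = 0.0 if free == 4 else math.exp(params[4])
    intercept = params[0] - beta_hat * x_mean
    fit = ModelFit(
        risk_factor=risk_factor,
        band=lab,
        outcome=outcome,
        beta=float(beta_hat),
        se=float(se_beta),
        coefficients={
            "intercept": float(intercept),
            "male": float(params[2]),
            "age_at_risk_centered": float(params[3]),
        },
        sigma_u=float(sigma_u),
        converged=converged,
        loglik=float(-res.fun),
        n_events=int(y.sum()),
        n_cohorts=n_cohorts,
        n_segments=len(segments),
    )
    if not converged:
        logger.warning("model for %s band %s did not converge", risk_factor, lab)
    return fit


def _fd_covariance(fun, x, rel_step: float = 1e-4):
    """Covariance from a central finite-difference Hessian."""
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += h[i]; xpp[j] += h[j]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4 * h[i] * h[j]
                )
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def fit_all_bands(
    segments: pd.DataFrame,
    risk_factor: str,
    outcome: str = "fatal",
    bands=AGE_BANDS,
    **kwargs,
) -> dict[str, ModelFit]:
    """Fit the band model for every band with events; bands without events
    (or that fail) are skipped with a logged reason."""
    fits: dict[str, ModelFit] = {}
    for band in bands:
        lab = band_label(band)
        sub = segments.loc[segments["band"] == lab]
        if len(sub) == 0 or sub["events"].sum() < 1:
            logger.info("band %s skipped: no events", lab)
            continue
        try:
            fits[lab] = fit_poisson_random_intercept(
                sub, risk_factor, outcome=outcome, band=band, **kwargs
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("band %s skipped: %s", lab, exc)
    return fits


# ---------------------------------------------------------------------------
# assembling relative risks


def assemble_rrs(
    fits_per_imputation: list[dict[str, ModelFit]],
    correction: CorrectionFactor | float = 1.0,
    increment: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rubin-pool per-imputation band fits, apply the regression-dilution
    correction and exponentiate at the display increment.

    Returns a tidy table with one row per band: risk_factor, band, outcome,
    corrected flag, increment, log_rr and se (corrected, per canonical
    unit), rr, ci_low, ci_high, df, m.  Bands where every imputation
    failed are absent from the table.
    """
    if not fits_per_imputation:
        raise ValueError("no fits supplied")
    bands: list[str] = []
    for fits in fits_per_imputation:
        for lab in fits:
            if lab not in bands:
                bands.append(lab)
    f = correction.factor if isinstance(correction, CorrectionFactor) else float(correction)
    rows = []
    for lab in bands:
        good = [
            fits[lab]
            for fits in fits_per_imputation
            if lab in fits and fits[lab].converged
        ]
        if not good:
            logger.warning("band %s absent: no converged fits", lab)
            continue
        if len(good) >= 2:
            pooled = rubin_pool([g.beta for g in good], [g.se**2 for g in good])
            point, se, df, m = pooled.point, pooled.se, pooled.df, pooled.m
        else:
            point, se, df, m = good[0].beta, good[0].se, math.inf, 1
        point_c, se_c = apply_correction(point, se, f)
        tq = stats.norm.ppf(1 - alpha / 2) if math.isinf(df) else stats.t.ppf(1 - alpha / 2, df)
        rows.append(
            {
                "risk_factor": good[0].risk_factor,
                "band": lab,
                "outcome": good[0].outcome,
                "corrected": f != 1.0,
                "increment": increment,
                "log_rr": point_c,
                "se": se_c,
                "rr": math.exp(point_c * increment),
                "ci_low": math.exp((point_c - tq * se_c) * increment),
                "ci_high": math.exp((point_c + tq * se_c) * increment),
                "df": df,
                "m": m,
            }
        )
    return pd.DataFrame(rows)


def stratified_rrs(
    segments: pd.DataFrame,
    strata: dict[str, str],
    risk_factor: str,
    correction: CorrectionFactor | float = 1.0,
    increment: float = 1.0,
    outcome: str = "fatal",
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Independent band fits per cohort stratum (e.g. sub-region).

    ``strata`` maps cohort_id -> stratum name; strata with fewer than two
    cohorts are skipped with a warning.
    """
    unmapped = set(segments["cohort_id"].astype(str)) - set(strata)
    if unmapped:
        raise ValueError(f"cohorts missing from strata map: {sorted(unmapped)}")
    out: dict[str, pd.DataFrame] = {}
    mapped = segments["cohort_id"].astype(str).map(strata)
    for stratum in sorted(set(strata.values())):
        sub = segments.loc[mapped == stratum]
        if sub["cohort_id"].nunique() < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 cohorts; skipped")
            continue
        fits = fit_all_bands(sub, risk_factor, outcome=outcome, **kwargs)
        if fits:
            out[stratum] = assemble_rrs([fits], correction, increment)
    return out
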