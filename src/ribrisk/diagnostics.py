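"""Influence and residual diagnostics, confidence bands, and quality indices.

These are the checking steps of the injury-risk-curve construction
procedure: leave-one-out DFBETA influence statistics with the 2/sqrt(n)
threshold, Q-Q and residual-vs-fitted (Tukey-Anscombe) diagnostics,
delta-method 95% confidence bands on the risk curve, and the quality-index
grading of band width at fixed risk levels and ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fitting import _ERR_DIST, AFTFit, coupons_to_frame, fit_aft
from .params import RiskParameters
from .risk import strain_at_risk

logger = logging.getLogger(__name__)

#: Quality-index grade boundaries on the relative confidence-interval width,
#: following the WorldSID/ISO convention; configurable per call.
QI_GRADES = ((0.5, "good"), (1.0, "fair"), (1.5, "marginal"))


@dataclass
class InfluenceReport:
    """Leave-one-out DFBETA influence statistics for one fit."""

    dfbetas: pd.DataFrame      # index subject_id, one column per parameter
    threshold: float           # 2 / sqrt(n)
    flagged_ids: list[str]
    unevaluable_ids: list[str]


def dfbetas(data, fit: AFTFit) -> InfluenceReport:
    """Standardized per-observation influence on each fitted parameter.

    Entry (i, j) = (theta_j - theta_j^(-i)) / SE(theta_j), where the
    leave-one-out estimate comes from a full refit without observation i
    (cheap at coupon-test sample sizes).  An observation is flagged when any
    entry exceeds 2/sqrt(n) in magnitude.
    """
    if not fit.converged:
        raise ValueError("influence diagnostics require a converged fit")
    df = coupons_to_frame(data).reset_index(drop=True)
    n = len(df)
    threshold = 2.0 / np.sqrt(n)
    se = np.sqrt(np.diag(fit.covariance))
    full = np.array([fit.coef[name] for name in fit.param_names[:-1]] + [np.log(fit.sigma)])

    rows, flagged, unevaluable = {}, [], []
    for i in range(n):
        sid = str(df.loc[i, "subject_id"])
        try:
            loo = fit_aft(df.drop(index=i), fit.family, fit.covariates)
            if not loo.converged:
                raise RuntimeError("leave-one-out fit did not converge")
        except Exception as exc:  # noqa: BLE001 - row marked, not fatal
            logger.warning("leave-one-out refit failed for %s: %s", sid, exc)
            unevaluable.append(sid)
            rows[sid] = np.full(len(full), np.nan)
            continue
        loo_theta = np.array(
            [loo.coef[name] for name in loo.param_names[:-1]] + [np.log(loo.sigma)]
        )
        d = (full - loo_theta) / se
        rows[sid] = d
        if np.any(np.abs(d) > threshold):
            flagged.append(sid)

    table = pd.DataFrame.from_dict(rows, orient="index", columns=fit.param_names)
    table.index.name = "subject_id"
    return InfluenceReport(table, float(threshold), flagged, unevaluable)


@dataclass
class ResidualReport:
    """Q-Q points and Tukey-Anscombe pairs for a fitted AFT model."""

    qq: pd.DataFrame                # theoretical, empirical (sorted)
    residuals_vs_fitted: pd.DataFrame  # fitted (log-strain), residual


def residual_diagnostics(data, fit: AFTFit) -> ResidualReport:
    """Standardized residuals against the family's error distribution.

    Residual r_i = (ln s_i - x_i beta) / sigma for exact observations,
    paired with theoretical quantiles at plotting positions (i - 0.5)/n.
    """
    if not fit.converged:
        raise ValueError("residual diagnostics require a converged fit")
    df = coupons_to_frame(data)
    exact = df[df["censor"] == "exact"]
    from .fitting import _design

    X, _ = _design(exact, fit.covariates)
    beta = np.array([fit.coef[name] for name in fit.param_names[:-1]])
    mu = X @ beta
    r = (np.log(exact["failure_strain"].to_numpy(float)) - mu) / fit.sigma

    n = len(r)
    dist = _ERR_DIST[fit.family]
    pp = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame({"theoretical": dist.ppf(pp), "empirical": np.sort(r)})
    ta = pd.DataFrame({"fitted": mu, "residual": r})
    return ResidualReport(qq, ta)


def confidence_band(
    fit: AFTFit,
    ages,
    strains,
    level: float = 0.95,
    sex: str = "F",
) -> pd.DataFrame:
    """Pointwise delta-method confidence band for the risk curve.

    The band is built on the linear-predictor scale
    z(s, a) = (ln s - x(a) beta) / sigma (where it is asymptotically
    normal), then mapped through the family CDF, which keeps it inside
    [0, 1] and containing the point estimate.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    cov = fit.covariance
    if not np.all(np.isfinite(cov)):
        raise ValueError("confidence band undefined: covariance unavailable")
    dist = _ERR_DIST[fit.family]
    beta = np.array([fit.coef[name] for name in fit.param_names[:-1]])
    c = norm.ppf(0.5 + level / 2.0)

    rows = []
    for age in np.atleast_1d(ages):
        x = fit.design_row(float(age), sex)
        mu = float(x @ beta)
        for s in np.atleast_1d(strains):
            z = (np.log(s) - mu) / fit.sigma
            # dz/dbeta_j = -x_j / sigma ; dz/d(ln sigma) = -z
            g = np.append(-x / fit.sigma, -z)
            var = float(g @ cov @ g)
            sd = np.sqrt(max(var, 0.0))
            rows.append(
                {
                    "age": float(age),
                    "strain": float(s),
                    "risk": float(dist.cdf(z)),
                    "lower": float(dist.cdf(z - c * sd)),
                    "upper": float(dist.cdf(z + c * sd)),
                }
            )
    return pd.DataFrame(rows)


def _grade(rel_width: float, grades=QI_GRADES) -> str:
    for bound, name in grades:
        if rel_width < bound:
            return name
    return "unacceptable"


def quality_index(
    fit: AFTFit,
    risk_levels=(0.05, 0.25, 0.50),
    ages=(25.0, 50.0, 75.0),
    level: float = 0.95,
    grades=QI_GRADES,
) -> pd.DataFrame:
    """Grade the risk curve by relative confidence-interval width.

    At each (risk level, age) cell the strain giving that risk is found by
    closed-form inversion, the confidence band is evaluated there, and the
    relative width r = (upper - lower) / mid is graded good / fair /
    marginal / unacceptable at the conventional 0.5 / 1.0 / 1.5 boundaries.
    """
    params: RiskParameters = fit.params
    rows = []
    for age in ages:
        for rl in risk_levels:
            s = strain_at_risk(rl, age, params)
            try:
                band = confidence_band(fit, [age], [s], level=level)
            except ValueError:
                rows.append(
                    {"risk_level": rl, "age": age, "strain": s,
                     "rel_width": np.nan, "grade": "unevaluable"}
                )
                continue
            lo, up, mid = band["lower"][0], band["upper"][0], band["risk"][0]
            r = (up - lo) / mid
            rows.append(
                {"risk_level": rl, "age": age, "strain": s,
                 "rel_width": float(r), "grade": _grade(r, grades)}
            )
    return pd.DataFrame(rows)
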