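"""Maximum-likelihood AFT fitting of failure-strain data (ISO-style pipeline).

Implements the model-construction steps of the standard injury-risk-curve
procedure: covariate screening by ANOVA, parametric accelerated-failure-time
fits for the log-normal, Weibull, and log-logistic families by maximum
likelihood, and AIC-based family selection.  Influence and residual
diagnostics live in :mod:`ribrisk.diagnostics`.

The AFT model for failure true strain ``T`` with covariate row ``x`` is

    ln(T) = x @ beta + sigma * eps

with ``eps`` standard normal (log-normal family), standard logistic
(log-logistic), or standard Gumbel-minimum (Weibull, shape alpha = 1/sigma).
Exact observations contribute density terms to the likelihood; right-, left-,
and interval-censored observations contribute survival/CDF terms.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import gumbel_l, logistic, norm

from .params import FAMILY_ORDER, Family, RiskParameters

logger = logging.getLogger(__name__)

CENSOR_CODES = ("exact", "right", "left", "interval")

_ERR_DIST = {
    Family.LOGNORMAL: norm,
    Family.LOGLOGISTIC: logistic,
    Family.WEIBULL: gumbel_l,
}


@dataclass(frozen=True)
class CouponRecord:
    """One tensile-test observation of rib cortical bone.

    ``failure_strain`` is TRUE strain (> 0).  For interval-censored rows,
    ``failure_strain`` is the lower bound and ``strain_upper`` the upper.
    """

    subject_id: str
    age: float
    sex: str
    failure_strain: float
    censor: str = "exact"
    strain_rate: float = 0.5
    strain_upper: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.age <= 120.0:
            raise ValueError(f"age {self.age} outside [0, 120]")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.failure_strain <= 0:
            raise ValueError("failure_strain must be > 0 (true strain)")
        if self.censor not in CENSOR_CODES:
            raise ValueError(f"unknown censor code {self.censor!r}")
        if self.censor == "interval":
            if self.strain_upper is None or self.strain_upper <= self.failure_strain:
                raise ValueError("interval censoring needs strain_upper > failure_strain")


def coupons_to_frame(data) -> pd.DataFrame:
    """Normalize a coupon dataset (records or DataFrame) to a DataFrame."""
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in data])
    required = {"subject_id", "age", "sex", "failure_strain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coupon data missing columns: {sorted(missing)}")
    if "censor" not in df.columns:
        df["censor"] = "exact"
    if "strain_upper" not in df.columns:
        df["strain_upper"] = np.nan
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    bad = ~df["censor"].isin(CENSOR_CODES)
    if bad.any():
        raise ValueError(f"unknown censor code(s): {sorted(df.loc[bad, 'censor'].unique())}")
    if (df["failure_strain"] <= 0).any():
        raise ValueError("all failure strains must be > 0 (true strain)")
    return df


def _data_fingerprint(df: pd.DataFrame, covariates: Sequence[str]) -> str:
    cols = ["age", "failure_strain", "censor"] + (["sex"] if "sex" in covariates else [])
    payload = df[cols].sort_values(["age", "failure_strain"]).to_csv(index=False)
    return hashlib.sha1(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------

def screen_covariates(data, alpha: float = 0.05) -> pd.DataFrame:
    """Type-II ANOVA of ln(failure strain) on age, sex, and their interaction.

    Returns a table with columns ``term, df, F, p, significant``; terms with
    p < ``alpha`` are the recommended AFT covariates.  With a single sex in
    the data, the sex terms are omitted with a warning.  Zero-variance
    predictors yield non-estimable (NaN) F statistics rather than errors.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = coupons_to_frame(data)
    if df["age"].nunique() < 2 and df["sex"].nunique() < 2:
        raise ValueError("need at least two distinct ages or both sexes to screen")
    work = pd.DataFrame(
        {
            "log_strain": np.log(df["failure_strain"].to_numpy(float)),
            "age": df["age"].to_numpy(float),
            "sex": df["sex"].to_numpy(),
        }
    )
    if np.ptp(work["log_strain"].to_numpy()) == 0.0:
        raise ValueError("degenerate model: failure strain is constant")

    both_sexes = work["sex"].nunique() == 2
    age_varies = work["age"].nunique() >= 2
    not_estimable: list[str] = []
    if not both_sexes:
        logger.warning("only one sex present; sex terms omitted from the screen")
        formula = "log_strain ~ age"
    elif not age_varies:
        # constant predictor: its F is undefined (zero-variance design column)
        logger.warning("age is constant; age terms reported as not estimable")
        not_estimable = ["age", "age:sex"]
        formula = "log_strain ~ C(sex)"
    else:
        formula = "log_strain ~ age * C(sex)"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance terms raise RuntimeWarnings
        model = smf.ols(formula, data=work).fit()
        table = anova_lm(model, typ=2)

    rename = {"C(sex)": "sex", "age:C(sex)": "age:sex"}
    rows = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = rename.get(term, term)
        F, p = float(row["F"]), float(row["PR(>F)"])
        rows.append(
            {
                "term": name,
                "df": float(row["df"]),
                "F": F,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    for term in not_estimable:
        rows.append({"term": term, "df": np.nan, "F": np.nan, "p": np.nan,
                     "significant": False})
    return pd.DataFrame(rows)


def recommended_covariates(anova_table: pd.DataFrame) -> list[str]:
    """Main-effect covariates whose screen p-value falls below the level."""
    keep = []
    for _, row in anova_table.iterrows():
        if row["term"] in ("age", "sex") and row["significant"]:
            keep.append(row["term"])
    return keep


# ---------------------------------------------------------------------------
# AFT maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class AFTFit:
    """Result of a parametric AFT maximum-likelihood fit.

    ``covariance`` is the observed-information covariance over
    ``param_names`` = coefficient names followed by ``log_sigma``.
    """

    family: Family
    coef: dict[str, float]
    sigma: float
    loglik: float
    aic: float
    n: int
    covariance: np.ndarray
    param_names: list[str]
    converged: bool
    covariates: tuple[str, ...]
    data_hash: str = ""
    n_censored: int = 0

    @property
    def k(self) -> int:
        """Number of free parameters (coefficients + scale)."""
        return len(self.param_names)

    @property
    def params(self) -> RiskParameters:
        """Risk-function parameters (requires covariates within {age})."""
        extra = set(self.covariates) - {"age"}
        if extra:
            raise ValueError(
                f"fit includes covariates {sorted(extra)}; cannot be expressed "
                "as (alpha, beta0, beta1) risk parameters"
            )
        alpha = self.sigma if self.family is Family.LOGNORMAL else 1.0 / self.sigma
        return RiskParameters(
            family=self.family,
            alpha=alpha,
            beta0=self.coef["intercept"],
            beta1=self.coef.get("age", 0.0),
            meta={"source": "fit", "n": self.n, "loglik": self.loglik, "aic": self.aic},
        )

    def design_row(self, age: float, sex: str = "F") -> np.ndarray:
        return _design(
            pd.DataFrame({"age": [age], "sex": [sex]}), self.covariates
        )[0][0]


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "age":
            cols.append(df["age"].to_numpy(float))
            names.append("age")
        elif cov == "sex":
            cols.append((df["sex"].to_numpy() == "M").astype(float))
            names.append("sex_M")
        else:
            raise ValueError(f"unsupported covariate {cov!r}")
    return np.column_stack(cols), names


def _neg_loglik(theta, X, logt, logt_upper, censor, dist):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    z = (logt - mu) / sigma
    ll = 0.0
    exact = censor == 0
    if exact.any():
        ll += np.sum(dist.logpdf(z[exact]) - log_sigma - logt[exact])
    right = censor == 1
    if right.any():
        ll += np.sum(dist.logsf(z[right]))
    left = censor == 2
    if left.any():
        ll += np.sum(dist.logcdf(z[left]))
    interval = censor == 3
    if interval.any():
        zu = (logt_upper[interval] - mu[interval]) / sigma
        pr = dist.cdf(zu) - dist.cdf(z[interval])
        if np.any(pr <= 0):
            return np.inf
        ll += np.sum(np.log(pr))
    return -ll if np.isfinite(ll) else np.inf


def _numeric_hessian(f, x, step=1e-5):
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_aft(
    data,
    family: Family | str = Family.LOGNORMAL,
    covariates: Sequence[str] = ("age",),
    gtol: float = 1e-8,
) -> AFTFit:
    """Fit a parametric AFT model to coupon data by maximum likelihood.

    Quasi-Newton (BFGS) optimization on (beta, ln sigma), started from the
    ordinary least-squares fit of ln(strain) on the covariates; covariance
    from the observed information (numerical Hessian at the optimum).
    The returned log-likelihood is for the failure strain itself (density
    terms include the 1/t Jacobian), so AIC values are comparable with
    standard survival packages.
    """
    fam = Family.coerce(family)
    df = coupons_to_frame(data)
    covariates = tuple(covariates)
    X, names = _design(df, covariates)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations for {p + 1} parameters")
    logt = np.log(df["failure_strain"].to_numpy(float))
    with np.errstate(invalid="ignore"):
        logt_upper = np.log(df["strain_upper"].to_numpy(float))
    censor = df["censor"].map({c: i for i, c in enumerate(CENSOR_CODES)}).to_numpy()
    dist = _ERR_DIST[fam]

    # OLS start on the point values (censored rows enter as-is: a start only)
    beta0, *_ = np.linalg.lstsq(X, logt, rcond=None)
    resid = logt - X @ beta0
    sigma0 = max(float(np.sqrt(np.mean(resid**2))), 1e-3)
    x0 = np.append(beta0, np.log(sigma0))

    f = lambda th: _neg_loglik(th, X, logt, logt_upper, censor, dist)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(f, x0, method="BFGS", options={"gtol": gtol, "maxiter": 500})
        if not res.success:  # polish from the BFGS point
            res2 = optimize.minimize(f, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if res2.fun <= res.fun:
                res = res2

    theta = res.x
    if theta[-1] < -12.0:
        raise ValueError("scale collapsed to zero: degenerate data")
    loglik = -f(theta)
    if loglik < -f(x0) - 1e-6:
        logger.warning("optimum below the least-squares start; flagging non-convergence")
    converged = bool(res.success or np.max(np.abs(optimize.approx_fprime(theta, f, 1e-7))) < 1e-3)
    if not converged:
        logger.warning("AFT fit did not converge cleanly (family=%s)", fam.value)

    H = _numeric_hessian(f, theta)
    try:
        cov = np.linalg.inv(H)
        # symmetrize; tiny asymmetry from finite differences
        cov = 0.5 * (cov + cov.T)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError("negative variance")
    except np.linalg.LinAlgError:
        logger.warning("observed information not invertible; covariance unavailable")
        cov = np.full((len(theta), len(theta)), np.nan)
        converged = False

    coef = dict(zip(names, theta[:-1]))
    k = len(theta)
    return AFTFit(
        family=fam,
        coef={k_: float(v) for k_, v in coef.items()},
        sigma=float(np.exp(theta[-1])),
        loglik=float(loglik),
        aic=float(2 * k - 2 * loglik),
        n=n,
        covariance=cov,
        param_names=names + ["log_sigma"],
        converged=converged,
        covariates=covariates,
        data_hash=_data_fingerprint(df, covariates),
        n_censored=int(np.sum(censor != 0)),
    )


def fit_all_families(data, covariates: Sequence[str] = ("age",)) -> dict[Family, AFTFit]:
    """Fit all three AFT families on the same data and covariates."""
    return {fam: fit_aft(data, fam, covariates) for fam in FAMILY_ORDER}


# ---------------------------------------------------------------------------
# AIC model selection
# ---------------------------------------------------------------------------

@dataclass
class AICRanking:
    """AIC comparison across families fitted to identical data."""

    table: pd.DataFrame  # columns: family, aic, delta; sorted by delta
    recommended: Family

    def delta(self, family: Family | str) -> float:
        fam = Family.coerce(family)
        row = self.table[self.table["family"] == fam.value]
        return float(row["delta"].iloc[0])


def aic_deltas(aics: Mapping[Family | str, float]) -> AICRanking:
    """Rank candidate families by AIC; deltas are vs. the minimum.

    Equal-AIC ties are broken by the fixed family preference order
    (log-normal, log-logistic, Weibull).
    """
    fams = [Family.coerce(f) for f in aics]
    values = {Family.coerce(f): float(v) for f, v in aics.items()}
    amin = min(values.values())
    order_idx = {f: i for i, f in enumerate(FAMILY_ORDER)}
    ranked = sorted(fams, key=lambda f: (values[f], order_idx.get(f, 99)))
    table = pd.DataFrame(
        {
            "family": [f.value for f in ranked],
            "aic": [values[f] for f in ranked],
            "delta": [values[f] - amin for f in ranked],
        }
    )
    return AICRanking(table=table, recommended=ranked[0])


def compare_aic(fits: Iterable[AFTFit]) -> AICRanking:
    """AIC ranking of AFT fits; refuses fits on differing data/covariates."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.data_hash != ref.data_hash or f.covariates != ref.covariates:
            raise ValueError("AIC comparison requires identical data and covariates")
    return aic_deltas({f.family: f.aic for f in fits})
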