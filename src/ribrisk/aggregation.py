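"""Probabilistic rib-fracture framework: from per-rib strains to NFRk+ risk.

An occupant's 24 rib cortical bone meshes each yield a peak first principal
true strain.  Each strain maps to a per-rib fracture probability via the
age-adjusted risk function; assuming independent ribs, the number of
fractured ribs N follows the Poisson-binomial distribution of the 24
Bernoulli indicators, from which NFRk+ = P(N >= k) is read off.  Population
risk curves over crash severity (delta-v) and age are then fitted to case
NFRk+ risks with a fractional-response (quasi-binomial) logistic model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .params import RiskParameters
from .risk import fracture_risk

logger = logging.getLogger(__name__)

#: Canonical rib keys: left/right sides, levels 1..12.
RIB_KEYS = tuple(f"{side}{level}" for side in "LR" for level in range(1, 13))


@dataclass(frozen=True)
class RibStrainSet:
    """One occupant's 24 peak first principal rib strains (true convention).

    ``strains`` maps rib keys ``L1..L12, R1..R12`` to nonnegative peak true
    strains (a single peak per rib, extracted upstream from the FE output).
    """

    occupant_age: float
    strains: Mapping[str, float]
    case_meta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.strains)
        missing = set(RIB_KEYS) - keys
        extra = keys - set(RIB_KEYS)
        if missing or extra:
            raise ValueError(
                f"rib strain set must cover exactly {len(RIB_KEYS)} ribs; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        if any(v < 0 for v in self.strains.values()):
            raise ValueError("rib strains must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.strains[k] for k in RIB_KEYS], dtype=float)


def per_rib_risks(ribset: RibStrainSet, params: RiskParameters) -> np.ndarray:
    """Fracture probability for each of the 24 ribs, in ``RIB_KEYS`` order.

    Evaluated in lenient mode: meshes reporting zero strain get risk 0.
    """
    return np.asarray(
        fracture_risk(ribset.as_array(), ribset.occupant_age, params, strict=False)
    )


@dataclass(frozen=True)
class NFRDistribution:
    """Probability mass function of the number of fractured ribs."""

    pmf: np.ndarray  # length n_ribs + 1, counts 0..n

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        if np.any(pmf < -1e-12) or abs(pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf entries must be probabilities summing to 1")
        object.__setattr__(self, "pmf", pmf)

    @property
    def n_ribs(self) -> int:
        return len(self.pmf) - 1

    def mean(self) -> float:
        return float(np.arange(len(self.pmf)) @ self.pmf)

    def at_least(self, k: int) -> float:
        """P(N >= k): the NFRk+ risk."""
        if not 0 <= k <= self.n_ribs:
            raise ValueError(f"k must lie in [0, {self.n_ribs}]")
        if k == 0:
            return 1.0
        return float(min(max(1.0 - self.pmf[:k].sum(), 0.0), 1.0))


def nfr_distribution(p) -> NFRDistribution:
    """Exact Poisson-binomial PMF of the fractured-rib count.

    Iterative convolution (dynamic programming): starting from the
    degenerate pmf at 0 fractures, each rib's Bernoulli(p_i) is folded in
    with one O(n) update.  Exact and numerically stable at n = 24.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("per-rib probabilities must lie in [0, 1]")
    pmf = np.zeros(len(p) + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return NFRDistribution(pmf)


def nfr_at_least(p, k: int) -> float:
    """NFRk+ risk: probability of k or more fractured ribs."""
    return nfr_distribution(p).at_least(k)


# ---------------------------------------------------------------------------
# Population risk curves
# ---------------------------------------------------------------------------

@dataclass
class PopulationCurve:
    """Fractional-response logistic risk curve over delta-v and age.

    logit(risk) = intercept + slope_delta_v * delta_v + slope_age * age.
    Coefficients come from a binomial-family GLM on fractional NFRk+
    responses; the quasi-binomial dispersion is estimated but does not
    alter the coefficients.
    """

    intercept: float
    slope_delta_v: float
    slope_age: float
    n_cases: int
    dispersion: float = 1.0
    converged: bool = True

    def predict(self, delta_v, age):
        return expit(self.intercept + self.slope_delta_v * np.asarray(delta_v, float)
                     + self.slope_age * np.asarray(age, float))


def fit_population_curve(cases: pd.DataFrame, response: str = "risk") -> PopulationCurve:
    """Fit a population NFRk+ risk curve on (delta_v, age) by quasi-binomial GLM.

    ``cases`` needs columns ``delta_v``, ``age`` and the fractional response
    column (values in [0, 1]); an optional ``weight`` column supplies prior
    weights (default 1).  A constant response yields an intercept-only curve
    with a warning; complete separation is flagged as non-convergence.
    """
    import statsmodels.api as sm

    for col in ("delta_v", "age", response):
        if col not in cases.columns:
            raise ValueError(f"cases table missing column {col!r}")
    if len(cases) < 3:
        raise ValueError("need at least 3 cases to fit a population curve")
    y = cases[response].to_numpy(float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must be fractions in [0, 1]")
    w = cases["weight"].to_numpy(float) if "weight" in cases.columns else np.ones(len(y))

    if np.ptp(y) == 0.0:
        logger.warning("constant response %g: returning intercept-only curve", y[0])
        eps = 1e-12
        b0 = float(logit(np.clip(y[0], eps, 1 - eps)))
        return PopulationCurve(b0, 0.0, 0.0, len(y), dispersion=0.0)

    X = sm.add_constant(cases[["delta_v", "age"]].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial responses
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=200)

    coefs = np.asarray(res.params, dtype=float)
    converged = bool(res.converged) and bool(np.all(np.abs(coefs) < 1e3))
    if not converged:
        logger.warning("population-curve GLM did not converge (separation?)")
    df_resid = max(res.df_resid, 1)
    dispersion = float(res.pearson_chi2 / df_resid)
    return PopulationCurve(
        intercept=float(coefs[0]),
        slope_delta_v=float(coefs[1]),
        slope_age=float(coefs[2]),
        n_cases=len(y),
        dispersion=dispersion,
        converged=converged,
    )


def delta_v_at_risk(curve: PopulationCurve, risk: float, age: float) -> float:
    """Crash severity (km/h) at which the fitted curve crosses a risk level."""
    if not 0 < risk < 1:
        raise ValueError("risk must lie strictly inside (0, 1)")
    if curve.slope_delta_v == 0.0:
        raise ValueError("curve has zero delta-v slope: no crossing exists")
    return float((logit(risk) - curve.intercept - curve.slope_age * age) / curve.slope_delta_v)
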