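"""Evaluation and inversion of age-adjusted strain-based fracture risk.

All evaluation is on TRUE (logarithmic) strain, the quantity explicit finite
element codes report; engineering strains must be converted first with
:func:`engineering_to_true_strain`.

The risk of fracture at true strain ``s`` and age ``a`` is the failure-strain
CDF of the fitted AFT model:

    lognormal    F = Phi((ln s - mu_a) / alpha)
    weibull      F = 1 - exp(-(s / lambda_a)^alpha)
    loglogistic  F = 1 / (1 + (s / lambda_a)^(-alpha))

with ``mu_a = beta0 + beta1*a`` and ``lambda_a = exp(mu_a)``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import special
from scipy.stats import norm

from .params import Family, RiskParameters

logger = logging.getLogger(__name__)

#: Age span of the donor data behind the reference parameters; evaluation
#: outside it is extrapolation and triggers a logged warning.
FITTED_AGE_RANGE = (17.0, 99.0)


def engineering_to_true_strain(e):
    """Convert engineering strain (ΔL/L0) to true (logarithmic) strain.

    true = ln(1 + engineering).  Defined for e > -1.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= -1.0):
        raise ValueError("engineering strain must be > -1")
    out = np.log1p(e)
    return out.item() if out.ndim == 0 else out


def true_to_engineering_strain(t):
    """Inverse of :func:`engineering_to_true_strain`: exp(t) - 1."""
    t = np.asarray(t, dtype=float)
    out = np.expm1(t)
    return out.item() if out.ndim == 0 else out


def _warn_extrapolation(age) -> None:
    lo, hi = FITTED_AGE_RANGE
    a = np.asarray(age, dtype=float)
    if np.any((a < lo) | (a > hi)):
        logger.warning(
            "age outside the fitted range [%g, %g]; risk is an extrapolation",
            lo,
            hi,
        )


def fracture_risk(strain, age, params: RiskParameters, *, strict: bool = True):
    """Probability of rib cortical bone fracture at a true strain and age.

    Parameters
    ----------
    strain:
        Peak first principal TRUE strain (dimensionless), scalar or array.
    age:
        Occupant/donor age in years; broadcast against ``strain``.
    params:
        Fitted :class:`~ribrisk.params.RiskParameters`.
    strict:
        If True (library default), strain <= 0 raises.  If False (lenient
        mode, used for per-rib aggregation where meshes can report zero
        strain), nonpositive strains map to risk 0 with a logged warning.

    Returns
    -------
    Probability in [0, 1], strictly increasing in strain, and increasing in
    age when ``beta1 < 0``.
    """
    s = np.asarray(strain, dtype=float)
    a = np.asarray(age, dtype=float)
    nonpos = s <= 0
    if np.any(nonpos):
        if strict:
            raise ValueError("true strain must be > 0 for risk evaluation")
        logger.warning(
            "%d nonpositive strain value(s) clamped to risk 0 (lenient mode)",
            int(np.count_nonzero(nonpos)),
        )
    _warn_extrapolation(a)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(np.where(nonpos, 1.0, s)) - params.location(a)) / params.sigma
    if params.family is Family.LOGNORMAL:
        p = norm.cdf(z)
    elif params.family is Family.WEIBULL:
        p = -np.expm1(-np.exp(z))
    elif params.family is Family.LOGLOGISTIC:
        p = special.expit(z)
    else:  # pragma: no cover - Family.coerce guards this
        raise ValueError(f"unknown family {params.family!r}")
    p = np.where(nonpos, 0.0, p)
    return p.item() if p.ndim == 0 else p


def strain_at_risk(risk, age, params: RiskParameters):
    """True strain producing a given fracture risk at a given age.

    Closed-form inverse of :func:`fracture_risk` per family; risk must lie
    strictly inside (0, 1).
    """
    r = np.asarray(risk, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("risk must lie strictly inside (0, 1)")
    a = np.asarray(age, dtype=float)
    _warn_extrapolation(a)

    if params.family is Family.LOGNORMAL:
        z = norm.ppf(r)
    elif params.family is Family.WEIBULL:
        # F = 1 - exp(-e^z)  =>  z = ln(-ln(1-r))
        z = np.log(-np.log1p(-r))
    elif params.family is Family.LOGLOGISTIC:
        z = special.logit(r)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {params.family!r}")
    s = np.exp(params.location(a) + params.sigma * z)
    return s.item() if s.ndim == 0 else s


def decade_strain_factor(beta1: float, years: float = 10.0) -> tuple[float, float]:
    """AFT acceleration factor over an aging span, and its complement.

    Returns ``(factor, reduction)`` with ``factor = exp(beta1 * years)``:
    after ``years`` of aging a subject requires only ``factor`` times the
    strain to reach the same fracture risk, i.e. failure strain is reduced
    by ``reduction = 1 - factor`` over the span.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    factor = float(np.exp(beta1 * years))
    return factor, 1.0 - factor
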