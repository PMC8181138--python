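"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ribrisk as rr

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Independent oracles (series / enumeration; no scipy involved)
# ---------------------------------------------------------------------------

def erf_series(x: float, terms: int = 70) -> float:
    """Taylor-series erf, independent of scipy; accurate for |x| <= ~2.5."""
    s = 0.0
    term = x
    for n in range(terms):
        s += term / (2 * n + 1)
        term *= -x * x / (n + 1)
    return 2.0 / math.sqrt(math.pi) * s


def normal_cdf_oracle(z: float) -> float:
    return 0.5 + 0.5 * erf_series(z / math.sqrt(2.0))


def log1p_series(e: Fraction, terms: int = 60) -> float:
    """Alternating log series in exact rational arithmetic."""
    s = Fraction(0)
    for n in range(1, terms):
        s += Fraction((-1) ** (n + 1)) * e**n / n
    return float(s)


def poisson_binomial_enumeration(p: np.ndarray) -> np.ndarray:
    """Exhaustive 2^n enumeration of the fractured-rib count PMF (n <= ~14).

    Vectorized over all outcome bitmasks; independent of the DP recurrence.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # (2^n, n)
    probs = np.prod(np.where(masks == 1, p, 1.0 - p), axis=1)
    counts = masks.sum(axis=1)
    return np.bincount(counts, weights=probs, minlength=n + 1)


def bisect_strain(risk: float, age: float, params, lo=1e-10, hi=10.0, iters=200):
    """Root-find the strain for a risk level directly on fracture_risk."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if rr.fracture_risk(mid, age, params) < risk:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ref_lognormal() -> rr.RiskParameters:
    return rr.reference_parameters("lognormal")


@pytest.fixture(scope="session", params=[f.value for f in rr.Family])
def ref_any_family(request) -> rr.RiskParameters:
    return rr.reference_parameters(request.param)


@pytest.fixture(scope="session")
def coupons58():
    """One seeded synthetic coupon dataset at the study conditions (n=58)."""
    return rr.simulate_coupons(rr.CouponGeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fit58(coupons58) -> rr.AFTFit:
    return rr.fit_aft(coupons58, "lognormal", ("age",))
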