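"""Synthetic coupon-test and rib-strain datasets for pipeline testing.

The donor-level tensile dataset behind the reference risk function is not
publicly deposited, so this module generates datasets with the same
statistical structure the analysis assumes: log-linear decline of failure
strain with age around an AFT truth, truncated-normal donor ages matching
the published moments (mean 56.2, SD 26.1, bounded to 17-99 years), and
one coupon per subject.  A second generator emulates the *structure* of
stochastic human-body-model simulation output: per-case crash severity
(delta-v) and occupant age with 24 per-rib peak true strains distributed
log-normally around a severity-dependent median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gumbel_l, logistic, norm, truncnorm

from .params import Family, RiskParameters, reference_parameters
from .risk import true_to_engineering_strain

_ERR_RVS = {
    Family.LOGNORMAL: norm,
    Family.LOGLOGISTIC: logistic,
    Family.WEIBULL: gumbel_l,
}


@dataclass(frozen=True)
class CouponGeneratorConfig:
    """Configuration for synthetic tensile coupon datasets.

    Defaults reproduce the study conditions of the reference fit: 58
    subjects, ages truncated-normal(56.2, 26.1) on [17, 99], 31/58 male,
    log-normal AFT truth from the shipped reference parameters, no sex
    effect, true-strain output, all observations exact.
    """

    n: int = 58
    age_mean: float = 56.2
    age_sd: float = 26.1
    age_bounds: tuple[float, float] = (17.0, 99.0)
    truth: RiskParameters = field(default_factory=reference_parameters)
    sex_ratio: float = 31.0 / 58.0
    sex_effect: float = 0.0          # added to ln(strain) for males; 0 = no effect
    strain_convention: str = "true"  # or "engineering"
    right_censor_at: float | None = None  # true-strain threshold, None = all exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError("age_bounds must be ordered")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.strain_convention not in ("true", "engineering"):
            raise ValueError("strain_convention must be 'true' or 'engineering'")
        # truncation window must intersect the bulk of the age distribution
        if hi < self.age_mean - 6 * self.age_sd or lo > self.age_mean + 6 * self.age_sd:
            raise ValueError("age bounds exclude the age distribution entirely")


def simulate_coupons(config: CouponGeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic coupon-test dataset from a known AFT truth.

    Returns a DataFrame with the coupon CSV schema (``subject_id, age, sex,
    failure_strain, strain_convention, censor, strain_rate``).  Ages are
    truncated-normal within the configured bounds; ln(strain) follows
    beta0 + beta1*age (+ sex_effect for males) + sigma*eps with the error
    law of the truth's family.  Sex is assigned independently of strain
    unless ``sex_effect`` is nonzero.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_bounds
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                         size=config.n, random_state=rng)
    male = rng.random(config.n) < config.sex_ratio
    eps = _ERR_RVS[config.truth.family].rvs(size=config.n, random_state=rng)
    log_s = (config.truth.location(ages)
             + config.sex_effect * male.astype(float)
             + config.truth.sigma * eps)
    strain = np.exp(log_s)

    censor = np.full(config.n, "exact", dtype=object)
    if config.right_censor_at is not None:
        hit = strain > config.right_censor_at
        strain = np.where(hit, config.right_censor_at, strain)
        censor[hit] = "right"

    if config.strain_convention == "engineering":
        strain = true_to_engineering_strain(strain)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(config.n)],
            "age": ages,
            "sex": np.where(male, "M", "F"),
            "failure_strain": strain,
            "strain_convention": config.strain_convention,
            "censor": censor,
            "strain_rate": 0.5,
        }
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration for synthetic rib-strain case tables.

    Emulates the structure (not the physics) of stochastic crash-simulation
    output: per-case delta-v and occupant age uniform over their ranges,
    and 24 per-rib peak true strains log-normal around a median that grows
    log-linearly with severity:

        median(dv) = strain_floor * exp(strain_slope * (dv - dv_min)).

    Defaults place the median between ~0.6% true strain at the severity
    floor and ~2.5% at 80 km/h — the range over which the reference risk
    function transitions from negligible to high per-rib risk.
    """

    n_cases: int = 200
    delta_v_range: tuple[float, float] = (20.0, 80.0)
    age_range: tuple[float, float] = (20.0, 90.0)
    strain_floor: float = 0.006
    strain_slope: float = 0.024   # per km/h, on the log-strain scale
    rib_spread: float = 0.35      # SD of ln(strain) across ribs within a case
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.delta_v_range[0] > self.delta_v_range[1]:
            raise ValueError("delta_v_range must be ordered")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered")
        if self.strain_floor <= 0 or self.rib_spread <= 0:
            raise ValueError("spread parameters must be positive")


def median_rib_strain(config: ScenarioConfig, delta_v) -> np.ndarray:
    """Median per-rib true strain at a crash severity (strictly increasing)."""
    dv = np.asarray(delta_v, dtype=float)
    return config.strain_floor * np.exp(config.strain_slope * (dv - config.delta_v_range[0]))


def simulate_rib_strain_cases(config: ScenarioConfig) -> pd.DataFrame:
    """Generate a rib-strain case table with the rib CSV schema.

    Columns: ``case_id, occupant_age, delta_v, L1..L12, R1..R12`` (peak
    first principal true strains).  Reproducible given the seed.
    """
    from .aggregation import RIB_KEYS

    rng = np.random.default_rng(config.seed)
    dv = rng.uniform(*config.delta_v_range, size=config.n_cases)
    ages = rng.uniform(*config.age_range, size=config.n_cases)
    med = median_rib_strain(config, dv)
    strains = med[:, None] * np.exp(
        config.rib_spread * rng.standard_normal((config.n_cases, len(RIB_KEYS)))
    )
    out = pd.DataFrame(strains, columns=list(RIB_KEYS))
    out.insert(0, "delta_v", dv)
    out.insert(0, "occupant_age", ages)
    out.insert(0, "case_id", [f"C{i:04d}" for i in range(config.n_cases)])
    return out


def with_seed(config, seed: int):
    """Copy of a generator config with a different seed."""
    return replace(config, seed=seed)
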