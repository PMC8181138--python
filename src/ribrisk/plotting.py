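"""Deterministic plotting of risk curves and risk-level strain loci."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .params import RiskParameters
from .risk import fracture_risk, strain_at_risk


def plot_risk_curves(
    models: Sequence[RiskParameters] | RiskParameters,
    ages: Sequence[float] = (25.0, 50.0, 75.0),
    strain_grid: np.ndarray | None = None,
    out: str | Path | None = None,
    labels: Sequence[str] | None = None,
):
    """Risk-vs-true-strain curves for several ages (and model overlays).

    Fixed grid, no randomness: repeated calls on the same inputs draw the
    same data.  Returns the matplotlib figure.
    """
    if isinstance(models, RiskParameters):
        models = [models]
    ages = list(ages)
    if not ages:
        raise ValueError("at least one age is required")
    if strain_grid is None:
        strain_grid = np.linspace(1e-4, 0.06, 400)
    if labels is None:
        labels = [m.family.value for m in models]

    fig, ax = plt.subplots(figsize=(6, 4))
    for m, lab in zip(models, labels):
        for age in ages:
            risk = fracture_risk(strain_grid, age, m)
            suffix = f", {lab}" if len(models) > 1 else ""
            ax.plot(strain_grid, risk, label=f"age {age:g}{suffix}")
    ax.set_xlabel("true strain (-)")
    ax.set_ylabel("rib fracture risk")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def plot_strain_loci(
    params: RiskParameters,
    risk_levels: Sequence[float] = (0.05, 0.50, 0.95),
    age_grid: np.ndarray | None = None,
    data=None,
    out: str | Path | None = None,
):
    """Strains producing fixed risk levels across the age span.

    Optionally overlays (age, failure strain) observations from a coupon
    dataset.  The 50% locus equals exp(beta0 + beta1*age) for the
    log-normal and log-logistic families.
    """
    if age_grid is None:
        age_grid = np.linspace(17.0, 99.0, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in risk_levels:
        ax.plot(age_grid, strain_at_risk(r, age_grid, params), label=f"{100 * r:g}% risk")
    if data is not None:
        ax.scatter(data["age"], data["failure_strain"], s=12, c="k", alpha=0.6,
                   label="failure strains")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("true strain (-)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
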