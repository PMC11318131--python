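"""Two-arm sample size and the analytic cost-effectiveness rule.

The per-arm sample size of a simple two-arm trial with a continuous outcome
is ``n = F (sigma_1^2 + sigma_2^2) / d^2`` with
``F = (z_{1-alpha/2} + z_{power})^2`` (normal approximation, equal arms).
Because total measurement cost is proportional to ``n * unit_cost`` and
``n`` is proportional to the outcome variance on the measured scale, a
cheaper-but-noisier measure achieves the same power for less money exactly
when its relative increase in effective variance is smaller than the
gold standard's relative increase in unit cost — the decision rule
implemented by :func:`decide`.

Measurement noise enters the effective variance in two ways: the variance
from outcome categorisation ``sigma_c^2`` (additive) and classical
measurement error implied by a concurrent validity ``r < 1`` (the error
variance ``sigma^2 (1 - r^2) / r^2`` makes the measure correlate ``r`` with
the truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import norm as _norm

__all__ = [
    "TrialDesign",
    "MeasureSpec",
    "CostDecision",
    "critical_factor",
    "required_n",
    "effective_variance",
    "decide",
]


@dataclass(frozen=True)
class TrialDesign:
    """Design parameters of a two-arm superiority trial with equal arms."""

    d: float
    alpha: float = 0.05
    power: float = 0.9
    sd1: float = 1.0
    sd2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.d <= 0:
            raise ValueError("difference to detect must be positive")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("per-arm SDs must be positive")


@dataclass(frozen=True)
class MeasureSpec:
    """Cost and noise profile of one outcome measure.

    ``validity_r`` is the concurrent validity correlation against the gold
    standard (1 for the gold standard itself); ``sigma_c_sq`` the variance
    from the measure's outcome categorisation; ``length_items`` the burden
    proxy used by the non-response model.
    """

    unit_cost: float
    validity_r: float = 1.0
    sigma_c_sq: float = 0.0
    length_items: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.unit_cost <= 0:
            raise ValueError("unit_cost must be positive")
        if not 0 < self.validity_r <= 1:
            raise ValueError("validity_r must be in (0, 1]")
        if self.sigma_c_sq < 0:
            raise ValueError("sigma_c_sq must be non-negative")
        if self.length_items < 1:
            raise ValueError("length_items must be >= 1")


@dataclass(frozen=True)
class CostDecision:
    """Outcome of comparing a cheap measure against the gold standard."""

    n_per_arm_gold: float
    n_per_arm_cheap: float
    total_cost_gold: float
    total_cost_cheap: float
    variance_ratio: float
    cost_ratio: float
    cheap_is_cost_effective: bool


def critical_factor(alpha: float, power: float) -> float:
    """``F = (z_{1-alpha/2} + z_{power})^2`` of the sample-size formula."""
    return float((_norm.ppf(1 - alpha / 2) + _norm.ppf(power)) ** 2)


def required_n(design: TrialDesign, ceil: bool = False) -> float:
    """Per-arm sample size ``F (sd1^2 + sd2^2) / d^2``.

    Returned unrounded by default so downstream algebra stays exact; pass
    ``ceil=True`` for a whole number of participants.
    """
    F = critical_factor(design.alpha, design.power)
    n = F * (design.sd1**2 + design.sd2**2) / design.d**2
    return float(math.ceil(n)) if ceil else float(n)


def effective_variance(
    sigma_sq: float, measure: MeasureSpec, validity_mode: str = "classical"
) -> float:
    """Outcome variance on the measured scale.

    ``"classical"`` adds categorisation variance and the classical-error
    variance implied by the validity:
    ``sigma^2 + sigma_c^2 + sigma^2 (1 - r^2) / r^2``.  The alternative
    ``"attenuation"`` mode instead treats low validity as shrinking the
    detectable effect (``d -> r d``), which is algebraically equivalent to
    dividing the whole variance (including sigma_c^2) by ``r^2``.
    """
    if sigma_sq <= 0:
        raise ValueError("population variance must be positive")
    r = measure.validity_r
    if validity_mode == "classical":
        return sigma_sq / r**2 + measure.sigma_c_sq
    if validity_mode == "attenuation":
        return (sigma_sq + measure.sigma_c_sq) / r**2
    raise ValueError(f"unknown validity_mode: {validity_mode!r}")


def decide(
    design: TrialDesign,
    gold: MeasureSpec,
    cheap: MeasureSpec,
    sigma_sq: float,
    validity_mode: str = "classical",
    ceil_n: bool = False,
) -> CostDecision:
    """Apply the analytic cost-effectiveness rule.

    Computes the per-arm sample size under each measure's effective
    variance, prices both trials (two arms at the measure's unit cost), and
    declares the cheap measure cost-effective when its variance ratio is
    strictly below the unit-cost ratio.  Ties go to the gold standard,
    which carries less information-bias risk.
    """
    var_gold = effective_variance(sigma_sq, gold, validity_mode)
    var_cheap = effective_variance(sigma_sq, cheap, validity_mode)
    n_gold = required_n(replace(design, sd1=math.sqrt(var_gold), sd2=math.sqrt(var_gold)), ceil=ceil_n)
    n_cheap = required_n(replace(design, sd1=math.sqrt(var_cheap), sd2=math.sqrt(var_cheap)), ceil=ceil_n)
    total_gold = 2.0 * n_gold * gold.unit_cost
    total_cheap = 2.0 * n_cheap * cheap.unit_cost
    variance_ratio = var_cheap / var_gold
    cost_ratio = gold.unit_cost / cheap.unit_cost
    return CostDecision(
        n_per_arm_gold=n_gold,
        n_per_arm_cheap=n_cheap,
        total_cost_gold=total_gold,
        total_cost_cheap=total_cheap,
        variance_ratio=variance_ratio,
        cost_ratio=cost_ratio,
        cheap_is_cost_effective=variance_ratio < cost_ratio,
    )
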