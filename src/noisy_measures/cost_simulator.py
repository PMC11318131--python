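"""Cost-ratio simulation: cheap questionnaires vs the gold standard.

For a grid of population outcome SDs and questionnaire lengths (category
counts), compute the ratio of the total outcome-measurement cost of a
cheaper-but-noisier measure to that of the 100-level gold standard, at equal
power.  Per grid cell the pipeline is fully analytic: build the constrained
discrete normal outcome distribution, get the categorisation variance of the
scale, inflate by the measure's validity, convert effective variances into
per-arm sample sizes, optionally inflate recruitment for burden-driven
non-response, and price both designs.

With non-response ignored, longer questionnaires (more categories) win once
the population SD is appreciable; charging for the extra recruitment that
longer questionnaires need reverses the ordering in favour of shorter ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .burden_response import apply_to_rate, response_multiplier
from .categorisation import (
    categorisation_variance,
    constrained_normal_distribution,
    make_scale,
)
from .power_cost import MeasureSpec, TrialDesign, effective_variance, required_n

__all__ = ["SimulationConfig", "CostCurvePoint", "run", "as_dataframe", "export_curves"]


def _default_sd_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.5, 25.001, 0.5), 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for the cost-ratio grid.

    Lengths are proxied by item counts: the gold standard counts as
    ``gold_levels`` items and an M-category questionnaire as M items; RQ for
    the non-response penalty is each measure's length over the shortest
    measure in the scenario.  ``response_model`` chooses how the burden
    power law converts to a response probability: ``"rate"`` multiplies the
    baseline rate by RQ**slope (the conversion behind "50% more people per
    doubling"), ``"odds"`` applies the multiplier on the odds scale.
    ``seed`` is accepted for stochastic extensions; the default pipeline is
    fully analytic.
    """

    alpha: float = 0.05
    power: float = 0.9
    d: float = 0.1
    validity_r: float = 0.7
    gold_cost: float = 50.0
    cheap_cost: float = 5.0
    gold_levels: int = 100
    lo: int = 0
    hi: int = 99
    mu: float = 49.5
    sd_grid: tuple[float, ...] = field(default_factory=_default_sd_grid)
    category_counts: tuple[int, ...] = (3, 5, 8, 10, 15)
    include_nonresponse: bool = True
    baseline_response_p: float = 0.97
    burden_slope: float = -0.594
    response_model: str = "rate"
    lost_cost_equals_followed: bool = True
    validity_mode: str = "classical"
    midpoint_convention: str = "published"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gold_cost <= 0 or self.cheap_cost <= 0:
            raise ValueError("unit costs must be positive")
        if not self.sd_grid or not self.category_counts:
            raise ValueError("sd_grid and category_counts must be non-empty")
        if any(sd <= 0 for sd in self.sd_grid):
            raise ValueError("outcome SDs must be positive")
        if not 0 < self.baseline_response_p < 1:
            raise ValueError("baseline_response_p must be in (0, 1)")
        if self.response_model not in ("rate", "odds"):
            raise ValueError(f"unknown response_model: {self.response_model!r}")
        if self.gold_levels < max(self.category_counts):
            raise ValueError("gold standard must have at least as many levels as any scale")


@dataclass(frozen=True)
class CostCurvePoint:
    """One (outcome SD, category count) cell of the simulation grid."""

    sd: float
    M: int
    nonresponse: bool
    effective_var_cheap: float
    effective_var_gold: float
    n_cheap: float
    n_gold: float
    recruited_cheap: float
    recruited_gold: float
    total_cost_cheap: float
    total_cost_gold: float
    cost_ratio: float


def _response_p(config: SimulationConfig, items: float, shortest: float) -> float:
    rq = items / shortest
    mult = response_multiplier(rq, config.burden_slope)
    if config.response_model == "odds":
        return apply_to_rate(config.baseline_response_p, mult)
    return min(1.0, config.baseline_response_p * mult)


def run(config: SimulationConfig) -> list[CostCurvePoint]:
    """Evaluate the cost-ratio grid for one non-response setting."""
    design = TrialDesign(d=config.d, alpha=config.alpha, power=config.power)
    shortest = float(min(config.category_counts))
    p_gold = _response_p(config, config.gold_levels, shortest)
    points: list[CostCurvePoint] = []
    for sd in config.sd_grid:
        dist = constrained_normal_distribution(config.mu, sd, config.lo, config.hi)
        sigma_sq = dist.variance()
        gold = MeasureSpec(unit_cost=config.gold_cost, length_items=config.gold_levels,
                           name="gold")
        var_gold = effective_variance(sigma_sq, gold, config.validity_mode)
        n_gold = required_n(replace(design, sd1=var_gold**0.5, sd2=var_gold**0.5))
        for M in config.category_counts:
            scale = make_scale(M, config.lo, config.hi, config.midpoint_convention)
            sigma_c_sq = categorisation_variance(dist, scale).sigma_c_sq
            cheap = MeasureSpec(
                unit_cost=config.cheap_cost,
                validity_r=config.validity_r,
                sigma_c_sq=sigma_c_sq,
                length_items=M,
                name=f"{M}-category",
            )
            var_cheap = effective_variance(sigma_sq, cheap, config.validity_mode)
            n_cheap = required_n(replace(design, sd1=var_cheap**0.5, sd2=var_cheap**0.5))
            if config.include_nonresponse:
                p_cheap = _response_p(config, M, shortest)
                recruited_gold = n_gold / p_gold
                recruited_cheap = n_cheap / p_cheap
            else:
                recruited_gold, recruited_cheap = n_gold, n_cheap
            billed_gold = recruited_gold if config.lost_cost_equals_followed else n_gold
            billed_cheap = recruited_cheap if config.lost_cost_equals_followed else n_cheap
            total_gold = 2.0 * billed_gold * config.gold_cost
            total_cheap = 2.0 * billed_cheap * config.cheap_cost
            points.append(
                CostCurvePoint(
                    sd=float(sd),
                    M=M,
                    nonresponse=config.include_nonresponse,
                    effective_var_cheap=var_cheap,
                    effective_var_gold=var_gold,
                    n_cheap=n_cheap,
                    n_gold=n_gold,
                    recruited_cheap=recruited_cheap,
                    recruited_gold=recruited_gold,
                    total_cost_cheap=total_cheap,
                    total_cost_gold=total_gold,
                    cost_ratio=total_cheap / total_gold,
                )
            )
    return points


def as_dataframe(points: Sequence[CostCurvePoint]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in points])


def export_curves(points: Sequence[CostCurvePoint], path, plot_path=None) -> pd.DataFrame:
    """Write the grid as CSV; optionally plot cost ratio vs SD.

    The plot draws one line per category count and one panel per
    non-response setting present in ``points``.
    """
    if not points:
        raise ValueError("no points to export")
    df = as_dataframe(points)
    df.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        settings = sorted(df["nonresponse"].unique())
        fig, axes = plt.subplots(1, len(settings), figsize=(6 * len(settings), 4.5),
                                 squeeze=False, sharey=True)
        for ax, setting in zip(axes[0], settings):
            panel = df[df["nonresponse"] == setting]
            for M, grp in panel.groupby("M"):
                ax.plot(grp["sd"], grp["cost_ratio"], label=f"{M} categories")
            ax.axhline(1.0, color="grey", lw=0.8, ls="--")
            ax.set_xlabel("population outcome SD")
            ax.set_title("with non-response" if setting else "without non-response")
            ax.set_yscale("log")
        axes[0][0].set_ylabel("cheap : gold total cost ratio")
        axes[0][-1].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
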