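"""Participant burden and questionnaire response: the power-law meta-regression.

Randomised trials that allocate participants to a longer or a shorter
questionnaire estimate, per trial, the log odds ratio of responding
(long vs short).  Regressing that log OR on the log of the questionnaire
length ratio RQ with inverse-variance weights and an additive random effect
(tau^2 by REML) yields a power law on the natural scale,

    OR = RQ ** slope,

with a published slope near -0.594: doubling a questionnaire's length
multiplies the odds of response by 2**-0.594 ~ 0.66, i.e. reduces response
by around one third and requires asking roughly 50% more people to collect
the same number of outcomes.

The real trial-level dataset behind the published fit is not distributed
with this package; :func:`synth_trials` generates trial sets under the same
model so the estimator is testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "BurdenTrial",
    "MetaRegressionFit",
    "trial_effect",
    "fit",
    "response_multiplier",
    "apply_to_rate",
    "synth_trials",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = [
    "id",
    "resp_long",
    "nonresp_long",
    "resp_short",
    "nonresp_short",
    "len_long",
    "len_short",
    "length_unit",
]


@dataclass(frozen=True)
class BurdenTrial:
    """One randomised long-vs-short questionnaire trial (2x2 counts).

    Lengths may be pages, questions, words or minutes, as long as both arms
    of a trial use the same unit; only the within-trial ratio is used.
    Counts may be non-integral (expected counts are valid input).
    """

    id: str
    resp_long: float
    nonresp_long: float
    resp_short: float
    nonresp_short: float
    len_long: float
    len_short: float
    length_unit: str = "pages"

    def __post_init__(self) -> None:
        counts = (self.resp_long, self.nonresp_long, self.resp_short, self.nonresp_short)
        if any(c < 0 for c in counts):
            raise ValueError(f"trial {self.id}: counts must be non-negative")
        if self.resp_long + self.nonresp_long == 0 or self.resp_short + self.nonresp_short == 0:
            raise ValueError(f"trial {self.id}: an arm has no participants")
        if self.len_short <= 0 or self.len_long < self.len_short:
            raise ValueError(f"trial {self.id}: need len_long >= len_short > 0")

    @property
    def length_ratio(self) -> float:
        return self.len_long / self.len_short


def trial_effect(trial: BurdenTrial) -> tuple[float, float]:
    """Log odds ratio of response (long vs short) and its sampling variance.

    Uses the standard Woolf variance (sum of reciprocal cell counts); if any
    cell is zero, 0.5 is added to all four cells (Gart continuity
    correction).
    """
    a, b = trial.resp_long, trial.nonresp_long
    c, d = trial.resp_short, trial.nonresp_short
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a / b) / (c / d))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return log_or, var


@dataclass(frozen=True)
class MetaRegressionFit:
    """Random-effects meta-regression of log OR on log length ratio."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    tau_sq: float
    tau_sq_null: float
    r_sq_pct: float
    k: int
    quad_coef: float | None = None

    def as_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "ci95_slope": list(self.ci95_slope),
            "tau_sq": self.tau_sq,
            "tau_sq_null": self.tau_sq_null,
            "r_sq_pct": self.r_sq_pct,
            "k": self.k,
        }
        if self.quad_coef is not None:
            d["quad_coef"] = self.quad_coef
        return d


def _reml_tau_sq(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-study variance tau^2.

    Profiles the restricted log-likelihood of the weighted regression over
    tau^2 >= 0 (weights 1/(v_i + tau^2)).
    """

    def nll(tau_sq: float) -> float:
        w = 1.0 / (v + tau_sq)
        xtwx = X.T @ (X * w[:, None])
        beta = np.linalg.solve(xtwx, X.T @ (w * y))
        resid = y - X @ beta
        sign, logdet = np.linalg.slogdet(xtwx)
        return 0.5 * (np.sum(np.log(v + tau_sq)) + logdet + np.sum(w * resid**2))

    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1.0)
    res = minimize_scalar(nll, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-10})
    # the boundary tau^2 = 0 may beat the interior optimum
    return 0.0 if nll(0.0) <= res.fun else float(res.x)


def _wls(y: np.ndarray, X: np.ndarray, v: np.ndarray, tau_sq: float):
    w = 1.0 / (v + tau_sq)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * y))
    return beta, cov


def fit(trials: Sequence[BurdenTrial], quadratic: bool = False) -> MetaRegressionFit:
    """Fit the random-effects log-log meta-regression.

    Weights combine each trial's inverse sampling variance with an additive
    between-study component estimated by REML.  ``r_sq_pct`` is the
    proportional reduction in tau^2 relative to the intercept-only model
    (one convention for a meta-regression pseudo R^2).  With
    ``quadratic=True`` a (log RQ)^2 term is added; its coefficient is
    reported in ``quad_coef``.
    """
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for a meta-regression")
    effects = [trial_effect(t) for t in trials]
    y = np.array([e[0] for e in effects])
    v = np.array([e[1] for e in effects])
    x = np.log([t.length_ratio for t in trials])
    if np.ptp(x) == 0:
        raise ValueError("all length ratios equal: slope is unidentifiable")

    cols = [np.ones_like(x), x] + ([x**2] if quadratic else [])
    X = np.column_stack(cols)
    tau_sq = _reml_tau_sq(y, X, v)
    beta, cov = _wls(y, X, v, tau_sq)
    tau_sq_null = _reml_tau_sq(y, np.ones((len(y), 1)), v)
    r_sq = 100.0 * max(0.0, 1.0 - tau_sq / tau_sq_null) if tau_sq_null > 0 else 0.0

    slope, se_slope = float(beta[1]), float(np.sqrt(cov[1, 1]))
    return MetaRegressionFit(
        slope=slope,
        intercept=float(beta[0]),
        se_slope=se_slope,
        se_intercept=float(np.sqrt(cov[0, 0])),
        ci95_slope=(slope - 1.96 * se_slope, slope + 1.96 * se_slope),
        tau_sq=float(tau_sq),
        tau_sq_null=float(tau_sq_null),
        r_sq_pct=float(r_sq),
        k=len(trials),
        quad_coef=float(beta[2]) if quadratic else None,
    )


def response_multiplier(rq: float, slope: float = -0.594) -> float:
    """Odds multiplier ``RQ ** slope`` for a questionnaire RQ times longer."""
    if rq <= 0:
        raise ValueError("length ratio must be positive")
    return float(rq**slope)


def apply_to_rate(p0: float, multiplier: float) -> float:
    """Apply an odds multiplier to a baseline response probability."""
    if not 0 < p0 < 1:
        raise ValueError("baseline response probability must be in (0, 1)")
    if multiplier <= 0:
        raise ValueError("odds multiplier must be positive")
    odds = multiplier * p0 / (1 - p0)
    return odds / (1 + odds)


def synth_trials(
    k: int = 40,
    true_slope: float = -0.594,
    true_intercept: float = 0.0,
    tau: float = 0.25,
    baseline_p: float = 0.7,
    n_per_arm: int = 200,
    length_ratio_range: tuple[float, float] = (1.25, 4.0),
    len_short: float = 4.0,
    seed: int | np.random.Generator | None = None,
    sampling: str = "binomial",
) -> list[BurdenTrial]:
    """Generate questionnaire-length trials under the power-law model.

    Per trial: log RQ is uniform over the log of ``length_ratio_range``, a
    study effect is drawn from Normal(0, tau^2), the short arm responds with
    probability ``baseline_p`` and the long arm with the odds-scaled
    probability; counts are Binomial(``n_per_arm``).  With
    ``sampling="expected"`` the expected (non-integral) counts are emitted
    instead — the noiseless limit used to check estimator consistency.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if not 0 < baseline_p < 1:
        raise ValueError("baseline_p must be in (0, 1)")
    if sampling not in ("binomial", "expected"):
        raise ValueError(f"unknown sampling mode: {sampling!r}")
    lo, hi = length_ratio_range
    if not 1 <= lo <= hi:
        raise ValueError("length_ratio_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)

    trials = []
    for i in range(k):
        log_rq = rng.uniform(math.log(lo), math.log(hi))
        u = rng.normal(0.0, tau) if tau > 0 else 0.0
        mult = math.exp(true_intercept + true_slope * log_rq + u)
        p_short = baseline_p
        p_long = apply_to_rate(p_short, mult)
        if sampling == "binomial":
            r_long = int(rng.binomial(n_per_arm, p_long))
            r_short = int(rng.binomial(n_per_arm, p_short))
        else:
            r_long = n_per_arm * p_long
            r_short = n_per_arm * p_short
        trials.append(
            BurdenTrial(
                id=f"synth-{i + 1:03d}",
                resp_long=r_long,
                nonresp_long=n_per_arm - r_long,
                resp_short=r_short,
                nonresp_short=n_per_arm - r_short,
                len_long=len_short * math.exp(log_rq),
                len_short=len_short,
                length_unit="pages",
            )
        )
    return trials


def read_trials(path) -> list[BurdenTrial]:
    """Read a delimited trial table (columns as in ``TRIAL_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - {"length_unit"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    if "length_unit" not in df.columns:
        df["length_unit"] = "pages"
    return [
        BurdenTrial(
            id=str(row.id),
            resp_long=row.resp_long,
            nonresp_long=row.nonresp_long,
            resp_short=row.resp_short,
            nonresp_short=row.nonresp_short,
            len_long=row.len_long,
            len_short=row.len_short,
            length_unit=row.length_unit,
        )
        for row in df.itertuples(index=False)
    ]


def write_trials(trials: Sequence[BurdenTrial], path) -> None:
    """Write trials as a CSV with the standard column layout."""
    pd.DataFrame([t.__dict__ for t in trials], columns=TRIAL_COLUMNS).to_csv(
        path, index=False
    )
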