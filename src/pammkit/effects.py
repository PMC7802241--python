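"""Derived quantities from a fitted model.

All effects are reported for an average subject (frailty z = 0), with
pointwise 95% confidence intervals computed on the linear-predictor scale
from the Bayesian posterior covariance and transformed monotonically.
Hazards are per day; the incidence scale multiplies by 365.25 episodes per
child-year, matching the convention of reporting a "yearly incidence rate"
for a piece-wise constant daily hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson

from .model import PAMMFit

__all__ = [
    "EffectCurve",
    "SeasonGrid",
    "hazard_curve",
    "hazard_ratio_curve",
    "cumulative_incidence",
    "select_final_model",
    "season_grids",
    "season_label",
]

YEAR_DAYS = 365.25
_Z95 = float(norm.ppf(0.975))

_SCALES = {"hazard_per_day", "incidence_per_child_year", "hazard_ratio", "cumulative_incidence"}


@dataclass
class EffectCurve:
    """Per-interval estimate with pointwise 95% bounds."""

    t: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_j": self.t, "estimate": self.estimate, "lower": self.lower, "upper": self.upper}
        )


@dataclass
class SeasonGrid:
    """Age x day-of-year lattice of incidence or hazard-ratio values."""

    age: np.ndarray
    day_of_year: np.ndarray
    values: np.ndarray  # shape (len(age), len(day_of_year))
    scale: str
    variant: str  # season_at_birth | current_season

    def to_frame(self) -> pd.DataFrame:
        aa, dd = np.meshgrid(self.age, self.day_of_year, indexing="ij")
        return pd.DataFrame(
            {"age": aa.ravel(), "day_of_year": dd.ravel(), "value": self.values.ravel()}
        )


def _linear_predictor_rows(fit: PAMMFit, t: np.ndarray, covariate_values: dict[str, float]) -> np.ndarray:
    """Design rows at times ``t`` with fixed covariate values, z = 0."""
    d = fit.design
    n = len(t)
    X = np.zeros((n, d.X.shape[1]))
    for name, ti in d.terms.items():
        if name == "intercept":
            X[:, ti.sl] = 1.0
        elif ti.kind == "parametric":
            if name not in covariate_values:
                raise ValueError(f"no value supplied for covariate {name!r}")
            X[:, ti.sl] = float(covariate_values[name])
        elif ti.kind == "baseline_smooth":
            X[:, ti.sl] = ti.block.evaluate(t)
        elif ti.kind == "varying_coefficient":
            xv = float(covariate_values[d.spec.covariate])
            X[:, ti.sl] = ti.block.evaluate(np.full(n, xv), t)
        elif ti.kind == "tensor":
            season = covariate_values.get(d.spec.tensor.season_col)
            if season is None:
                raise ValueError(
                    f"tensor model needs a value for {d.spec.tensor.season_col!r}"
                )
            X[:, ti.sl] = ti.block.evaluate(t, np.full(n, float(season)))
    return X


def hazard_curve(
    fit: PAMMFit,
    covariate_values: dict[str, float] | None = None,
    scale: str = "hazard_per_day",
) -> EffectCurve:
    """Per-interval hazard exp(eta(t_j)) at z = 0 with pointwise 95% CI.

    ``scale='incidence_per_child_year'`` multiplies by 365.25.
    """
    if scale not in ("hazard_per_day", "incidence_per_child_year"):
        raise ValueError("scale must be hazard_per_day or incidence_per_child_year")
    covariate_values = covariate_values or {}
    t = fit.t_grid
    X = _linear_predictor_rows(fit, t, covariate_values)
    eta = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov, X), 0.0))
    mult = YEAR_DAYS if scale == "incidence_per_child_year" else 1.0
    return EffectCurve(
        t=t,
        estimate=mult * np.exp(eta),
        lower=mult * np.exp(eta - _Z95 * se),
        upper=mult * np.exp(eta + _Z95 * se),
        scale=scale,
    )


def hazard_ratio_curve(fit: PAMMFit, covariate: str | None = None) -> EffectCurve:
    """HR(t) = exp(b1 + f1(t_j)) between covariate levels 1 and 0.

    Flat at exp(b1) for a time-constant (model 1) fit; pointwise 95% CI from
    var(b1 + f1(t_j)) on the log scale.
    """
    covariate = covariate or fit.spec.covariate
    if covariate is None or covariate not in fit.design.terms:
        raise ValueError(f"covariate {covariate!r} not in the model")
    d = fit.design
    t = fit.t_grid
    n = len(t)
    Xc = np.zeros((n, d.X.shape[1]))
    Xc[:, d.terms[covariate].sl] = 1.0
    if "f1" in d.terms:
        Xc[:, d.terms["f1"].sl] = d.terms["f1"].block.evaluate(np.ones(n), t)
    log_hr = Xc @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xc, fit.cov, Xc), 0.0))
    return EffectCurve(
        t=t,
        estimate=np.exp(log_hr),
        lower=np.exp(log_hr - _Z95 * se),
        upper=np.exp(log_hr + _Z95 * se),
        scale="hazard_ratio",
    )


def cumulative_incidence(
    fit: PAMMFit,
    covariate_values: dict[str, float] | None = None,
    which: int = 1,
) -> EffectCurve:
    """P(at least ``which`` episodes by t) at z = 0.

    The cumulative hazard Lambda(t_j) sums hazard x interval width over
    intervals up to t_j.  For the first episode the curve is
    1 - exp(-Lambda); for k >= 2 it is the conditional-Poisson tail
    P(N(t) >= k) under the fitted intensity at z = 0.  CIs are delta-method
    on log Lambda, mapped monotonically.
    """
    if which < 1:
        raise ValueError("which must be >= 1")
    covariate_values = covariate_values or {}
    t = fit.t_grid
    X = _linear_predictor_rows(fit, t, covariate_values)
    lam = np.exp(X @ fit.beta)
    w = fit.design.interval_widths
    contrib = lam * w
    Lambda = np.cumsum(contrib)
    # gradient of Lambda wrt beta: sum_l w_l lam_l x_l for l <= j
    G = np.cumsum(contrib[:, None] * X, axis=0)
    var_L = np.maximum(np.einsum("ij,jk,ik->i", G, fit.cov, G), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_logL = np.where(Lambda > 0, np.sqrt(var_L) / Lambda, 0.0)
    L_lo = Lambda * np.exp(-_Z95 * se_logL)
    L_hi = Lambda * np.exp(_Z95 * se_logL)

    def tail(L: np.ndarray) -> np.ndarray:
        if which == 1:
            return 1.0 - np.exp(-L)
        return poisson.sf(which - 1, L)

    return EffectCurve(
        t=t,
        estimate=tail(Lambda),
        lower=tail(L_lo),
        upper=tail(L_hi),
        scale="cumulative_incidence",
    )


def select_final_model(fit_model1: PAMMFit, fit_model2: PAMMFit, alpha: float = 0.05) -> dict:
    """Choose between the time-constant and time-varying effect models.

    Model 2 is preferred iff the test of the difference smooth f1 rejects
    at level ``alpha`` (strict inequality); otherwise the time-constant
    model 1 is kept.  Returns a report with both fits, the decision, and a
    per-group incidence / hazard-ratio summary.
    """
    cov = fit_model1.spec.covariate
    if cov is None or cov != fit_model2.spec.covariate:
        raise ValueError("fits must share the same binary covariate")
    if "f1" not in fit_model2.design.terms:
        raise ValueError("fit_model2 has no time-varying term")
    stat, rank, p = fit_model2.smooth_tests["f1"]
    chosen = "model2" if p < alpha else "model1"

    def _ir(f: PAMMFit, level: float) -> dict:
        i0 = f.design.terms["intercept"].sl.start
        i1 = f.design.terms[cov].sl.start
        c = np.zeros(len(f.beta))
        c[i0] = 1.0
        c[i1] = level
        est = float(c @ f.beta)
        se = float(np.sqrt(c @ f.cov @ c))
        return {
            "ir": YEAR_DAYS * float(np.exp(est)),
            "ci": [YEAR_DAYS * float(np.exp(est - _Z95 * se)), YEAR_DAYS * float(np.exp(est + _Z95 * se))],
        }

    def _hr(f: PAMMFit) -> dict:
        est, se, pval = f.parametric_estimate(cov)
        return {
            "hr": float(np.exp(est)),
            "ci": [float(np.exp(est - _Z95 * se)), float(np.exp(est + _Z95 * se))],
            "p": pval,
        }

    return {
        "covariate": cov,
        "alpha": alpha,
        "f1_p": p,
        "f1_stat": stat,
        "f1_rank": rank,
        "f1_edf": fit_model2.edf_by_term["f1"],
        "chosen": chosen,
        "model1": {"ir_group0": _ir(fit_model1, 0), "ir_group1": _ir(fit_model1, 1), **_hr(fit_model1)},
        "model2": {
            "ir_group0": _ir(fit_model2, 0),
            "ir_group1": _ir(fit_model2, 1),
            "avg_hr": _hr(fit_model2),
        },
        "fits": {"model1": fit_model1, "model2": fit_model2},
    }


_SEASONS_SOUTH = (
    (60, 151, "Autumn"),
    (152, 243, "Winter"),
    (244, 334, "Spring"),
)


def season_label(day_of_year: int) -> str:
    """Southern-hemisphere season of a calendar day (1-365): summer spans
    day 335 - day 365 and day 1 - day 59."""
    if not 1 <= day_of_year <= 365:
        raise ValueError("day_of_year must be in 1..365")
    for lo, hi, name in _SEASONS_SOUTH:
        if lo <= day_of_year <= hi:
            return name
    return "Summer"


def season_grids(
    fit: PAMMFit,
    variant: str = "current_season",
    *,
    age_step: float = 2.0,
    doy_step: float = 2.0,
) -> tuple[SeasonGrid, SeasonGrid]:
    """Incidence and HR-vs-day-1 lattices from a tensor (model 3) fit.

    The incidence grid is 365.25 * exp(b0 + g(t, x)) at z = 0; the HR grid
    is exp(g(t, x) - g(t, 1)), the hazard ratio of calendar day x relative
    to day 1 (mid-summer) at each age.
    """
    if variant not in ("current_season", "season_at_birth"):
        raise ValueError(f"unknown variant {variant!r}")
    d = fit.design
    if d.tensor_term is None:
        raise ValueError("fit has no tensor term; season grids need model 3")
    block = d.terms[d.tensor_term].block
    sl = d.terms[d.tensor_term].sl
    i0 = d.terms["intercept"].sl.start

    ages = np.arange(d.t_grid.min(), d.t_grid.max() + 1e-9, age_step)
    doys = np.arange(1.0, 365.0 + 1e-9, doy_step)
    A, Dy = np.meshgrid(ages, doys, indexing="ij")
    Xg = block.evaluate(A.ravel(), Dy.ravel())
    g = (Xg @ fit.beta[sl]).reshape(A.shape)
    Xref = block.evaluate(ages, np.ones(len(ages)))
    g_ref = Xref @ fit.beta[sl]

    inc = YEAR_DAYS * np.exp(fit.beta[i0] + g)
    hr = np.exp(g - g_ref[:, None])
    return (
        SeasonGrid(age=ages, day_of_year=doys, values=inc, scale="incidence_per_child_year", variant=variant),
        SeasonGrid(age=ages, day_of_year=doys, values=hr, scale="hazard_ratio", variant=variant),
    )
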