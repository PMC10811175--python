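"""Combining ranking-derived worths with metric measurements.

Breeding programs want trait values on an absolute scale (e.g. yield in
t/ha), while tricot produces rankings.  When a metric trait is measured on a
subset of plots, the ranking data can lend statistical power to the sparse
metric data: per-item shrunken means from the metric subset (a one-way
BLUP-style estimator) are regressed on the log-worths from the full ranking
data, and the fitted values ("enhanced" estimates) typically track the true
item values better than the subset means alone.

``simulate_fig6`` runs this whole pipeline on simulated trials with known
truth and reports both correlations and the regression slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .plackett_luce import PlackettLuce
from .rankings import Ranking

__all__ = [
    "subset_item_estimates",
    "calibrate",
    "CalibrationModel",
    "Fig6Result",
    "simulate_fig6",
]


def subset_item_estimates(subset: pd.DataFrame, shrinkage: float | None = None) -> pd.Series:
    """Per-item metric estimates from a plot subset, shrunk toward the grand
    mean.

    ``subset`` needs columns ``item`` and ``value``.  Each item mean is
    shrunk with factor n_i / (n_i + lambda) where lambda = sigma2_e /
    sigma2_g is estimated by the one-way method of moments; if the
    between-item variance estimate is non-positive, lambda falls back to 1.
    Pass ``shrinkage`` to fix lambda (``shrinkage=np.inf`` gives the grand
    mean for every item; 0 gives raw means).  This mirrors the shrinkage
    structure of a one-way mixed model BLUP without the mixed-model
    machinery.
    """
    for col in ("item", "value"):
        if col not in subset.columns:
            raise ValidationError(f"subset needs a {col!r} column")
    if subset.empty:
        raise ValidationError("empty metric subset")
    vals = subset["value"].astype(float)
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite metric values")
    grand = vals.mean()
    groups = subset.groupby("item")["value"]
    n_i = groups.size()
    means = groups.mean()
    if shrinkage is None:
        g = len(n_i)
        N = len(subset)
        if g < 2 or N <= g:
            lam = 1.0
        else:
            ss_within = float(
                ((vals.to_numpy() - means.reindex(subset["item"]).to_numpy()) ** 2).sum()
            )
            ss_between = float((n_i * (means - grand) ** 2).sum())
            ms_within = ss_within / (N - g)
            ms_between = ss_between / (g - 1)
            n0 = (N - float((n_i**2).sum()) / N) / (g - 1)
            sigma2_g = (ms_between - ms_within) / n0
            lam = ms_within / sigma2_g if sigma2_g > 0 else 1.0
    else:
        lam = shrinkage
    if np.isinf(lam):
        shrink = pd.Series(0.0, index=means.index)
    else:
        shrink = n_i / (n_i + lam)
    return (grand + shrink * (means - grand)).rename("estimate")


@dataclass
class CalibrationModel:
    """OLS of metric estimates on log-worth, with per-item fitted values."""

    intercept: float
    slope: float
    slope_se: float
    residual_sd: float
    enhanced: pd.Series

    @property
    def slope_t(self) -> float:
        return self.slope / self.slope_se if self.slope_se > 0 else np.inf


def calibrate(logworth: pd.Series, estimates: pd.Series) -> CalibrationModel:
    """Regress per-item metric estimates on log-worths; the fitted values
    are the enhanced per-item estimates."""
    common = logworth.index.intersection(estimates.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 items with both quantities")
    x = logworth.loc[common].astype(float).to_numpy()
    y = estimates.loc[common].astype(float).to_numpy()
    if np.var(x) == 0:
        raise ValidationError("zero variance in log-worths")
    n = len(common)
    sxx = float(((x - x.mean()) ** 2).sum())
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted
    dof = max(n - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    slope_se = residual_sd / np.sqrt(sxx)
    return CalibrationModel(
        intercept=intercept,
        slope=slope,
        slope_se=slope_se,
        residual_sd=residual_sd,
        enhanced=pd.Series(fitted, index=common, name="enhanced"),
    )


@dataclass
class Fig6Result:
    """Paired accuracy of subset-only vs ranking-enhanced item estimates."""

    cor_subset: float
    cor_enhanced: float
    slope: float
    slope_t: float
    truth: pd.Series
    subset_estimates: pd.Series
    enhanced: pd.Series


def simulate_fig6(
    n_items: int = 12,
    n_farms: int = 150,
    subset_plots: int = 30,
    sigma_g: float = 1.0,
    sigma_e: float = 1.0,
    seed: int = 0,
) -> Fig6Result:
    """Full metric-fusion pipeline on one simulated trial.

    True item effects ~ N(0, sigma_g^2); every farm grows a random triad and
    each plot yields effect + N(0, sigma_e^2) noise; farms rank their three
    plots by observed value; a random subset of ``subset_plots`` plots is
    "measured".  Returns correlations of subset-only and enhanced estimates
    with the truth, plus the estimates-on-log-worth regression slope.
    """
    if sigma_g < 0 or sigma_e < 0:
        raise ValidationError("variance components must be non-negative")
    if sigma_g == 0 and sigma_e == 0:
        raise ValidationError("degenerate simulation: all values identical")
    if subset_plots > n_farms * 3:
        raise ValidationError("subset larger than the number of plots")
    from .design import random_balanced_design  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    items = [f"V{i + 1:02d}" for i in range(n_items)]
    truth = pd.Series(rng.normal(0.0, sigma_g, n_items), index=items, name="truth")
    design = random_balanced_design(n_items, n_farms, 3,
                                    seed=int(rng.integers(2**31)), items=items)
    plot_rows = []
    rankings = []
    for farm, block in enumerate(design.blocks):
        vals = {it: truth[it] + rng.normal(0.0, sigma_e) for it in block}
        order = sorted(block, key=lambda it: -vals[it])
        rankings.append(Ranking(tuple(order)))
        for it in block:
            plot_rows.append({"participant_id": str(farm + 1), "item": it,
                              "value": vals[it]})
    plots = pd.DataFrame(plot_rows)
    subset = plots.iloc[rng.choice(len(plots), size=subset_plots, replace=False)]
    missing = set(items) - set(subset["item"])
    if missing:  # guarantee every item has at least one measured plot
        extra = plots[plots["item"].isin(missing)].groupby("item").head(1)
        subset = pd.concat([subset, extra])
    est = subset_item_estimates(subset)

    model = PlackettLuce(rankings, items=items)
    res = model.fit(check_connectivity=False, compute_vcov=False)
    if res.separated:  # noiseless rankings separate; keep worths finite
        res = model.fit(check_connectivity=False, regularize=True)
    logworth = res.theta

    cal = calibrate(logworth, est)
    est = est.reindex(items)
    enhanced = cal.enhanced.reindex(items)

    def cor(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    return Fig6Result(
        cor_subset=cor(est, truth),
        cor_enhanced=cor(enhanced, truth),
        slope=cal.slope,
        slope_t=cal.slope_t,
        truth=truth,
        subset_estimates=est,
        enhanced=enhanced,
    )
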