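"""Thermal time, attachment-dynamics regression and group statistics.

Below-ground parasite establishment is tracked against thermal time
(growing degree days, GDD) rather than calendar time.  The attachment
count per observation tube follows a sigmoidal course in GDD, modeled
with the three-parameter log-logistic form standard in weed science,

    y(x) = a / (1 + (x / x0)^b),

where ``a`` is the upper asymptote (attachments per tube), ``x0`` the
thermal time of the inflection (y(x0) = a/2), and ``b`` a dimensionless
shape; ``b < 0`` gives an increasing sigmoid.

Group comparisons use one-way ANOVA with Tukey-HSD post-hoc decisions at
alpha = 0.05, and measurement accuracy is summarized by an ordinary
least-squares regression of estimated on actual values with its RMSE and
percent error (RMSE over the mean actual value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "AttachmentSeries",
    "LogisticFit",
    "GroupComparison",
    "RegressionReport",
    "log_logistic",
    "gdd_from_temperature",
    "fit_log_logistic",
    "compare_groups",
    "accuracy_regression",
    "percent_difference",
    "format_percent",
]


@dataclass
class AttachmentSeries:
    """Attachment counts per tube against cumulative thermal time."""

    gdd: np.ndarray
    attachments: np.ndarray

    def __post_init__(self) -> None:
        gdd = np.asarray(self.gdd, dtype=np.float64)
        att = np.asarray(self.attachments, dtype=np.float64)
        if gdd.ndim != 1 or gdd.shape != att.shape:
            raise ValueError("gdd and attachments must be equal-length 1-D")
        if not (np.diff(gdd) > 0).all():
            raise ValueError("gdd must be strictly increasing")
        if (att < 0).any():
            raise ValueError("attachment counts must be non-negative")
        self.gdd, self.attachments = gdd, att

    def __len__(self) -> int:
        return self.gdd.shape[0]


@dataclass
class LogisticFit:
    """Log-logistic fit y = a / (1 + (x/x0)^b) with diagnostics."""

    a: float
    x0: float
    b: float
    se_a: float
    se_x0: float
    se_b: float
    r_squared: float
    rmse: float
    p_value: float
    converged: bool
    degenerate: bool = False

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.x0, self.b)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return log_logistic(np.asarray(x, dtype=np.float64), *self.params)


@dataclass
class GroupComparison:
    """One-way ANOVA + Tukey-HSD outcome for one parameter at one session."""

    parameter: str
    session_gdd: float | None
    group_names: list[str]
    means: np.ndarray
    sems: np.ndarray
    n: np.ndarray
    f_statistic: float
    p_anova: float
    p_tukey: float
    alpha: float
    significant: bool
    percent_diff: float | None = None
    percent_reference: str | None = None


@dataclass
class RegressionReport:
    """OLS of estimated on actual values with accuracy summaries."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float  # same units as the inputs
    percent_error: float  # RMSE / mean(actual) x 100
    n: int


def log_logistic(x, a: float, x0: float, b: float):
    """Three-parameter log-logistic curve a / (1 + (x/x0)^b)."""
    x = np.asarray(x, dtype=np.float64)
    return a / (1.0 + (x / x0) ** b)


# ---------------------------------------------------------------------------
# thermal time
# ---------------------------------------------------------------------------

def gdd_from_temperature(
    hourly_temps: pd.Series, t_base: float = 5.0
) -> pd.DataFrame:
    """Cumulative growing degree days from an hourly temperature series.

    Each day contributes max(0, mean hourly temperature - t_base) degree
    days; the ``gdd`` column is the cumulative sum from the first day of
    the series (the planting date).  Days with fewer than 24 records are
    flagged in the ``incomplete`` column so gaps are visible.

    Parameters
    ----------
    hourly_temps : pd.Series of soil temperature in degrees C with a
        DatetimeIndex (hourly or finer).
    t_base : base temperature in degrees C below which no thermal time
        accumulates (default 5, configurable per crop).
    """
    if len(hourly_temps) == 0:
        raise ValueError("temperature series is empty")
    if not isinstance(hourly_temps.index, pd.DatetimeIndex):
        raise ValueError("temperature series must have a DatetimeIndex")
    if not hourly_temps.index.is_monotonic_increasing:
        raise ValueError("temperature timestamps must be ordered")
    daily = hourly_temps.groupby(hourly_temps.index.floor("D")).agg(
        ["mean", "count"]
    )
    out = pd.DataFrame(
        {
            "mean_temp": daily["mean"],
            "hours": daily["count"],
            "increment": np.maximum(0.0, daily["mean"] - t_base),
        }
    )
    out["gdd"] = out["increment"].cumsum()
    out["incomplete"] = out["hours"] < 24
    return out


# ---------------------------------------------------------------------------
# attachment-dynamics regression
# ---------------------------------------------------------------------------

def fit_log_logistic(series: AttachmentSeries) -> LogisticFit:
    """Least-squares log-logistic fit with multi-start initialization.

    Starts bracket both sigmoid orientations and several inflection
    guesses; the best converged start (lowest residual sum of squares)
    wins.  Standard errors are asymptotic (from the Jacobian), the
    p-value is the F-test of the curve against a constant-mean model.
    A constant response is flagged degenerate rather than fit.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    x, y = series.gdd, series.attachments
    n = len(series)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-12 * max(1.0, float(np.abs(y).max())):
        return LogisticFit(
            a=float(y.mean()), x0=float(np.median(x)), b=0.0,
            se_a=np.nan, se_x0=np.nan, se_b=np.nan,
            r_squared=0.0, rmse=0.0, p_value=1.0,
            converged=False, degenerate=True,
        )
    a0s = [max(y.max(), 1e-6), 1.2 * max(y.max(), 1e-6)]
    x0s = [np.median(x), x.mean(), 0.5 * (x[0] + x[-1])]
    b0s = [-8.0, -4.0, -2.0, -1.0, 1.0, 2.0, 4.0, 8.0]
    best = None
    for a0 in a0s:
        for x00 in x0s:
            for b0 in b0s:
                try:
                    popt, pcov = optimize.curve_fit(
                        log_logistic,
                        x,
                        y,
                        p0=[a0, x00, b0],
                        bounds=([1e-12, 1e-12, -np.inf], [np.inf] * 3),
                        maxfev=20000,
                    )
                except (RuntimeError, optimize.OptimizeWarning, ValueError):
                    continue
                sse = float(np.sum((y - log_logistic(x, *popt)) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError(
            "log-logistic fit failed to converge from any start "
            f"(n={n}, y range [{y.min():.3g}, {y.max():.3g}])"
        )
    sse, popt, pcov = best
    dof = max(n - 3, 1)
    se = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else [np.nan] * 3
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / n))
    if sse < 1e-300:
        p_value = 0.0
    else:
        f_stat = ((sst - sse) / 2.0) / (sse / dof)
        p_value = float(stats.f.sf(f_stat, 2, dof))
    return LogisticFit(
        a=float(popt[0]), x0=float(popt[1]), b=float(popt[2]),
        se_a=float(se[0]), se_x0=float(se[1]), se_b=float(se[2]),
        r_squared=float(r2), rmse=rmse, p_value=p_value,
        converged=True,
    )


# ---------------------------------------------------------------------------
# group comparison and accuracy
# ---------------------------------------------------------------------------

def compare_groups(
    values_by_group: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    parameter: str = "",
    session_gdd: float | None = None,
) -> GroupComparison:
    """One-way ANOVA with a Tukey-HSD pairwise decision at ``alpha``.

    With exactly two groups Tukey-HSD is the studentized-range equivalent
    of the two-sample t-test; both the ANOVA and the Tukey p-value are
    reported.  Identical zero-variance groups yield p = 1 rather than an
    error.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=np.float64) for g in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    means = np.array([g.mean() for g in groups])
    sems = np.array([g.std(ddof=1) / np.sqrt(len(g)) for g in groups])
    ns = np.array([len(g) for g in groups])
    pooled_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if pooled_var == 0 and np.allclose(means, means[0]):
        f_stat, p_anova, p_tukey = 0.0, 1.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*groups)
        tukey = stats.tukey_hsd(*groups)
        p_tukey = float(np.min(tukey.pvalue[~np.eye(len(groups), dtype=bool)]))
        f_stat, p_anova = float(f_stat), float(p_anova)
    return GroupComparison(
        parameter=parameter,
        session_gdd=session_gdd,
        group_names=names,
        means=means,
        sems=sems,
        n=ns,
        f_statistic=f_stat,
        p_anova=p_anova,
        p_tukey=p_tukey,
        alpha=alpha,
        significant=p_tukey <= alpha,
    )


def accuracy_regression(
    estimated: np.ndarray | list[float], actual: np.ndarray | list[float]
) -> RegressionReport:
    """OLS of estimated on actual values, with RMSE and percent error.

    Percent error is the RMSE of the regression residuals divided by the
    mean actual value, x100.
    """
    est = np.asarray(estimated, dtype=np.float64)
    act = np.asarray(actual, dtype=np.float64)
    if est.shape != act.shape or est.ndim != 1 or len(est) < 3:
        raise ValueError("estimated/actual must be equal-length 1-D, n >= 3")
    if np.allclose(act, act[0]):
        raise ValueError("actual values have zero variance; cannot regress")
    model = sm.OLS(est, sm.add_constant(act)).fit()
    resid = model.resid
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RegressionReport(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        rmse=rmse,
        percent_error=rmse / float(act.mean()) * 100.0,
        n=len(est),
    )


def percent_difference(
    control: float, infected: float, reference: str = "infected"
) -> float:
    """|control - infected| relative to the chosen reference group, x100.

    The reference is explicit because reported differences mix both
    conventions (e.g. height differences relative to the infected mean,
    volume differences relative to the control mean).
    """
    ref = {"control": control, "infected": infected}.get(reference)
    if ref is None:
        raise ValueError("reference must be 'control' or 'infected'")
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return abs(control - infected) / ref * 100.0


def format_percent(value: float) -> int:
    """Integer percent for display, truncated toward zero."""
    return int(value)
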