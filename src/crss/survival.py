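"""Survival-analysis primitives shared by the staging pipeline.

Kaplan–Meier estimation and the two-sample log-rank test are implemented
directly on numpy arrays so that the cutoff search can evaluate hundreds of
candidate thresholds cheaply; Cox proportional-hazards fitting delegates to
lifelines.  Concordance, information criteria, survival-at-horizon summaries
and rank-based group comparisons round out the toolkit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "LogrankResult",
    "GroupTestResult",
    "WEEKS_PER_YEAR",
    "kaplan_meier",
    "logrank_test",
    "fit_cox",
    "concordance_index",
    "km_summary",
    "group_tests",
]

#: Weeks per year used when survival tables are summarized at yearly horizons.
WEEKS_PER_YEAR = 52.18


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate over the distinct observed times.

    ``survival[k]`` is S(t) at ``times[k]`` (right-continuous step function);
    ``at_risk``, ``n_events`` and ``n_censored`` describe the risk set at
    each distinct time, so counts are conserved step to step.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) for arbitrary t >= 0 (left value between steps)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    @property
    def median(self) -> float | None:
        """First time at which S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size == 0:
            return None
        return float(self.times[below[0]])


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox proportional-hazards model.

    Hazard ratios are exponentiated coefficients with Wald 95% confidence
    intervals; ``aic = -2 logPL + 2k`` and ``bic = -2 logPL + k ln(d)`` with
    d the number of observed events.
    """

    names: tuple[str, ...]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_partial_likelihood: float
    n_params: int
    n_events: int
    c_index: float
    aic: float
    bic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "hr_ci_lower": self.ci_lower,
                "hr_ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )


@dataclass(frozen=True)
class GroupTestResult:
    kruskal_statistic: float
    kruskal_p: float
    pairwise_p: tuple[float, ...]  # successive groups: (1 vs 2, 2 vs 3, ...)


def _as_survival_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) estimator.

    With no observed events the curve is identically 1.
    """
    t, e = _as_survival_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, start = np.unique(t, return_index=True)
    counts = np.diff(np.append(start, t.size))
    d = np.add.reduceat(e, start)           # events at each distinct time
    c = counts - d                          # censorings at each distinct time
    n = t.size - np.concatenate(([0], np.cumsum(counts)[:-1]))  # at risk
    surv = np.cumprod(1.0 - d / n)
    return SurvivalCurve(
        times=uniq,
        survival=surv,
        at_risk=n.astype(int),
        n_events=d.astype(int),
        n_censored=c.astype(int),
    )


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_a: np.ndarray) -> float:
    """Two-sample log-rank chi-square (df=1) with the standard tie handling.

    ``in_a`` flags membership of group A.  Returns 0 when the variance is
    zero (e.g. no events).
    """
    event_times = times[events == 1]
    if event_times.size == 0:
        return 0.0
    uniq = np.unique(event_times)

    ta = np.sort(times[in_a])
    tb = np.sort(times[~in_a])
    na = ta.size - np.searchsorted(ta, uniq, side="left")
    nb = tb.size - np.searchsorted(tb, uniq, side="left")
    nj = na + nb

    ea = np.sort(times[in_a & (events == 1)])
    eall = np.sort(event_times)
    da = np.searchsorted(ea, uniq, side="right") - np.searchsorted(ea, uniq, side="left")
    dj = np.searchsorted(eall, uniq, side="right") - np.searchsorted(eall, uniq, side="left")

    with np.errstate(invalid="ignore", divide="ignore"):
        expected = dj * na / nj
        var = np.where(
            nj > 1,
            dj * (na / nj) * (nb / nj) * (nj - dj) / (nj - 1),
            0.0,
        )
    observed_minus_expected = float(np.sum(da - expected))
    variance = float(np.sum(var))
    if variance <= 0:
        return 0.0
    return observed_minus_expected ** 2 / variance


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sample log-rank test comparing the survival of groups A and B."""
    ta, ea = _as_survival_arrays(times_a, events_a)
    tb, eb = _as_survival_arrays(times_b, events_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: ta.size] = True
    chi2 = _logrank_chi2(times, events, in_a)
    return LogrankResult(chi_square=chi2, p_value=float(stats.chi2.sf(chi2, 1)))


def fit_cox(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    alpha: float = 0.05,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    Parameters
    ----------
    covariates:
        2-D array (n subjects x k covariates) or DataFrame.
    names:
        Covariate names; required when ``covariates`` is a bare array.

    Raises
    ------
    ValueError
        For a covariate that is constant across subjects (named in the
        message) or when no events are observed.
    """
    t, e = _as_survival_arrays(times, events)
    if isinstance(covariates, pd.DataFrame):
        X = covariates.reset_index(drop=True)
        names = list(X.columns)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != t.size:
            X = X.T
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        X = pd.DataFrame(X, columns=names)
    if int(e.sum()) < 1:
        raise ValueError("Cox fit requires at least one observed event")
    for name in names:
        if np.ptp(X[name].to_numpy(dtype=float)) == 0:
            raise ValueError(f"degenerate covariate {name!r} is constant across subjects")

    df = X.copy()
    df["_T"], df["_E"] = t, e
    fitter = CoxPHFitter(alpha=alpha)
    fitter.fit(df, duration_col="_T", event_col="_E")

    summary = fitter.summary
    k = len(names)
    d = int(e.sum())
    log_pl = float(fitter.log_likelihood_)
    risk = fitter.predict_partial_hazard(X).to_numpy(dtype=float)
    return CoxFit(
        names=tuple(names),
        coefficients={n: float(summary.loc[n, "coef"]) for n in names},
        hazard_ratios={n: float(summary.loc[n, "exp(coef)"]) for n in names},
        ci_lower={n: float(summary.loc[n, "exp(coef) lower 95%"]) for n in names},
        ci_upper={n: float(summary.loc[n, "exp(coef) upper 95%"]) for n in names},
        p_values={n: float(summary.loc[n, "p"]) for n in names},
        log_partial_likelihood=log_pl,
        n_params=k,
        n_events=d,
        c_index=concordance_index(t, e, risk),
        aic=-2.0 * log_pl + 2.0 * k,
        bic=-2.0 * log_pl + k * math.log(d),
    )


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's concordance index for risk scores against censored times.

    A pair is usable when the earlier time is an observed event; concordant
    pairs have the higher risk score on the earlier event, tied scores count
    one half.  Higher is better; 0.5 is chance.
    """
    t, e = _as_survival_arrays(times, events)
    r = np.asarray(risk_scores, dtype=float)
    if r.shape != t.shape:
        raise ValueError("risk_scores must match times in length")
    try:
        # lifelines orients concordance toward longer survival, so negate risk.
        return float(_lifelines_cindex(t, -r, e))
    except ZeroDivisionError:
        raise ValueError("no usable (comparable) pairs for concordance") from None


def km_summary(
    curve: SurvivalCurve,
    horizons_years=(1, 2, 3, 4, 5),
) -> dict[str, float | None]:
    """Survival fraction at yearly horizons plus the median survival (weeks).

    Horizons are converted at 52.18 weeks per year and read off the
    right-continuous step function; the median is None when the curve never
    reaches 0.5.
    """
    out: dict[str, float | None] = {
        f"year_{y}": curve.survival_at(y * WEEKS_PER_YEAR) for y in horizons_years
    }
    out["median_weeks"] = curve.median
    return out


def group_tests(groups) -> GroupTestResult:
    """Kruskal–Wallis across all groups plus successive pairwise rank-sum tests.

    ``groups`` is an ordered sequence of value lists (e.g. a parameter's
    values per risk stage); pairwise tests compare each stage with the next.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("group_tests requires at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # Identical samples carry no evidence of a difference.
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*arrays)
    pairwise = []
    for a, b in zip(arrays[:-1], arrays[1:]):
        if np.array_equal(a, b):
            pairwise.append(1.0)
        else:
            pairwise.append(float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
    return GroupTestResult(
        kruskal_statistic=float(kw_stat),
        kruskal_p=float(kw_p),
        pairwise_p=tuple(pairwise),
    )
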