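"""Survival and group-comparison machinery for biochemical-recurrence
analyses: Kaplan–Meier curves, the k-sample log-rank test, Cox proportional
hazards with Breslow tie handling, quintile stratification, and pooled
t-test / one-way ANOVA group comparisons.

The Cox model is fitted by Newton–Raphson maximization of the Breslow
partial likelihood with step-halving; the Wald 95% confidence interval is
exp(beta +/- 1.959964 * SE). All times are follow-up months from surgery
(no delayed entry); events are biochemical recurrences, non-events are
right-censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class SurvivalData:
    """Follow-up times (months), event indicators and named covariates."""

    times: np.ndarray
    events: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValidationError("times and events must have equal length")
        if np.any(~np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValidationError("times must be finite and >= 0")
        if self.covariates is not None and len(self.covariates) != len(self.times):
            raise ValidationError("covariates must match times in length")


@dataclass
class KMCurve:
    """Product-limit estimate: survival step function with at-risk counts."""

    event_times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function starting at 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (one row per covariate)."""

    coef: pd.Series
    hr: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    converged: bool
    n_iter: int
    log_likelihood: float
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "SE": self.se,
                "CI95_low": self.ci_low,
                "CI95_high": self.ci_high,
                "p": self.p,
            }
        )


def km_curve(data: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censoring at an event time is handled with the usual convention that
    censored subjects are still at risk at that time.
    """
    if data.times.size == 0:
        raise ValidationError("need at least one subject")
    order = np.argsort(data.times, kind="mergesort")
    t, e = data.times[order], data.events[order]

    event_times = np.unique(t[e])
    n = t.size
    survival, at_risk, n_events = [], [], []
    s = 1.0
    for et in event_times:
        r = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / r
        at_risk.append(r)
        n_events.append(d)
        survival.append(s)
    return KMCurve(
        event_times=np.asarray(event_times, float),
        survival=np.asarray(survival, float),
        at_risk=np.asarray(at_risk, int),
        n_events=np.asarray(n_events, int),
    )


def logrank_test(data: SurvivalData, groups: Sequence) -> tuple[float, int, float]:
    """k-sample log-rank test: (chi-square, df, p).

    Standard observed-minus-expected statistic with the hypergeometric
    variance (including the (n-d)/(n-1) tie correction), df = k - 1.
    """
    groups = np.asarray(groups)
    if groups.shape != data.times.shape:
        raise ValidationError("groups must match times in length")
    levels = np.unique(groups)
    k = levels.size
    if k < 2:
        raise ValidationError("log-rank needs >= 2 groups")

    t, e = data.times, data.events
    event_times = np.unique(t[e])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        d = int(((t == et) & e).sum())
        if n <= 1:
            continue
        n_j = np.array([(at_risk & (groups == g)).sum() for g in levels], float)
        d_j = np.array([((t == et) & e & (groups == g)).sum() for g in levels], float)
        frac = n_j / n
        o_minus_e += d_j - d * frac
        scale = d * (n - d) / (n - 1)
        cov += scale * (np.diag(frac) - np.outer(frac, frac))

    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood)


def _breslow_parts(beta, t_desc, e_desc, x_desc, group_end):
    """Log partial likelihood, score and information (Breslow ties).

    Inputs are sorted by descending time; ``group_end[i]`` is the index of
    the last row sharing row i's time, so cumulative sums through that index
    cover the full risk set including tied subjects.
    """
    eta = x_desc @ beta
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    s0 = np.cumsum(theta)[group_end]
    s1 = np.cumsum(theta[:, None] * x_desc, axis=0)[group_end]
    xbar = s1 / s0[:, None]

    ev = e_desc
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0[ev])))
    score = x_desc[ev].sum(axis=0) - xbar[ev].sum(axis=0)

    p = x_desc.shape[1]
    s2 = np.cumsum(theta[:, None, None] * (x_desc[:, :, None] * x_desc[:, None, :]), axis=0)[
        group_end
    ]
    info = np.zeros((p, p))
    idx = np.flatnonzero(ev)
    info = (s2[idx] / s0[idx, None, None]).sum(axis=0) - (
        xbar[idx][:, :, None] * xbar[idx][:, None, :]
    ).sum(axis=0)
    return loglik, score, info


def _sorted_for_cox(times, events, x):
    order = np.argsort(-times, kind="mergesort")
    t_desc = times[order]
    e_desc = events[order]
    x_desc = x[order]
    # last index of each tied-time block (descending order -> ties adjacent)
    n = t_desc.size
    group_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_desc[j + 1] == t_desc[i]:
            j += 1
        group_end[i : j + 1] = j
        i = j + 1
    return t_desc, e_desc, x_desc, group_end


def cox_fit(
    data: SurvivalData,
    covariate_names: Optional[Sequence[str]] = None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit the Cox model by Newton–Raphson on the Breslow partial likelihood.

    Convergence is declared when the largest score component falls below
    ``tol``. Non-convergence or a monotone likelihood (perfect separation,
    recognisable by diverging coefficients) leaves ``converged=False``; the
    caller must check the flag.
    """
    if ties != "breslow":
        raise ValidationError(f"only Breslow tie handling is implemented, got {ties!r}")
    if data.covariates is None:
        raise ValidationError("covariates are required for a Cox fit")
    names = list(covariate_names) if covariate_names is not None else list(data.covariates.columns)
    x = data.covariates[names].to_numpy(float)
    n, p = x.shape
    n_events = int(data.events.sum())
    if n_events < p:
        raise ValidationError(f"{n_events} events cannot support {p} covariates")
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValidationError(f"constant covariates: {bad}")

    t_desc, e_desc, x_desc, group_end = _sorted_for_cox(data.times, data.events, x)

    beta = np.zeros(p)
    loglik, score, info = _breslow_parts(beta, t_desc, e_desc, x_desc, group_end)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # at large n rounding noise in the cumulative sums floors the score
        # above any absolute tolerance; a vanishing Newton step means the
        # maximum has been reached to machine precision
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
        # step-halving keeps the likelihood non-decreasing
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_parts(
                new_beta, t_desc, e_desc, x_desc, group_end
            )
            # relative slack: near the optimum the recomputed log likelihood
            # differs by rounding noise proportional to its magnitude
            if new_ll >= loglik - 1e-10 * (abs(loglik) + 1.0):
                break
            step *= 0.5
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
    else:
        it = max_iter
    if np.max(np.abs(score)) < tol:
        converged = True
    # monotone likelihood (perfect separation): the partial likelihood
    # flattens as beta diverges, so the score criterion can be met at an
    # absurd coefficient; a log hazard ratio beyond 10 (HR > 2e4) on any
    # covariate is treated as separation, not a fit
    if np.any(np.abs(beta) > 10):
        converged = False

    try:
        var = np.linalg.inv(info)
        se = np.sqrt(np.diag(var))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    coef = pd.Series(beta, index=names, name="coef")
    se_s = pd.Series(se, index=names, name="SE")
    z = coef / se_s
    return CoxFit(
        coef=coef,
        hr=np.exp(coef).rename("HR"),
        se=se_s,
        ci_low=np.exp(coef - Z_95 * se_s).rename("CI95_low"),
        ci_high=np.exp(coef + Z_95 * se_s).rename("CI95_high"),
        p=pd.Series(2 * stats.norm.sf(np.abs(z)), index=names, name="p"),
        converged=converged,
        n_iter=it,
        log_likelihood=loglik,
        n=n,
        n_events=n_events,
    )


def cox_score_test(data: SurvivalData, covariate: str) -> tuple[float, float]:
    """Score (Rao) test of beta=0 for a single covariate: (chi-square, p).

    With untied event times this equals the two-sample log-rank statistic
    for a binary covariate.
    """
    if data.covariates is None or covariate not in data.covariates:
        raise ValidationError(f"covariate {covariate!r} not found")
    x = data.covariates[[covariate]].to_numpy(float)
    t_desc, e_desc, x_desc, group_end = _sorted_for_cox(data.times, data.events, x)
    _, score, info = _breslow_parts(np.zeros(1), t_desc, e_desc, x_desc, group_end)
    chi2 = float(score[0] ** 2 / info[0, 0])
    return chi2, float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Stratification and group comparison


def quintile_strata(values: Sequence[float]) -> np.ndarray:
    """Quintile labels 1–5 with cut points at the 20/40/60/80th percentiles.

    Percentiles use linear interpolation between order statistics; a value
    equal to a cut point goes to the lower stratum. Degenerate input (all
    values equal) collapses to a single stratum with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValidationError("need >= 5 values for quintiles")
    if np.any(~np.isfinite(v)):
        raise ValidationError("values must be finite")
    cuts = np.percentile(v, [20, 40, 60, 80])
    if np.all(v == v[0]):
        warnings.warn("all values identical; single quintile stratum", stacklevel=2)
        return np.ones(v.size, dtype=int)
    return 1 + np.sum(v[:, None] > cuts[None, :], axis=1)


def group_compare(
    values: Sequence[float],
    groups: Sequence,
    test: Optional[Literal["ttest", "anova"]] = None,
) -> tuple[float, float]:
    """Two-sided pooled-variance t-test (2 groups) or one-way ANOVA (>=3).

    Returns (statistic, p). ``test`` forces a choice; by default it follows
    the number of groups.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = [lv for lv in pd.unique(g)]
    samples = [v[g == lv] for lv in levels]
    if len(samples) < 2:
        raise ValidationError("need >= 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValidationError("every group needs >= 2 values")
    if test is None:
        test = "ttest" if len(samples) == 2 else "anova"
    if test == "ttest":
        if len(samples) != 2:
            raise ValidationError("t-test requires exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown test {test!r}")
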