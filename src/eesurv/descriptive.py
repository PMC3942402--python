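"""Descriptive cohort summaries and the two-group Cox hazard ratio.

The Cox stage is the only place censoring indicators are honoured; the
parametric likelihood stages treat survival times as fully observed. The
two-group proportional-hazards model has a single binary covariate, so the
Breslow partial likelihood reduces to sufficient statistics per distinct
event time and Newton-Raphson converges in a handful of steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NumericSummary",
    "FrequencyTable",
    "CoxResult",
    "summarize_numeric",
    "frequency_table",
    "cox_two_group_hr",
    "round_half_away",
]


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (spreadsheet-style), e.g. 0.25 -> 0.3."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass(frozen=True)
class NumericSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q2: float
    q3: float
    variance: float
    units: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "mean", "sd", "median", "q1", "q2", "q3", "variance", "units")}


def summarize_numeric(values, units: str = "") -> NumericSummary:
    """Sample summary with n-1 SD and linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least two values to summarize")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    sd = float(np.std(arr, ddof=1))
    q1, q2, q3 = (float(np.percentile(arr, q, method="linear")) for q in (25, 50, 75))
    return NumericSummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        q1=q1,
        q2=q2,
        q3=q3,
        variance=sd * sd,
        units=units,
    )


@dataclass(frozen=True)
class FrequencyTable:
    counts: dict
    percents: dict  # to 1 decimal, round half away from zero
    total: int

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"count": self.counts, "percent": self.percents}
        ).rename_axis("category")


def frequency_table(labels) -> FrequencyTable:
    """Counts and percentages (1 decimal) of a categorical column."""
    arr = list(labels)
    if len(arr) == 0:
        raise ValueError("label vector is empty")
    counts: dict = {}
    for lab in arr:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(arr)
    percents = {k: round_half_away(100.0 * v / total, 1) for k, v in counts.items()}
    return FrequencyTable(counts=counts, percents=percents, total=total)


# ---------------------------------------------------------------------------
# two-group Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    coef: float                 # log hazard ratio (group 1 vs group 0)
    hr: float
    se_robust: float
    se_model: float
    wald_ci: tuple              # robust-SE Wald 95% CI on the HR scale
    profile_ci: tuple           # profile-likelihood 95% CI on the HR scale
    loglik: float
    n_iter: int


def _breslow_stats(times, events, group):
    """Per distinct event time: total deaths, group-1 deaths, risk counts."""
    order = np.argsort(times, kind="mergesort")
    t, e, g = times[order], events[order], group[order]
    event_times = np.unique(t[e == 1])
    d_tot = np.empty(event_times.size)
    d1 = np.empty(event_times.size)
    n0 = np.empty(event_times.size)
    n1 = np.empty(event_times.size)
    for i, et in enumerate(event_times):
        at_event = (t == et) & (e == 1)
        d_tot[i] = at_event.sum()
        d1[i] = (at_event & (g == 1)).sum()
        at_risk = t >= et
        n1[i] = (at_risk & (g == 1)).sum()
        n0[i] = (at_risk & (g == 0)).sum()
    return event_times, d_tot, d1, n0, n1


def _partial_loglik(theta, d_tot, d1, n0, n1):
    s0 = n0 + n1 * np.exp(theta)
    return float(np.sum(d1) * theta - np.sum(d_tot * np.log(s0)))


def cox_two_group_hr(
    times,
    events,
    group,
    conf_level: float = 0.95,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Two-group Cox hazard ratio with Breslow ties.

    Parameters
    ----------
    times, events, group : array-likes of equal length
        Durations, event indicators (1 = death), and a two-level group
        column; the higher-sorted label is coded 1 and its hazard is
        expressed relative to the other group.

    Returns
    -------
    CoxResult with the log-hazard coefficient, the hazard ratio, a robust
    (sandwich) Wald CI and a profile-likelihood CI.
    """
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events).ravel().astype(int)
    g_raw = np.asarray(group).ravel()
    if not (t.size == e.size == g_raw.size):
        raise ValueError("times, events and group must have equal length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("durations must be positive and finite")
    levels = np.unique(g_raw)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    g = (g_raw == levels[1]).astype(int)
    for lev, mask in ((levels[0], g == 0), (levels[1], g == 1)):
        if e[mask].sum() < 1:
            raise ValueError(f"group {lev!r} has no events")

    _, d_tot, d1, n0, n1 = _breslow_stats(t, e, g)
    d1_sum = float(d1.sum())

    theta = 0.0
    trace = []
    for it in range(1, max_iter + 1):
        r = np.exp(theta)
        s0 = n0 + n1 * r
        zbar = n1 * r / s0
        grad = d1_sum - float(np.sum(d_tot * zbar))
        info = float(np.sum(d_tot * zbar * (1.0 - zbar)))
        trace.append((it, theta, grad))
        if info <= 0:
            raise RuntimeError(f"singular information at iteration {it}: {trace}")
        step = grad / info
        theta += np.clip(step, -5.0, 5.0)
        if abs(grad) < tol:
            break
    else:
        raise RuntimeError(f"Newton-Raphson did not converge: trace={trace[-5:]}")

    r = np.exp(theta)
    s0 = n0 + n1 * r
    zbar = n1 * r / s0
    info = float(np.sum(d_tot * zbar * (1.0 - zbar)))
    se_model = 1.0 / math.sqrt(info)

    # sandwich variance from per-subject score residuals
    haz_inc = d_tot / s0            # Breslow baseline hazard increments
    event_times = np.unique(t[e == 1])
    cum_h = np.cumsum(haz_inc)
    cum_hz = np.cumsum(haz_inc * zbar)
    idx = np.searchsorted(event_times, t, side="right") - 1  # last event time <= t_i
    zbar_at = np.zeros(t.size)
    has_evt = (idx >= 0) & (e == 1) & np.isin(t, event_times)
    pos = np.searchsorted(event_times, t)
    pos = np.clip(pos, 0, event_times.size - 1)
    zbar_at[has_evt] = zbar[pos[has_evt]]
    ch = np.where(idx >= 0, cum_h[np.maximum(idx, 0)], 0.0)
    chz = np.where(idx >= 0, cum_hz[np.maximum(idx, 0)], 0.0)
    risk = np.exp(theta * g)
    u = e * (g - zbar_at) - risk * (g * ch - chz)
    var_robust = float(np.sum(u**2)) / info**2
    se_robust = math.sqrt(var_robust)

    zcrit = stats.norm.ppf(0.5 + conf_level / 2.0)
    wald_ci = (math.exp(theta - zcrit * se_robust), math.exp(theta + zcrit * se_robust))

    # profile-likelihood CI: 2*(l(theta_hat) - l(theta)) = chi2 quantile
    ll_hat = _partial_loglik(theta, d_tot, d1, n0, n1)
    crit = stats.chi2.ppf(conf_level, df=1)

    def lr_gap(th):
        return 2.0 * (ll_hat - _partial_loglik(th, d_tot, d1, n0, n1)) - crit

    def bracket_root(direction):
        step = max(4.0 * se_model, 0.5)
        far = theta + direction * step
        while lr_gap(far) < 0:
            step *= 2.0
            far = theta + direction * step
            if step > 1e3:
                raise RuntimeError("profile CI bracketing failed")
        from scipy.optimize import brentq

        lo, hi = sorted((theta, far))
        return brentq(lr_gap, lo, hi, xtol=1e-10)

    profile_ci = (math.exp(bracket_root(-1.0)), math.exp(bracket_root(+1.0)))

    return CoxResult(
        coef=float(theta),
        hr=float(math.exp(theta)),
        se_robust=se_robust,
        se_model=se_model,
        wald_ci=wald_ci,
        profile_ci=profile_ci,
        loglik=ll_hat,
        n_iter=it,
    )
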