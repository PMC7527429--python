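"""Survival evaluation: Kaplan-Meier curves, log-rank test, time-dependent AUC.

These are the evaluation primitives for a median-split risk stratification:
product-limit survival curves per risk group, the two-group log-rank
chi-square, and the discrimination of a baseline risk score for events by a
horizon t (cumulative-case / dynamic-control AUC with inverse probability
of censoring weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "TimeROC",
    "kaplan_meier",
    "log_rank",
    "time_dependent_auc",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""

    event_times: np.ndarray  # sorted distinct event times
    at_risk: np.ndarray  # n_j just before each event time
    events: np.ndarray  # d_j events at each event time
    survival: np.ndarray  # S(t_j) after the step at t_j

    def at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def before(self, t: float) -> float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.event_times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    observed: np.ndarray  # O_g per group
    expected: np.ndarray  # E_g per group
    variance: float
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class TimeROC:
    horizon: float
    auc: float
    n_cases: int
    n_controls: int


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty survival input")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def kaplan_meier(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator under right censoring.

    Subjects censored at an event time remain in the risk set for that
    time (censoring is tie-broken after events, the standard convention).
    """
    time, event = _check_surv(time, event)
    n = time.size
    event_times = np.unique(time[event == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for j, t in enumerate(event_times):
        at_risk[j] = int((time >= t).sum())
        d[j] = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d[j] / at_risk[j]
        surv[j] = s
    return SurvivalCurve(event_times=event_times, at_risk=at_risk, events=d, survival=surv)


def censoring_km(time, event) -> SurvivalCurve:
    """KM estimate of the censoring distribution G (event roles flipped)."""
    time, event = _check_surv(time, event)
    return kaplan_meier(time, 1 - event)


def log_rank(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance per event time.

    At each distinct event time t_j the observed group-A events are
    compared with the expectation d_j * n_Aj / n_j under the null of equal
    hazards; the chi-square statistic is (O_A - E_A)^2 / V with df = 1.
    """
    time_a, event_a = _check_surv(time_a, event_a)
    time_b, event_b = _check_surv(time_b, event_b)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    grp_a = np.concatenate([np.ones(time_a.size, bool), np.zeros(time_b.size, bool)])
    if event.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(time[event == 1])
    o_a = e_a = var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n_aj = (at_risk & grp_a).sum()
        d_j = ((time == t) & (event == 1)).sum()
        d_aj = ((time == t) & (event == 1) & grp_a).sum()
        o_a += d_aj
        e_a += d_j * n_aj / n_j
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero: no comparable risk sets")
    chi2 = (o_a - e_a) ** 2 / var
    o_total = float(event.sum())
    return LogRankResult(
        observed=np.array([o_a, o_total - o_a]),
        expected=np.array([e_a, o_total - e_a]),
        variance=float(var),
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


def time_dependent_auc(scores, time, event, t_horizon: float) -> TimeROC:
    """Cumulative-case / dynamic-control AUC at horizon ``t_horizon``.

    Cases are subjects with an observed event by the horizon; controls are
    subjects still event-free past it.  Censoring is handled by inverse
    probability of censoring weighting (IPCW): each case i is weighted by
    1 / G(T_i-) and each control by 1 / G(t), where G is the KM estimate
    of the censoring survival function.  Score ties count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _check_surv(time, event)
    if scores.shape != time.shape:
        raise ValueError("scores and time must have equal length")
    if t_horizon <= 0:
        raise ValueError("horizon must be positive")

    is_case = (time <= t_horizon) & (event == 1)
    is_control = time > t_horizon
    n_cases = int(is_case.sum())
    n_controls = int(is_control.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"horizon {t_horizon}: need >=1 case and >=1 control "
            f"(got {n_cases} cases, {n_controls} controls)"
        )

    G = censoring_km(time, event)
    w_case = np.array([1.0 / G.before(t) for t in time[is_case]])
    g_t = G.at(t_horizon)
    if g_t <= 0:
        raise ValueError(f"censoring survival is zero at horizon {t_horizon}")
    w_control = np.full(n_controls, 1.0 / g_t)

    s_case = scores[is_case]
    s_control = scores[is_control]
    # weighted concordance over all case-control pairs
    num = 0.0
    for sc, wc in zip(s_case, w_case):
        gt = (sc > s_control).astype(float)
        eq = (sc == s_control).astype(float)
        num += wc * float(np.dot(gt + 0.5 * eq, w_control))
    denom = w_case.sum() * w_control.sum()
    return TimeROC(
        horizon=float(t_horizon),
        auc=float(num / denom),
        n_cases=n_cases,
        n_controls=n_controls,
    )
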