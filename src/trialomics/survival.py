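"""Kaplan-Meier estimation and the two-sided log-rank (Mantel-Cox) test.

The product-limit estimator and the two-group Mantel-Cox statistic are
implemented directly so that the curve object carries full risk-set
bookkeeping (at-risk, events, censorings per time) and the test result
carries per-group observed and expected event counts; the test suite
cross-checks both against lifelines. Ties of events and censorings at the
same time are resolved events-first (the standard convention). The median
is the smallest event time t with S(t) <= 0.5, or NOT_REACHED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "NOT_REACHED",
    "SurvivalCurve",
    "LogRankResult",
    "km_fit",
    "km_median",
    "logrank_test",
]

#: sentinel for a median that the curve never reaches
NOT_REACHED = math.inf


def _as_arrays(sample: Sequence[tuple[float, bool]]) -> tuple[np.ndarray, np.ndarray]:
    if len(sample) == 0:
        raise ValueError("survival sample must be non-empty")
    times = np.asarray([t for t, _ in sample], dtype=float)
    events = np.asarray([bool(e) for _, e in sample], dtype=bool)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValueError("times must be finite and non-negative")
    return times, events


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with risk-set bookkeeping at each event time."""

    times: np.ndarray  # distinct times with >= 1 event
    at_risk: np.ndarray  # n_i at each event time
    events: np.ndarray  # d_i at each event time
    survival: np.ndarray  # S(t_i)
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        return km_median(self)


@dataclass(frozen=True)
class LogRankResult:
    """Two-group Mantel-Cox test: chi-square on 1 df.

    ``degenerate`` flags cases where the hypergeometric variance sums to
    zero (e.g. no events, or all subjects share one time); by convention
    the statistic is then 0 and p = 1.
    """

    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    degenerate: bool = False


def km_fit(sample: Sequence[tuple[float, bool]]) -> SurvivalCurve:
    """Fit the Kaplan-Meier product-limit estimator.

    ``sample`` is a sequence of (time, event) pairs; event=False means
    right-censored. Censored subjects leave the risk set after their time
    (events-first at ties).
    """
    times, events = _as_arrays(sample)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    distinct = np.unique(times[events])
    at_risk = np.empty(len(distinct), dtype=np.int64)
    d = np.empty(len(distinct), dtype=np.int64)
    surv = np.empty(len(distinct), dtype=float)
    s = 1.0
    for i, t in enumerate(distinct):
        ni = int(np.sum(times >= t))  # censored at t still at risk: events first
        di = int(np.sum((times == t) & events))
        s *= 1.0 - di / ni
        at_risk[i], d[i], surv[i] = ni, di, s
    return SurvivalCurve(times=distinct, at_risk=at_risk, events=d, survival=surv, n_subjects=n)


def km_median(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NOT_REACHED if none."""
    below = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if len(below) == 0:
        return NOT_REACHED
    return float(curve.times[below[0]])


def logrank_test(
    group_a: Sequence[tuple[float, bool]],
    group_b: Sequence[tuple[float, bool]],
) -> LogRankResult:
    """Two-sided two-group log-rank (Mantel-Cox) test.

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the pooled risk set; the
    squared sum of (O - E) over times, divided by the summed hypergeometric
    variance, is chi-square with 1 df under the null of equal hazards.
    """
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])

    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    exp_a = 0.0
    obs_b = 0.0
    exp_b = 0.0
    for t in event_times:
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & ~group).sum())
        died = (times == t) & events
        d_tot = int(died.sum())
        d_a = int((died & ~group).sum())
        e_a = d_tot * n_a / n_tot
        obs_a += d_a
        exp_a += e_a
        obs_b += d_tot - d_a
        exp_b += d_tot - e_a
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += (
                d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var <= 0.0:
        return LogRankResult(
            chi_square=0.0, df=1, p_value=1.0,
            observed=(obs_a, obs_b), expected=(exp_a, exp_b), degenerate=True,
        )
    stat = o_minus_e**2 / var
    p = float(chi2.sf(stat, df=1))
    return LogRankResult(
        chi_square=float(stat), df=1, p_value=p,
        observed=(obs_a, obs_b), expected=(exp_a, exp_b),
    )


def sample_from_frame(df, time_col: str = "pfs_months", event_col: str = "pfs_event"):
    """Extract a (time, event) sample from a clinical DataFrame slice."""
    return list(zip(df[time_col].astype(float), df[event_col].astype(bool)))
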