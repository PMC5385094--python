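"""Kaplan-Meier estimation and k-sample log-rank comparison of clusters.

Survival differences between lncRNA clusters are assessed at a fixed
horizon (default 60 months): follow-up beyond the horizon is
administratively censored at the horizon (events exactly at the boundary
are kept as events), curves come from the product-limit estimator, and the
global k-sample log-rank test compares observed with expected events using
the hypergeometric variance at each event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import InputError


@dataclass
class SurvivalCurve:
    times: np.ndarray          # event-time grid, starts at 0
    survival: np.ndarray       # product-limit S(t), non-increasing, S(0)=1
    at_risk: np.ndarray        # subjects at risk entering each grid time
    censor_times: np.ndarray   # observed censoring times (plot ticks)


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise InputError("times and events must be aligned vectors")
    if t.size == 0:
        raise InputError("need at least one subject")
    if (t < 0).any():
        raise InputError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise InputError("events must be 0/1")
    return t, e.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i),
    with tied events aggregated per distinct time."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Global k-sample log-rank test: (chi-square statistic, df = k-1, p)."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise InputError("groups must align with times")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise InputError("need >= 2 non-empty groups")
    for lab in labels:
        if np.all(t[g == lab] == 0):
            raise InputError(f"group {lab!r} has all times 0")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def censor_at(times, events, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at the horizon.

    Subjects with time > horizon become (horizon, censored); subjects at or
    before the horizon — including events exactly at it — are unchanged.
    """
    if horizon <= 0:
        raise InputError("horizon must be > 0")
    t, e = _check_surv(times, events)
    over = t > horizon
    t = np.where(over, horizon, t)
    e = np.where(over, 0, e)
    return t, e


def km_by_group(times, events, groups) -> dict[object, SurvivalCurve]:
    """One product-limit curve per group label."""
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    return {lab: km_estimate(t[g == lab], e[g == lab]) for lab in pd.unique(g)}
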