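"""Responder stratification, Kaplan-Meier estimation, and log-rank tests.

Patients progressing before the first scan (PFS < 2 months with a
progression event) are non-responders (NR); patients reaching 2 months,
censored or not, are responders (Resp). Censoring before the threshold is
an explicit "indeterminate" class: such patients cannot be shown to have
progressed early and are excluded from NR/Resp contrasts.

The two-group comparison is the standard log-rank test (hypergeometric
variance at each distinct event time); its hazard-ratio summary is the
ratio of observed-to-expected event ratios, (O_a/E_a)/(O_b/E_b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from lifelines import KaplanMeierFitter

from .config import ThresholdConfig
from .stats import chi_square_independence

__all__ = [
    "stratify_response",
    "KMEstimate",
    "kaplan_meier",
    "SurvivalComparison",
    "km_logrank",
    "response_vs_cbor",
    "MEDIAN_NOT_REACHED",
]

#: sentinel for a median survival never reached
MEDIAN_NOT_REACHED = float("inf")

_CLINICAL_COLS = ("patient", "pfs_months", "event")


def stratify_response(
    records: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> pd.Series:
    """Label patients NR / Resp / indeterminate from PFS and event flags."""
    cfg = cfg or ThresholdConfig()
    missing = set(_CLINICAL_COLS) - set(records.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    pfs = records["pfs_months"].astype(float)
    if (pfs < 0).any():
        raise ValueError("pfs_months must be non-negative")
    event = records["event"].astype(int)
    labels = np.where(
        pfs >= cfg.pfs_responder_min,
        "Resp",
        np.where(event == 1, "NR", "indeterminate"),
    )
    return pd.Series(labels, index=records.index, name="response")


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray       # distinct observed times, ascending
    survival: np.ndarray    # S(t) at those times
    at_risk: np.ndarray     # number at risk just before each time
    median: float           # earliest t with S(t) <= 0.5, inf if never


def kaplan_meier(times, events) -> KMEstimate:
    """Product-limit survival estimate with a first-crossing median."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0 or times.shape != events.shape:
        raise ValueError("times and events must be non-empty and matched")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor row unless it is an observed time
    if grid.size and grid[0] == 0.0 and not np.any(times == 0.0):
        grid, surv = grid[1:], surv[1:]
    at_risk = np.array([(times >= t).sum() for t in grid], dtype=int)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(grid[below[0]]) if below.size else MEDIAN_NOT_REACHED
    return KMEstimate(times=grid, survival=surv, at_risk=at_risk, median=median)


@dataclass(frozen=True)
class SurvivalComparison:
    statistic: float
    p: float
    hazard_ratio: float          # group a relative to group b
    observed: tuple[float, float]
    expected: tuple[float, float]
    median: tuple[float, float]
    at_risk_table: pd.DataFrame  # per distinct event time: n at risk / events per group


def km_logrank(
    times_a, events_a, times_b, events_b
) -> SurvivalComparison:
    """Two-group log-rank test with an O/E hazard-ratio summary.

    At each distinct event time t, with n_g at risk and d_g events in group
    g (n = n_a + n_b, d = d_a + d_b), the expected events in group a are
    d * n_a / n and the hypergeometric variance is
    d * (n_a/n) * (1 - n_a/n) * (n - d)/(n - 1). The chi-square statistic
    is (O_a - E_a)^2 / V with 1 df; HR = (O_a/E_a)/(O_b/E_b).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = e_a = var = 0.0
    rows = []
    for t in event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        d_a = float(((ta == t) & (ea == 1)).sum())
        d_b = float(((tb == t) & (eb == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n == 0:
            continue
        exp_a = d * n_a / n
        o_a += d_a
        e_a += exp_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        rows.append(
            {"time": t, "n_risk_a": n_a, "n_risk_b": n_b, "events_a": d_a, "events_b": d_b}
        )
    o_b = float(ea.sum() + eb.sum()) - o_a
    e_b = float(o_a + o_b) - e_a

    stat = (o_a - e_a) ** 2 / var if var > 0 else 0.0
    p = float(sps.chi2.sf(stat, df=1)) if var > 0 else 1.0
    if e_a > 0 and e_b > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
    elif o_a == 0 and o_b > 0:
        hr = 0.0
    else:
        hr = math.inf
    km_a = kaplan_meier(ta, ea)
    km_b = kaplan_meier(tb, eb)
    return SurvivalComparison(
        statistic=float(stat),
        p=p,
        hazard_ratio=float(hr),
        observed=(o_a, o_b),
        expected=(e_a, e_b),
        median=(km_a.median, km_b.median),
        at_risk_table=pd.DataFrame(rows),
    )


def response_vs_cbor(labels: pd.Series, cbor: pd.Series):
    """Contingency of NR/Resp labels against best-overall-response categories.

    Indeterminate patients are excluded; empty categories are dropped before
    the chi-square test of independence.
    """
    keep = labels.isin(["NR", "Resp"])
    table = pd.crosstab(labels[keep], cbor[keep])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two response labels and two cBOR categories")
    result = chi_square_independence(table.to_numpy())
    return table, result
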