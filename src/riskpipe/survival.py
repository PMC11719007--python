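"""Kaplan-Meier estimation and Mantel-Cox log-rank comparison of predicted
low- vs high-risk groups (PFS and OS endpoints).

Estimation is delegated to lifelines; this module provides the pipeline's
record types and output contracts. Ties between an event and a censoring at
the same time follow the standard Kaplan-Meier convention (the event is
processed first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["SurvivalRecord", "KMCurve", "km_estimate", "logrank_test"]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool  # True = progression/death observed, False = censored
    endpoint: str = "PFS"  # PFS | OS
    risk_group: str = ""   # low | high

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _unpack(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        times = records["time"].to_numpy(dtype=float)
        events = records["event"].to_numpy(dtype=bool)
    else:
        times = np.array([r.time for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=bool)
    if len(times) == 0:
        raise ValueError("at least one record required")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    return times, events


def km_estimate(records) -> KMCurve:
    """Product-limit survival estimate; censored times reduce the at-risk
    count without stepping the curve down."""
    times, events = _unpack(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(t)
    t, s = t[order], s[order]
    at_risk = np.array([(times >= ti).sum() for ti in t])
    return KMCurve(times=t, survival=s, at_risk=at_risk)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Mantel-Cox log-rank comparison of two survival groups.

    Returns (chi-square statistic, p-value from chi2 with 1 df).
    """
    ta, ea = _unpack(group_a)
    tb, eb = _unpack(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
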