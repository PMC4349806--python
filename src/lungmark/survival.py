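"""Median dichotomization and nonparametric survival comparison.

Feature scores are split at a threshold (the in-sample median by default,
or a threshold carried over from a training cohort), and the two groups are
compared with Kaplan-Meier curves and the two-group log-rank test. Subjects
scoring exactly at the threshold go to the low group by default.

The product-limit estimation and the log-rank statistic are delegated to
``lifelines``; this module wraps them behind the package's group/curve
types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalGroup",
    "KMCurve",
    "dichotomize_at_median",
    "km_estimate",
    "logrank_test",
    "median_split_logrank",
]


@dataclass(frozen=True)
class SurvivalGroup:
    """One arm of a dichotomized cohort: parallel time/event arrays."""

    label: str  # "low" or "high"
    times: np.ndarray  # days, >= 0
    events: np.ndarray  # 1 = death, 0 = censored

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "events", np.asarray(self.events, int))
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must be parallel arrays")
        if (self.times < 0).any():
            raise ValueError("survival times must be >= 0")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("events must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: S(t) evaluated at distinct event times."""

    event_times: np.ndarray  # sorted distinct times with >= 1 event
    survival_prob: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def dichotomize_at_median(scores, times, events, threshold: float | None = None):
    """Split subjects into low/high groups at a feature threshold.

    ``threshold`` defaults to the in-sample median; an external threshold
    (e.g. a training-cohort median applied to a validation cohort) overrides
    it. Scores <= threshold go to the low group, > threshold to the high
    group. An empty group is returned as-is with a warning.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must be parallel")
    if len(scores) < 2:
        raise ValueError("need at least 2 subjects to dichotomize")
    if threshold is None:
        threshold = float(np.median(scores))
    low = scores <= threshold
    if low.all() or not low.any():
        logger.warning("threshold %.6g produces an empty group", threshold)
    return (
        SurvivalGroup("low", times[low], events[low]),
        SurvivalGroup("high", times[~low], events[~low]),
    )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    has_event = tbl["observed"] > 0
    event_times = tbl.index.to_numpy(float)[has_event]
    surv = kmf.survival_function_["KM_estimate"].reindex(tbl.index).to_numpy(float)[has_event]
    at_risk = tbl["at_risk"].to_numpy(float)[has_event]
    return KMCurve(event_times=event_times, survival_prob=surv, at_risk=at_risk)


def logrank_test(group_a: SurvivalGroup, group_b: SurvivalGroup) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi_square, p_value)``.

    The statistic is the usual hypergeometric observed-minus-expected sum,
    chi-square distributed with 1 df under the null. Returns ``(nan, nan)``
    when no events occurred in either group.
    """
    from lifelines.statistics import logrank_test as _ll_logrank

    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if group_a.events.sum() + group_b.events.sum() == 0:
        return math.nan, math.nan
    res = _ll_logrank(group_a.times, group_b.times, event_observed_A=group_a.events, event_observed_B=group_b.events)
    return float(res.test_statistic), float(res.p_value)


def median_split_logrank(scores, times, events, threshold: float | None = None):
    """Convenience wrapper: dichotomize, fit both KM curves, run log-rank.

    Returns ``(low_group, high_group, low_curve, high_curve, chi2, p)``;
    curves are None for an empty group, in which case the test is NaN.
    """
    low, high = dichotomize_at_median(scores, times, events, threshold)
    low_curve = km_estimate(low.times, low.events) if len(low) else None
    high_curve = km_estimate(high.times, high.events) if len(high) else None
    if len(low) and len(high):
        chi2, p = logrank_test(low, high)
    else:
        chi2, p = math.nan, math.nan
    return low, high, low_curve, high_curve, chi2, p
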