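"""Survival and response endpoints: Kaplan-Meier, log-rank, ORR/DCR.

Overall survival runs from the start of immunotherapy to death (alive
patients censored at last contact); progression-free survival runs to
progression or death (censored at the last adequate assessment). Best
response uses RECIST v1.1 categories; the objective response rate is
CR+PR and the disease control rate CR+PR+SD. Median follow-up is the
reverse Kaplan-Meier median (censoring indicator flipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io import BestResponse, PatientRecord
from .profiling import round_half_up

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "ResponseSummary",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "response_rates",
    "median_followup",
    "os_records",
    "pfs_records",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored time-to-event observation (months)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(
                f"patient {self.patient_id!r}: negative survival time {self.time}"
            )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: right-continuous step function S(t).

    ``times`` holds the distinct event times in increasing order with the
    number at risk just before each and S evaluated at each. The median is
    the smallest time with S(t) <= 0.5, or None when S never reaches 0.5.
    """

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]
    median: float | None

    def probability_at(self, t: float) -> float:
        """S(t) for arbitrary t >= 0 (right-continuous)."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass(frozen=True)
class ResponseSummary:
    n: int
    orr_pct: float
    dcr_pct: float


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    df: int


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    When events and censorings tie at the same time, events are processed
    first (the standard convention), i.e. tied censored subjects are still
    at risk for the tied event.
    """
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    out_times, out_risk, out_events, out_surv = [], [], [], []
    s = 1.0
    median = None
    for t in event_times:
        at_risk = int(np.count_nonzero(times >= t))
        d = int(np.count_nonzero(events & (times == t)))
        s *= 1.0 - d / at_risk
        out_times.append(float(t))
        out_risk.append(at_risk)
        out_events.append(d)
        out_surv.append(s)
        if median is None and s <= 0.5:
            median = float(t)
    return KMCurve(
        times=tuple(out_times),
        at_risk=tuple(out_risk),
        events=tuple(out_events),
        survival=tuple(out_surv),
        median=median,
    )


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> LogRankResult:
    """Unweighted (Mantel-Haenszel) log-rank test across two or more groups.

    The chi-square statistic on g-1 degrees of freedom compares observed
    event counts per group with their expectation under a common hazard,
    using the variance-covariance of the hypergeometric event allocation
    at each distinct event time.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    if any(len(grp) == 0 for grp in groups):
        raise ValueError("every group must be non-empty")
    times = np.concatenate([[r.time for r in grp] for grp in groups])
    events = np.concatenate([[r.event for r in grp] for grp in groups]).astype(bool)
    labels = np.concatenate([[i] * len(grp) for i, grp in enumerate(groups)])

    event_times = np.unique(times[events])
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in event_times:
        at_risk_mask = times >= t
        n_t = int(at_risk_mask.sum())
        d_t = int((events & (times == t)).sum())
        n_i = np.array([(at_risk_mask & (labels == i)).sum() for i in range(g)], float)
        d_i = np.array(
            [(events & (times == t) & (labels == i)).sum() for i in range(g)], float
        )
        observed += d_i
        expected += d_t * n_i / n_t
        if n_t > 1:
            frac = n_i / n_t
            factor = d_t * (n_t - d_t) / (n_t - 1)
            cov += factor * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: g - 1]
    v = cov[: g - 1, : g - 1]
    # pseudo-inverse guards the degenerate no-variance case (e.g. no events)
    chi2 = float(diff @ np.linalg.pinv(v) @ diff) if v.size else 0.0
    if not np.any(np.diag(cov) > 0):
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df=g - 1))
    return LogRankResult(statistic=chi2, p_value=p, df=g - 1)


def response_rates(
    patients: Sequence[PatientRecord],
    *,
    exclude_ne: bool = False,
) -> ResponseSummary:
    """ORR (CR+PR) and DCR (CR+PR+SD) percentages, one decimal.

    Non-evaluable patients count in the denominator by default (the
    conservative intention-to-treat convention); ``exclude_ne=True``
    drops them from the denominator.
    """
    if not patients:
        raise ValueError("need at least one patient")
    pool = (
        [p for p in patients if p.best_response is not BestResponse.NE]
        if exclude_ne
        else list(patients)
    )
    if not pool:
        raise ValueError("no evaluable patients after excluding NE")
    n = len(pool)
    responders = sum(
        p.best_response in (BestResponse.CR, BestResponse.PR) for p in pool
    )
    controlled = responders + sum(
        p.best_response is BestResponse.SD for p in pool
    )
    return ResponseSummary(
        n=n,
        orr_pct=round_half_up(100.0 * responders / n, 1),
        dcr_pct=round_half_up(100.0 * controlled / n, 1),
    )


def median_followup(
    records: Sequence[SurvivalRecord],
    *,
    method: Literal["reverse_km", "observed"] = "reverse_km",
) -> float | None:
    """Median follow-up time in months.

    The default reverse Kaplan-Meier flips the censoring indicator (a
    censoring becomes the "event" of interest); when every patient died the
    reverse-KM median can be undefined and None is returned. ``observed``
    gives the plain median of observation times.
    """
    if not records:
        raise ValueError("need at least one survival record")
    if method == "observed":
        return float(np.median([r.time for r in records]))
    flipped = [
        SurvivalRecord(patient_id=r.patient_id, time=r.time, event=not r.event)
        for r in records
    ]
    return km_estimate(flipped).median


def os_records(patients: Sequence[PatientRecord]) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(patient_id=p.patient_id, time=p.os_months, event=p.os_event)
        for p in patients
    ]


def pfs_records(patients: Sequence[PatientRecord]) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(patient_id=p.patient_id, time=p.pfs_months, event=p.pfs_event)
        for p in patients
    ]
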