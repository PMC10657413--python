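"""Surrogate-endpoint survival: event extraction, Kaplan-Meier, log-rank.

Mortality is not observed directly in these studies; instead the first
measurement day on which an animal's tumor volume reaches a threshold
(default 1200 mm^3) serves as a surrogate death time.  Animals that never
reach the threshold are censored at their last observed day — including
animals removed early for non-tumor humane reasons.  Event times sit on
the measurement grid (no interpolation between the thrice-weekly
assessments).

The product-limit (Kaplan-Meier) estimate and the unweighted two-sided
log-rank test are computed with lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DegenerateInputError, InsufficientDataError, ValidationError
from .io import MeasurementTable

DEFAULT_ENDPOINT_VOLUME = 1200.0  # mm^3


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    group: str
    time: float  # study day
    event: bool  # True = endpoint volume reached; False = censored


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate on the distinct event days."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        for time, surv in zip(self.times, self.survival):
            if surv <= 0.5:
                return time
        return float("inf")


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def surrogate_events(
    table: MeasurementTable, threshold: float = DEFAULT_ENDPOINT_VOLUME
) -> list[SurvivalRecord]:
    """Per-animal surrogate event/censor times at a volume threshold.

    Event time = first measurement day with volume >= threshold (an animal
    that crosses and later regresses still has its event at the first
    crossing).  Animals never reaching the threshold are censored at their
    last measured day.
    """
    if threshold <= 0:
        raise ValidationError(f"endpoint volume must be > 0, got {threshold}")
    records: list[SurvivalRecord] = []
    for animal, sub in table.data.groupby("animal_id", sort=False):
        vol = sub.dropna(subset=["volume"]).sort_values("day")
        if len(vol) == 0:
            raise ValidationError(f"animal {animal}: no volume measurements")
        over = vol[vol["volume"] >= threshold]
        group = str(vol["group"].iloc[0])
        if len(over):
            records.append(
                SurvivalRecord(str(animal), group, float(over["day"].iloc[0]), True)
            )
        else:
            records.append(
                SurvivalRecord(str(animal), group, float(vol["day"].iloc[-1]), False)
            )
    return records


def km_estimate(records: list[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit curve from survival records.

    Ties between events and censorings at the same day are handled
    events-first (the standard convention: a censored animal at day t is
    still at risk for an event at day t).
    """
    if not records:
        raise InsufficientDataError("km_estimate: no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    return KmCurve(
        times=tuple(float(t) for t in ev.index),
        survival=tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in ev.index),
        at_risk=tuple(int(n) for n in ev["at_risk"]),
        n_events=tuple(int(d) for d in ev["observed"]),
    )


def logrank_test(
    arm_a: list[SurvivalRecord], arm_b: list[SurvivalRecord]
) -> LogRankResult:
    """Two-sided unweighted log-rank comparison of two arms.

    Standard chi-square statistic with hypergeometric (tie-corrected)
    variance at each distinct event time, referred to chi-square with
    1 df.
    """
    if not arm_a or not arm_b:
        raise InsufficientDataError("logrank_test: both arms need >= 1 record")
    if not any(r.event for r in [*arm_a, *arm_b]):
        raise DegenerateInputError("logrank_test: no events in either arm")
    res = _ll_logrank(
        [r.time for r in arm_a],
        [r.time for r in arm_b],
        event_observed_A=[r.event for r in arm_a],
        event_observed_B=[r.event for r in arm_b],
    )
    return LogRankResult(
        chi_square=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": r.animal_id, "group": r.group, "time": r.time, "event": r.event}
            for r in records
        ]
    )


def km_to_frame(curve: KmCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
        }
    )
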