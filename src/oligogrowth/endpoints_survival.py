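"""Survival endpoints, Kaplan-Meier estimation and the two-group log-rank test.

Endpoints, all measured in days from the start of immune-checkpoint blockade:

* OS   — overall survival: time to all-cause death.
* PFS  — progression-free survival: time to first progression or death.
* PFS2 — time to second progression (after the next treatment line) or death.

Death counts as an event for all three endpoints, so for every patient
PFS <= OS and PFS <= PFS2.

The product-limit estimator and the Mantel-Haenszel log-rank statistic are
implemented directly on numpy arrays (risk sets via sorted-array bisection),
with the standard conventions: tied events handled jointly in one risk-set
update, censorings tied with events treated as occurring just after them,
hypergeometric variance per event time, no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

ENDPOINTS = ("OS", "PFS", "PFS2")

#: "3-year" evaluation horizon in days.
THREE_YEARS = 1095.0


class SurvivalInputError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    """One (time, event) pair: event=True means observed, False means censored."""

    patient_id: str
    endpoint: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise SurvivalInputError(f"unknown endpoint {self.endpoint!r}")
        if self.time < 0:
            raise SurvivalInputError(
                f"patient {self.patient_id}: negative time {self.time}"
            )


def build_endpoint(row: Mapping, endpoint: str) -> SurvivalRecord:
    """Map one patient row to a SurvivalRecord for ``endpoint``.

    Expects columns ``{os|pfs|pfs2}_days`` and ``{os|pfs|pfs2}_event`` plus
    ``patient_id``; enforces PFS <= OS and PFS <= PFS2 and 0/1 event flags.
    """
    if endpoint not in ENDPOINTS:
        raise SurvivalInputError(f"unknown endpoint {endpoint!r}")
    key = endpoint.lower()
    time = float(row[f"{key}_days"])
    event = row[f"{key}_event"]
    if event not in (0, 1, 0.0, 1.0, True, False):
        raise SurvivalInputError(
            f"patient {row['patient_id']}: {key}_event must be 0/1, got {event!r}"
        )
    if time < 0:
        raise SurvivalInputError(
            f"patient {row['patient_id']}: negative {key}_days {time}"
        )
    if float(row["pfs_days"]) > float(row["os_days"]):
        raise SurvivalInputError(
            f"patient {row['patient_id']}: pfs_days exceeds os_days"
        )
    if float(row["pfs_days"]) > float(row["pfs2_days"]):
        raise SurvivalInputError(
            f"patient {row['patient_id']}: pfs_days exceeds pfs2_days"
        )
    return SurvivalRecord(
        patient_id=str(row["patient_id"]), endpoint=endpoint,
        time=time, event=bool(event),
    )


def endpoint_arrays(patients, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, events) arrays for one endpoint from a patient table."""
    key = endpoint.lower()
    if endpoint not in ENDPOINTS:
        raise SurvivalInputError(f"unknown endpoint {endpoint!r}")
    times = np.asarray(patients[f"{key}_days"], dtype=float)
    events = np.asarray(patients[f"{key}_event"], dtype=bool)
    return times, events


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve over the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event. All-censored inputs yield empty arrays (S identically 1).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int


def _coerce(records_or_times, events=None) -> tuple[np.ndarray, np.ndarray]:
    if events is not None:
        return (np.asarray(records_or_times, dtype=float),
                np.asarray(events, dtype=bool))
    recs = list(records_or_times)
    return (np.array([r.time for r in recs], dtype=float),
            np.array([r.event for r in recs], dtype=bool))


def km_estimate(records_or_times, events=None) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Accepts either a list of :class:`SurvivalRecord` or ``(times, events)``
    arrays. S(t) = prod over event times t_i <= t of (1 - d_i / n_i), with
    n_i the number still at risk at t_i (censorings tied with events remain
    in the risk set for that update).
    """
    times, events_arr = _coerce(records_or_times, events)
    if times.size == 0:
        raise SurvivalInputError("km_estimate requires at least one record")
    if np.any(times < 0):
        raise SurvivalInputError("negative survival time")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events_arr[order]
    ev_times = np.unique(t_sorted[e_sorted])
    n = times.size
    at_risk = n - np.searchsorted(t_sorted, ev_times, side="left")
    d = np.array([int(np.sum(e_sorted[t_sorted == t])) for t in ev_times])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=ev_times, survival=surv,
                   at_risk=at_risk, n_events=d, n_subjects=n)


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function evaluation S(t); 1 before the first event time."""
    if t < 0:
        raise SurvivalInputError(f"t must be >= 0, got {t}")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


NOT_REACHED = None
"""Sentinel: the curve never drops to 0.5, so median survival is undefined."""


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or ``NOT_REACHED`` (None)."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.event_times[below[0]])


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank chi-squared (1 df), symmetric in group labels."""

    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    df: int = 1


def logrank_test(
    times_a, events_a=None, times_b=None, events_b=None
) -> LogRankResult:
    """Mantel-Haenszel log-rank test for two groups.

    Call either with two lists of :class:`SurvivalRecord`
    (``logrank_test(recs_a, recs_b)``) or with four arrays
    (``times_a, events_a, times_b, events_b``).

    statistic = (sum_i (O_i - E_i))^2 / sum_i Var_i over the distinct pooled
    event times, with hypergeometric variance per time; the p-value is the
    chi-squared(1) upper tail. Zero pooled events give statistic 0, p 1.
    """
    if times_b is None:
        # two record lists
        ta, ea = _coerce(times_a)
        tb, eb = _coerce(events_a)
    else:
        ta, ea = _coerce(times_a, events_a)
        tb, eb = _coerce(times_b, events_b)
    if ta.size == 0 or tb.size == 0:
        raise SurvivalInputError("both groups must be nonempty")

    ta_sorted = np.sort(ta)
    tb_sorted = np.sort(tb)
    pooled_times = np.concatenate([ta[ea], tb[eb]])
    ev_times = np.unique(pooled_times)
    if ev_times.size == 0:
        return LogRankResult(0.0, 1.0, (ta.size, tb.size))

    n1 = ta.size - np.searchsorted(ta_sorted, ev_times, side="left")
    n2 = tb.size - np.searchsorted(tb_sorted, ev_times, side="left")
    d1 = np.array([int(np.sum(ea[ta == t])) for t in ev_times])
    d2 = np.array([int(np.sum(eb[tb == t])) for t in ev_times])
    n = n1 + n2
    d = d1 + d2

    expected1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n > 1,
            d * (n1 / n) * (n2 / n) * (n - d) / np.maximum(n - 1, 1),
            0.0,
        )
    observed_minus_expected = float(np.sum(d1 - expected1))
    total_var = float(np.sum(var))
    if total_var == 0.0:
        return LogRankResult(0.0, 1.0, (ta.size, tb.size))
    stat = observed_minus_expected**2 / total_var
    p = float(chi2.sf(stat, 1))
    return LogRankResult(float(stat), p, (ta.size, tb.size))


def km_table(curve: KMCurve):
    """KM curve as a plain table (time, at_risk, events, survival) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk,
            "events": curve.n_events,
            "survival": curve.survival,
        }
    )
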