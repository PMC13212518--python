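"""Per-plant trait time series and the operations built on them.

A :class:`GrowthSeries` is the unit of all fitting: an ordered, strictly
increasing day axis (days after transplanting, day 1 = first day after
transplant) with matched nonnegative trait values.  On top of it sit
difference-quotient growth rates, debounced curd-appearance detection,
developmental alignment (curd appearance mapped to day 1), and cohort mean
series truncated to days with at least ``min_n`` contributing plants.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrowthSeries",
    "RateSeries",
    "growth_rate",
    "detect_curd_appearance",
    "align_to_appearance",
    "truncated_mean_series",
    "days_after_transplant",
]

#: traits measured as areas (cm^2) vs lengths (cm)
AREA_TRAITS = ("LA", "CA")
LENGTH_TRAITS = ("PCW", "FCD")
CURD_TRAITS = ("CA", "FCD")


@dataclass(frozen=True)
class GrowthSeries:
    """Ordered (day, value) trajectory of one trait for one plant."""

    plant_id: str
    trait: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if days.ndim != 1 or values.ndim != 1:
            raise ValueError("days and values must be 1-D")
        if days.size != values.size:
            raise ValueError("days and values must have equal length")
        if days.size and np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError("trait values must be nonnegative")

    def __len__(self) -> int:
        return int(self.days.size)

    @property
    def final_value(self) -> float:
        return float(self.values[-1])

    @property
    def final_day(self) -> float:
        return float(self.days[-1])


@dataclass(frozen=True)
class RateSeries:
    """Difference-quotient growth rates indexed at interval midpoints."""

    plant_id: str
    trait: str
    days: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "days", np.asarray(self.days, float))
        object.__setattr__(self, "rates", np.asarray(self.rates, float))


def growth_rate(series: GrowthSeries, window="consecutive") -> RateSeries:
    """Difference-quotient growth rate of a trait series.

    ``window="consecutive"`` uses successive acquisitions:
    ``rate_i = (v_i - v_{i-1}) / (t_i - t_{i-1})``.  A numeric window instead
    pairs each point with the nearest earlier point at least ``window`` days
    back.  Rates are stamped at the interval midpoint.
    """
    t, v = series.days, series.values
    if t.size < 2:
        raise ValueError("growth rate needs at least 2 points")
    if window == "consecutive":
        dt = np.diff(t)
        rates = np.diff(v) / dt
        mid = 0.5 * (t[1:] + t[:-1])
        return RateSeries(series.plant_id, series.trait, mid, rates)
    window = float(window)
    if window <= 0:
        raise ValueError("window must be positive")
    mids, rates = [], []
    for i in range(1, t.size):
        spans = t[i] - t[:i]
        ok = np.nonzero(spans >= window)[0]
        if ok.size == 0:
            continue
        j = int(ok[-1])  # nearest earlier day spanning >= window
        mids.append(0.5 * (t[i] + t[j]))
        rates.append((v[i] - v[j]) / (t[i] - t[j]))
    return RateSeries(series.plant_id, series.trait, np.array(mids), np.array(rates))


def detect_curd_appearance(
    days: Sequence[float],
    detected: Sequence[bool] | None = None,
    min_consecutive: int = 2,
) -> float | None:
    """First acquisition day starting a run of curd detections.

    ``days`` are the plant's acquisition days in order; ``detected`` flags
    whether a curd was segmented on that day (all True if omitted, i.e. the
    caller passes only detection days).  A run of at least
    ``min_consecutive`` consecutive acquisitions with a detection debounces
    single-frame false positives.  Returns ``None`` when no qualifying run
    exists — absence is a valid outcome, not an error.
    """
    days = np.asarray(days, float)
    if detected is None:
        det = np.ones(days.size, dtype=bool)
    else:
        det = np.asarray(detected, dtype=bool)
    if det.size != days.size:
        raise ValueError("days and detected must have equal length")
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    if days.size and np.any(np.diff(days) <= 0):
        raise ValueError("acquisition days must be strictly increasing")
    run_start, run_len = None, 0
    for day, flag in zip(days, det):
        if flag:
            if run_len == 0:
                run_start = day
            run_len += 1
            if run_len >= min_consecutive:
                return float(run_start)
        else:
            run_len = 0
    return None


def align_to_appearance(
    series: GrowthSeries,
    tca: float,
    drop_before: bool | None = None,
) -> GrowthSeries:
    """Re-index a series to developmental time with curd appearance = day 1.

    Points before ``tca`` are dropped for curd traits (a curd does not exist
    before it appears); for leaf traits the full trajectory is kept by
    default.
    """
    if tca is None or not np.isfinite(tca):
        raise ValueError("curd appearance day (tca) is missing")
    if series.days.size and tca > series.days[-1]:
        raise ValueError("tca lies beyond the observed series")
    if drop_before is None:
        drop_before = series.trait in CURD_TRAITS
    days = series.days - tca + 1.0
    values = series.values
    if drop_before:
        keep = series.days >= tca
        days, values = days[keep], values[keep]
    return GrowthSeries(series.plant_id, series.trait, days, values)


def truncated_mean_series(
    group: Iterable[GrowthSeries],
    min_n: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-day arithmetic mean across plants, truncated to days with n >= min_n.

    Returns ``(days, means, n)``.  Days contributed by fewer than ``min_n``
    series are omitted, which trims stragglers at the trajectory tails and
    avoids survivor bias from single abnormal plants.
    """
    group = list(group)
    if not group:
        raise ValueError("empty series group")
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    bucket: dict[float, list[float]] = {}
    for s in group:
        for d, v in zip(s.days, s.values):
            bucket.setdefault(float(d), []).append(float(v))
    days = np.array(sorted(d for d, vs in bucket.items() if len(vs) >= min_n))
    means = np.array([np.mean(bucket[d]) for d in days])
    ns = np.array([len(bucket[d]) for d in days], dtype=int)
    return days, means, ns


def days_after_transplant(date, transplant_date) -> int:
    """Calendar day index with day 1 = first day after transplanting."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(transplant_date, str):
        transplant_date = _dt.date.fromisoformat(transplant_date)
    delta = (date - transplant_date).days
    if delta < 0:
        raise ValueError(f"image date {date} precedes transplant {transplant_date}")
    return int(delta)
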