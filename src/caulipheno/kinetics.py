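"""Growth kinetics from fitted curves.

For a sigmoidal leaf-area fit the growth-rate curve (first derivative) has a
single peak; the rapid growth period is the interval between the two
inflection points of that rate curve — the roots of the *third* derivative
flanking the rate peak.  For the sine curd model the rate is analytic,
``rate(t) = (A pi / w) cos(pi (t - tc) / w)``, peaking at ``tc``; the
harvest-time rate relative to the peak rate, together with the trend of the
rate at harvest, classifies a curd's harvest status into three kinetic
types: still accelerating (steady climbing), at the rate plateau (peak
burst), or past the peak (mature and full).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .models import ModelFit, get_model

__all__ = [
    "KineticsSummary",
    "CurdKinetics",
    "rapid_growth_window",
    "curd_rate_stats",
    "classify_curd",
    "inflection_vs_tca_regression",
    "KineticsError",
]

#: kinetic harvest-status labels
MATURE_FULL = "mature_full"
PEAK_BURST = "peak_burst"
STEADY_CLIMBING = "steady_climbing"


class KineticsError(RuntimeError):
    """Degenerate fit: kinetic landmarks not recoverable."""


@dataclass(frozen=True)
class KineticsSummary:
    """Rapid-growth-period landmarks of a sigmoidal fit (days)."""

    t_infl1: float
    t_infl2: float
    t_max_rate: float
    max_rate: float

    @property
    def rapid_duration(self) -> float:
        return self.t_infl2 - self.t_infl1

    def __post_init__(self):
        if not (self.t_infl1 < self.t_max_rate < self.t_infl2):
            raise KineticsError(
                "inflection points must bracket the growth-rate peak"
            )


@dataclass(frozen=True)
class CurdKinetics:
    """Harvest-time curd growth-rate statistics from a sine fit."""

    t_peak_rate: float
    max_rate: float  # cm^2/day
    harvest_day: float
    harvest_rate: float
    rate_ratio: float
    trend_at_harvest: str  # rising | plateau | falling
    growth_duration: float | None = None  # harvest - curd appearance, days
    harvest_clamped: bool = False

    def __post_init__(self):
        if not -1e-9 <= self.rate_ratio <= 1.0 + 1e-9:
            raise ValueError("rate_ratio must lie in [0, 1]")


_ROOT_TOL = 1e-8  # days


def _bracketed_root(func, lo: float, hi: float, n_grid: int = 600) -> float:
    """Find one sign change of func on [lo, hi] and refine it by bisection."""
    ts = np.linspace(lo, hi, n_grid)
    vals = np.array([func(t) for t in ts])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        exact = np.nonzero(vals == 0)[0]
        if exact.size:
            return float(ts[exact[0]])
        raise KineticsError("no sign change found in the search window")
    i = int(idx[0])
    return float(brentq(func, ts[i], ts[i + 1], xtol=_ROOT_TOL))


def rapid_growth_window(fit: ModelFit) -> KineticsSummary:
    """Rapid-growth-period landmarks from a converged sigmoidal fit.

    The rate peak is the root of the second derivative; the window endpoints
    are the two roots of the third derivative bracketing it, found by
    bisection on the analytic derivatives.  Landmarks falling outside a
    10x-extended observation window flag a degenerate fit.
    """
    spec = fit.spec
    if not spec.sigmoid:
        raise ValueError(f"model {fit.model!r} is not a sigmoid growth model")
    if not fit.converged:
        raise KineticsError("fit did not converge; kinetics would be meaningless")
    p = fit.param_array
    params = fit.params
    if fit.model == "richards":
        center = params["tc"]
        w_char = 1.0 / params["k"]
    else:  # logistic / gompertz: rate peak at ln(b)/k
        center = math.log(max(params["b"], 1e-300)) / params["k"]
        w_char = 1.0 / params["k"]

    lo, hi = center - 5.0 * w_char, center + 5.0 * w_char
    d2 = lambda t: float(spec.deriv2(p, t))
    d3 = lambda t: float(spec.deriv3(p, t))
    t_max = _bracketed_root(d2, lo, hi)
    t1 = _bracketed_root(d3, lo, t_max - _ROOT_TOL)
    t2 = _bracketed_root(d3, t_max + _ROOT_TOL, hi)

    span = max(float(fit.days[-1] - fit.days[0]), 1.0)
    win_lo = float(fit.days[0]) - 4.5 * span
    win_hi = float(fit.days[-1]) + 4.5 * span
    if not (win_lo <= t1 and t2 <= win_hi):
        raise KineticsError(
            "rapid-growth landmarks fall outside the 10x-extended observation "
            "window; the fit is degenerate"
        )
    max_rate = float(spec.deriv1(p, t_max))
    return KineticsSummary(t_infl1=t1, t_infl2=t2, t_max_rate=t_max, max_rate=max_rate)


def curd_rate_stats(
    fit: ModelFit,
    harvest_day: float,
    tca: float | None = None,
) -> CurdKinetics:
    """Harvest-time rate statistics from a converged sine curd fit.

    ``rate(t) = (A pi / w) cos(pi (t - tc) / w)`` peaks at ``tc``; harvest
    days outside the fitted monotone half-period ``[tc - w/2, tc + w/2]``
    are clamped to it and flagged.
    """
    if fit.model != "sine":
        raise ValueError("curd rate statistics require a sine fit")
    if not fit.converged:
        raise KineticsError("sine fit did not converge")
    A, tc, w = fit.params["A"], fit.params["tc"], fit.params["w"]
    if w <= 0:
        raise ValueError("sine half-period width w must be positive")
    lo, hi = tc - w / 2.0, tc + w / 2.0
    clamped = not (lo <= harvest_day <= hi)
    h = min(max(float(harvest_day), lo), hi)
    max_rate = A * math.pi / w
    phase = math.pi * (h - tc) / w
    harvest_rate = max_rate * math.cos(phase)
    ratio = min(max(harvest_rate / max_rate, 0.0), 1.0)
    # trend = sign of d(rate)/dt at harvest: -max_rate * (pi/w) * sin(phase)
    if abs(phase) < 1e-12:
        trend = "plateau"
    elif phase < 0:
        trend = "rising"
    else:
        trend = "falling"
    duration = None if tca is None else float(harvest_day) - float(tca)
    return CurdKinetics(
        t_peak_rate=tc,
        max_rate=max_rate,
        harvest_day=float(harvest_day),
        harvest_rate=harvest_rate,
        rate_ratio=ratio,
        trend_at_harvest=trend,
        growth_duration=duration,
        harvest_clamped=clamped,
    )


def classify_curd(stats: CurdKinetics, plateau_threshold: float = 0.95) -> str:
    """Three-way kinetic harvest-status label.

    A harvest-time rate within ``plateau_threshold`` of the peak rate is the
    rate plateau (peak burst); otherwise a still-rising rate means the curd
    is pre-peak (steady climbing) and a falling one post-peak (mature and
    full).
    """
    if not 0.0 < plateau_threshold <= 1.0:
        raise ValueError("plateau_threshold must be in (0, 1]")
    if stats.rate_ratio >= plateau_threshold:
        return PEAK_BURST
    if stats.trend_at_harvest == "rising":
        return STEADY_CLIMBING
    return MATURE_FULL


def inflection_vs_tca_regression(pairs) -> dict[str, float]:
    """OLS of leaf inflection-point-2 day on observed curd appearance day.

    ``pairs`` is a sequence of ``(tca, t_infl2)``.  Returns slope, intercept
    and R² of ``t_infl2 = slope * tca + intercept``, plus the mean lead time
    ``mean(tca - t_infl2)`` — positive when the leaf-growth deceleration
    point precedes visible curd appearance.
    """
    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (tca, t_infl2) pairs")
    tca, t2 = arr[:, 0], arr[:, 1]
    res = linregress(tca, t2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue ** 2),
        "lead_time": float(np.mean(tca - t2)),
        "n": int(arr.shape[0]),
    }
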