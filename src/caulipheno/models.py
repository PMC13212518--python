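"""Growth-model zoo and nonlinear least-squares fitting.

The zoo covers the candidate functions used for cauliflower organ-growth
trajectories: three classic sigmoids (logistic, Gompertz, generalized
Richards) plus linear, power, quadratic and exponential baselines for leaf
area, and a monotone sine half-period for curd area.  Every model carries
closed-form first, second and third time derivatives so that growth-rate
peaks and rapid-growth-period endpoints can be located analytically
downstream.

Fitting is unweighted (or sigma-weighted) least squares with bounded
trust-region optimisation and seeded multi-start initialisation; goodness of
fit is reported as R², a degrees-of-freedom-corrected RMSE, MAE, and reduced
chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .series import GrowthSeries

__all__ = [
    "ModelSpec",
    "FitOptions",
    "GoodnessOfFit",
    "ModelFit",
    "MODEL_ZOO",
    "LEAF_MODELS",
    "CURD_MODELS",
    "get_model",
    "evaluate_model",
    "fit_model",
    "goodness_of_fit",
    "compare_models",
    "DomainError",
]


class DomainError(ValueError):
    """Parameter/time combination leaves the model's real domain."""


ParamVec = np.ndarray
ModelFunc = Callable[[ParamVec, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ModelSpec:
    """A named growth model with closed-form value and derivatives.

    ``value`` and the derivative functions take ``(params, t)`` with params
    ordered as in ``param_names``.  ``bounds`` and ``init`` produce
    data-driven box constraints and a starting point for fitting.
    """

    name: str
    param_names: tuple[str, ...]
    value: ModelFunc
    deriv1: ModelFunc
    deriv2: ModelFunc
    deriv3: ModelFunc
    bounds: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    init: Callable[[np.ndarray, np.ndarray], np.ndarray]
    sigmoid: bool = False

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_dict(self, p: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, [float(x) for x in p]))

    def params_array(self, p: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        if isinstance(p, Mapping):
            return np.array([p[name] for name in self.param_names], float)
        return np.asarray(p, float)


# --------------------------------------------------------------------------
# model definitions
# --------------------------------------------------------------------------

def _as_t(t):
    return np.asarray(t, dtype=float)


# linear: y = a t + b
def _linear_val(p, t):
    return p[0] * _as_t(t) + p[1]


def _linear_d1(p, t):
    return np.full_like(_as_t(t), p[0])


def _zeros(p, t):
    return np.zeros_like(_as_t(t))


def _linear_bounds(t, y):
    return (np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]))


def _linear_init(t, y):
    a, b = np.polyfit(t, y, 1)
    return np.array([a, b])


# power: y = a t^b  (requires t > 0)
def _power_val(p, t):
    t = _as_t(t)
    if np.any(t < 0):
        raise DomainError("power model requires t >= 0")
    return p[0] * np.power(t, p[1])


def _power_d1(p, t):
    t = _as_t(t)
    a, b = p
    return a * b * np.power(t, b - 1.0)


def _power_d2(p, t):
    t = _as_t(t)
    a, b = p
    return a * b * (b - 1.0) * np.power(t, b - 2.0)


def _power_d3(p, t):
    t = _as_t(t)
    a, b = p
    return a * b * (b - 1.0) * (b - 2.0) * np.power(t, b - 3.0)


def _power_bounds(t, y):
    return (np.array([1e-12, 1e-3]), np.array([np.inf, 10.0]))


def _power_init(t, y):
    mask = (t > 0) & (y > 0)
    if mask.sum() >= 2:
        b, loga = np.polyfit(np.log(t[mask]), np.log(y[mask]), 1)
        b = min(max(b, 1e-3), 10.0)
        return np.array([math.exp(loga), b])
    return np.array([max(y.max(), 1.0) / max(t.max(), 1.0), 1.0])


# quadratic: y = a t^2 + b t + c
def _quad_val(p, t):
    t = _as_t(t)
    return p[0] * t * t + p[1] * t + p[2]


def _quad_d1(p, t):
    return 2.0 * p[0] * _as_t(t) + p[1]


def _quad_d2(p, t):
    return np.full_like(_as_t(t), 2.0 * p[0])


def _quad_bounds(t, y):
    inf = np.inf
    return (np.array([-inf] * 3), np.array([inf] * 3))


def _quad_init(t, y):
    return np.asarray(np.polyfit(t, y, 2), float)


# exponential: y = a e^(b t)
def _exp_val(p, t):
    return p[0] * np.exp(p[1] * _as_t(t))


def _exp_d1(p, t):
    return p[0] * p[1] * np.exp(p[1] * _as_t(t))


def _exp_d2(p, t):
    return p[0] * p[1] ** 2 * np.exp(p[1] * _as_t(t))


def _exp_d3(p, t):
    return p[0] * p[1] ** 3 * np.exp(p[1] * _as_t(t))


def _exp_bounds(t, y):
    return (np.array([1e-12, -2.0]), np.array([np.inf, 2.0]))


def _exp_init(t, y):
    mask = y > 0
    if mask.sum() >= 2:
        b, loga = np.polyfit(t[mask], np.log(y[mask]), 1)
        b = min(max(b, -2.0), 2.0)
        return np.array([math.exp(loga), b])
    return np.array([max(y[0], 1.0), 0.05])


# logistic: y = a / (1 + b e^(-k t))
def _logi_s(p, t):
    a, b, k = p
    return b * np.exp(-k * _as_t(t))


def _logi_val(p, t):
    return p[0] / (1.0 + _logi_s(p, t))


def _logi_d1(p, t):
    a, b, k = p
    s = _logi_s(p, t)
    return a * k * s / (1.0 + s) ** 2


def _logi_d2(p, t):
    a, b, k = p
    s = _logi_s(p, t)
    return a * k * k * s * (s - 1.0) / (1.0 + s) ** 3


def _logi_d3(p, t):
    a, b, k = p
    s = _logi_s(p, t)
    return a * k ** 3 * s * (s * s - 4.0 * s + 1.0) / (1.0 + s) ** 4


def _logi_bounds(t, y):
    ymax = max(float(np.max(y)), 1e-9)
    span = max(float(t[-1] - t[0]), 1.0)
    return (
        np.array([ymax * 0.5, 1e-6, 1e-4]),
        np.array([ymax * 10.0, 1e9, 50.0 / span]),
    )


def _sigmoid_rate_k(t, y, a):
    """Log-linearise y/(a-y) on interior points to estimate (k, t_mid)."""
    frac = np.clip(y / a, 1e-6, 1 - 1e-6)
    z = np.log(frac / (1.0 - frac))
    interior = (frac > 0.02) & (frac < 0.98)
    if interior.sum() >= 2:
        k, c = np.polyfit(t[interior], z[interior], 1)
    else:
        k, c = np.polyfit(t, z, 1)
    k = max(k, 1e-4)
    return k, -c / k


def _steepest_day(t, y):
    rates = np.diff(y) / np.diff(t)
    mid = 0.5 * (t[1:] + t[:-1])
    return float(mid[int(np.argmax(rates))])


def _logi_init(t, y):
    a = 1.05 * float(np.max(y))
    k, tmid = _sigmoid_rate_k(t, y, a)
    tmid = _steepest_day(t, y) if not np.isfinite(tmid) else tmid
    b = math.exp(min(k * tmid, 500.0))
    return np.array([a, b, k])


# gompertz: y = a exp(-b e^(-k t))
def _gomp_u(p, t):
    a, b, k = p
    return b * np.exp(-k * _as_t(t))


def _gomp_val(p, t):
    return p[0] * np.exp(-_gomp_u(p, t))


def _gomp_d1(p, t):
    a, b, k = p
    u = _gomp_u(p, t)
    return a * k * u * np.exp(-u)


def _gomp_d2(p, t):
    a, b, k = p
    u = _gomp_u(p, t)
    return a * k * k * u * (u - 1.0) * np.exp(-u)


def _gomp_d3(p, t):
    a, b, k = p
    u = _gomp_u(p, t)
    return a * k ** 3 * u * (u * u - 3.0 * u + 1.0) * np.exp(-u)


def _gomp_bounds(t, y):
    ymax = max(float(np.max(y)), 1e-9)
    span = max(float(t[-1] - t[0]), 1.0)
    return (
        np.array([ymax * 0.5, 1e-6, 1e-4]),
        np.array([ymax * 10.0, 1e9, 50.0 / span]),
    )


def _gomp_init(t, y):
    a = 1.05 * float(np.max(y))
    frac = np.clip(y / a, 1e-6, 1 - 1e-6)
    z = np.log(-np.log(frac))
    negk, logb = np.polyfit(t, z, 1)
    k = max(-negk, 1e-4)
    b = math.exp(min(logb, 500.0))
    return np.array([a, b, k])


# generalized Richards: y = a [1 + (d-1) e^(-k (t - tc))]^(1/(1-d)), d > 1
def _rich_parts(p, t):
    a, k, tc, d = p
    if d <= 1.0:
        raise DomainError("richards shape d must exceed 1")
    s = (d - 1.0) * np.exp(-k * (_as_t(t) - tc))
    g = 1.0 + s
    m = 1.0 / (1.0 - d)
    return a, k, s, g, m


def _rich_val(p, t):
    a, k, s, g, m = _rich_parts(p, t)
    return a * np.power(g, m)


def _rich_d1(p, t):
    a, k, s, g, m = _rich_parts(p, t)
    return -a * m * k * s * np.power(g, m - 1.0)


def _rich_d2(p, t):
    a, k, s, g, m = _rich_parts(p, t)
    return a * m * k * k * s * np.power(g, m - 2.0) * (g + (m - 1.0) * s)


def _rich_d3(p, t):
    a, k, s, g, m = _rich_parts(p, t)
    poly = g * g + 3.0 * (m - 1.0) * s * g + (m - 1.0) * (m - 2.0) * s * s
    return -a * m * k ** 3 * s * np.power(g, m - 3.0) * poly


def _rich_bounds(t, y):
    ymax = max(float(np.max(y)), 1e-9)
    span = max(float(t[-1] - t[0]), 1.0)
    return (
        np.array([ymax * 0.5, 1e-4, float(t[0]) - 2.0 * span, 1.001]),
        np.array([ymax * 10.0, 50.0 / span, float(t[-1]) + 2.0 * span, 10.0]),
    )


def _rich_init(t, y):
    a = 1.05 * float(np.max(y))
    k, tmid = _sigmoid_rate_k(t, y, a)
    if not np.isfinite(tmid):
        tmid = _steepest_day(t, y)
    # d = 2 makes Richards coincide with the logistic, a neutral start
    return np.array([a, k, tmid, 2.0])


# sine half-period: y = y0 + A sin(pi (t - tc) / w)
def _sine_phase(p, t):
    y0, A, tc, w = p
    if w <= 0:
        raise DomainError("sine half-period width w must be positive")
    return np.pi * (_as_t(t) - tc) / w


def _sine_val(p, t):
    y0, A, tc, w = p
    return y0 + A * np.sin(_sine_phase(p, t))


def _sine_d1(p, t):
    y0, A, tc, w = p
    return (A * np.pi / w) * np.cos(_sine_phase(p, t))


def _sine_d2(p, t):
    y0, A, tc, w = p
    return -(A * (np.pi / w) ** 2) * np.sin(_sine_phase(p, t))


def _sine_d3(p, t):
    y0, A, tc, w = p
    return -(A * (np.pi / w) ** 3) * np.cos(_sine_phase(p, t))


def _sine_bounds(t, y):
    span = max(float(t[-1] - t[0]), 1.0)
    yspan = max(float(np.max(y) - np.min(y)), 1e-9)
    inf = np.inf
    return (
        np.array([-10.0 * yspan, 1e-9, float(t[0]) - 10.0 * span, span * 0.5]),
        np.array([10.0 * yspan, 1e6 * yspan, float(t[-1]) + 10.0 * span, span * 40.0]),
    )


def _sine_init(t, y):
    """Two candidate starts spanning the sine family's distinct basins.

    (a) rising quarter-wave: minimum at t_first, peak rate at t_last;
    (b) parabola mimic: a wide sine whose extremum matches the vertex and
    curvature of the least-squares quadratic, covering arcs that look
    polynomial rather than quarter-wave.
    """
    span = max(float(t[-1] - t[0]), 1.0)
    w = 2.0 * span
    tc = float(t[-1])
    A = max(float(np.max(y) - np.min(y)), 1e-9)
    y0 = float(np.min(y)) + A
    starts = [np.array([y0, A, tc, w])]

    qa, qb, qc = np.polyfit(t, y, 2)
    if abs(qa) > 1e-12:
        tv = -qb / (2.0 * qa)
        yv = qa * tv * tv + qb * tv + qc
        w2 = 4.0 * span
        A2 = 2.0 * abs(qa) * w2 * w2 / math.pi ** 2
        if qa < 0:  # concave: sine peak at the vertex
            starts.append(np.array([yv - A2, A2, tv - w2 / 2.0, w2]))
        else:  # convex: sine trough at the vertex
            starts.append(np.array([yv + A2, A2, tv + w2 / 2.0, w2]))
    return np.vstack(starts)


MODEL_ZOO: dict[str, ModelSpec] = {
    "linear": ModelSpec(
        "linear", ("a", "b"), _linear_val, _linear_d1, _zeros, _zeros,
        _linear_bounds, _linear_init,
    ),
    "power": ModelSpec(
        "power", ("a", "b"), _power_val, _power_d1, _power_d2, _power_d3,
        _power_bounds, _power_init,
    ),
    "quadratic": ModelSpec(
        "quadratic", ("a", "b", "c"), _quad_val, _quad_d1, _quad_d2, _zeros,
        _quad_bounds, _quad_init,
    ),
    "logistic": ModelSpec(
        "logistic", ("a", "b", "k"), _logi_val, _logi_d1, _logi_d2, _logi_d3,
        _logi_bounds, _logi_init, sigmoid=True,
    ),
    "gompertz": ModelSpec(
        "gompertz", ("a", "b", "k"), _gomp_val, _gomp_d1, _gomp_d2, _gomp_d3,
        _gomp_bounds, _gomp_init, sigmoid=True,
    ),
    "richards": ModelSpec(
        "richards", ("a", "k", "tc", "d"), _rich_val, _rich_d1, _rich_d2,
        _rich_d3, _rich_bounds, _rich_init, sigmoid=True,
    ),
    "sine": ModelSpec(
        "sine", ("y0", "A", "tc", "w"), _sine_val, _sine_d1, _sine_d2,
        _sine_d3, _sine_bounds, _sine_init,
    ),
    "exponential": ModelSpec(
        "exponential", ("a", "b"), _exp_val, _exp_d1, _exp_d2, _exp_d3,
        _exp_bounds, _exp_init,
    ),
}

#: candidate zoo for leaf-area trajectories
LEAF_MODELS: tuple[str, ...] = (
    "linear", "power", "quadratic", "logistic", "gompertz", "richards",
)
#: candidate zoo for curd-area trajectories
CURD_MODELS: tuple[str, ...] = ("linear", "power", "quadratic", "sine", "exponential")


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_ZOO[name]
    except KeyError:
        raise KeyError(f"unknown growth model {name!r}; known: {sorted(MODEL_ZOO)}")


def evaluate_model(
    spec: ModelSpec | str,
    params: Mapping[str, float] | Sequence[float],
    t,
    order: int = 0,
):
    """Evaluate a model (or one of its first three derivatives) at times t."""
    if isinstance(spec, str):
        spec = get_model(spec)
    p = spec.params_array(params)
    if not np.all(np.isfinite(p)):
        raise DomainError(f"non-finite parameters for model {spec.name!r}")
    func = (spec.value, spec.deriv1, spec.deriv2, spec.deriv3)[order]
    out = func(p, t)
    return out


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GoodnessOfFit:
    r2: float
    rmse: float
    mae: float
    reduced_chi_sq: float
    r2_defined: bool = True


def goodness_of_fit(
    observed,
    predicted,
    k: int,
    sigma=None,
    n_params: int | None = None,
) -> GoodnessOfFit:
    """R², df-corrected RMSE, MAE and reduced chi-square.

    Parameters
    ----------
    k
        Number of independent variables of the model; RMSE divides by
        ``n - k - 1``.
    sigma
        Per-point standard errors for reduced chi-square (default 1).
    n_params
        Number of fitted parameters ``p`` for the chi-square denominator
        ``n - p``; defaults to ``k + 1``.
    """
    y = np.asarray(observed, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    p = n_params if n_params is not None else k + 1
    if n <= p:
        raise ValueError(f"need n > n_params observations (n={n}, p={p})")
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
        r2_defined = True
    else:
        r2 = 1.0 if ss_res == 0.0 else float("nan")
        r2_defined = ss_res == 0.0
    rmse = math.sqrt(ss_res / (n - k - 1))
    mae = float(np.mean(np.abs(resid)))
    sig = np.ones(n) if sigma is None else np.asarray(sigma, float)
    chi2 = float(np.sum((resid / sig) ** 2)) / (n - p)
    return GoodnessOfFit(r2, rmse, mae, chi2, r2_defined)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Multi-start least-squares settings.

    ``n_starts`` counts the heuristic initial point plus jittered restarts;
    ``sigma`` holds per-point standard errors for weighted fitting.
    """

    n_starts: int = 8
    jitter_scale: float = 0.2
    max_iterations: int = 200
    tol: float = 1e-12
    seed: int = 0
    sigma: np.ndarray | None = None

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one model to one growth series."""

    model: str
    params: dict[str, float]
    n: int
    k: int
    days: np.ndarray
    predictions: np.ndarray
    r2: float
    rmse: float
    mae: float
    reduced_chi_sq: float
    converged: bool
    cost: float
    r2_defined: bool = True

    @property
    def spec(self) -> ModelSpec:
        return get_model(self.model)

    @property
    def param_array(self) -> np.ndarray:
        return self.spec.params_array(self.params)

    def predict(self, t, order: int = 0):
        return evaluate_model(self.spec, self.params, t, order=order)


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, GrowthSeries):
        return series.days.astype(float), series.values.astype(float)
    t, y = series
    return np.asarray(t, float), np.asarray(y, float)


def fit_model(series, spec: ModelSpec | str, options: FitOptions | None = None) -> ModelFit:
    """Fit a growth model by seeded multi-start bounded least squares.

    The best start by residual cost wins; if no start converges the fit is
    returned with ``converged=False`` (never an exception).
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    options = options or FitOptions()
    t, y = _series_arrays(series)
    if t.size <= spec.n_params:
        raise ValueError(
            f"series of length {t.size} cannot constrain {spec.n_params} parameters"
        )
    sig = np.ones_like(y) if options.sigma is None else np.asarray(options.sigma, float)
    lb, ub = spec.bounds(t, y)

    # Every zoo model is a single-variable function y(t): RMSE uses the
    # single-regressor convention k = 1 (denominator n - 2); reduced
    # chi-square divides by n - p with p the fitted parameter count.
    k = 1

    def residuals(p):
        try:
            pred = spec.value(p, t)
        except (DomainError, FloatingPointError):
            return np.full_like(y, 1e12)
        with np.errstate(all="ignore"):
            r = (y - pred) / sig
        return np.where(np.isfinite(r), r, 1e12)

    rng = np.random.default_rng(options.seed)
    # init may propose several candidate basins; jittered restarts cycle
    # through them until n_starts total starts have been tried
    eps = 1e-10
    span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)

    def _inside(x):
        return np.minimum(np.maximum(x, lb + eps * np.abs(span)),
                          ub - eps * np.abs(span))

    candidates = np.atleast_2d(spec.init(t, y))
    n_total = max(options.n_starts, len(candidates))

    best = None
    best_cost = np.inf
    for i in range(n_total):
        base = candidates[i % len(candidates)]
        if i < len(candidates):
            start = _inside(base)
        else:
            jitter = 1.0 + options.jitter_scale * rng.standard_normal(base.size)
            start = _inside(base * jitter)
        try:
            sol = least_squares(
                residuals, start, bounds=(lb, ub), method="trf",
                max_nfev=options.max_iterations * spec.n_params,
                xtol=options.tol, ftol=options.tol, gtol=options.tol,
                x_scale="jac",
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol

    if best is None:
        nan = float("nan")
        return ModelFit(spec.name, spec.params_dict(candidates[0]), t.size, k, t,
                        np.full_like(y, nan), nan, np.inf, nan, nan,
                        converged=False, cost=np.inf, r2_defined=False)
    pred = spec.value(best.x, t)
    gof = goodness_of_fit(y, pred, k=k, sigma=sig, n_params=spec.n_params)
    return ModelFit(
        model=spec.name,
        params=spec.params_dict(best.x),
        n=t.size,
        k=k,
        days=t,
        predictions=pred,
        r2=gof.r2,
        rmse=gof.rmse,
        mae=gof.mae,
        reduced_chi_sq=gof.reduced_chi_sq,
        converged=bool(best.success),
        cost=float(best.cost),
        r2_defined=gof.r2_defined,
    )


def compare_models(
    series,
    specs: Sequence[ModelSpec | str],
    options: FitOptions | None = None,
) -> list[ModelFit]:
    """Fit several candidate models and rank them.

    Ranking is by RMSE ascending with ties broken by fewer parameters;
    non-converged fits sort last.
    """
    fits = [fit_model(series, s, options) for s in specs]

    def key(f: ModelFit):
        return (not f.converged, f.rmse if np.isfinite(f.rmse) else np.inf,
                f.spec.n_params)

    return sorted(fits, key=key)
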