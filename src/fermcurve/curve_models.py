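"""Logistic and Gompertz production-curve models with AIC model selection.

Both models are the classical three-parameter re-parametrisations in terms of
biologically interpretable quantities:

* ``A``   — maximum capacity (MaxConc in mM or mg/mL, or MaxCFU),
* ``mu``  — maximum rate, the slope at the inflection point (units of value/h),
* ``lam`` — lag phase λ (h), the x-intercept of the inflection tangent.

logistic:  y(t) = A / (1 + exp(4 mu / A * (lam - t) + 2))
Gompertz:  y(t) = A * exp(-exp(mu * e / A * (lam - t) + 1))

Fitting is bounded nonlinear least squares with a tangent-rule heuristic
start and jittered restarts; competing models are compared by a Gaussian
log-likelihood AIC (both have k = 3, so any consistent AIC convention ranks
them identically).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .screen_data import SampleSeries

__all__ = [
    "MODELS",
    "CurveParams",
    "CurveFit",
    "FitError",
    "DegenerateSeriesError",
    "logistic_value",
    "gompertz_value",
    "model_value",
    "aic_score",
    "fit_curve",
    "select_model",
]

MODELS = ("logistic", "gompertz")

_N_RESTARTS = 4  # jittered restarts on top of the heuristic start


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted."""


class DegenerateSeriesError(FitError):
    """Series carries no usable signal (constant / too short)."""


@dataclass(frozen=True)
class CurveParams:
    """Capacity A, maximum rate mu, lag lam of a sigmoid production curve."""

    A: float
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not np.isfinite(self.lam):
            raise ValueError("lam must be finite")


def logistic_value(params: CurveParams, t):
    """Evaluate the logistic curve at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    z = 4.0 * params.mu / params.A * (params.lam - t) + 2.0
    with np.errstate(over="ignore"):  # exp overflow -> y == 0, the limit
        return params.A / (1.0 + np.exp(z))


def gompertz_value(params: CurveParams, t):
    """Evaluate the Gompertz curve at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    z = params.mu * math.e / params.A * (params.lam - t) + 1.0
    with np.errstate(over="ignore"):
        return params.A * np.exp(-np.exp(z))


_MODEL_FUNCS = {"logistic": logistic_value, "gompertz": gompertz_value}


def model_value(model: str, params: CurveParams, t):
    """Dispatch to :func:`logistic_value` or :func:`gompertz_value`."""
    try:
        return _MODEL_FUNCS[model](params, t)
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass
class CurveFit:
    """A fitted production curve: model id, parameters and diagnostics."""

    model: str
    params: CurveParams
    rss: float
    aic: float
    n_points: int
    converged: bool
    #: AIC of every candidate model considered by :func:`select_model`.
    aic_competitors: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if self.n_points < 4:
            raise ValueError("need at least 4 points (one more than parameters)")

    def predict(self, t):
        return model_value(self.model, self.params, t)

    def named_params(self) -> dict[str, float]:
        return {"A": self.params.A, "mu": self.params.mu, "lam": self.params.lam}


def aic_score(rss: float, n_points: int, n_params: int = 3) -> float:
    """Gaussian-likelihood AIC: ``n ln(2 pi rss / n) + n + 2 (k + 1)``.

    Lower is better.  ``rss == 0`` (a perfect fit) returns ``-inf`` with a
    warning, which correctly wins every comparison.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n_points <= n_params:
        raise ValueError("n_points must exceed n_params")
    if rss == 0:
        warnings.warn("perfect fit (rss = 0): AIC reported as -inf", stacklevel=2)
        return -math.inf
    n = n_points
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (n_params + 1)


def _heuristic_start(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Tangent-rule initial guess: A0 = max(y); mu0 = steepest forward slope;
    lam0 = intercept of the steepest tangent with the time axis."""
    a0 = float(np.max(y))
    dy = np.diff(y)
    dt = np.diff(t)
    slopes = dy / dt
    i = int(np.argmax(slopes))
    mu0 = float(slopes[i])
    if mu0 <= 0:  # non-increasing data; give the optimiser something small
        mu0 = max(a0, 1e-6) / max(float(t[-1] - t[0]), 1.0)
        lam0 = float(t[0])
    else:
        t_star = 0.5 * float(t[i] + t[i + 1])
        y_star = 0.5 * float(y[i] + y[i + 1])
        lam0 = t_star - y_star / mu0
    return a0, mu0, lam0


def fit_curve(
    series: SampleSeries,
    model: str,
    t_end: float | None = None,
    log10_values: bool = False,
) -> CurveFit:
    """Least-squares fit of one model to one series.

    The fit is performed on values normalised by their maximum (the models
    are equivariant under uniform value rescaling: fitting ``c*y`` yields
    ``(c*A, c*mu, lam)``), with a heuristic start plus 4 deterministic
    jittered restarts, keeping the lowest-RSS solution.  ``log10_values``
    fits the decadic log of the data (optional for viable counts).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if log10_values:
        y = np.log10(np.maximum(y, 1.0))
    n = len(t)
    if n < 4:
        raise DegenerateSeriesError(
            f"series {series.key}: need >= 4 points, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateSeriesError(f"series {series.key}: constant series")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise DegenerateSeriesError(f"series {series.key}: no positive values")
    if t_end is None:
        t_end = float(np.max(t))
    ys = y / ymax

    func = _MODEL_FUNCS[model]

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = CurveParams(A=theta[0], mu=theta[1], lam=theta[2])
        return func(p, t) - ys

    lb = np.array([1e-9, 1e-12, -t_end])
    ub = np.array([10.0, np.inf, t_end])
    a0, mu0, lam0 = _heuristic_start(t, ys)
    starts = [np.array([a0, mu0, np.clip(lam0, -t_end, t_end)])]
    rng = np.random.default_rng(0)  # fixed: the fit must be deterministic
    for _ in range(_N_RESTARTS):
        jitter = rng.uniform(0.5, 2.0, size=2)
        lam_j = lam0 + rng.uniform(-0.2, 0.2) * (t[-1] - t[0])
        starts.append(np.array([a0 * jitter[0], mu0 * jitter[1],
                                np.clip(lam_j, -t_end, t_end)]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, np.minimum(ub, 1e12))
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                max_nfev=5000)
        except Exception:  # numerical failure from a bad start
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError(f"series {series.key}: all {model} starts failed")
    rss_s, sol = best
    # accept an exhausted-budget solution whose gradient is effectively flat
    converged = bool(sol.status > 0
                     or np.max(np.abs(sol.grad)) < 1e-8 * max(rss_s, 1e-12))
    if not converged:
        raise FitError(
            f"series {series.key}: {model} fit did not converge "
            f"(best rss {rss_s * ymax**2:.4g})")
    A = float(sol.x[0]) * ymax
    mu = float(sol.x[1]) * ymax
    lam = float(sol.x[2])
    rss = rss_s * ymax ** 2
    flags = []
    if lam < 0:
        flags.append("negative-lag")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = aic_score(rss, n)
    return CurveFit(model=model, params=CurveParams(A, mu, lam), rss=rss,
                    aic=aic, n_points=n, converged=converged, flags=flags)


def select_model(
    series: SampleSeries,
    t_end: float | None = None,
    log10_values: bool = False,
) -> CurveFit:
    """Fit both candidate models and keep the lower-AIC one.

    Ties break toward logistic.  Both AIC scores are recorded on the
    returned fit.  If one model fails, the other is returned; if both fail,
    a composite :class:`FitError` is raised.
    """
    fits: dict[str, CurveFit] = {}
    errors: dict[str, Exception] = {}
    for model in MODELS:
        try:
            fits[model] = fit_curve(series, model, t_end=t_end,
                                    log10_values=log10_values)
        except FitError as exc:
            errors[model] = exc
    if not fits:
        if all(isinstance(e, DegenerateSeriesError) for e in errors.values()):
            raise next(iter(errors.values()))
        raise FitError(f"series {series.key}: both models failed: {errors}")
    aics = {m: f.aic for m, f in fits.items()}
    # ties toward logistic: MODELS orders logistic first, min is stable
    chosen = min(fits, key=lambda m: (aics[m], MODELS.index(m)))
    fit = fits[chosen]
    fit.aic_competitors = aics
    return fit
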