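"""Additive growth–decline model for viable-count patterns.

Total viable-count series in batch fermentations rise, peak and decline.
Rather than a bespoke multi-phase model, the pattern is summarised by two
ordinary sigmoid fits joined at the tipping point ``tx`` — the earliest time
the series attains its maximum:

* the *growth* branch fits the series with every point after ``tx`` held at
  the peak value (a plateau), yielding GroRate (mu), Lag (lam), MaxCFU (A);
* the *decline* branch holds every point before ``tx`` at the peak, mirrors
  time (t -> t_end - t) so the decline reads as a growth curve, and fits
  again, yielding DeclineRate, DeclineLag, DeclineMaxCFU.

Together with ``tx`` that is seven interpretable parameters.  The quantity
``t_end - DeclineLag`` measures how long the substrate sustains the
population; a negative DeclineLag flags a population that has not declined
to zero within the observation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curve_models import CurveFit, FitError, model_value, select_model
from .screen_data import SampleSeries, ScreenDataError

__all__ = [
    "AdditiveFit",
    "find_tipping_point",
    "plateau_after",
    "mirror_decline",
    "fit_additive",
    "evaluate_additive",
    "sustainability",
]

#: The seven reported scalar parameters of an additive fit.
ADDITIVE_PARAM_NAMES = ("MaxCFU", "GroRate", "Lag", "tx",
                        "DeclineMaxCFU", "DeclineRate", "DeclineLag")


@dataclass
class AdditiveFit:
    """Two-branch additive fit of a growth-then-decline pattern."""

    growth: CurveFit | None
    decline: CurveFit | None
    tx: float
    cfu_tx: float
    t_end: float = 205.0
    growth_error: str | None = None
    decline_error: str | None = None
    flags: list[str] = field(default_factory=list)

    def named_params(self) -> dict[str, float]:
        """The seven scalar parameters (NaN for a failed branch)."""
        g = self.growth.params if self.growth else None
        d = self.decline.params if self.decline else None
        nan = float("nan")
        return {
            "MaxCFU": g.A if g else nan,
            "GroRate": g.mu if g else nan,
            "Lag": g.lam if g else nan,
            "tx": self.tx,
            "DeclineMaxCFU": d.A if d else nan,
            "DeclineRate": d.mu if d else nan,
            "DeclineLag": d.lam if d else nan,
        }

    @property
    def model(self) -> str:
        g = self.growth.model if self.growth else "none"
        d = self.decline.model if self.decline else "none"
        return f"{g}+{d}"


def find_tipping_point(series: SampleSeries) -> tuple[float, float]:
    """Earliest time attaining the series maximum, and the value there."""
    if len(series) == 0:
        raise ScreenDataError(f"series {series.key}: empty series")
    i = int(np.argmax(series.values))  # argmax returns the first maximum
    return float(series.times[i]), float(series.values[i])


def _require_sampled(series: SampleSeries, tx: float) -> int:
    idx = np.nonzero(series.times == tx)[0]
    if len(idx) == 0:
        raise ScreenDataError(
            f"series {series.key}: tx={tx} is not a sampled time")
    return int(idx[0])


def plateau_after(series: SampleSeries, tx: float) -> SampleSeries:
    """Replace every value after ``tx`` by the value at ``tx``."""
    i = _require_sampled(series, tx)
    values = series.values.copy()
    values[i + 1:] = values[i]
    return SampleSeries(series.candidate_id, series.replicate, series.analyte,
                        series.times.copy(), values, series.unit)


def mirror_decline(series: SampleSeries, tx: float, t_end: float) -> SampleSeries:
    """Plateau before ``tx``, then mirror time so the decline reads as growth.

    Values at t < tx are replaced by the value at ``tx``; times map to
    ``t_end - t`` and the series is re-sorted to increasing time.
    """
    if t_end < float(series.times[-1]):
        raise ScreenDataError(
            f"series {series.key}: t_end={t_end} earlier than last sample")
    i = _require_sampled(series, tx)
    values = series.values.copy()
    values[:i] = values[i]
    times = t_end - series.times
    order = np.argsort(times)
    return SampleSeries(series.candidate_id, series.replicate, series.analyte,
                        times[order], values[order], series.unit)


def fit_additive(
    series: SampleSeries,
    t_end: float = 205.0,
    exclude_padding: bool = False,
) -> AdditiveFit:
    """Fit the two-branch additive model to one viable-count series.

    Each branch runs the usual logistic/Gompertz fit with AIC selection on
    its transformed series; branch failures are recorded as error flags on a
    partial result rather than raised.  ``exclude_padding`` drops the
    plateau-padded points (synthetic constants) from each branch's residuals,
    keeping the point at ``tx`` itself.
    """
    tx, cfu_tx = find_tipping_point(series)
    fit = AdditiveFit(growth=None, decline=None, tx=tx, cfu_tx=cfu_tx,
                      t_end=t_end)

    def _trim(s: SampleSeries, keep: np.ndarray) -> SampleSeries:
        return SampleSeries(s.candidate_id, s.replicate, s.analyte,
                            s.times[keep], s.values[keep], s.unit)

    grow = plateau_after(series, tx)
    if exclude_padding:
        grow = _trim(grow, grow.times <= tx)
    try:
        fit.growth = select_model(grow, t_end=t_end)
    except (FitError, ScreenDataError) as exc:
        fit.growth_error = str(exc)
        fit.flags.append("growth-not-estimable")

    decl = mirror_decline(series, tx, t_end)
    if exclude_padding:
        decl = _trim(decl, decl.times <= t_end - tx)
    try:
        fit.decline = select_model(decl, t_end=t_end)
    except (FitError, ScreenDataError) as exc:
        fit.decline_error = str(exc)
        fit.flags.append("decline-not-estimable")

    if fit.decline is not None and fit.decline.params.lam < 0:
        fit.flags.append("not fully declined within observation window")
    return fit


def evaluate_additive(fit: AdditiveFit, t) -> np.ndarray:
    """Evaluate the piecewise additive model at time(s) ``t``.

    t < tx uses the growth branch at t; t > tx the decline branch at
    ``t_end - t``; exactly at tx the mean of the two branch values (the model
    need not be continuous at the tipping point).
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if fit.growth is None or fit.decline is None:
        raise FitError("both branches must be estimable to evaluate")
    g = model_value(fit.growth.model, fit.growth.params, t)
    d = model_value(fit.decline.model, fit.decline.params, fit.t_end - t)
    out = np.where(t < fit.tx, g, d)
    out = np.where(t == fit.tx, 0.5 * (g + d), out)
    return float(out[0]) if scalar else out


def sustainability(fit: AdditiveFit) -> float:
    """Sustained-growth time ``t_end - DeclineLag`` (hours).

    A negative DeclineLag gives a value beyond ``t_end``, flagging a
    population that had not yet levelled off to zero within the window.
    """
    if fit.decline is None:
        raise FitError("decline branch not estimable: " +
                       (fit.decline_error or "missing"))
    lam = fit.decline.params.lam
    value = fit.t_end - lam
    if lam < 0:
        warnings.warn(
            "negative DeclineLag: population not fully declined within "
            f"the {fit.t_end} h window (sustainability {value:.1f} h)",
            stacklevel=2)
        if "not fully declined within observation window" not in fit.flags:
            fit.flags.append("not fully declined within observation window")
    return value
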