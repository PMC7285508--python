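"""Composite SCFAs/NH3 eubiosis indicator.

Total short-chain fatty acids (acetate + propionate + butyrate, mM) capture
saccharolytic potential — more is better; dissolved ammonia (mg/mL) is
un-assimilated nitrogen after proteolysis — less is better.  Because the two
carry different units, each is min–max scaled into (1, 10) before the
quotient is taken; scaling into (1, 10) rather than (0, 1) keeps the
denominator away from zero so the ratio is always finite and bounded in
[0.1, 10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_data import ScreenDataset, ScreenDataError

__all__ = [
    "AssayReading",
    "ScalingSpec",
    "total_scfa",
    "ammonia_concentration",
    "minmax_scale",
    "ratio_indicator",
    "build_indicator_table",
]

SCFA_COMPONENTS = ("acetate", "propionate", "butyrate")


@dataclass(frozen=True)
class AssayReading:
    """Microplate absorbance pair at 340 nm: before (a1) / after (a2) the
    glutamate-dehydrogenase step.  NADPH consumption means a1 >= a2; a
    violation is flagged with a warning, not fatal."""

    a1: float
    a2: float

    @property
    def delta(self) -> float:
        if self.a1 < self.a2:
            warnings.warn(
                f"A1 ({self.a1}) < A2 ({self.a2}): NADPH gain is unexpected",
                stacklevel=3)
        return self.a1 - self.a2


@dataclass(frozen=True)
class ScalingSpec:
    """Min–max scaling ceilings and grouping domain."""

    a: float = 1.0
    b: float = 10.0
    domain: str = "per_timepoint"  # or "global"

    def __post_init__(self) -> None:
        if not self.b > self.a:
            raise ValueError(f"need b > a, got a={self.a}, b={self.b}")
        if self.domain not in ("per_timepoint", "global"):
            raise ValueError(f"unknown scaling domain {self.domain!r}")


def total_scfa(acetate, propionate, butyrate):
    """Total SCFA (mM) as the sum of acetate, propionate and butyrate.

    Valerate and caproate are deliberately excluded (negligible in infant
    fecal fermentations).
    """
    parts = [np.asarray(x, dtype=float) for x in (acetate, propionate, butyrate)]
    for name, x in zip(SCFA_COMPONENTS, parts):
        if np.any(x < 0):
            raise ValueError(f"negative {name} concentration")
    total = parts[0] + parts[1] + parts[2]
    return float(total) if np.ndim(total) == 0 else total


def ammonia_concentration(
    sample: AssayReading,
    standard: AssayReading,
    standard_conc: float = 0.04,
    dilution_factor: float = 1.0,
) -> float:
    """Dissolved NH3 (mg/mL) from the enzymatic assay.

    ``(sample dA / standard dA) * standard_conc``, where dA = A1 - A2 is the
    NADPH consumption.  ``dilution_factor`` multiplies the result for
    protocols where the standard does not absorb the sample dilution
    (default 1: the formula as stated).
    """
    std_delta = standard.delta
    if std_delta <= 0:
        raise ValueError(
            f"assay failure: standard dA = {std_delta} (must be positive)")
    return sample.delta / std_delta * standard_conc * dilution_factor


def minmax_scale(values, spec: ScalingSpec = ScalingSpec()) -> np.ndarray:
    """Affine rescale of ``values`` so min -> a and max -> b (default 1, 10)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmax == xmin:
        raise ValueError("undefined scale: all values equal (X_max == X_min)")
    return spec.a + (x - xmin) * (spec.b - spec.a) / (xmax - xmin)


def ratio_indicator(scaled_scfa, scaled_nh3, spec: ScalingSpec = ScalingSpec()):
    """Elementwise scaled-SCFA / scaled-NH3 quotient, bounded in [a/b, b/a]."""
    s = np.asarray(scaled_scfa, dtype=float)
    n = np.asarray(scaled_nh3, dtype=float)
    for name, x in (("scaled_scfa", s), ("scaled_nh3", n)):
        if np.any((x < spec.a) | (x > spec.b)):
            raise ValueError(
                f"{name} outside the scaled range [{spec.a}, {spec.b}]")
    out = s / n
    return float(out) if np.ndim(out) == 0 else out


def _replicate_mean(dataset: ScreenDataset, candidate: str, analyte: str,
                    time: float) -> float:
    vals = []
    for s in dataset.replicates(candidate, analyte):
        hit = np.nonzero(s.times == time)[0]
        if len(hit):
            vals.append(s.values[int(hit[0])])
    if not vals:
        raise ScreenDataError(
            f"missing {analyte} for candidate {candidate!r} at t={time} h")
    return float(np.mean(vals))


def _cell_value(dataset: ScreenDataset, candidate: str, analyte: str,
                time: float) -> float:
    """Replicate-mean value; total SCFA falls back to summing components."""
    try:
        return _replicate_mean(dataset, candidate, analyte, time)
    except ScreenDataError:
        if analyte != "total_scfa":
            raise
        return float(sum(_replicate_mean(dataset, candidate, comp, time)
                         for comp in SCFA_COMPONENTS))


def build_indicator_table(
    dataset: ScreenDataset,
    spec: ScalingSpec = ScalingSpec(),
    times=None,
    candidates=None,
) -> pd.DataFrame:
    """Per candidate x time indicator table.

    Columns: candidate, time_h, total_scfa, nh3, scaled_scfa, scaled_nh3,
    ratio.  Inputs are replicate means; scaling is applied per time-point
    across candidates (so candidates are comparable at each sampling time) or
    globally, per ``spec.domain``.
    """
    if candidates is None:
        candidates = dataset.candidates()
    if times is None:
        times = sorted({float(t) for s in dataset.series for t in s.times
                        if s.analyte in ("total_scfa", "nh3")
                        or s.analyte in SCFA_COMPONENTS})
    times = [float(t) for t in times]
    if len(candidates) < 2:
        raise ScreenDataError("need >= 2 candidates to define the scaling")

    rows = []
    for t in times:
        for cand in candidates:
            rows.append({
                "candidate": cand,
                "time_h": t,
                "total_scfa": _cell_value(dataset, cand, "total_scfa", t),
                "nh3": _cell_value(dataset, cand, "nh3", t),
            })
    table = pd.DataFrame(rows)

    def _scale(group: pd.DataFrame) -> pd.DataFrame:
        group = group.copy()
        group["scaled_scfa"] = minmax_scale(group["total_scfa"], spec)
        group["scaled_nh3"] = minmax_scale(group["nh3"], spec)
        return group

    if spec.domain == "per_timepoint":
        parts = []
        for t, group in table.groupby("time_h", sort=True):
            try:
                parts.append(_scale(group))
            except ValueError as exc:
                raise ScreenDataError(f"at t={t} h: {exc}") from exc
        table = pd.concat(parts, ignore_index=True)
    else:
        table = _scale(table)
    table["ratio"] = ratio_indicator(table["scaled_scfa"], table["scaled_nh3"],
                                     spec)
    return table
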