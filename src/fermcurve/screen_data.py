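"""Domain types and IO for parallel fermentation screens.

A screen measures several analytes (viable counts, individual and total
short-chain fatty acids, dissolved ammonia) for a panel of carbohydrate
candidates fermented in replicate over ~200 h.  The canonical interchange
format is a long (tidy) CSV with columns
``candidate,replicate,time_h,analyte,value,unit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "SampleSeries",
    "ScreenDataset",
    "ScreenDesign",
    "ScreenDataError",
    "default_schedule",
    "count_raw_datapoints",
    "count_parameter_datapoints",
    "read_screen",
    "write_screen",
    "write_parameter_table",
]

#: Recognised analyte labels.
ANALYTES = ("cfu", "acetate", "propionate", "butyrate", "total_scfa", "nh3", "ratio")

#: The 19-point sampling schedule of the reference screen design (hours):
#: four points on day 1, three on days 2-4, two on day 5, one on days 6-9.
_SCHEDULE = (0, 4, 10, 22, 24, 30, 36, 48, 55, 61, 73, 79, 85, 97, 109,
             130, 153, 178, 205)

REQUIRED_COLUMNS = ("candidate", "replicate", "time_h", "analyte", "value", "unit")


class ScreenDataError(ValueError):
    """Raised for malformed or inconsistent screen data."""


def default_schedule() -> list[float]:
    """Return the default 19-point sampling schedule in hours (0–205)."""
    return [float(t) for t in _SCHEDULE]


@dataclass
class SampleSeries:
    """One candidate x replicate x analyte time series.

    times are hours (strictly increasing, >= 0); values are non-negative
    unless ``allow_negative`` was requested at read time (baseline-subtracted
    inputs).
    """

    candidate_id: str
    replicate: int
    analyte: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ScreenDataError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ScreenDataError(
                f"series {self.key}: {len(self.times)} times vs "
                f"{len(self.values)} values"
            )
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ScreenDataError(f"series {self.key}: times not strictly increasing")
        if len(self.times) and self.times[0] < 0:
            raise ScreenDataError(f"series {self.key}: negative time")
        if not np.all(np.isfinite(self.values)):
            raise ScreenDataError(f"series {self.key}: non-finite value")
        if int(self.replicate) < 1:
            raise ScreenDataError(f"series {self.key}: replicate must be >= 1")
        self.replicate = int(self.replicate)
        if self.analyte not in ANALYTES:
            raise ScreenDataError(
                f"series {self.key}: unknown analyte {self.analyte!r}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.candidate_id, self.replicate, self.analyte)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ScreenDataset:
    """A collection of :class:`SampleSeries` sharing a sampling schedule."""

    series: list[SampleSeries]
    t_end: float = 205.0
    schedule: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.schedule is None:
            times: set[float] = set()
            for s in self.series:
                times.update(s.times.tolist())
            self.schedule = sorted(times) if times else default_schedule()
        self.schedule = [float(t) for t in self.schedule]
        sched = set(self.schedule)
        for s in self.series:
            extra = set(s.times.tolist()) - sched
            if extra:
                raise ScreenDataError(
                    f"series {s.key}: times {sorted(extra)} not in schedule"
                )
        if self.schedule and self.t_end < max(self.schedule):
            raise ScreenDataError(
                f"t_end={self.t_end} earlier than last scheduled point "
                f"{max(self.schedule)}"
            )

    def get(self, candidate: str, replicate: int, analyte: str) -> SampleSeries:
        for s in self.series:
            if s.key == (candidate, replicate, analyte):
                return s
        raise KeyError((candidate, replicate, analyte))

    def candidates(self) -> list[str]:
        out: list[str] = []
        for s in self.series:
            if s.candidate_id not in out:
                out.append(s.candidate_id)
        return out

    def analytes(self) -> list[str]:
        return sorted({s.analyte for s in self.series}, key=ANALYTES.index)

    def replicates(self, candidate: str, analyte: str) -> list[SampleSeries]:
        out = [s for s in self.series
               if s.candidate_id == candidate and s.analyte == analyte]
        return sorted(out, key=lambda s: s.replicate)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for t, v in zip(s.times, s.values):
                rows.append((s.candidate_id, s.replicate, t, s.analyte, v, s.unit))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@dataclass(frozen=True)
class ScreenDesign:
    """Size of a screen: candidates x time-points x replicates x patterns."""

    n_candidates: int
    n_timepoints: int
    n_replicates: int
    n_patterns: int

    def __post_init__(self) -> None:
        for name in ("n_candidates", "n_timepoints", "n_replicates", "n_patterns"):
            if int(getattr(self, name)) < 1:
                raise ScreenDataError(f"invalid design: {name} must be positive")


def count_raw_datapoints(design: ScreenDesign) -> int:
    """Raw data volume of a screen: the product of the four design sizes.

    The reference 13-candidate design (19 time-points, triplicate, 6 measured
    patterns) yields 13 x 19 x 3 x 6 = 4446 points.
    """
    return (design.n_candidates * design.n_timepoints
            * design.n_replicates * design.n_patterns)


def count_parameter_datapoints(
    n_candidates: int,
    n_replicates: int,
    n_metabolite_curves: int = 5,
    params_per_metabolite: int = 3,
    probiotic_params: int = 7,
) -> int:
    """Data volume after parametric reduction.

    Each metabolite curve is summarised by its parameters plus the fitted
    model identifier; the viable-count pattern by the seven additive-model
    parameters plus its model identifiers.  The reference design reduces to
    13 x 3 x ((5 x 4) + 8) = 1092 points, an almost 4-fold reduction.
    """
    args = (n_candidates, n_replicates, n_metabolite_curves,
            params_per_metabolite, probiotic_params)
    if any(int(a) < 1 for a in args):
        raise ScreenDataError("all counting inputs must be positive")
    per_set = (n_metabolite_curves * (params_per_metabolite + 1)
               + (probiotic_params + 1))
    return n_candidates * n_replicates * per_set


def read_screen(
    path,
    format: str = "long_csv",
    allow_negative: bool = False,
    t_end: float | None = None,
) -> ScreenDataset:
    """Read a long-format screen CSV into a validated :class:`ScreenDataset`.

    Duplicate (candidate, replicate, analyte, time) rows and negative values
    are rejected; ``allow_negative`` downgrades the latter to a warning for
    baseline-subtracted inputs.
    """
    if format != "long_csv":
        raise ScreenDataError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ScreenDataError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenDataError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ScreenDataError(f"{path}: no data rows")
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ScreenDataError(
                f"{path}: non-numeric {col} at row {bad[0] + 2} "
                f"(value {df.loc[bad[0], col]!r})"
            )
        df[col] = coerced
    if df[["time_h", "value"]].isna().any().any():
        row = int(df.index[df[["time_h", "value"]].isna().any(axis=1)][0])
        raise ScreenDataError(f"{path}: missing time/value at row {row + 2}")
    keys = ["candidate", "replicate", "analyte", "time_h"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(df.index[dup][0])
        raise ScreenDataError(
            f"{path}: duplicate key at row {row + 2}: "
            f"{tuple(df.loc[row, keys])}"
        )
    neg = df["value"] < 0
    if neg.any():
        row = int(df.index[neg][0])
        msg = (f"{path}: negative value at row {row + 2} "
               f"({df.loc[row, 'value']})")
        if allow_negative:
            warnings.warn(msg, stacklevel=2)
        else:
            raise ScreenDataError(msg + "; pass allow_negative for "
                                  "baseline-subtracted inputs")

    series = []
    for (cand, rep, analyte), grp in df.groupby(
            ["candidate", "replicate", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        unit = str(grp["unit"].iloc[0])
        series.append(SampleSeries(str(cand), int(rep), str(analyte),
                                   grp["time_h"].to_numpy(),
                                   grp["value"].to_numpy(), unit))
    if t_end is None:
        t_end = max(205.0, float(df["time_h"].max()))
    return ScreenDataset(series=series, t_end=t_end)


def write_screen(dataset: ScreenDataset, path) -> None:
    """Write a dataset back to the long CSV format (round-trip safe)."""
    dataset.to_frame().to_csv(path, index=False)


def write_parameter_table(fits: Mapping, path) -> pd.DataFrame:
    """Write a parameter summary CSV: one row per candidate x analyte.

    ``fits`` maps ``(candidate, analyte)`` to a list of per-replicate fit
    objects (anything exposing ``.model`` and ``.named_params()``; see
    :mod:`fermcurve.curve_models`).  Parameters are summarised as replicate
    mean and sample standard deviation, the convention used throughout the
    package, alongside the modal fitted-model name.
    """
    if not fits:
        raise ScreenDataError("no fits to write")
    rows = []
    for (candidate, analyte), replicate_fits in fits.items():
        replicate_fits = list(replicate_fits)
        if not replicate_fits:
            raise ScreenDataError(f"({candidate}, {analyte}): empty fit list")
        if len(replicate_fits) == 1:
            warnings.warn(
                f"({candidate}, {analyte}): single replicate, sd reported as 0",
                stacklevel=2,
            )
        models = [f.model for f in replicate_fits]
        row: dict = {
            "candidate": candidate,
            "analyte": analyte,
            "model": max(set(models), key=models.count),
            "n_replicates": len(replicate_fits),
        }
        names = replicate_fits[0].named_params().keys()
        for name in names:
            vals = np.array([f.named_params()[name] for f in replicate_fits])
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False, float_format="%.6g")
    return table
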