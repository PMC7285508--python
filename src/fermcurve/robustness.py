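"""Robustness battery for comparing candidate indicators across two times.

An indicator is "robust" if the per-candidate profile it produces at an
early time-point (e.g. 24 h) resembles the profile at a later one (48 h),
so that either time alone supports a rough candidate ranking.  The battery
quantifies that resemblance ten ways per indicator:

* dispersion of the per-candidate change, sd(|slope|)/mean(|slope|) — lower
  is better;
* paired t-test and Wilcoxon signed-rank p-values on the two profiles —
  higher means more distributional overlap;
* Pearson r and Spearman rho with their p-values — stronger correlation
  (and smaller correlation p) is better;
* Euclidean / Manhattan / cosine similarities of the z-scored profiles,
  with distance d mapped to similarity 1/(1+d) — higher is better.

With sample-sd z-scoring the Euclidean distance obeys d^2 = 2(n-1)(1-r) and
the cosine similarity equals Pearson r exactly; the battery asserts neither,
but the identities make the Euclidean and cosine rows reconstructable from
the Pearson row alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedProfiles",
    "PairedTestResult",
    "RobustnessReport",
    "slope_dispersion",
    "paired_tests",
    "correlations",
    "zscore",
    "similarity",
    "robustness_report",
]

STATISTICS = ("dispersion", "p_wilcoxon", "p_ttest", "spearman_rho",
              "spearman_p", "pearson_r", "pearson_p", "sim_euclidean",
              "sim_manhattan", "sim_cosine")

#: direction in which each statistic improves
_BETTER_HIGH = {"dispersion": False, "p_wilcoxon": True, "p_ttest": True,
                "spearman_rho": True, "spearman_p": False, "pearson_r": True,
                "pearson_p": False, "sim_euclidean": True,
                "sim_manhattan": True, "sim_cosine": True}


@dataclass
class PairedProfiles:
    """Per-candidate indicator values at two time-points, dt hours apart."""

    labels: list[str]
    v_early: np.ndarray
    v_late: np.ndarray
    dt: float = 24.0

    def __post_init__(self) -> None:
        self.v_early = np.asarray(self.v_early, dtype=float)
        self.v_late = np.asarray(self.v_late, dtype=float)
        self.labels = list(self.labels)
        if not (len(self.labels) == len(self.v_early) == len(self.v_late)):
            raise ValueError("labels, v_early and v_late must align")
        if len(self.labels) < 3:
            raise ValueError("need at least 3 candidates")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PairedTestResult:
    p_ttest: float
    p_wilcoxon: float
    flag: str | None = None

    def __iter__(self):
        return iter((self.p_ttest, self.p_wilcoxon))


def slope_dispersion(p: PairedProfiles) -> float:
    """Coefficient of variation of the absolute per-candidate slopes.

    slope_i = (late_i - early_i)/dt; returns sd(|slope|)/mean(|slope|) with
    sample sd.  Invariant to dt and to common positive rescaling.
    """
    slopes = np.abs((p.v_late - p.v_early) / p.dt)
    mean = slopes.mean()
    if mean == 0:
        raise ValueError("mean |slope| is zero: dispersion undefined")
    return float(slopes.std(ddof=1) / mean)


def paired_tests(p: PairedProfiles) -> PairedTestResult:
    """Two-sided paired t-test and Wilcoxon signed-rank p-values.

    The signed-rank test is exact for n <= 25 with no zero or tied
    differences, normal-approximated otherwise.  Degenerate cases: all
    differences zero -> (1, 1) flagged; zero-variance nonzero differences ->
    (0, exact minimum) flagged as a degenerate large effect.
    """
    diff = p.v_late - p.v_early
    if np.all(diff == 0):
        return PairedTestResult(1.0, 1.0, flag="degenerate-no-change")
    flag = None
    if np.ptp(diff) == 0:  # identical nonzero shifts: t statistic diverges
        flag = "degenerate-large-effect"
        p_t = 0.0
    else:
        p_t = float(stats.ttest_rel(p.v_late, p.v_early).pvalue)
    nz = diff[diff != 0]
    ties = len(np.unique(np.abs(nz))) < len(nz)
    zeros = len(nz) < len(diff)
    method = "exact" if (p.n <= 25 and not ties and not zeros) else "approx"
    p_w = float(stats.wilcoxon(p.v_late, p.v_early, method=method,
                               alternative="two-sided").pvalue)
    return PairedTestResult(p_t, p_w, flag=flag)


def correlations(p: PairedProfiles) -> tuple[float, float, float, float]:
    """(pearson_r, pearson_p, spearman_rho, spearman_p), two-sided.

    Pearson p comes from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df; Spearman is
    Pearson on ranks with the same t-approximation for its p-value.
    """
    for name, v in (("v_early", p.v_early), ("v_late", p.v_late)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} has zero variance")
    r, r_p = stats.pearsonr(p.v_early, p.v_late)
    rho, rho_p = _spearman_t(p.v_early, p.v_late)
    return float(r), float(r_p), float(rho), float(rho_p)


def _spearman_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_exact(x, y) -> tuple[float, float]:
    """Exact-permutation Spearman p (feasible for n <= 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    from itertools import permutations
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    count = total = 0
    for perm in permutations(ry):
        r = float(stats.pearsonr(rx, np.array(perm)).statistic)
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def zscore(v) -> np.ndarray:
    """Standardise to mean 0 and *sample* sd 1 (n-1 denominator)."""
    x = np.asarray(v, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-score undefined")
    return (x - x.mean()) / sd


def similarity(p: PairedProfiles) -> tuple[float, float, float]:
    """(Euclidean, Manhattan, cosine) similarity of the z-scored profiles.

    Distances map to similarity by 1/(1+d); the cosine of two z-scored
    vectors is reported raw and equals their Pearson correlation (it can be
    negative, which is flagged since similarities are nominally in [0, 1]).
    """
    ze = zscore(p.v_early)
    zl = zscore(p.v_late)
    d_eu = float(np.linalg.norm(ze - zl))
    d_ma = float(np.sum(np.abs(ze - zl)))
    cos = float(ze @ zl / (np.linalg.norm(ze) * np.linalg.norm(zl)))
    if cos < 0:
        warnings.warn(f"cosine similarity {cos:.4f} is negative "
                      "(outside the nominal [0, 1] range)", stacklevel=2)
    return 1.0 / (1.0 + d_eu), 1.0 / (1.0 + d_ma), cos


@dataclass
class RobustnessReport:
    """Battery statistics per indicator plus best-performer flags."""

    stats: pd.DataFrame
    best: pd.DataFrame
    flags: dict[str, str | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.stats.copy()
        out["best"] = [
            ",".join(c for c in STATISTICS if self.best.loc[ind, c])
            for ind in out.index
        ]
        return out


def robustness_report(tables: dict[str, PairedProfiles],
                      rtol: float = 1e-9) -> RobustnessReport:
    """Run the full battery on >= 2 indicators over the same candidates.

    Per statistic, the best performer(s) are flagged (lower dispersion and
    correlation p; higher everything else); ties within relative tolerance
    ``rtol`` are flagged jointly.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 indicators to compare")
    labels = None
    for name, prof in tables.items():
        if labels is None:
            labels = prof.labels
        elif prof.labels != labels:
            raise ValueError(
                f"indicator {name!r}: candidate labels do not match")
    rows = {}
    flags = {}
    for name, prof in tables.items():
        p_t, p_w = (res := paired_tests(prof))
        r, r_p, rho, rho_p = correlations(prof)
        sim_eu, sim_ma, sim_cos = similarity(prof)
        rows[name] = {
            "dispersion": slope_dispersion(prof),
            "p_wilcoxon": p_w, "p_ttest": p_t,
            "spearman_rho": rho, "spearman_p": rho_p,
            "pearson_r": r, "pearson_p": r_p,
            "sim_euclidean": sim_eu, "sim_manhattan": sim_ma,
            "sim_cosine": sim_cos,
        }
        flags[name] = res.flag
    stats_df = pd.DataFrame.from_dict(rows, orient="index")[list(STATISTICS)]
    best = pd.DataFrame(False, index=stats_df.index, columns=stats_df.columns)
    for col in STATISTICS:
        vals = stats_df[col]
        target = vals.max() if _BETTER_HIGH[col] else vals.min()
        tol = rtol * max(abs(target), 1e-300)
        best[col] = (vals - target).abs() <= tol
    return RobustnessReport(stats=stats_df, best=best, flags=flags)
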