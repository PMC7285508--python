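"""Candidate x parameter matrix assembly and exploratory outputs.

The fitted parameters all carry biological meaning (lag, maximum rate,
capacity), so they can be compared directly across candidates: as a
column-standardised clustered heatmap, as a pairwise Pearson correlation
matrix with significance stars, or as a PCA biplot.  Optional structural
covariates (molecular-weight peak count, first-peak MW, solubility code,
%N impurity) join on candidate id for structure–parameter correlation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .additive_growth import AdditiveFit
from .curve_models import CurveFit

__all__ = [
    "assemble_matrix",
    "correlation_matrix",
    "pca_biplot_data",
    "heatmap_data",
]

_METAB_PARAM_NAMES = {"A": "MaxConc", "mu": "ProRate", "lam": "Lag"}


def assemble_matrix(
    fits: Mapping[str, Mapping[str, Sequence[CurveFit]]],
    additive: Mapping[str, Sequence[AdditiveFit]] | None = None,
    covariates: pd.DataFrame | None = None,
    sustainability: bool = False,
    t_end: float = 205.0,
) -> pd.DataFrame:
    """One row per candidate, one column per replicate-mean parameter.

    ``fits`` maps candidate -> analyte -> per-replicate metabolite fits,
    producing columns like ``acetate_ProRate``; ``additive`` adds the seven
    viable-count parameters.  ``sustainability`` replaces DeclineLag by
    ``t_end - DeclineLag`` for display.  ``covariates`` (indexed or keyed by
    candidate) are joined preserving row order.
    """
    candidates = list(fits.keys())
    if not candidates:
        raise ValueError("no candidates")
    analytes = list(fits[candidates[0]].keys())
    rows = []
    for cand in candidates:
        if list(fits[cand].keys()) != analytes:
            raise ValueError(
                f"candidate {cand!r}: analyte set differs from "
                f"{candidates[0]!r} (ragged fit sets)")
        row: dict[str, float] = {}
        for analyte in analytes:
            reps = list(fits[cand][analyte])
            if not reps:
                raise ValueError(f"candidate {cand!r}: no fits for {analyte}")
            for raw, pretty in _METAB_PARAM_NAMES.items():
                row[f"{analyte}_{pretty}"] = float(
                    np.mean([f.named_params()[raw] for f in reps]))
        if additive is not None:
            reps = list(additive[cand])
            names = reps[0].named_params().keys()
            for name in names:
                vals = [f.named_params()[name] for f in reps]
                row[name] = float(np.mean(vals))
            if sustainability:
                row["sustainability"] = t_end - row.pop("DeclineLag")
        rows.append(row)
    matrix = pd.DataFrame(rows, index=pd.Index(candidates, name="candidate"))
    if covariates is not None:
        cov = covariates.copy()
        if "candidate" in cov.columns:
            cov = cov.set_index("candidate")
        matrix = matrix.join(cov, how="left")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate column names after covariate join")
    return matrix


def correlation_matrix(
    m: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r, two-sided p and significance stars.

    Stars: * p < 0.05, ** p < 0.01, *** p < 0.001.  Zero-variance columns
    yield NaN entries (flagged undefined) rather than an error.
    """
    if len(m) < 3:
        raise ValueError("need at least 3 candidates")
    cols = list(m.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    values = m.to_numpy(dtype=float)
    degenerate = np.ptp(values, axis=0) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate[i] or degenerate[j]:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(values[:, i], values[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    for i in range(k):
        if degenerate[i]:
            r[i, i] = np.nan
            p[i, i] = np.nan

    def _star(pv: float) -> str:
        if not np.isfinite(pv):
            return ""
        if pv < 0.001:
            return "***"
        if pv < 0.01:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    stars = np.vectorize(_star)(p)
    np.fill_diagonal(stars, "")
    idx = pd.Index(cols)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(stars, index=idx, columns=idx))


def _standardise(m: pd.DataFrame) -> np.ndarray:
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(m.columns, sd) if s == 0]
        raise ValueError(f"zero-variance column(s): {bad}")
    return (x - x.mean(axis=0)) / sd


def pca_biplot_data(
    m: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA: candidate scores, parameter loadings,
    explained-variance fractions (summing to 1).

    Columns are centred and unit-scaled (parameters mix units: h, mM/h,
    CFU), then decomposed by SVD.  Loadings are the right singular vectors,
    not scaled by the singular values.
    """
    if len(m) < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 rows and >= 2 columns")
    z = _standardise(m)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return (pd.DataFrame(scores, index=m.index, columns=pcs),
            pd.DataFrame(vt.T, index=m.columns, columns=pcs),
            explained)


def heatmap_data(
    m: pd.DataFrame,
    scale: str = "column_z",
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[pd.DataFrame, list, list]:
    """Column z-scored matrix plus hierarchical row/column leaf orders.

    Agglomerative clustering (Euclidean distance, complete linkage by
    default) is deterministic given the inputs; identical rows land in the
    same first-merged cluster and hence adjacent leaves.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    if scale == "column_z":
        z = _standardise(m)
    elif scale == "none":
        z = m.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    scaled = pd.DataFrame(z, index=m.index, columns=m.columns)
    row_order = hierarchy.leaves_list(
        hierarchy.linkage(pdist(z, metric=metric), method=method))
    col_order = hierarchy.leaves_list(
        hierarchy.linkage(pdist(z.T, metric=metric), method=method))
    return (scaled,
            [m.index[i] for i in row_order],
            [m.columns[i] for i in col_order])
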