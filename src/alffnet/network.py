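"""ROI functional-connectivity networks, node strength, and behaviour.

The clusters surviving the imaging-space correction serve as the nodes of
an undirected weighted network (31 nodes -> 465 edges in the reference
analysis).  Edges are Fisher-z-transformed Pearson correlations between
ROI-mean BOLD time series; the strength of node i is the sum of its
incident edge weights S_i = sum_{j != i} w_ij.  Edge weights keep their
sign; correlation thresholds are applied to |r|.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_roi_table",
    "roi_sphere_mask",
    "extract_roi_series",
    "build_connectivity",
    "count_edges",
    "threshold_network",
    "node_strength",
    "compare_edges",
    "behavior_correlation",
    "hemispheric_strength_summary",
]

_ROI_COLUMNS = [
    "snp_id",
    "gene",
    "alleles",
    "cluster_size_mm3",
    "x",
    "y",
    "z",
    "peak_f",
    "label",
    "abbrev",
    "hemisphere",
    "pass_S",
    "pass_SG",
]

#: Clip |r| below 1 before atanh so edge weights stay finite.
R_CLIP = 1.0 - 1e-7


def load_roi_table(path=None) -> pd.DataFrame:
    """Load an ROI table (default: the packaged 31-ROI table of
    interaction-cluster peaks, one row per significant cluster).

    Malformed rows are rejected with their line number.
    """
    if path is None:
        path = resources.files("alffnet.data") / "interaction_rois.tsv"
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("ROI table is empty")
    missing = [c for c in _ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in ("cluster_size_mm3", "x", "y", "z", "peak_f"):
            if not np.isfinite(pd.to_numeric(row[col], errors="coerce")):
                raise ValueError(f"ROI table line {line}: non-numeric {col!r}")
        if row["hemisphere"] not in ("L", "R", "B", "V"):
            raise ValueError(f"ROI table line {line}: bad hemisphere tag")
    df["pass_S"] = df["pass_S"].astype(bool)
    df["pass_SG"] = df["pass_SG"].astype(bool)
    return df


def roi_sphere_mask(
    center_mm: Sequence[float],
    radius_mm: float,
    affine: np.ndarray,
    shape: Sequence[int],
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of voxels within radius_mm of a millimetre coordinate."""
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape).reshape(3, -1)
    mm = (affine[:3, :3] @ idx + affine[:3, 3:4]).T
    dist2 = ((mm - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    mask = (dist2 <= radius_mm**2).reshape(shape)
    if brain_mask is not None:
        mask &= np.asarray(brain_mask, dtype=bool)
    return mask


def extract_roi_series(data4d: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean over ROI voxels at each time point."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    return np.asarray(data4d)[roi_mask].mean(axis=0)


def build_connectivity(roi_series: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from (T, n) ROI time series.

    Pearson r per pair, clipped to +/-(1 - 1e-7), then z = atanh(r);
    zero-variance series contribute zero-weight edges with a warning.
    The diagonal is set to 0 and is excluded from all statistics.
    """
    series = np.asarray(roi_series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a (T, n) array of ROI series")
    t, n = series.shape
    if t < 3 or n < 2:
        raise ValueError("need >=3 time points and >=2 ROIs")
    sd = series.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI series; their edges are 0",
            stacklevel=2,
        )
        series = series.copy()
        series[:, degenerate] = np.random.default_rng(0).standard_normal(t)[:, None]
    r = np.corrcoef(series, rowvar=False)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def count_edges(n_nodes: int) -> int:
    """Number of undirected edges of a complete graph: n(n-1)/2."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return n_nodes * (n_nodes - 1) // 2


def threshold_network(zmat: np.ndarray, r_threshold: float) -> np.ndarray:
    """Boolean retention matrix for edges with |r| >= r_threshold.

    The threshold is applied on the correlation scale (r = tanh(z)); the
    retained edges keep their z weights elsewhere.
    """
    if not 0.0 <= r_threshold < 1.0:
        raise ValueError("r threshold must lie in [0, 1)")
    z = np.asarray(zmat, dtype=float)
    keep = np.abs(np.tanh(z)) >= r_threshold
    np.fill_diagonal(keep, False)
    return keep


def node_strength(zmat: np.ndarray) -> np.ndarray:
    """S_i = sum of incident (signed) edge weights, excluding the diagonal."""
    z = np.asarray(zmat, dtype=float)
    return z.sum(axis=1) - np.diag(z)


def compare_edges(
    group_a: np.ndarray,
    group_b: np.ndarray,
    p_thresholds: Sequence[float] = (0.05, 0.01, 0.005, 0.001),
) -> tuple[pd.DataFrame, dict]:
    """Edge-wise two-sample pooled t-tests on Fisher-z weights.

    ``group_a``/``group_b`` are (n_subjects, n, n) stacks of connectivity
    matrices.  Returns a long table (one row per upper-triangle edge) and
    a dict mapping each p threshold to the list of significant edges
    (uncorrected, as in the original four-threshold sweep; a Bonferroni
    column is included in the table for reference).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("expected (subjects, n, n) stacks with matching n")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >=2 subjects per group")
    n = a.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    ea, eb = a[:, iu, ju], b[:, iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(ea, eb, axis=0)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    skipped = ~np.isfinite(t)
    n_edges = iu.size
    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "t": t,
            "p": p,
            "p_bonferroni": np.minimum(p * n_edges, 1.0),
            "skipped": skipped,
        }
    )
    sig = {
        thr: [
            (int(i), int(j))
            for i, j, pv, sk in zip(iu, ju, p, skipped)
            if not sk and pv < thr
        ]
        for thr in p_thresholds
    }
    return table, sig


def behavior_correlation(
    node_strengths: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson (or partial) correlations between node strength and
    cognitive scores.

    With covariates supplied, both strength and score are residualised on
    the covariates (plus an intercept) and the correlation of the
    residuals is reported with n - 2 - k degrees of freedom.  Both the
    uncorrected and Bonferroni-adjusted p are returned.
    """
    S = np.asarray(node_strengths, dtype=float)
    Y = np.asarray(scores, dtype=float)
    n = S.shape[0]
    if Y.shape[0] != n:
        raise ValueError("strength and score tables must have matching rows")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    k = 0
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        k = C.shape[1] - 1
        if k >= n - 2:
            raise ValueError("too many covariates for the sample size")
        beta_s, *_ = np.linalg.lstsq(C, S, rcond=None)
        beta_y, *_ = np.linalg.lstsq(C, Y, rcond=None)
        S = S - C @ beta_s
        Y = Y - C @ beta_y
    if (np.asarray(scores, dtype=float).std(axis=0) == 0).any():
        raise ValueError("constant score vector")
    Sc = S - S.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt(
        np.outer((Sc**2).sum(axis=0), (Yc**2).sum(axis=0))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Sc.T @ Yc) / denom
    r = np.clip(r, -R_CLIP, R_CLIP)
    df = n - 2 - k
    tstat = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    node_names = list(getattr(node_strengths, "columns", range(S.shape[1])))
    score_names = list(getattr(scores, "columns", range(Y.shape[1])))
    n_tests = r.size
    rows = [
        {
            "node": node_names[i],
            "score": score_names[j],
            "r": float(r[i, j]),
            "p": float(p[i, j]),
            "p_bonferroni": float(min(p[i, j] * n_tests, 1.0)),
        }
        for i in range(r.shape[0])
        for j in range(r.shape[1])
    ]
    return pd.DataFrame(rows)


def hemispheric_strength_summary(
    strengths: np.ndarray, hemispheres: Sequence[str]
) -> dict:
    """Aggregate node strength by hemisphere with a laterality index.

    Returns signed sums over L- and R-tagged nodes and the index
    (|L| - |R|)/(|L| + |R|), which is bounded in [-1, 1] even for signed
    weights; bilateral and vermis nodes are excluded.  With no tagged
    nodes the summary is reported as missing (NaN).
    """
    s = np.asarray(strengths, dtype=float)
    h = np.asarray(list(hemispheres))
    if s.shape[0] != h.shape[0]:
        raise ValueError("strengths and hemisphere tags must align")
    left = float(s[h == "L"].sum()) if (h == "L").any() else np.nan
    right = float(s[h == "R"].sum()) if (h == "R").any() else np.nan
    if np.isnan(left) and np.isnan(right):
        index = np.nan
    else:
        l = 0.0 if np.isnan(left) else abs(left)
        r = 0.0 if np.isnan(right) else abs(right)
        index = (l - r) / (l + r) if (l + r) != 0 else 0.0
    return {"left": left, "right": right, "laterality_index": index}
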