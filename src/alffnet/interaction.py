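"""Voxelwise genotype-by-group interaction mapping on ALFF maps.

For each SNP a general linear model is fitted at every in-mask voxel:

    ALFF ~ intercept + group + genotype code(s) + group x genotype
           + age + gender + education + grey-matter value

and the interaction term is tested with a partial F statistic comparing
the full model against the model without the interaction column(s).  The
genotype code is one column (recessive) or two orthogonal-polynomial
columns (genotypic), so the interaction has 1 or 2 numerator df.  The
grey-matter covariate is voxelwise: each subject contributes the value of
their grey-matter probability map at the voxel being tested, which
isolates functional differences that cannot be explained by local
anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genetics

__all__ = ["StatMap", "build_design", "fit_voxel_interaction", "interaction_f_map", "run_snp_scan"]


@dataclass
class StatMap:
    """Per-SNP voxelwise interaction F/p maps."""

    snp_id: str
    f: np.ndarray  # 3D
    p: np.ndarray  # 3D
    df1: int
    df2: int
    affine: np.ndarray
    mask: np.ndarray
    info: dict = field(default_factory=dict)


def build_design(
    phenotypes: pd.DataFrame, code_cols: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Assemble the common (non-voxelwise) design matrix.

    Column order: intercept, group (0 control / 1 aMCI), age, gender,
    education, genotype code column(s), interaction column(s).  Returns
    (X, index dict with 'interaction' giving the interaction column
    positions).
    """
    group = (phenotypes["group"].to_numpy() == "aMCI").astype(float)
    code_cols = np.atleast_2d(np.asarray(code_cols, dtype=float))
    if code_cols.shape[0] != len(phenotypes):
        code_cols = code_cols.T
    if code_cols.shape[0] != len(phenotypes):
        raise ValueError("genotype code rows do not match phenotype rows")
    inter = code_cols * group[:, None]
    X = np.column_stack(
        [
            np.ones(len(phenotypes)),
            group,
            phenotypes["age"].to_numpy(float),
            phenotypes["gender"].to_numpy(float),
            phenotypes["education"].to_numpy(float),
            code_cols,
            inter,
        ]
    )
    k = code_cols.shape[1]
    idx = {
        "group": 1,
        "code": list(range(5, 5 + k)),
        "interaction": list(range(5 + k, 5 + 2 * k)),
    }
    return X, idx


def fit_voxel_interaction(
    y: np.ndarray, design: np.ndarray, interaction_cols: Sequence[int]
) -> tuple[float, float]:
    """Partial F test for the interaction column(s) at one voxel.

    Least-squares fits of the full design and of the design with the
    interaction columns removed; F = ((RSS_r - RSS_f)/df1) / (RSS_f/df2)
    with df1 = rank(full) - rank(reduced) and df2 = n - rank(full).
    Rank-deficient or degenerate fits flag the voxel invalid via p = 1.
    """
    y = np.asarray(y, dtype=float)
    X_full = np.asarray(design, dtype=float)
    X_red = np.delete(X_full, list(interaction_cols), axis=1)
    n = y.size
    rank_f = np.linalg.matrix_rank(X_full)
    rank_r = np.linalg.matrix_rank(X_red)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 <= 0 or df2 <= 0:
        return 0.0, 1.0
    rss_f = float(((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2).sum())
    rss_r = float(((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2).sum())
    if rss_f <= 0 or not np.isfinite(rss_f):
        return 0.0, 1.0
    f_stat = max((rss_r - rss_f), 0.0) / df1 / (rss_f / df2)
    return float(f_stat), float(stats.f.sf(f_stat, df1, df2))


def _rss_with_voxel_covariate(
    Y: np.ndarray, X: np.ndarray, gm: np.ndarray | None
) -> tuple[np.ndarray, int]:
    """Residual sum of squares per voxel for design [X, gm_voxel].

    Y is (n, V); gm, if given, is (n, V) with one covariate column per
    voxel.  Projecting Y and gm onto the orthogonal complement of X turns
    the voxelwise column into a single extra rank-1 regression, which keeps
    the whole scan a handful of dense matrix products.
    Returns (rss (V,), rank of the design).
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    Q = U[:, :rank]
    R = Y - Q @ (Q.T @ Y)
    rss = (R**2).sum(axis=0)
    if gm is None:
        return rss, rank
    g = gm - Q @ (Q.T @ gm)
    gg = (g**2).sum(axis=0)
    gy = (g * R).sum(axis=0)
    ok = gg > 1e-12 * max(1.0, float(gg.max(initial=0.0)))
    extra = np.zeros_like(rss)
    extra[ok] = gy[ok] ** 2 / gg[ok]
    rss = rss - extra
    return rss, rank + 1  # gm assumed non-aliased where ok

def interaction_f_map(
    Y: np.ndarray,
    design: np.ndarray,
    interaction_cols: Sequence[int],
    gm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Vectorised partial F for the interaction over all voxels.

    Y is (n_subjects, V); gm, if given, is (n_subjects, V).  Returns
    (F (V,), p (V,), df1, df2).
    """
    Y = np.asarray(Y, dtype=np.float64)
    X_full = np.asarray(design, dtype=np.float64)
    X_red = np.delete(X_full, list(interaction_cols), axis=1)
    n = Y.shape[0]
    rss_f, rank_f = _rss_with_voxel_covariate(Y, X_full, gm)
    rss_r, rank_r = _rss_with_voxel_covariate(Y, X_red, gm)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 <= 0 or df2 <= 0:
        raise ValueError("design leaves no degrees of freedom for the interaction")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.clip(rss_r - rss_f, 0.0, None) / df1 / (rss_f / df2)
    bad = ~np.isfinite(f_stat) | (rss_f <= 0)
    f_stat[bad] = 0.0
    p = stats.f.sf(f_stat, df1, df2)
    p[bad] = 1.0
    return f_stat, p, df1, df2


def run_snp_scan(
    alff_stack: np.ndarray,
    gm_stack: np.ndarray | None,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    entry: genetics.SNPPanelEntry,
    mask: np.ndarray,
    affine: np.ndarray,
    model: genetics.GeneticModelChoice | None = None,
) -> StatMap:
    """Fit the interaction GLM at every in-mask voxel for one SNP.

    ``alff_stack`` is (n_subjects, V) over in-mask voxels in the order of
    ``phenotypes``; ``gm_stack`` likewise (rows of all-NaN mark a subject
    with a missing grey-matter map, which is mean-imputed with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(phenotypes)
    missing = set(phenotypes["subject_id"]) - set(genotypes["subject_id"])
    if missing:
        raise ValueError(f"subjects missing from genotype table: {sorted(missing)}")
    geno = genotypes.set_index("subject_id").loc[phenotypes["subject_id"]].reset_index()
    counts = genetics.genotype_counts(geno, entry)
    if model is None:
        model = genetics.select_genetic_model(
            genetics.compute_maf(counts).maf, entry.snp_id
        )
    minor = genetics.minor_allele_counts(geno, entry)
    code = genetics.code_genotypes(minor, model.model)
    X, idx = build_design(phenotypes, code)
    if gm_stack is not None:
        gm_stack = np.asarray(gm_stack, dtype=np.float64)
        nan_rows = np.isnan(gm_stack).all(axis=1)
        if nan_rows.any():
            warnings.warn(
                f"{int(nan_rows.sum())} subject(s) without a grey-matter map; "
                "mean-imputing the GM covariate",
                stacklevel=2,
            )
            gm_stack = gm_stack.copy()
            gm_stack[nan_rows] = np.nanmean(gm_stack, axis=0)
    f_flat, p_flat, df1, df2 = interaction_f_map(
        np.asarray(alff_stack, dtype=np.float64), X, idx["interaction"], gm_stack
    )
    f3 = np.zeros(mask.shape)
    p3 = np.ones(mask.shape)
    f3[mask] = f_flat
    p3[mask] = p_flat
    return StatMap(
        snp_id=entry.snp_id,
        f=f3,
        p=p3,
        df1=df1,
        df2=df2,
        affine=np.asarray(affine, dtype=float),
        mask=mask,
        info={
            "model": model.model,
            "maf": model.maf,
            "n_subjects": n,
            "gm_covariate": gm_stack is not None,
        },
    )
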