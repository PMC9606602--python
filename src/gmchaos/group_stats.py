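"""Group-level statistics on lambda maps and scalograms.

Voxel-wise inference uses an ordinary-least-squares general linear model
with an intercept, a group indicator, and optional covariates (age, sex,
education, smoking, alcohol, ...).  Family-wise error over voxels is
controlled by a permutation max-|t| procedure with Freedman-Lane
covariate handling; clusters are formed on the uncorrected map at a
cluster-defining threshold and filtered by an extent threshold with
26-neighborhood connectivity.  Point-by-scale scalogram comparisons use
per-cell two-sample t-tests with Benjamini-Hochberg FDR over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from gmchaos.errors import DesignMatrixError, PermutationError, ShapeMismatchError
from gmchaos.chaos import LambdaMap


@dataclass
class GLMResult:
    """Voxel-wise GLM group contrast: t map, two-sided p map, df, analysis mask."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: int
    mask: np.ndarray
    group_labels: tuple[str, str] = ("A", "B")


@dataclass
class FWEResult:
    """Permutation max-|t| corrected p map plus suprathreshold clusters.

    ``clusters`` rows: (size_voxels, peak_index, peak_t), clusters formed
    at the cluster-defining threshold and filtered at the extent
    threshold.
    """

    corrected_p_map: np.ndarray
    clusters: list[tuple[int, tuple[int, int, int], float]]
    glm: GLMResult
    n_perm: int


@dataclass
class ScaleTestResult:
    """Per-cell scalogram group test with BH-FDR over the point-by-scale grid."""

    p_grid: np.ndarray
    q_grid: np.ndarray
    sig_mask: np.ndarray
    significant_scales: np.ndarray
    t_grid: np.ndarray | None = None


def _stack_maps(maps: list[LambdaMap]) -> np.ndarray:
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"lambda maps have inconsistent shapes: {shapes}")
    return np.stack([m.data for m in maps], axis=0)


def build_design(
    table: pd.DataFrame, covariate_names: list[str] | None = None
) -> tuple[np.ndarray, tuple[str, str]]:
    """Design matrix [intercept, group indicator, covariates...].

    The group indicator is 0 for the first group level (sorted order) and
    1 for the second; the t contrast therefore tests group2 - group1.
    """
    covariate_names = covariate_names or []
    groups = sorted(table["group"].astype(str).unique())
    if len(groups) != 2:
        raise DesignMatrixError(f"need exactly 2 groups, got {groups}")
    counts = table["group"].astype(str).value_counts()
    if counts.min() < 2:
        raise DesignMatrixError("each group needs at least 2 subjects")
    for name in covariate_names:
        if name not in table.columns:
            raise DesignMatrixError(f"missing covariate column: {name}")
        if table[name].isna().any():
            raise DesignMatrixError(f"covariate {name!r} has missing values")
    indicator = (table["group"].astype(str) == groups[1]).to_numpy(dtype=np.float64)
    columns = [np.ones(len(table)), indicator]
    columns += [table[name].to_numpy(dtype=np.float64) for name in covariate_names]
    design = np.column_stack(columns)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignMatrixError("design matrix is rank-deficient")
    return design, (groups[0], groups[1])


def _glm_t(Y: np.ndarray, X: np.ndarray, contrast_col: int = 1) -> tuple[np.ndarray, int]:
    """t statistics for one design column, vectorized over response columns.

    Y: (n_subjects, n_voxels); X: (n_subjects, p).  Returns (t, df).
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DesignMatrixError(f"non-positive residual df ({df})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (p, n_voxels)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[contrast_col, contrast_col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[contrast_col] / se, 0.0)
    return t, df


def glm_contrast(
    maps: list[LambdaMap],
    table: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> GLMResult:
    """Voxel-wise OLS group contrast over lambda maps.

    The analysis mask contains voxels with nonzero variance across
    subjects.  ``t_map`` tests the group coefficient (group2 - group1,
    groups in sorted label order); ``p_map`` holds two-sided Student-t
    p-values, 1 outside the mask.
    """
    Y4 = _stack_maps(maps)
    if len(maps) != len(table):
        raise ShapeMismatchError("one covariate row per lambda map required")
    X, group_labels = build_design(table, covariate_names)
    # exact peak-to-peak test: float std of identical values can be a tiny
    # positive number, which would admit degenerate voxels into the mask
    mask = np.ptp(Y4, axis=0) > 0
    Y = Y4[:, mask]
    t_flat, df = _glm_t(Y, X)
    p_flat = 2.0 * stats.t.sf(np.abs(t_flat), df)
    t_map = np.zeros(Y4.shape[1:])
    p_map = np.ones(Y4.shape[1:])
    t_map[mask] = t_flat
    p_map[mask] = p_flat
    return GLMResult(t_map=t_map, p_map=p_map, df=df, mask=mask, group_labels=group_labels)


def _find_clusters(
    t_map: np.ndarray, p_map: np.ndarray, mask: np.ndarray, cdt_p: float, extent: int
) -> list[tuple[int, tuple[int, int, int], float]]:
    supra = mask & (p_map < cdt_p)
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    labels, n_labels = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_labels + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < extent:
            continue
        t_vals = t_map[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        peak = voxels[np.argmax(np.abs(t_vals))]
        clusters.append((len(voxels), tuple(int(c) for c in peak), float(t_map[tuple(peak)])))
    clusters.sort(key=lambda c: -c[0])
    return clusters


def permutation_fwe(
    maps: list[LambdaMap],
    table: pd.DataFrame,
    covariate_names: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    cdt_p: float = 0.001,
    extent: int = 10,
) -> FWEResult:
    """Permutation max-|t| FWE correction with Freedman-Lane covariate handling.

    The response is residualized on the nuisance part of the design
    (intercept + covariates), the residuals are permuted, the fitted
    nuisance part is added back, and the full model is refitted; the
    corrected voxel p-value is the rank of the observed |t| within the
    permutation distribution of the volume-wise maximum |t| (including
    the observed statistic, so p >= 1/(n_perm + 1)).  Clusters are formed
    on the *observed* uncorrected map at ``cdt_p`` (two-sided) and kept
    when at least ``extent`` voxels (26-connectivity).
    """
    if n_perm < 100:
        raise PermutationError(f"n_perm must be >= 100, got {n_perm}")
    glm = glm_contrast(maps, table, covariate_names)
    if not glm.mask.any():
        raise PermutationError("empty analysis mask (no voxel varies across subjects)")
    Y4 = _stack_maps(maps)
    X, _ = build_design(table, covariate_names)
    Y = Y4[:, glm.mask]
    n = Y.shape[0]
    # Freedman-Lane: residualize on nuisance columns (all but the group column)
    Z = np.delete(X, 1, axis=1)
    hat_z = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    fitted = hat_z @ Y
    resid = Y - fitted
    t_obs = glm.t_map[glm.mask]
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    exceed = np.zeros(t_obs.shape, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted + resid[perm]
        t_star, _ = _glm_t(Y_star, X)
        abs_star = np.abs(t_star)
        max_null[b] = abs_star.max()
        exceed += max_null[b] >= np.abs(t_obs)
    corrected = (1.0 + exceed) / (n_perm + 1.0)
    corrected_map = np.ones(glm.t_map.shape)
    corrected_map[glm.mask] = corrected
    clusters = _find_clusters(glm.t_map, glm.p_map, glm.mask, cdt_p, extent)
    return FWEResult(
        corrected_p_map=corrected_map, clusters=clusters, glm=glm, n_perm=n_perm
    )


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a flat p-value sequence.

    Returns ``(rejected, adjusted)`` where ``adjusted[i] = min_{j >= rank_i}
    p_(j) * n / j`` capped at 1, and ``rejected = adjusted < q``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    # multipletests rejects at adjusted <= q; the strict-threshold contract
    # used for scalogram grids is adjusted < q
    return adjusted < q, adjusted


def scalogram_group_test(
    scalograms_a: list, scalograms_b: list, q: float = 0.05
) -> ScaleTestResult:
    """Two-sample t-test per (point, scale) cell, BH-FDR over the full grid.

    ``significant_scales`` lists the scales with at least one cell at
    adjusted p < q.
    """
    if not scalograms_a or not scalograms_b:
        raise ShapeMismatchError("both groups need at least one scalogram")
    A = np.stack([s.coeffs for s in scalograms_a], axis=0)
    B = np.stack([s.coeffs for s in scalograms_b], axis=0)
    if A.shape[1:] != B.shape[1:]:
        raise ShapeMismatchError(
            f"scalogram shapes differ between groups: {A.shape[1:]} vs {B.shape[1:]}"
        )
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise DesignMatrixError("each group needs at least 2 subjects")
    scales = scalograms_a[0].scales
    t_grid, p_grid = stats.ttest_ind(A, B, axis=0)
    p_grid = np.where(np.isfinite(p_grid), p_grid, 1.0)
    t_grid = np.where(np.isfinite(t_grid), t_grid, 0.0)
    rejected, adjusted = bh_fdr(p_grid.ravel(), q=q)
    q_grid = adjusted.reshape(p_grid.shape)
    sig_mask = rejected.reshape(p_grid.shape)
    significant_scales = scales[sig_mask.any(axis=0)]
    return ScaleTestResult(
        p_grid=p_grid,
        q_grid=q_grid,
        sig_mask=sig_mask,
        significant_scales=significant_scales,
        t_grid=t_grid,
    )


def scalogram_group_test_per_scale(
    scalograms_a: list, scalograms_b: list, q: float = 0.05
) -> ScaleTestResult:
    """Variant applying BH separately within each scale (column-wise)."""
    base = scalogram_group_test(scalograms_a, scalograms_b, q=1.0)
    p_grid = base.p_grid
    q_grid = np.empty_like(p_grid)
    sig_mask = np.empty(p_grid.shape, dtype=bool)
    for s in range(p_grid.shape[1]):
        sig_mask[:, s], q_grid[:, s] = bh_fdr(p_grid[:, s], q=q)
    scales = scalograms_a[0].scales
    return ScaleTestResult(
        p_grid=p_grid,
        q_grid=q_grid,
        sig_mask=sig_mask,
        significant_scales=scales[sig_mask.any(axis=0)],
        t_grid=base.t_grid,
    )


def region_means(
    lmap: LambdaMap, atlas: np.ndarray, labels: list[int] | None = None
) -> pd.DataFrame:
    """Mean lambda over nonzero-map voxels per atlas label.

    Labels with no selected (nonzero-map) voxel get n_voxels = 0 and mean
    NaN.  Returns a DataFrame with columns label, mean, n_voxels.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != lmap.data.shape:
        raise ShapeMismatchError(
            f"atlas shape {atlas.shape} does not match map shape {lmap.data.shape}"
        )
    if labels is None:
        labels = sorted(int(v) for v in np.unique(atlas) if v != 0)
    selected = lmap.data != 0
    rows = []
    for lab in labels:
        in_region = selected & (atlas == lab)
        n_vox = int(np.count_nonzero(in_region))
        mean = float(lmap.data[in_region].mean()) if n_vox else np.nan
        rows.append({"label": lab, "mean": mean, "n_voxels": n_vox})
    return pd.DataFrame(rows)
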