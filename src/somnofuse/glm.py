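"""Mass-univariate GLM, second-level t-maps, thresholding and intersections.

First-level fits are ordinary least squares per voxel (no temporal
prewhitening; this simplification is recorded in map metadata). Group maps
are one-sample t-tests over per-subject beta/contrast volumes. Thresholded
maps use the uncorrected two-sided t quantile at p = 0.01 or 0.05 with a
minimum-cluster-extent rule (6-connectivity) as the only spatial
correction, and between-group comparison is the signed intersection of the
two groups' thresholded maps — explicitly not a significance statement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from scipy import stats as _stats

from .core import (
    ConfigurationError,
    DataError,
    DesignMatrix,
    DimensionError,
    GLMFit,
    NumericalError,
    PreconditionError,
    StatMap,
    ThresholdedMap,
    VolumeSeries,
)

#: face connectivity for voxel clusters
_STRUCTURE = _ndi.generate_binary_structure(3, 1)


def fit_first_level(series: VolumeSeries, design: DesignMatrix) -> GLMFit:
    """Per-voxel OLS of the BOLD series on the design matrix."""
    if design.n_scans != series.n_volumes:
        raise DimensionError(
            f"design has {design.n_scans} rows but series has {series.n_volumes} volumes")
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(np.arange(X.shape[1]), j)
            if np.linalg.matrix_rank(X[:, others]) == rank:
                bad.append(design.names[j])
        raise NumericalError(f"design is rank deficient; collinear columns: {bad}")
    df = design.n_scans - rank
    if df < 1:
        raise PreconditionError("no residual degrees of freedom")
    Y = series.data.reshape(-1, series.n_volumes).T  # scans x voxels
    nan_vox = np.isnan(Y).any(axis=0)
    if nan_vox.any():
        Y = np.where(np.isnan(Y), 0.0, Y)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    fit = GLMFit(
        betas=beta.T,
        residual_variance=sigma2,
        df=df,
        design=design,
        grid_shape=series.grid_shape,
    )
    if nan_vox.any():
        fit.nan_voxel_count = int(nan_vox.sum())
    return fit


def contrast_tmap(fit: GLMFit, contrast: np.ndarray) -> StatMap:
    """t = c'beta / sqrt(sigma^2 c'(X'X)^-1 c); zero-variance voxels get t=0."""
    c = np.asarray(contrast, float).ravel()
    if c.size != fit.design.n_columns:
        raise DimensionError("contrast length != design columns")
    if not np.any(c):
        raise ConfigurationError("all-zero contrast")
    X = fit.design.matrix
    xtx_inv = np.linalg.inv(X.T @ X)
    var_factor = float(c @ xtx_inv @ c)
    effect = fit.betas @ c
    denom = np.sqrt(fit.residual_variance * var_factor)
    t = np.zeros_like(effect)
    ok = denom > 0
    t[ok] = effect[ok] / denom[ok]
    return StatMap(
        t_values=t.reshape(fit.grid_shape), df=fit.df, level="first", contrast=c)


def second_level_ttest(maps: list[np.ndarray]) -> StatMap:
    """One-sample t against zero across subjects' volumes; df = n - 1."""
    if len(maps) < 2:
        raise PreconditionError("need at least 2 subjects")
    stack = np.stack([np.asarray(m, float) for m in maps])
    if stack.ndim != 4:
        raise DimensionError("each subject map must be a 3D volume")
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return StatMap(t_values=t, df=n - 1, level="second")


def threshold_map(
    stat_map: StatMap,
    p_threshold: float = 0.01,
    min_extent: int = 10,
    tail: str = "two-sided",
) -> ThresholdedMap:
    """Uncorrected voxelwise two-sided threshold + minimum cluster extent.

    Components are 6-connected; clusters of mixed sign are not possible
    because positive and negative voxels are labelled separately.
    """
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must be in (0, 1)")
    if tail != "two-sided":
        raise ConfigurationError("only two-sided thresholding is supported")
    cut = _stats.t.ppf(1 - p_threshold / 2, stat_map.df)
    t = stat_map.t_values
    mask = np.zeros(t.shape, bool)
    labels = np.zeros(t.shape, int)
    sizes: dict[int, int] = {}
    next_label = 1
    for sgn in (1, -1):
        supra = (t * sgn) >= cut
        lab, n = _ndi.label(supra, structure=_STRUCTURE)
        for k in range(1, n + 1):
            comp = lab == k
            size = int(comp.sum())
            if size >= min_extent:
                mask |= comp
                labels[comp] = next_label
                sizes[next_label] = size
                next_label += 1
    sign = np.sign(t).astype(int) * mask
    return ThresholdedMap(
        mask=mask,
        sign=sign,
        cluster_labels=labels,
        cluster_sizes=sizes,
        p_threshold=p_threshold,
        min_extent=min_extent,
        df=stat_map.df,
    )


def t_cutoff(df: int, p: float, tail: str = "two-sided") -> float:
    if tail == "two-sided":
        return float(_stats.t.ppf(1 - p / 2, df))
    return float(_stats.t.ppf(1 - p, df))


def intersect_maps(
    map_a: ThresholdedMap, map_b: ThresholdedMap, force: bool = False
) -> dict:
    """Signed intersection of two thresholded maps.

    Returns the joint mask split into same-sign and opposite-sign parts;
    the result carries no significance level — it only reports where both
    groups' (uncorrected, extent-filtered) maps overlap and whether their
    correlation directions agree.
    """
    if map_a.mask.shape != map_b.mask.shape:
        raise DimensionError("grid mismatch between maps")
    if not force and (
        map_a.p_threshold != map_b.p_threshold or map_a.min_extent != map_b.min_extent
    ):
        raise DataError("threshold settings differ between maps (use force=True)")
    joint = map_a.mask & map_b.mask
    same = joint & (map_a.sign == map_b.sign)
    opposite = joint & (map_a.sign == -map_b.sign) & (map_a.sign != 0)
    return {
        "joint_mask": joint,
        "same_sign_mask": same,
        "opposite_sign_mask": opposite,
        "n_joint": int(joint.sum()),
        "n_same_sign": int(same.sum()),
        "n_opposite_sign": int(opposite.sum()),
        "note": "intersection is a descriptive overlap, not a significance level",
    }


def label_regions(
    thresholded: ThresholdedMap,
    label_volume: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate each cluster's voxels against a label volume.

    One row per (cluster, label) pair plus the cluster's dominant label
    and mean-t sign; rows are sorted by cluster size (descending).
    """
    if label_volume.shape != thresholded.mask.shape:
        raise DimensionError("label volume grid mismatch")
    names = dict(names or {})
    present = np.unique(label_volume)
    for k in present:
        if int(k) not in names:
            names[int(k)] = f"label_{int(k)}"
    rows = []
    for cid, size in sorted(
        thresholded.cluster_sizes.items(), key=lambda kv: -kv[1]
    ):
        comp = thresholded.cluster_labels == cid
        sgn = int(np.sign(thresholded.sign[comp].sum()))
        labs, counts = np.unique(label_volume[comp], return_counts=True)
        dominant = names[int(labs[np.argmax(counts)])]
        for lab, cnt in zip(labs, counts):
            rows.append(
                {
                    "cluster_id": cid,
                    "cluster_size": size,
                    "label": names[int(lab)],
                    "voxels_in_label": int(cnt),
                    "fraction": cnt / size,
                    "dominant_label": dominant,
                    "sign": sgn,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "cluster_size", "label", "voxels_in_label",
            "fraction", "dominant_label", "sign",
        ],
    )


def region_sign(thresholded: ThresholdedMap, region_mask: np.ndarray) -> int:
    """Dominant sign of suprathreshold voxels inside a region mask.

    Returns +1 / -1 by majority of signed voxels, or 0 when the region
    holds no suprathreshold voxels (the "no activation" outcome).
    """
    s = thresholded.sign[region_mask]
    total = int(s.sum())
    if np.count_nonzero(s) == 0:
        return 0
    return int(np.sign(total)) if total != 0 else 0
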