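"""Data-quality validation: resting-network recovery and the alpha sanity GLM.

Two checks mirror standard EEG-fMRI quality practice: (1) spatial ICA of
time-concatenated wake-epoch BOLD should recover resting-state-network
spatial maps, and (2) a GLM driven by the all-electrode average alpha
band-limited power should localise to the occipital (secondary visual)
region. Both run on synthetic cohorts where the expected outcome is
planted and therefore checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.decomposition import FastICA

from .core import (
    DataError,
    DimensionError,
    MotionTrace,
    PreconditionError,
    StatMap,
    VolumeSeries,
)
from .design import HRFSpec, assemble_design, blp_regressor, occurrence_regressor
from .glm import contrast_tmap, fit_first_level, second_level_ttest, threshold_map
from .spectral import blp_time_series
from .synth import Cohort, LABEL_IDS, _network_maps


def network_templates(label_volume: np.ndarray) -> dict[str, np.ndarray]:
    """Planted resting-network spatial templates on the label grid."""
    return _network_maps(label_volume)


@dataclass
class ComponentMap:
    """Spatial ICA result: unit-normalised maps and their time courses."""

    maps: np.ndarray  # components x voxels
    time_courses: np.ndarray  # components x concatenated scans
    explained_variance: np.ndarray
    grid_shape: tuple[int, int, int]

    def map_volume(self, index: int) -> np.ndarray:
        return self.maps[index].reshape(self.grid_shape)


def spatial_ica(
    wake_series: list[VolumeSeries], n_components: int = 10, seed: int = 0
) -> ComponentMap:
    """Fixed-point ICA on time-concatenated segments, spatial sources.

    Segments are concatenated along time; sources are the spatial maps
    (non-Gaussianity maximised over voxels), deterministic for a given
    seed. Components are ordered by explained variance of their
    back-projection.
    """
    if not wake_series:
        raise PreconditionError("no wake segments supplied")
    grid = wake_series[0].grid_shape
    for s in wake_series[1:]:
        if s.grid_shape != grid:
            raise DimensionError("wake segments must share a grid")
    data = np.concatenate([s.data.reshape(-1, s.n_volumes) for s in wake_series], axis=1)
    n_vox, n_t = data.shape
    if n_components >= n_t:
        raise PreconditionError(
            f"n_components={n_components} must be < concatenated scans={n_t}")
    centered = data - data.mean(axis=1, keepdims=True)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps = ica.fit_transform(centered)  # voxels x components
    courses = ica.mixing_.T  # components x time
    var = np.array([
        np.var(np.outer(maps[:, k], courses[k])) for k in range(n_components)
    ])
    order = np.argsort(var)[::-1]
    maps = maps[:, order].T
    courses = courses[order]
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    maps = maps / norms
    return ComponentMap(
        maps=maps,
        time_courses=courses,
        explained_variance=var[order],
        grid_shape=grid,
    )


def match_component(components: ComponentMap, template: np.ndarray) -> dict:
    """Best-matching component by absolute spatial Pearson correlation."""
    tmpl = np.asarray(template, float).ravel()
    if tmpl.size != components.maps.shape[1]:
        raise DimensionError("template grid mismatch")
    if np.ptp(tmpl) == 0:
        raise DataError("constant template")
    tc = tmpl - tmpl.mean()
    best_idx, best_r = -1, 0.0
    for k in range(components.maps.shape[0]):
        m = components.maps[k] - components.maps[k].mean()
        denom = np.linalg.norm(m) * np.linalg.norm(tc)
        r = float(m @ tc / denom) if denom > 0 else 0.0
        if abs(r) > abs(best_r):
            best_idx, best_r = k, r
    return {"index": best_idx, "correlation": best_r}


def wake_segments(cohort: Cohort) -> list[VolumeSeries]:
    """Initial-wake BOLD segments of every subject, for merged-time ICA."""
    segments = []
    for subj in cohort.subjects:
        if subj.bold is None:
            continue
        wake = subj.events.for_condition("wake")
        if wake.empty:
            continue
        onset = float(wake["onset"].iloc[0])
        dur = float(wake["duration"].iloc[0])
        i0 = int(onset / subj.bold.tr)
        i1 = max(i0 + 2, int((onset + dur) / subj.bold.tr))
        segments.append(
            VolumeSeries(
                subj.bold.data[..., i0:i1], subj.bold.tr,
                subj.bold.voxel_size, subj.bold.origin))
    return segments


def alpha_sanity_glm(
    cohort: Cohort,
    hrf: HRFSpec = HRFSpec(),
    p_threshold: float = 0.05,
    min_extent: int = 10,
    blp_window: float = 2.0,
    blp_step: float = 1.0,
    use_truth_blp: bool = False,
    blp_series: list | None = None,
) -> dict:
    """All-electrode alpha-power GLM: does activation land occipitally?

    For each subject the average alpha relative power over *all* channels
    (computed from the subject's EEG, or from the generator's planted
    power trajectory when ``use_truth_blp``) is HRF-convolved and fitted
    against the BOLD series together with the initial-wake regressor and
    motion covariates. Alpha betas enter a second-level one-sample t-test
    thresholded at ``p_threshold``; the report gives the fraction of
    suprathreshold voxels inside the secondary-visual-cortex label.
    """
    spec = cohort.spec
    n_scans = spec.n_scans
    subject_betas = []
    for si, subj in enumerate(cohort.subjects):
        if subj.bold is None:
            raise PreconditionError(f"subject {subj.subject_id} has no BOLD data")
        if blp_series is not None:
            blp = blp_series[si]
            alpha_col = blp_regressor(
                blp, "alpha", np.arange(blp.values.shape[0]), hrf, n_scans, spec.tr)
        elif use_truth_blp or subj.eeg is None:
            from .synth import _hrf_convolve_zscore

            driver = subj.truth.rel_power_truth[:, :, 2].mean(axis=0)  # alpha
            alpha_col = _hrf_convolve_zscore(driver, spec.tr, hrf)
        else:
            blp = blp_time_series(
                subj.eeg, window=blp_window, step=blp_step,
                t_start=-spec.pre_roll)
            all_channels = np.arange(subj.eeg.n_channels)
            alpha_col = blp_regressor(blp, "alpha", all_channels, hrf, n_scans, spec.tr)
        wake = subj.events.for_condition("wake")
        wake_col = occurrence_regressor(
            wake["onset"].to_numpy(), wake["duration"].to_numpy(), hrf, n_scans, spec.tr)
        motion = subj.truth.true_motion or MotionTrace(
            np.zeros((n_scans, 3)), np.zeros((n_scans, 3)))
        # condition responses stay in the model: awakening epochs raise
        # alpha power, so an unmodelled A response would leak into the
        # alpha regressor's beta
        cond_cols = {}
        for cond in ("A", "T"):
            sel = subj.events.for_condition(cond)
            cond_cols[cond] = occurrence_regressor(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), hrf, n_scans, spec.tr)
        design = assemble_design(
            condition_cols=cond_cols,
            blp_cols={"blp_alpha": alpha_col},
            motion=motion,
            wake_col=wake_col,
            tr=spec.tr,
        )
        fit = fit_first_level(subj.bold, design)
        subject_betas.append(fit.beta_volume("blp_alpha"))
    tmap: StatMap = second_level_ttest(subject_betas)
    thr = threshold_map(tmap, p_threshold=p_threshold, min_extent=min_extent)
    svc = cohort.label_volume == LABEL_IDS["secondary_visual_cortex"]
    n_supra = int(thr.mask.sum())
    inside = int((thr.mask & svc).sum())
    return {
        "stat_map": tmap,
        "thresholded": thr,
        "n_suprathreshold": n_supra,
        "n_in_occipital_label": inside,
        "occipital_fraction": inside / n_supra if n_supra else 0.0,
    }
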