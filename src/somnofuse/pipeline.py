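"""End-to-end runner: simulate -> preprocess -> spectra -> statistics -> maps.

The pipeline reproduces the full analysis flow on a synthetic cohort:
EEG artifact removal, windowed relative band power, electrode-space
cluster permutation tests between groups (per band, for A epochs, T
epochs and their difference), electrode selection from the most
significant cluster, EEG-informed first-level GLMs per subject, per-group
second-level t-maps for the A/T conditions and the alpha/theta/delta BLP
covariates, thresholding, signed between-group intersections, and region
reports. Outputs are tagged with the hypothesis-family identifiers H1-H27
so the run directory is auditable family by family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import BAND_NAMES, ConfigurationError, EventTable, StatMap
from .design import HRFSpec, assemble_design, blp_regressor, event_regressor, occurrence_regressor
from .eeg_preprocess import preprocess_chain
from .glm import (
    contrast_tmap,
    fit_first_level,
    intersect_maps,
    label_regions,
    region_sign,
    second_level_ttest,
    threshold_map,
)
from .group_stats import (
    cluster_permutation_test,
    default_distance_threshold,
    electrode_adjacency,
    select_electrodes,
)
from .io import save_events, save_motion, save_stat_map
from .qc import (
    alpha_sanity_glm,
    match_component,
    network_templates,
    spatial_ica,
    wake_segments,
)
from .spectral import blp_time_series
from .synth import (
    Cohort,
    CohortSpec,
    GROUPS,
    LABEL_IDS,
    iter_subjects,
    make_label_volume,
    sensor_positions,
)

#: BLP-vs-BOLD hypothesis families are defined for these bands only; the
#: beta band participates in the electrode-space EEG comparisons but has
#: no BOLD coupling family.
BOLD_BANDS = ("alpha", "theta", "delta")

#: hypothesis-family identifiers per covariate: (control map, patient map,
#: intersection)
_BOLD_FAMILIES = {
    "A": ("H1", "H2", "H3"),
    "T": ("H4", "H5", "H6"),
    "alpha": ("H7", "H8", "H9"),
    "theta": ("H10", "H11", "H12"),
    "delta": ("H13", "H14", "H15"),
}
#: EEG permutation hypothesis identifiers per comparison x band
_EEG_FAMILIES = {
    ("T", "alpha"): "H16", ("T", "beta"): "H17",
    ("T", "delta"): "H18", ("T", "theta"): "H19",
    ("A", "alpha"): "H20", ("A", "beta"): "H21",
    ("A", "delta"): "H22", ("A", "theta"): "H23",
    ("T-A", "alpha"): "H24", ("T-A", "beta"): "H25",
    ("T-A", "delta"): "H26", ("T-A", "theta"): "H27",
}


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    blp_window: float = 2.0
    blp_step: float = 1.0
    p_primary: float = 0.01
    p_fallback: float = 0.05
    min_extent: int = 10
    n_perm: int = 1000
    perm_seed: int = 0
    cluster_alpha: float = 0.05
    electrode_significance: float = 0.05
    with_artifacts: bool = True
    run_qc: bool = True
    ica_components: int = 8
    bold_bands: tuple[str, ...] = BOLD_BANDS

    def validate(self) -> None:
        for p in (self.p_primary, self.p_fallback):
            if not (0 < p < 1):
                raise ConfigurationError("thresholds must be in (0, 1)")
        bad = set(self.bold_bands) - set(BOLD_BANDS)
        if bad:
            raise ConfigurationError(
                f"no BLP-BOLD hypothesis family is defined for bands {sorted(bad)}; "
                "the electrode-space EEG comparisons still cover all four bands")
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        hrf = HRFSpec(**raw.pop("hrf", {}))
        return cls(cohort=cohort, hrf=hrf, **raw)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _epoch_average_power(blp, events: EventTable, condition: str) -> np.ndarray:
    """Per-subject epoch-averaged relative power, channels x 4.

    Windows are assigned to an epoch when their center falls inside it;
    values are averaged per epoch first, then across epochs, so long
    epochs do not dominate.
    """
    sel = events.for_condition(condition)
    per_epoch = []
    for _, row in sel.iterrows():
        inside = (blp.window_centers >= row["onset"]) & (
            blp.window_centers < row["onset"] + row["duration"])
        if inside.any():
            per_epoch.append(blp.values[:, inside, :].mean(axis=1))
    if not per_epoch:
        # degenerate subject: fall back to the session average
        return blp.values.mean(axis=1)
    return np.mean(per_epoch, axis=0)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full flow; returns the result dictionary and writes the
    run directory (maps, tables, QC report, provenance manifest)."""
    config.validate()
    spec = config.cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": {
        "n_controls": spec.n_controls, "n_patients": spec.n_patients,
        "tr": spec.tr, "session_duration": spec.session_duration,
        "seed": spec.seed, "p_primary": config.p_primary,
        "p_fallback": config.p_fallback, "min_extent": config.min_extent,
        "n_perm": config.n_perm,
        "note": "voxel p-values are uncorrected; no AR(1) prewhitening",
    }}
    label_volume = make_label_volume(spec.grid_shape)
    positions, labels = sensor_positions(spec.n_channels)

    # ---- stage 1: simulate + per-subject EEG processing ------------------
    subjects = []
    for subj in iter_subjects(spec, with_eeg=True, with_bold=True,
                              with_artifacts=config.with_artifacts):
        if config.with_artifacts:
            eeg = preprocess_chain(subj.eeg)
        else:
            from .eeg_preprocess import filter_and_reference

            eeg = filter_and_reference(subj.eeg)
        blp = blp_time_series(
            eeg, window=config.blp_window, step=config.blp_step,
            t_start=-spec.pre_roll)
        epoch_power = {
            cond: _epoch_average_power(blp, subj.events, cond) for cond in ("A", "T")}
        save_events(subj.events, out / f"{subj.subject_id}_events.tsv")
        save_motion(subj.truth.true_motion, out / f"{subj.subject_id}_motion.tsv")
        # raw EEG is no longer needed; keep the light artefacts only
        subj.eeg = None
        subj.truth.clean_eeg = None
        subjects.append({
            "bundle": subj, "blp": blp, "epoch_power": epoch_power})
    manifest["stages"]["simulate+eeg"] = {
        "n_subjects": len(subjects),
        "blp_hash": _sha(np.concatenate([s["blp"].values.ravel() for s in subjects])),
    }

    # ---- stage 2: electrode-space group statistics -----------------------
    adjacency = electrode_adjacency(positions, default_distance_threshold(positions))
    eeg_results: dict[str, dict] = {}
    control = [s for s in subjects if s["bundle"].group == "control"]
    patient = [s for s in subjects if s["bundle"].group == "patient"]

    def table(group, comparison, band_idx):
        rows = []
        for s in group:
            if comparison == "T-A":
                rows.append(
                    s["epoch_power"]["T"][:, band_idx] - s["epoch_power"]["A"][:, band_idx])
            else:
                rows.append(s["epoch_power"][comparison][:, band_idx])
        return np.stack(rows)

    electrode_sets: dict[str, np.ndarray] = {}
    for comparison in ("A", "T", "T-A"):
        for bi, band in enumerate(BAND_NAMES):
            res = cluster_permutation_test(
                table(control, comparison, bi), table(patient, comparison, bi),
                adjacency, n_perm=config.n_perm,
                cluster_alpha=config.cluster_alpha, seed=config.perm_seed)
            hid = _EEG_FAMILIES[(comparison, band)]
            eeg_results[hid] = {
                "comparison": comparison,
                "band": band,
                "clusters": [
                    {"members": [labels[i] for i in c.members],
                     "statistic": c.statistic, "p": c.monte_carlo_p}
                    for c in res.clusters],
                "min_p": min((c.monte_carlo_p for c in res.clusters), default=None),
            }
            if comparison == "A" and band in config.bold_bands:
                members, prov = select_electrodes(res, config.electrode_significance)
                if prov["fallback_all_channels"]:
                    members = np.arange(spec.n_channels)
                electrode_sets[band] = members
                eeg_results[hid]["electrode_selection"] = {
                    "channels": [labels[i] for i in members], **prov}
    (out / "eeg_hypotheses.json").write_text(json.dumps(eeg_results, indent=1))
    manifest["stages"]["eeg_stats"] = {
        "n_tests": len(eeg_results),
        "electrode_sets": {b: len(v) for b, v in electrode_sets.items()},
    }

    # ---- stage 3: first-level GLMs per subject ---------------------------
    n_scans = spec.n_scans
    covariates = ["A", "T", *config.bold_bands]
    beta_maps: dict[str, dict[str, list[np.ndarray]]] = {
        cov: {g: [] for g in GROUPS} for cov in covariates}
    for s in subjects:
        subj = s["bundle"]
        cond_cols = {
            cond: event_regressor(subj.events, cond, config.hrf, n_scans, spec.tr)
            for cond in ("A", "T")}
        wake = subj.events.for_condition("wake")
        wake_col = occurrence_regressor(
            wake["onset"].to_numpy(), wake["duration"].to_numpy(),
            config.hrf, n_scans, spec.tr)
        motion = subj.truth.true_motion
        # condition family: one design for A and T together
        design = assemble_design(cond_cols, {}, motion, wake_col, spec.tr)
        fit = fit_first_level(subj.bold, design)
        for cond in ("A", "T"):
            beta_maps[cond][subj.group].append(fit.beta_volume(cond))
        # all BLP covariates enter one GLM jointly (each band with its own
        # selected electrode set): relative band powers are negatively
        # correlated because shares sum to one, so a single-band model
        # would attenuate each coupling through omitted-variable bias
        blp_cols = {
            f"blp_{band}": blp_regressor(
                s["blp"], band, electrode_sets[band], config.hrf, n_scans, spec.tr)
            for band in config.bold_bands}
        design_b = assemble_design(cond_cols, blp_cols, motion, wake_col, spec.tr)
        fit_b = fit_first_level(subj.bold, design_b)
        for band in config.bold_bands:
            beta_maps[band][subj.group].append(fit_b.beta_volume(f"blp_{band}"))
    manifest["stages"]["first_level"] = {"families": list(beta_maps)}

    # ---- stage 4: second level, thresholding, intersections --------------
    label_names = {v: k for k, v in LABEL_IDS.items()}
    bold_results: dict[str, dict] = {}
    sign_table: dict[str, dict] = {}
    for cov in covariates:
        h_control, h_patient, h_inter = _BOLD_FAMILIES[cov]
        thresholded = {}
        for group, hid in zip(GROUPS, (h_control, h_patient)):
            tmap: StatMap = second_level_ttest(beta_maps[cov][group])
            thr = threshold_map(tmap, config.p_primary, config.min_extent)
            used_p = config.p_primary
            if not thr.mask.any():
                thr = threshold_map(tmap, config.p_fallback, config.min_extent)
                used_p = config.p_fallback
            thresholded[group] = thr
            save_stat_map(
                tmap.t_values, (spec.voxel_size,) * 3,
                out / f"{hid}_{cov}_{group}_tmap.nii", df=tmap.df)
            regions = label_regions(thr, label_volume, label_names)
            regions.to_csv(out / f"{hid}_{cov}_{group}_clusters.tsv", sep="\t", index=False)
            bold_results[hid] = {
                "covariate": cov, "group": group, "p_threshold": used_p,
                "n_suprathreshold": int(thr.mask.sum()),
                "n_clusters": thr.n_clusters,
                "map_hash": _sha(tmap.t_values),
            }
            if cov in BOLD_BANDS:
                for region in (
                    "precuneus", "secondary_visual_cortex",
                    "dorsal_posterior_cingulate_cortex",
                ):
                    mask = label_volume == LABEL_IDS[region]
                    sign_table.setdefault(region, {}).setdefault(cov, {})[group] = (
                        region_sign(thr, mask))
        inter = intersect_maps(thresholded["control"], thresholded["patient"], force=True)
        bold_results[h_inter] = {
            "covariate": cov,
            "n_joint": inter["n_joint"],
            "n_same_sign": inter["n_same_sign"],
            "n_opposite_sign": inter["n_opposite_sign"],
            "note": inter["note"],
        }
    (out / "bold_hypotheses.json").write_text(json.dumps(bold_results, indent=1))
    (out / "coupling_sign_table.json").write_text(json.dumps(sign_table, indent=1))
    manifest["stages"]["second_level"] = {
        "map_hashes": {h: r.get("map_hash") for h, r in bold_results.items()}}

    # ---- stage 5: QC ------------------------------------------------------
    qc_report = None
    if config.run_qc:
        cohort = Cohort(
            spec=spec, subjects=[s["bundle"] for s in subjects],
            label_volume=label_volume, label_names=label_names)
        segments = wake_segments(cohort)
        comp = spatial_ica(
            segments, n_components=config.ica_components, seed=config.perm_seed)
        templates = network_templates(label_volume)
        network_match = {
            name: match_component(comp, tmpl)
            for name, tmpl in templates.items()}
        alpha_val = alpha_sanity_glm(
            cohort, config.hrf, p_threshold=config.p_fallback,
            min_extent=config.min_extent,
            blp_series=[s["blp"] for s in subjects])
        qc_report = {
            "network_match": {
                k: {"index": v["index"], "correlation": round(v["correlation"], 4)}
                for k, v in network_match.items()},
            "alpha_glm_occipital_fraction": alpha_val["occipital_fraction"],
            "alpha_glm_n_suprathreshold": alpha_val["n_suprathreshold"],
        }
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        manifest["stages"]["qc"] = qc_report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "eeg_hypotheses": eeg_results,
        "bold_hypotheses": bold_results,
        "sign_table": sign_table,
        "qc": qc_report,
        "manifest": manifest,
    }
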