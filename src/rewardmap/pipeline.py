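"""End-to-end reproducible runs: simulate -> fit -> cluster -> correlate -> report.

A :class:`RunConfig` resolves every tunable of the pipeline; stage seeds
are derived deterministically from ``master_seed`` so a run is
bit-reproducible.  Each stage can write its outputs (NIfTI volumes, TSV
tables, a YAML manifest echoing the resolved configuration and a hash of
it) into a run directory, and each stage can reload the previous stage's
outputs from that directory, which is what the command-line interface
uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import glm as glm_mod
from . import images
from . import stats as stats_mod
from . import synthetic as syn_mod
from . import task as task_mod
from .exceptions import RewardmapError

TSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    master_seed: int = 0
    n_subjects: int = 30
    tr: float = 2.5
    n_volumes: int = 240
    # HRF
    hrf_shape_n: int = 3
    hrf_tau: float = 1.25
    hrf_delay: float = 2.5
    # design
    layout: str = "four_task"
    response_offset_s: float = 0.75
    # simulation
    noise_sigma: float = 1.0
    noise_ar1_rho: float = 0.3
    noise_drift_amp: float = 1.0
    noise_motion_coupling: float = 0.5
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.3
    cue_amplitude: float = 1.0
    covariate_coupling: dict = field(
        default_factory=lambda: {"BIS_NP": {2: -0.56}, "BIS_MI": {}, "Age": {}})
    # group stage
    selection_alpha: float = 0.001
    spca_n_components: int = 10
    spca_l1_penalty: float | None = None
    spca_max_iter: int = 500
    connectivity: int = 26
    min_cluster_size: int = 20
    # reporting
    effect_bins: tuple = (0.1, 0.3, 0.5)

    def hrf_params(self) -> glm_mod.HRFParams:
        return glm_mod.HRFParams(self.hrf_shape_n, self.hrf_tau, self.hrf_delay)

    def noise_spec(self) -> syn_mod.NoiseSpec:
        return syn_mod.NoiseSpec(
            sigma=self.noise_sigma, ar1_rho=self.noise_ar1_rho,
            drift_amp=self.noise_drift_amp,
            motion_coupling=self.noise_motion_coupling)

    def spca_config(self) -> cluster_mod.SparsePCAConfig:
        return cluster_mod.SparsePCAConfig(
            n_components=self.spca_n_components,
            l1_penalty=self.spca_l1_penalty,
            max_iter=self.spca_max_iter)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_bins"] = list(self.effect_bins)
        d["covariate_coupling"] = {
            k: {int(c): float(r) for c, r in v.items()}
            for k, v in self.covariate_coupling.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "effect_bins" in d:
            d["effect_bins"] = tuple(d["effect_bins"])
        if "covariate_coupling" in d and d["covariate_coupling"] is not None:
            d["covariate_coupling"] = {
                k: {int(c): float(r) for c, r in (v or {}).items()}
                for k, v in d["covariate_coupling"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise RewardmapError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def manifest_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------- simulate

def stage_simulate(config: RunConfig, run_dir=None) -> syn_mod.Cohort:
    cohort = syn_mod.simulate_cohort(
        n_subjects=config.n_subjects,
        amplitude_distribution=syn_mod.AmplitudeDistribution(
            mean_contrast=config.amplitude_mean,
            sd_contrast=config.amplitude_sd),
        covariate_coupling=config.covariate_coupling,
        seed=config.master_seed,
        noise=config.noise_spec(),
        hrf_params=config.hrf_params(),
        tr=config.tr,
        n_volumes=config.n_volumes,
        cue_amplitude=config.cue_amplitude,
    )
    if run_dir is not None:
        save_cohort(cohort, run_dir)
    return cohort


def save_cohort(cohort: syn_mod.Cohort, run_dir) -> None:
    run_dir = _ensure_dir(run_dir)
    mask, labels = syn_mod.make_phantom(cohort.phantom)
    images.save_label_volume(mask.astype(int), cohort.phantom.affine,
                             run_dir / "mask.nii")
    images.save_label_volume(labels, cohort.phantom.affine,
                             run_dir / "truth_labels.nii")
    for s in cohort.subjects:
        if s.series is not None:
            images.save_series(s.series, run_dir / f"{s.subject_id}_bold.nii")
        task_mod.write_trial_log(s.records, run_dir / f"{s.subject_id}_events.tsv")
        pd.DataFrame(
            s.motion_trace,
            columns=[f"motion{j + 1}" for j in range(6)],
        ).to_csv(run_dir / f"{s.subject_id}_motion.tsv", sep="\t", index=False,
                 float_format=TSV_FLOAT_FORMAT)
    cohort.covariates.rename_axis("subject").to_csv(
        run_dir / "covariates.tsv", sep="\t", float_format=TSV_FLOAT_FORMAT)
    cohort.behavioral_table().to_csv(
        run_dir / "behavioral_scores.tsv", sep="\t")
    cohort.contrast_amplitudes.to_csv(
        run_dir / "true_contrast_amplitudes.tsv", sep="\t",
        float_format=TSV_FLOAT_FORMAT)


def load_cohort(config: RunConfig, run_dir) -> syn_mod.Cohort:
    """Reload a saved cohort (series, logs, motion, covariates)."""
    run_dir = Path(run_dir)
    phantom = syn_mod.default_phantom()
    mask_arr, _ = images.load_volume(run_dir / "mask.nii")
    mask = mask_arr.astype(bool)
    covariates = pd.read_csv(run_dir / "covariates.tsv", sep="\t",
                             index_col="subject")
    amps = pd.read_csv(run_dir / "true_contrast_amplitudes.tsv", sep="\t",
                       index_col="subject")
    subjects = []
    for sid in covariates.index:
        records = task_mod.read_trial_log(run_dir / f"{sid}_events.tsv")
        motion = pd.read_csv(run_dir / f"{sid}_motion.tsv", sep="\t").to_numpy()
        series_path = run_dir / f"{sid}_bold.nii"
        series = images.load_series(series_path, mask, tr=config.tr) \
            if series_path.exists() else None
        n_clusters = amps.shape[1]
        truth = syn_mod.SubjectGroundTruth(
            a_win=1.0 + amps.loc[sid].to_numpy(),
            a_loss=np.ones(n_clusters),
            motion_trace=motion)
        subjects.append(syn_mod.SubjectBundle(
            subject_id=sid, series=series, records=records,
            motion_trace=motion, truth=truth,
            scores=task_mod.compute_behavioral_scores(records)))
    return syn_mod.Cohort(
        phantom=phantom, subjects=subjects, covariates=covariates,
        contrast_amplitudes=amps,
        cluster_directions=np.asarray(syn_mod.DEFAULT_CLUSTER_DIRECTIONS),
        seeds={"master": str(config.master_seed)})


# --------------------------------------------------------------------- fit

def stage_fit(config: RunConfig, cohort: syn_mod.Cohort, run_dir=None):
    """Fit the subject GLMs; returns (contrast map stack, t-map stack)."""
    mask, _ = syn_mod.make_phantom(cohort.phantom)
    contrast_maps, tmaps = [], []
    for s in cohort.subjects:
        if s.series is None:
            raise RewardmapError(f"{s.subject_id}: no BOLD series available")
        pc1 = glm_mod.compute_pc1(s.series)
        design = glm_mod.build_design_matrix(
            s.records, s.motion_trace, pc1,
            hrf_params=config.hrf_params(), tr=config.tr,
            n_volumes=config.n_volumes, layout=config.layout,
            response_offset_s=config.response_offset_s)
        res = glm_mod.fit_glm(s.series, design)
        cmap = np.zeros(mask.shape)
        cmap[mask] = res.contrast_estimate()
        tvol = res.tmap().to_volume(fill=0.0)
        contrast_maps.append(cmap)
        tmaps.append(tvol)
        if run_dir is not None:
            run_dir = _ensure_dir(run_dir)
            images.save_volume(cmap, cohort.phantom.affine,
                               run_dir / f"{s.subject_id}_contrast.nii")
            images.save_volume(tvol, cohort.phantom.affine,
                               run_dir / f"{s.subject_id}_tmap.nii")
    if run_dir is not None and cohort.subjects:
        # design-matrix audit for the first subject
        s = cohort.subjects[0]
        pc1 = glm_mod.compute_pc1(s.series)
        design = glm_mod.build_design_matrix(
            s.records, s.motion_trace, pc1,
            hrf_params=config.hrf_params(), tr=config.tr,
            n_volumes=config.n_volumes, layout=config.layout,
            response_offset_s=config.response_offset_s)
        design.to_frame().to_csv(run_dir / "design_matrix_sub-001.tsv",
                                 sep="\t", index=False,
                                 float_format=TSV_FLOAT_FORMAT)
    return np.asarray(contrast_maps), np.asarray(tmaps)


def load_contrast_maps(run_dir, subject_ids):
    run_dir = Path(run_dir)
    return np.asarray([
        images.load_volume(run_dir / f"{sid}_contrast.nii")[0]
        for sid in subject_ids])


# ----------------------------------------------------------------- cluster

def stage_cluster(config: RunConfig, cohort: syn_mod.Cohort,
                  contrast_maps, run_dir=None):
    mask, _ = syn_mod.make_phantom(cohort.phantom)
    label_map, label_names = cluster_mod.make_toy_label_map(mask)
    model = cluster_mod.GroupActivation(contrast_maps, mask,
                                        cohort.phantom.affine)
    results = model.fit(
        selection_alpha=config.selection_alpha,
        spca_config=config.spca_config(),
        connectivity=config.connectivity,
        min_size=config.min_cluster_size,
        label_map=label_map,
        label_names=label_names)
    if run_dir is not None:
        run_dir = _ensure_dir(run_dir)
        table = results.cluster_table
        table.to_frame().to_csv(run_dir / "cluster_table.tsv", sep="\t",
                                index=False, float_format=TSV_FLOAT_FORMAT)
        table.subject_means_frame(
            [s.subject_id for s in cohort.subjects]).to_csv(
            run_dir / "cluster_subject_means.tsv", sep="\t",
            float_format=TSV_FLOAT_FORMAT)
        cluster_vol = np.zeros(mask.shape, dtype=int)
        for c in table.clusters:
            cluster_vol[tuple(c.voxels.T)] = c.id
        images.save_label_volume(cluster_vol, cohort.phantom.affine,
                                 run_dir / "cluster_labels.nii")
    return results


# --------------------------------------------------------------- correlate

def stage_correlate(config: RunConfig, cohort: syn_mod.Cohort,
                    cluster_results, run_dir=None):
    subject_ids = [s.subject_id for s in cohort.subjects]
    means = cluster_results.cluster_table.subject_means_frame(subject_ids)
    inter = None
    if means.shape[1] >= 2:
        inter = stats_mod.intercluster_correlations(means)
    covariates = pd.concat([cohort.covariates, cohort.behavioral_table()],
                           axis=1)
    cross, long = stats_mod.cross_domain_correlations(
        means, covariates, effect_bins=config.effect_bins)
    if run_dir is not None:
        run_dir = _ensure_dir(run_dir)
        if inter is not None:
            inter.r.to_csv(run_dir / "intercluster_r.tsv", sep="\t",
                           float_format=TSV_FLOAT_FORMAT)
            inter.p.to_csv(run_dir / "intercluster_p.tsv", sep="\t",
                           float_format=TSV_FLOAT_FORMAT)
            inter.bonferroni.to_csv(run_dir / "intercluster_bonferroni.tsv",
                                    sep="\t")
        long.to_csv(run_dir / "crossdomain_long.tsv", sep="\t", index=False,
                    float_format=TSV_FLOAT_FORMAT)
    return inter, cross, long


# ------------------------------------------------------------------ report

def stage_report(config: RunConfig, cohort: syn_mod.Cohort, run_dir=None):
    behavioral = stats_mod.descriptive_table(cohort.behavioral_table())
    covariate = stats_mod.descriptive_table(cohort.covariates)
    if run_dir is not None:
        run_dir = _ensure_dir(run_dir)
        behavioral.to_csv(run_dir / "behavioral_descriptives.tsv", sep="\t",
                          index=False)
        covariate.to_csv(run_dir / "covariate_descriptives.tsv", sep="\t",
                         index=False)
    return behavioral, covariate


@dataclass
class PipelineResult:
    cohort: syn_mod.Cohort
    contrast_maps: np.ndarray | None
    cluster_results: object | None
    intercluster: object | None
    crossdomain: object | None
    crossdomain_long: pd.DataFrame | None
    behavioral_descriptives: pd.DataFrame
    covariate_descriptives: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig, run_dir=None) -> PipelineResult:
    """Execute all stages; optionally write every output to ``run_dir``."""
    t0 = time.time()
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.manifest_hash(),
        "stages": {},
    }
    cohort = stage_simulate(config, run_dir)
    manifest["stages"]["simulate"] = {"n_subjects": cohort.n_subjects}

    contrast_maps = cluster_results = inter = cross = long = None
    if cohort.n_subjects >= 2:
        contrast_maps, _ = stage_fit(config, cohort, run_dir)
        cluster_results = stage_cluster(config, cohort, contrast_maps, run_dir)
        manifest["stages"]["cluster"] = {
            "n_selected": int(cluster_results.selection.n_voxels),
            "n_kept": int(cluster_results.spca.kept.sum()),
            "spca_l1_penalty": float(cluster_results.spca.l1_penalty),
            "spca_n_components": int(config.spca_n_components),
            "n_clusters": len(cluster_results.cluster_table),
        }
        if len(cluster_results.cluster_table):
            inter, cross, long = stage_correlate(
                config, cohort, cluster_results, run_dir)
        else:
            manifest["stages"]["correlate"] = "skipped (no clusters)"
    else:
        # single-subject runs stop after the subject-level stage
        contrast_maps, _ = stage_fit(config, cohort, run_dir)
        manifest["stages"]["group"] = "skipped (n_subjects < 2)"
    behavioral, covariate = stage_report(config, cohort, run_dir)
    manifest["elapsed_s"] = round(time.time() - t0, 3)

    if run_dir is not None:
        run_dir = _ensure_dir(run_dir)
        with open(run_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(manifest)), fh,
                           sort_keys=True)
    return PipelineResult(
        cohort=cohort,
        contrast_maps=contrast_maps,
        cluster_results=cluster_results,
        intercluster=inter,
        crossdomain=cross,
        crossdomain_long=long,
        behavioral_descriptives=behavioral,
        covariate_descriptives=covariate,
        manifest=manifest,
    )
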