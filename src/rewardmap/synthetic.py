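"""Synthetic BOLD phantoms and cohorts with known ground truth.

The generator stands in for the study's scan data: a desk-scale
ellipsoidal "brain" (default 24 x 24 x 12 voxels) containing disjoint
truth clusters in which the win-feedback response amplitude differs
from the loss-feedback amplitude.  Each subject's series is

    baseline + a_win * (h * win onsets) + a_loss * (h * loss onsets)
    [inside that voxel's truth cluster]
    + cue-locked response everywhere in the mask
    + low-frequency drift + motion-coupled artifact + AR(1) noise,

with task regressors sampled exactly as the GLM module samples them, so
noiseless simulation followed by fitting recovers the amplitudes to
machine precision.  Event responses are locked to feedback onsets (the
moment win/loss information arrives); the cue response is a separate
global nuisance so task/nuisance separation is testable.

Cohorts draw per-subject contrast amplitudes (a_win - a_loss) per
cluster from a normal distribution and generate behavioral covariates
as linear functions of designated standardized cluster amplitudes plus
Gaussian noise, achieving caller-specified population correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, label as ndi_label
from scipy.signal import lfilter

from . import task as task_mod
from .exceptions import (
    InvalidCouplingError,
    InvalidInputError,
    InvalidSpecError,
)
from .glm import DEFAULT_N_VOLUMES, DEFAULT_TR, HRFParams, event_regressor
from .images import SubjectTimeSeries


def _default_affine(grid_dims, voxel_size_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    # world origin at the grid centre
    aff[:3, 3] = -(np.array(grid_dims) - 1) / 2.0 * np.array(voxel_size_mm)
    return aff


@dataclass
class PhantomSpec:
    """Geometry of the synthetic brain and its planted truth clusters.

    ``truth_clusters`` is a list of (voxel_coords, region_label) pairs
    where voxel_coords is an (N, 3) integer array.  Clusters must be
    disjoint, connected under the pipeline's connectivity rule, and lie
    strictly inside the ellipsoidal brain mask.
    """

    grid_dims: tuple = (24, 24, 12)
    voxel_size_mm: tuple = (2.5, 2.5, 3.5)
    affine: np.ndarray | None = None
    truth_clusters: list = field(default_factory=list)

    def __post_init__(self):
        if any(d <= 0 for d in self.grid_dims):
            raise InvalidSpecError("grid dimensions must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.grid_dims, self.voxel_size_mm)

    @property
    def cluster_labels(self) -> list:
        return [lab for _, lab in self.truth_clusters]


def _ellipsoid_mask(grid_dims) -> np.ndarray:
    dims = np.array(grid_dims, dtype=float)
    center = (dims - 1) / 2.0
    semi = dims / 2.0 * 0.92
    grids = np.indices(grid_dims).astype(float)
    r2 = sum(((grids[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the brain mask and the truth-cluster label volume.

    Returns (mask, labels): mask is a boolean ellipsoid; labels assigns
    cluster id 1..K to truth voxels and 0 elsewhere.
    """
    mask = _ellipsoid_mask(spec.grid_dims)
    labels = np.zeros(spec.grid_dims, dtype=int)
    seen = set()
    for k, (coords, region) in enumerate(spec.truth_clusters, start=1):
        coords = np.asarray(coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidSpecError(f"cluster {region!r}: coords must be (N, 3)")
        if np.any(coords < 0) or np.any(coords >= np.array(spec.grid_dims)):
            raise InvalidSpecError(f"cluster {region!r} extends outside the grid")
        if not mask[tuple(coords.T)].all():
            raise InvalidSpecError(f"cluster {region!r} extends outside the brain mask")
        key = set(map(tuple, coords))
        if seen & key:
            raise InvalidSpecError(f"cluster {region!r} overlaps another cluster")
        seen |= key
        blob = np.zeros(spec.grid_dims, dtype=bool)
        blob[tuple(coords.T)] = True
        _, n_comp = ndi_label(blob, structure=np.ones((3, 3, 3)))
        if n_comp != 1:
            raise InvalidSpecError(f"cluster {region!r} is not connected")
        labels[tuple(coords.T)] = k
    return mask, labels


def _blob_coords(center, radii, grid_dims):
    """Integer voxel coordinates of a small ellipsoidal blob."""
    grids = np.indices(grid_dims).astype(float)
    r2 = sum(((grids[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return np.argwhere(r2 <= 1.0)


def default_phantom() -> PhantomSpec:
    """Desk-scale phantom with four truth clusters.

    Three clusters carry a win > loss contrast and one (the "occipital"
    stand-in) carries loss > win, mirroring a study in which a single
    region responds more to losses.
    """
    dims = (24, 24, 12)
    spec = PhantomSpec(grid_dims=dims)
    centers = [(7.0, 8.0, 5.5), (16.0, 8.0, 5.5), (7.5, 16.0, 5.5), (16.0, 15.5, 5.5)]
    names = ["R. Striatum", "L. Striatum", "R. Parietal", "L. Occipital"]
    for c, name in zip(centers, names):
        coords = _blob_coords(c, (2.4, 2.4, 2.0), dims)
        spec.truth_clusters.append((coords, name))
    return spec


#: Truth-cluster contrast directions matching :func:`default_phantom`.
DEFAULT_CLUSTER_DIRECTIONS = (1.0, 1.0, 1.0, -1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: stationary AR(1) + drift + motion-coupled artifact."""

    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 1.0
    motion_coupling: float = 0.5

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidSpecError("sigma must be non-negative")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise InvalidSpecError("ar1_rho must be in [0, 1)")


@dataclass
class SubjectGroundTruth:
    """Per-subject simulation truth: amplitudes, motion, baseline."""

    a_win: np.ndarray  # per truth cluster
    a_loss: np.ndarray
    motion_trace: np.ndarray  # (n, 6)
    baseline: float = 100.0

    def __post_init__(self):
        self.a_win = np.atleast_1d(np.asarray(self.a_win, dtype=float))
        self.a_loss = np.atleast_1d(np.asarray(self.a_loss, dtype=float))
        if self.a_win.shape != self.a_loss.shape:
            raise InvalidInputError("a_win and a_loss must align")


def simulate_motion(n_volumes: int, rng, step_sd: float = 0.02,
                    smooth_sigma: float = 3.0) -> np.ndarray:
    """Six smooth random-walk motion series (3 translations, 3 rotations)."""
    steps = rng.normal(0.0, step_sd, size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    return gaussian_filter1d(walk, smooth_sigma, axis=0)


def ar1_noise(shape, sigma, rho, rng) -> np.ndarray:
    """Stationary AR(1) Gaussian noise along the last axis, marginal SD sigma."""
    if sigma == 0:
        return np.zeros(shape)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    e = rng.normal(0.0, innov_sd, size=shape)
    # stationary start
    e[..., 0] = rng.normal(0.0, sigma, size=shape[:-1])
    return lfilter([1.0], [1.0, -rho], e, axis=-1)


def drift_signal(n_volumes: int, amp: float, rng, n_voxels: int) -> np.ndarray:
    """Low-frequency drift: linear ramp + two cosine bases, random weights."""
    t = np.linspace(-1.0, 1.0, n_volumes)
    bases = np.stack([t, np.cos(np.pi * (t + 1) / 2), np.cos(np.pi * (t + 1))])
    coef = rng.normal(0.0, amp, size=(n_voxels, 3))
    return coef @ bases


def simulate_bold(
    records,
    phantom: PhantomSpec,
    truth: SubjectGroundTruth,
    hrf_params: HRFParams = HRFParams(),
    noise: NoiseSpec = NoiseSpec(),
    seed=None,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    cue_amplitude: float = 1.0,
) -> SubjectTimeSeries:
    """Simulate one subject's 4D BOLD series on the phantom grid."""
    rng = np.random.default_rng(seed)
    mask, labels = make_phantom(phantom)
    n_clusters = len(phantom.truth_clusters)
    if truth.a_win.shape[0] != n_clusters:
        raise InvalidInputError(
            f"amplitude arrays have {truth.a_win.shape[0]} entries for "
            f"{n_clusters} truth clusters"
        )
    motion = np.asarray(truth.motion_trace, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise InvalidInputError("motion trace length must equal n_volumes")
    last_cue = max((r.cue_onset_s for r in records), default=0.0)
    if last_cue > (n_volumes - 1) * tr + 1e-9:
        raise InvalidInputError("trial records extend beyond the acquisition")

    frame_times = np.arange(n_volumes) * tr
    win_reg = event_regressor(
        [r.feedback_onset_s for r in records if r.outcome == "win"],
        frame_times, hrf_params)
    loss_reg = event_regressor(
        [r.feedback_onset_s for r in records if r.outcome == "loss"],
        frame_times, hrf_params)
    cue_reg = event_regressor(
        [r.cue_onset_s for r in records if r.outcome != "missed"],
        frame_times, hrf_params)

    n_vox = int(mask.sum())
    signal = np.full((n_vox, n_volumes), float(truth.baseline))
    signal += cue_amplitude * cue_reg
    cluster_ids = labels[mask]
    for k in range(1, n_clusters + 1):
        in_k = cluster_ids == k
        signal[in_k] += truth.a_win[k - 1] * win_reg + truth.a_loss[k - 1] * loss_reg
    if noise.drift_amp > 0:
        signal += drift_signal(n_volumes, noise.drift_amp, rng, n_vox)
    if noise.motion_coupling != 0:
        signal += noise.motion_coupling * motion[:, 0]
    if noise.sigma > 0:
        signal += ar1_noise((n_vox, n_volumes), noise.sigma, noise.ar1_rho, rng)

    data = np.zeros((*phantom.grid_dims, n_volumes))
    data[mask] = signal
    return SubjectTimeSeries(data=data, affine=phantom.affine, mask=mask, tr=tr)


@dataclass(frozen=True)
class AmplitudeDistribution:
    """Between-subject distribution of cluster contrast amplitudes.

    Per subject s and cluster c, the contrast delta_sc = a_win - a_loss
    is drawn Normal(mean_contrast * direction_c, sd_contrast).  The loss
    amplitude is fixed at ``a_loss_base`` and a_win = a_loss + delta.
    """

    mean_contrast: float = 1.0
    sd_contrast: float = 0.3
    a_loss_base: float = 1.0

    def __post_init__(self):
        if self.sd_contrast <= 0:
            raise InvalidSpecError("sd_contrast must be positive")


#: Plausible instrument scales (mean, SD) used to place generated
#: covariates on familiar units; keys may appear in coupling specs.
COVARIATE_SCALES = {
    "BIS_NP": (19.80, 4.61),
    "BIS_MI": (19.30, 3.28),
    "BIS_AI": (12.57, 3.19),
    "BIS_Tot": (51.67, 8.60),
    "TOL_ExcMovMade": (7.83, 6.66),
    "VST_TotCor_Fw": (10.21, 2.78),
    "Age": (27.4, 5.0),
    "Education": (15.8, 2.1),
}


@dataclass
class SubjectBundle:
    """Everything simulated for one subject."""

    subject_id: str
    series: SubjectTimeSeries | None
    records: list
    motion_trace: np.ndarray
    truth: SubjectGroundTruth
    scores: task_mod.BehavioralScores


@dataclass
class Cohort:
    """A simulated cohort with its ground truth and covariate table."""

    phantom: PhantomSpec
    subjects: list
    covariates: pd.DataFrame
    contrast_amplitudes: pd.DataFrame  # subjects x clusters (true deltas)
    cluster_directions: np.ndarray
    seeds: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def behavioral_table(self) -> pd.DataFrame:
        rows = {s.subject_id: s.scores.to_dict() for s in self.subjects}
        frame = pd.DataFrame(rows).T[list(task_mod.SCORE_COLUMNS)]
        frame.index.name = "subject"
        return frame


def _generate_covariates(deltas, dist, coupling, rng, subject_ids):
    """Covariates as linear functions of standardized cluster amplitudes.

    ``coupling`` maps covariate name -> {cluster_index: target_r}.  With
    cluster amplitudes independent across clusters, cov = sum_c r_c z_c +
    sqrt(1 - sum r_c^2) eps has population correlation r_c with cluster c.
    """
    n = deltas.shape[0]
    data = {}
    for name, targets in coupling.items():
        targets = dict(targets)
        rs = np.array(list(targets.values()), dtype=float)
        if np.sum(rs**2) >= 1.0:
            raise InvalidCouplingError(
                f"covariate {name!r}: sum of squared target correlations "
                f"{np.sum(rs**2):.3f} >= 1 is unattainable"
            )
        z = np.zeros(n)
        for c, r in targets.items():
            zc = (deltas[:, c] - deltas[:, c].mean()) / deltas[:, c].std(ddof=0) \
                if n > 1 else np.zeros(n)
            z += r * zc
        z += np.sqrt(1.0 - np.sum(rs**2)) * rng.normal(size=n)
        mean, sd = COVARIATE_SCALES.get(name, (0.0, 1.0))
        data[name] = mean + sd * z
    return pd.DataFrame(data, index=subject_ids)


def simulate_cohort(
    n_subjects: int = 30,
    phantom: PhantomSpec | None = None,
    amplitude_distribution: AmplitudeDistribution = AmplitudeDistribution(),
    covariate_coupling: dict | None = None,
    seed=None,
    cluster_directions=None,
    noise: NoiseSpec = NoiseSpec(),
    policy: task_mod.AgentPolicy = task_mod.AgentPolicy(
        p_bet50_base=0.5, risk_shift_after_loss=0.15, pie_sensitivity=1.0,
        miss_rate=0.02),
    hrf_params: HRFParams = HRFParams(),
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    cue_amplitude: float = 1.0,
    simulate_series: bool = True,
) -> Cohort:
    """Simulate a full cohort: BOLD series, trial logs, motion, covariates.

    ``covariate_coupling`` maps covariate names to ``{cluster_index:
    target_population_r}``; uncoupled covariates can be requested with an
    empty mapping.  Setting ``simulate_series=False`` skips the 4D BOLD
    arrays (cheap mode for covariate/correlation studies on ground-truth
    amplitudes).
    """
    if phantom is None:
        phantom = default_phantom()
        if cluster_directions is None:
            cluster_directions = DEFAULT_CLUSTER_DIRECTIONS
    n_clusters = len(phantom.truth_clusters)
    if cluster_directions is None:
        cluster_directions = np.ones(n_clusters)
    cluster_directions = np.asarray(cluster_directions, dtype=float)
    if cluster_directions.shape != (n_clusters,):
        raise InvalidInputError("one direction per truth cluster required")
    if covariate_coupling is None:
        covariate_coupling = {"BIS_NP": {min(2, n_clusters - 1): -0.56},
                              "BIS_MI": {}, "Age": {}}
    for name, targets in covariate_coupling.items():
        for c in targets:
            if not 0 <= c < n_clusters:
                raise InvalidCouplingError(
                    f"covariate {name!r} couples to unknown cluster {c}")

    master = np.random.SeedSequence(seed)
    seed_amp, seed_cov, *subject_seeds = master.spawn(2 + n_subjects)
    rng_amp = np.random.default_rng(seed_amp)
    dist = amplitude_distribution
    deltas = rng_amp.normal(
        dist.mean_contrast * cluster_directions,
        dist.sd_contrast,
        size=(n_subjects, n_clusters),
    )
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_subjects)]
    covariates = _generate_covariates(
        deltas, dist, covariate_coupling, np.random.default_rng(seed_cov),
        subject_ids)

    subjects = []
    for i, sid in enumerate(subject_ids):
        child = subject_seeds[i].spawn(4)
        design = task_mod.generate_task_design(
            seed=child[0], n_trials=n_volumes, tr=tr)
        records = task_mod.simulate_agent_bets(design, policy, seed=child[1])
        motion = simulate_motion(n_volumes, np.random.default_rng(child[2]))
        truth = SubjectGroundTruth(
            a_win=dist.a_loss_base + deltas[i],
            a_loss=np.full(n_clusters, dist.a_loss_base),
            motion_trace=motion,
        )
        series = None
        if simulate_series:
            series = simulate_bold(
                records, phantom, truth, hrf_params=hrf_params, noise=noise,
                seed=child[3], tr=tr, n_volumes=n_volumes,
                cue_amplitude=cue_amplitude)
        subjects.append(SubjectBundle(
            subject_id=sid, series=series, records=records,
            motion_trace=motion, truth=truth,
            scores=task_mod.compute_behavioral_scores(records)))

    amp_frame = pd.DataFrame(
        deltas, index=subject_ids,
        columns=[f"cluster_{k + 1}" for k in range(n_clusters)])
    amp_frame.index.name = "subject"
    return Cohort(
        phantom=phantom,
        subjects=subjects,
        covariates=covariates,
        contrast_amplitudes=amp_frame,
        cluster_directions=cluster_directions,
        seeds={"master": repr(seed), "entropy": int(master.entropy or 0)},
    )
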