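"""Group-level cluster extraction for the win-loss contrast.

Subject contrast maps are pooled into a subjects x voxels matrix over
voxels passing an activation-selection rule (default: across-subject
one-sample t, two-sided alpha = 0.001 uncorrected).  A sparse PCA
refines that selection: loadings are estimated by the elastic-net
alternating scheme in which the loading step is an L1 soft-thresholding
(LASSO) that drives non-cluster voxels to exactly zero; a voxel is kept
iff it loads on any of the top-k components.  Kept voxels are then
grouped into connected components (default 26-connectivity), components
below the minimum size are dropped, and each surviving cluster is
summarised by its size, world-space centroid, anatomical label,
win>loss / loss>win direction, and per-subject mean activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .exceptions import (
    ConvergenceError,
    InvalidInputError,
    InvalidParameterError,
)
from .images import mask_to_world


@dataclass
class GroupDataMatrix:
    """Subjects x selected-voxels matrix of subject-level contrast values."""

    values: np.ndarray  # (S, m)
    voxel_index: np.ndarray  # (m, 3) voxel coordinates
    selection_rule: dict = field(default_factory=dict)
    grid_dims: tuple | None = None

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def select_activated_voxels(
    contrast_maps,
    mask: np.ndarray,
    alpha: float = 0.001,
    statistic: str = "t",
    threshold: float | None = None,
) -> GroupDataMatrix:
    """Select voxels activated across the cohort.

    ``contrast_maps`` is a list of 3D per-subject contrast volumes (or an
    (S, V) matrix over mask voxels).  Default rule: the across-subject
    one-sample t at a voxel exceeds, in absolute value, the two-sided
    critical value at ``alpha`` with S-1 df.  A direct ``threshold`` on
    |t| (or on |mean| with ``statistic='mean'``) may be given instead.
    """
    mask = np.asarray(mask, dtype=bool)
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim == 4:  # stacked volumes (S, x, y, z)
        maps = maps[:, mask]
    if maps.ndim != 2:
        raise InvalidInputError("contrast_maps must be (S, V) or a volume stack")
    S = maps.shape[0]
    if S < 2:
        raise InvalidInputError("need at least 2 subjects to select voxels")

    mean = maps.mean(axis=0)
    if statistic == "t":
        sd = maps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(sd > 0, mean / (sd / np.sqrt(S)), 0.0)
        if threshold is None:
            threshold = float(t_dist.ppf(1.0 - alpha / 2.0, S - 1))
    elif statistic == "mean":
        stat = mean
        if threshold is None:
            raise InvalidParameterError("statistic='mean' requires a threshold")
    else:
        raise InvalidParameterError(f"unknown selection statistic {statistic!r}")

    selected = np.abs(stat) >= threshold
    if not selected.any():
        warnings.warn("activation selection is empty", stacklevel=2)
    coords = np.argwhere(mask)[selected]
    return GroupDataMatrix(
        values=maps[:, selected],
        voxel_index=coords,
        selection_rule={"statistic": statistic, "alpha": alpha,
                        "threshold": float(threshold)},
        grid_dims=mask.shape,
    )


@dataclass(frozen=True)
class SparsePCAConfig:
    """Sparse PCA settings.

    ``l1_penalty=None`` selects the penalty automatically from the
    spectrum of column scores |X'X a_j|: the threshold is placed at the
    largest multiplicative gap in the sorted scores (the elbow between
    coherent-signal columns and isolated noise columns).  When no gap
    exceeds ``gap_factor`` the data show no noise floor and a penalty
    below the smallest score is used, keeping every column.
    """

    n_components: int = 10
    l1_penalty: float | None = None
    ridge_penalty: float = 0.0
    max_iter: int = 500
    tol: float = 1e-4
    gap_factor: float = 1.9

    def __post_init__(self):
        if self.n_components < 1:
            raise InvalidParameterError("n_components must be >= 1")
        if self.l1_penalty is not None and self.l1_penalty < 0:
            raise InvalidParameterError("l1_penalty must be non-negative")
        if self.ridge_penalty < 0:
            raise InvalidParameterError("ridge_penalty must be non-negative")


@dataclass
class SparsePCAResult:
    kept: np.ndarray  # boolean over input columns
    loadings: np.ndarray  # (m, k), columns ordered by explained variance
    explained_variance: np.ndarray
    l1_penalty: float
    n_iter: int


def _soft_threshold(x, lam):
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def _spca_at_penalty(X, k, lam, ridge, max_iter, tol, A0=None):
    """Elastic-net alternating sPCA at a fixed L1 penalty.

    Alternates an orthonormal projection step A = UV' (from the SVD of
    X'X B) with a loading step B_j = soft(X'(X a_j), lam) / (1 + ridge),
    the closed-form elastic-net solution in the large-ridge limit.
    Convergence is declared on the sparse loadings B (relative change
    below ``tol`` with a stable support); the rotation A may keep
    drifting in variance-flat directions without affecting the result.
    """
    m = X.shape[1]
    if A0 is None:
        _, s0, vt0 = np.linalg.svd(X, full_matrices=False)
        if s0[0] == 0:
            return np.zeros((m, k)), 0
        A = vt0[:k].T  # m x k init from ordinary PCA
    else:
        A = A0
    B = np.zeros((m, k))
    n_iter, delta, stable_run = 0, np.inf, 0
    for n_iter in range(1, max_iter + 1):
        XA = X @ A
        B_new = _soft_threshold(X.T @ XA, lam) / (1.0 + ridge)
        M = X.T @ (X @ B_new)
        u, _, vt = np.linalg.svd(M, full_matrices=False)
        A_new = u @ vt
        delta = np.abs(B_new - B).max() / max(np.abs(B_new).max(), 1e-30)
        # stability of the row support (the kept-voxel set), not of the
        # individual entries, which may flicker at the threshold
        same_rows = np.array_equal(np.any(B_new != 0, axis=1),
                                   np.any(B != 0, axis=1))
        stable_run = stable_run + 1 if same_rows else 0
        A, B = A_new, B_new
        if n_iter > 1 and stable_run >= 1 and delta < tol:
            return B, n_iter
        # components with tied variances rotate freely without changing
        # which loadings are nonzero; a long stable support is converged
        if stable_run >= 20 and delta < 0.05:
            return B, n_iter
    raise ConvergenceError(
        f"sparse PCA did not converge in {max_iter} iterations",
        diagnostics={"n_iter": n_iter, "last_update": float(delta),
                     "l1_penalty": float(lam), "support_stable_run": stable_run},
    )


def _elbow_penalty(X, k, gap_factor):
    """Automatic penalty separating signal columns from the noise floor.

    Column scores |X'X a_j| from the ordinary-PCA initialisation are
    sorted and the threshold is placed inside the largest multiplicative
    gap, considering only splits whose lower class holds at least 5% of
    the columns (the extreme tail of near-orthogonal noise columns
    otherwise produces spurious gaps).  When no gap reaches
    ``gap_factor`` the spectrum has no noise floor and a penalty below
    every score is returned, keeping every column.
    """
    _, s0, vt0 = np.linalg.svd(X, full_matrices=False)
    if s0[0] == 0:
        return 0.0, None
    A = vt0[:k].T
    scores = np.abs(X.T @ (X @ A)).max(axis=1)
    positive = np.sort(scores[scores > 0])  # ascending
    if positive.size < 2:
        return 0.0, A
    min_lower = max(2, int(0.05 * positive.size))
    best_i, best_ratio = None, 1.0
    for i in range(min_lower, positive.size):
        ratio = positive[i] / positive[i - 1]
        if ratio > best_ratio:
            best_ratio, best_i = ratio, i
    if best_i is None or best_ratio < gap_factor:
        return 0.5 * positive[0], A  # no noise floor: keep everything
    return float(np.sqrt(positive[best_i - 1] * positive[best_i])), A


def spca_refine(
    data: GroupDataMatrix,
    config: SparsePCAConfig = SparsePCAConfig(),
) -> SparsePCAResult:
    """Refine the selected voxel set with sparse PCA.

    A voxel is kept iff it has a nonzero loading on any of the top-k
    sparse components.  With ``l1_penalty=0`` the loading step has no
    thresholding and the kept set equals all columns (ordinary PCA
    support).
    """
    X = np.asarray(data.values, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("need at least 2 subjects and 2 voxels")
    X = X - X.mean(axis=0)
    m = X.shape[1]
    k = min(config.n_components, m, X.shape[0] - 1)

    if config.l1_penalty is not None:
        lam = float(config.l1_penalty)
        B, n_iter = _spca_at_penalty(
            X, k, lam, config.ridge_penalty, config.max_iter, config.tol)
    else:
        lam, A0 = _elbow_penalty(X, k, config.gap_factor)
        B, n_iter = _spca_at_penalty(
            X, k, lam, config.ridge_penalty, config.max_iter, config.tol,
            A0=A0)

    kept = np.any(B != 0, axis=1)
    # order components by the variance of their scores
    comp_var = np.var(X @ B, axis=0)
    order = np.argsort(comp_var)[::-1]
    return SparsePCAResult(
        kept=kept,
        loadings=B[:, order],
        explained_variance=comp_var[order],
        l1_penalty=float(lam),
        n_iter=n_iter,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ActivationCluster:
    """One refined activation cluster."""

    id: int
    size: int
    voxels: np.ndarray  # (size, 3)
    centroid_world: np.ndarray
    direction: str  # "win>loss" or "loss>win"
    label: str
    subject_means: np.ndarray
    mean: float
    sd: float
    se: float


@dataclass
class ClusterTable:
    """Refined clusters, ordered by size descending."""

    clusters: list
    connectivity: int
    min_size: int

    def __len__(self):
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append({
                "id": c.id,
                "size": c.size,
                "label": c.label,
                "direction": c.direction,
                "centroid_x": c.centroid_world[0],
                "centroid_y": c.centroid_world[1],
                "centroid_z": c.centroid_world[2],
                "mean": c.mean,
                "sd": c.sd,
                "se": c.se,
            })
        return pd.DataFrame(
            rows, columns=["id", "size", "label", "direction", "centroid_x",
                           "centroid_y", "centroid_z", "mean", "sd", "se"])

    def subject_means_frame(self, subject_ids=None) -> pd.DataFrame:
        data = {f"C{c.id:02d}": c.subject_means for c in self.clusters}
        frame = pd.DataFrame(data)
        if subject_ids is not None:
            frame.index = list(subject_ids)
        frame.index.name = "subject"
        return frame


def connected_components(binary_volume: np.ndarray, connectivity: int = 26):
    """Label connected components; returns (label volume, count)."""
    if connectivity not in _STRUCTURES:
        raise InvalidParameterError("connectivity must be 6, 18 or 26")
    return ndimage.label(np.asarray(binary_volume, dtype=bool),
                         structure=_STRUCTURES[connectivity])


def cluster_subject_means(voxels: np.ndarray, subject_maps) -> dict:
    """Per-subject mean activation over a voxel set, with mean/SD/SE.

    ``subject_maps`` is a stack of per-subject 3D contrast volumes.  SD
    uses the n-1 denominator and SE = SD / sqrt(n_subjects).
    """
    maps = np.asarray(subject_maps, dtype=float)
    vox = tuple(np.asarray(voxels, dtype=int).T)
    per_subject = maps[(slice(None),) + vox].mean(axis=1)
    n = per_subject.shape[0]
    sd = float(per_subject.std(ddof=1)) if n > 1 else 0.0
    return {
        "subject_means": per_subject,
        "mean": float(per_subject.mean()),
        "sd": sd,
        "se": sd / np.sqrt(n) if n > 0 else 0.0,
    }


def extract_clusters(
    kept_voxels: np.ndarray,
    subject_maps,
    affine: np.ndarray,
    connectivity: int = 26,
    min_size: int = 20,
    label_map: np.ndarray | None = None,
    label_names: dict | None = None,
) -> ClusterTable:
    """Extract size-filtered connected clusters from the kept voxel set.

    ``kept_voxels`` is a boolean 3D volume (or an (N, 3) coordinate array
    with the grid implied by ``subject_maps``).  Clusters are ordered by
    size descending; the centroid is the affine-mapped mean voxel
    coordinate; the label is taken from ``label_map`` at the labeled
    voxel nearest the centroid; the direction is win>loss iff the
    group-mean cluster value is positive.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if isinstance(kept_voxels, np.ndarray) and kept_voxels.dtype == bool:
        kept_vol = kept_voxels
    else:
        kept_vol = np.zeros(maps.shape[1:], dtype=bool)
        coords = np.asarray(kept_voxels, dtype=int)
        if len(coords):
            kept_vol[tuple(coords.T)] = True
    labeled, n_comp = connected_components(kept_vol, connectivity)

    comps = []
    for comp_id in range(1, n_comp + 1):
        vox = np.argwhere(labeled == comp_id)
        if len(vox) >= min_size:
            comps.append(vox)
    comps.sort(key=lambda v: (-len(v), tuple(v[0])))

    clusters = []
    for cid, vox in enumerate(comps, start=1):
        stats = cluster_subject_means(vox, maps)
        centroid_vox = vox.mean(axis=0)
        centroid_world = mask_to_world(affine, centroid_vox)[0]
        label = ""
        if label_map is not None:
            labeled_coords = np.argwhere(label_map > 0)
            if len(labeled_coords):
                d2 = ((labeled_coords - centroid_vox) ** 2).sum(axis=1)
                code = int(label_map[tuple(labeled_coords[np.argmin(d2)])])
                label = (label_names or {}).get(code, str(code))
        clusters.append(ActivationCluster(
            id=cid,
            size=len(vox),
            voxels=vox,
            centroid_world=centroid_world,
            direction="win>loss" if stats["mean"] > 0 else "loss>win",
            label=label,
            subject_means=stats["subject_means"],
            mean=stats["mean"],
            sd=stats["sd"],
            se=stats["se"],
        ))
    return ClusterTable(clusters=clusters, connectivity=connectivity,
                        min_size=min_size)


def make_toy_label_map(mask: np.ndarray, n_lr: int = 2, n_ap: int = 3):
    """A toy anatomical label volume partitioning the mask into 6 regions.

    Splits the mask into left/right halves and three anterior-posterior
    bands, a stand-in for an anatomical atlas lookup.  Returns
    (label volume, {code: name}).
    """
    mask = np.asarray(mask, dtype=bool)
    dims = mask.shape
    labels = np.zeros(dims, dtype=int)
    names = {}
    band_names = ["Frontal", "Striatal", "Occipital"]
    xs, ys = np.indices(dims)[:2]
    code = 0
    for lr in range(n_lr):
        side = "R" if lr == 0 else "L"
        in_lr = (xs < dims[0] / 2) if lr == 0 else (xs >= dims[0] / 2)
        for ap in range(n_ap):
            lo, hi = ap * dims[1] / n_ap, (ap + 1) * dims[1] / n_ap
            code += 1
            names[code] = f"{side}. {band_names[ap % len(band_names)]}"
            labels[mask & in_lr & (ys >= lo) & (ys < hi)] = code
    return labels, names


class GroupActivation:
    """Group-level activation model: selection -> sPCA -> clusters.

    Parameters
    ----------
    contrast_maps : (S, x, y, z) stack of subject contrast volumes
    mask : boolean brain mask shared by all subjects
    affine : voxel-to-world map of the common grid
    """

    def __init__(self, contrast_maps, mask, affine):
        self.contrast_maps = np.asarray(contrast_maps, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.affine = np.asarray(affine, dtype=float)
        if self.contrast_maps.ndim != 4:
            raise InvalidInputError("contrast_maps must be a (S, x, y, z) stack")
        if self.contrast_maps.shape[1:] != self.mask.shape:
            raise InvalidInputError("maps and mask must share a grid")

    def fit(
        self,
        selection_alpha: float = 0.001,
        spca_config: SparsePCAConfig = SparsePCAConfig(),
        connectivity: int = 26,
        min_size: int = 20,
        label_map=None,
        label_names=None,
    ) -> "GroupActivationResults":
        selection = select_activated_voxels(
            self.contrast_maps, self.mask, alpha=selection_alpha)
        if selection.n_voxels < 2:
            spca = SparsePCAResult(
                kept=np.ones(selection.n_voxels, dtype=bool),
                loadings=np.zeros((selection.n_voxels, 1)),
                explained_variance=np.zeros(1),
                l1_penalty=0.0, n_iter=0)
        else:
            spca = spca_refine(selection, spca_config)
        kept_coords = selection.voxel_index[spca.kept]
        kept_vol = np.zeros(self.mask.shape, dtype=bool)
        if len(kept_coords):
            kept_vol[tuple(kept_coords.T)] = True
        table = extract_clusters(
            kept_vol, self.contrast_maps, self.affine,
            connectivity=connectivity, min_size=min_size,
            label_map=label_map, label_names=label_names)
        return GroupActivationResults(self, selection, spca, table)


class GroupActivationResults:
    """Results of the group activation refinement."""

    def __init__(self, model, selection, spca, cluster_table):
        self.model = model
        self.selection = selection
        self.spca = spca
        self.cluster_table = cluster_table

    def summary(self) -> str:
        t = self.cluster_table
        lines = [
            "Group activation refinement",
            "=" * 34,
            f"subjects              {self.model.contrast_maps.shape[0]:>7d}",
            f"selected voxels       {self.selection.n_voxels:>7d}"
            f"  (|t| >= {self.selection.selection_rule.get('threshold', 0):.3f})",
            f"kept after sPCA       {int(self.spca.kept.sum()):>7d}"
            f"  (l1 = {self.spca.l1_penalty:.4g})",
            f"clusters (size >= {t.min_size})  {len(t):>4d}",
        ]
        for c in t.clusters:
            lines.append(
                f"  C{c.id:02d} size={c.size:<4d} {c.direction:<9s} "
                f"mean={c.mean:8.3f} sd={c.sd:7.3f} se={c.se:7.3f} {c.label}")
        return "\n".join(lines)
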