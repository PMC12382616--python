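"""Subject-level voxel-wise GLM for the win-loss contrast.

The BOLD signal at each voxel is modelled as

    y_v = X beta_v + e_v

with an n x p design matrix X shared across voxels.  Under the default
layout p = 11: the first column is the first principal component of the
masked series (a global nuisance), columns 2-7 are the six rigid-body
motion parameters, and columns 8-11 are unit-peak gamma-HRF regressors
locked to loss-feedback, win-feedback, cue, and response onsets.

Estimation uses the pseudo-inverse G of X'X:

    beta_hat_v = G X' y_v
    sigma2_v   = (y'y - y'X G X'y) / df,   df = n - 1 - rank(G)
    t_v        = C' beta_hat_v / sqrt(sigma2_v * C'GC)

The per-voxel t index is treated as an activation score, not converted
to parametric p-values at the subject level.  By default the data and
every regressor are temporally mean-centred before fitting (no explicit
intercept column), which the "n - 1" term of the df formula reflects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    DegenerateModelError,
    InvalidContrastError,
    InvalidInputError,
    InvalidParameterError,
)
from .images import SubjectTimeSeries

#: Singular values below max(sv) * RANK_TOL are treated as zero when
#: computing rank(G) and the pseudo-inverse, so df is reproducible on
#: rank-deficient designs.
RANK_TOL = 1e-10

DEFAULT_TR = 2.5
DEFAULT_N_VOLUMES = 240

#: Column roles of the default (four task column) layout, in order.
DEFAULT_ROLES = (
    "pc1",
    "motion1",
    "motion2",
    "motion3",
    "motion4",
    "motion5",
    "motion6",
    "loss_feedback",
    "win_feedback",
    "cue",
    "response",
)


@dataclass(frozen=True)
class HRFParams:
    """Gamma HRF parameters: shape n, dispersion tau (s), onset delay (s).

    The kernel peaks at ``delay + (shape_n - 1) * tau`` seconds and is
    rescaled to unit peak amplitude.
    """

    shape_n: int = 3
    tau: float = 1.25
    delay: float = 2.5

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("tau must be positive")
        if self.shape_n < 1 or int(self.shape_n) != self.shape_n:
            raise InvalidParameterError("shape_n must be an integer >= 1")
        if self.delay < 0:
            raise InvalidParameterError("delay must be non-negative")


def gamma_hrf(time_grid, params: HRFParams = HRFParams()):
    """Sample the unit-peak gamma hemodynamic response on ``time_grid``.

    h(t) = ((t-d)/tau)^(n-1) exp(-(t-d)/tau) / (tau (n-1)!) for t >= d,
    0 before the delay d, then rescaled so its maximum is 1.
    """
    t = np.asarray(time_grid, dtype=float)
    n, tau, d = int(params.shape_n), params.tau, params.delay
    s = np.maximum(t - d, 0.0) / tau
    h = s ** (n - 1) * np.exp(-s) / (tau * math.factorial(n - 1))
    h[t < d] = 0.0
    # analytic mode of the gamma kernel
    peak_s = float(n - 1)
    peak = peak_s ** (n - 1) * np.exp(-peak_s) / (tau * math.factorial(n - 1)) \
        if n > 1 else 1.0 / tau
    return h / peak


def event_regressor(onsets, frame_times, params: HRFParams = HRFParams()):
    """HRF convolved with a delta train at ``onsets``, sampled at frame times.

    Computed by direct summation h(t_k - onset) over events, which is
    exact for delta trains at arbitrary (off-grid) onsets.
    """
    onsets = np.asarray(onsets, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if onsets.size == 0:
        return np.zeros(frame_times.shape)
    lags = frame_times[:, None] - onsets[None, :]
    return gamma_hrf(lags.ravel(), params).reshape(lags.shape).sum(axis=1)


def compute_pc1(series, mask=None) -> np.ndarray:
    """First principal component (time domain) of the masked voxel data.

    Each voxel's temporal mean is removed; the returned unit-norm length-n
    time course is the first right singular vector of the voxels x time
    matrix, sign-aligned to correlate positively with the global mean
    signal.
    """
    if isinstance(series, SubjectTimeSeries):
        data = series.frame_matrix().T  # voxels x time
    else:
        data = np.asarray(series, dtype=float)
        if data.ndim == 4:
            if mask is None:
                raise InvalidInputError("a mask is required with 4D input")
            data = data[np.asarray(mask, dtype=bool)]
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise InvalidInputError("need at least 2 voxels and 2 time points")
    centered = data - data.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise DegenerateInputError("series is temporally constant at every voxel")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    global_mean = centered.mean(axis=0)
    if np.dot(pc1, global_mean) < 0:
        pc1 = -pc1
    return pc1


@dataclass
class DesignMatrix:
    """Labelled n x p regressor matrix with its contrast vector."""

    values: np.ndarray
    column_roles: tuple
    contrast: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("design matrix must be 2D")
        if len(self.column_roles) != self.values.shape[1]:
            raise InvalidInputError("one role per column required")
        if len(set(self.column_roles)) != len(self.column_roles):
            raise InvalidInputError("column roles must be unique")
        if self.contrast.shape != (self.values.shape[1],):
            raise InvalidInputError("contrast length must equal column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, role: str) -> np.ndarray:
        return self.values[:, self.column_roles.index(role)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_roles))


def build_design_matrix(
    records,
    motion_trace,
    pc1,
    hrf_params: HRFParams = HRFParams(),
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    layout: str = "four_task",
    response_offset_s: float = 0.75,
) -> DesignMatrix:
    """Assemble the design matrix from trial records and nuisance series.

    Event columns are unit-peak HRF regressors for loss-feedback,
    win-feedback, cue, and response onsets (``layout='four_task'``, the
    default 11-column layout) or for loss/win feedback only
    (``layout='two_task'``, 9 columns, provided for sensitivity checks).
    Missed trials contribute to no event column.  The response onset is
    modelled at a fixed ``response_offset_s`` after the cue.
    """
    motion = np.asarray(motion_trace, dtype=float)
    pc1 = np.asarray(pc1, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise InvalidInputError(
            f"motion trace must have shape ({n_volumes}, 6), got {motion.shape}"
        )
    if pc1.shape != (n_volumes,):
        raise InvalidInputError(f"pc1 must have length {n_volumes}")
    frame_times = np.arange(n_volumes) * tr

    loss_onsets = [r.feedback_onset_s for r in records if r.outcome == "loss"]
    win_onsets = [r.feedback_onset_s for r in records if r.outcome == "win"]
    played = [r for r in records if r.outcome != "missed"]
    cue_onsets = [r.cue_onset_s for r in played]
    response_onsets = [r.cue_onset_s + response_offset_s for r in played]

    cols = [pc1] + [motion[:, j] for j in range(6)]
    cols.append(event_regressor(loss_onsets, frame_times, hrf_params))
    cols.append(event_regressor(win_onsets, frame_times, hrf_params))
    if layout == "four_task":
        roles = DEFAULT_ROLES
        cols.append(event_regressor(cue_onsets, frame_times, hrf_params))
        cols.append(event_regressor(response_onsets, frame_times, hrf_params))
    elif layout == "two_task":
        roles = DEFAULT_ROLES[:9]
    else:
        raise InvalidInputError(f"unknown layout {layout!r}")

    contrast = np.zeros(len(roles))
    contrast[roles.index("loss_feedback")] = -1.0
    contrast[roles.index("win_feedback")] = +1.0
    return DesignMatrix(np.column_stack(cols), roles, contrast)


@dataclass
class TMap:
    """Per-voxel activation index over the brain mask.

    ``values`` is NaN where the index is undefined (zero residual
    variance); those voxels are flagged in ``undefined`` rather than
    silently zeroed.
    """

    values: np.ndarray
    undefined: np.ndarray
    df: int
    mask: np.ndarray | None = None

    def to_volume(self, fill=np.nan) -> np.ndarray:
        if self.mask is None:
            raise InvalidInputError("no mask attached to this t-map")
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol


class SubjectGLM:
    """Voxel-wise general linear model for one subject.

    Parameters
    ----------
    endog : SubjectTimeSeries or ndarray
        The BOLD data; an (n, V) matrix, or a 4D array with ``mask``,
        or a :class:`SubjectTimeSeries`.
    design : DesignMatrix
    center : bool
        Temporally mean-centre the data and every regressor before
        fitting (default). The df formula n - 1 - rank(G) reflects the
        one degree of freedom spent on centring.
    """

    def __init__(self, endog, design: DesignMatrix, mask=None, center: bool = True):
        if isinstance(endog, SubjectTimeSeries):
            self.mask = endog.mask
            y = endog.frame_matrix()
        else:
            endog = np.asarray(endog, dtype=float)
            if endog.ndim == 4:
                if mask is None:
                    raise InvalidInputError("a mask is required with 4D input")
                self.mask = np.asarray(mask, dtype=bool)
                y = endog[self.mask].T
            else:
                self.mask = mask
                y = np.atleast_2d(endog)
                if y.shape[0] == 1 and y.size > 1 and design.n == y.shape[1]:
                    y = y.T
        if y.shape[0] != design.n:
            raise InvalidInputError(
                f"series length {y.shape[0]} does not match design rows {design.n}"
            )
        self.endog = y
        self.design = design
        self.center = center

    def fit(self, rank_tol: float = RANK_TOL) -> "SubjectGLMResults":
        X = self.design.values
        Y = self.endog
        n, p = X.shape
        if self.center:
            X = X - X.mean(axis=0)
            Y = Y - Y.mean(axis=0)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        keep = s > (s[0] * rank_tol if s.size and s[0] > 0 else np.inf)
        rank = int(keep.sum())
        df = n - 1 - rank
        if df < 1:
            raise DegenerateModelError(f"df = {df} < 1 (n={n}, rank={rank})")
        s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        # G = pseudo-inverse of X'X
        G = (vt.T * s_inv**2) @ vt
        uty = u.T @ Y
        beta = (vt.T * s_inv) @ uty  # = G X' Y
        rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", uty[keep], uty[keep])
        sigma2 = np.maximum(rss, 0.0) / df
        return SubjectGLMResults(self, beta, sigma2, df, rank, G, X, Y)


class SubjectGLMResults:
    """Estimates from a fitted :class:`SubjectGLM`.

    Attributes
    ----------
    params : (p, V) ndarray of beta_hat per voxel
    sigma2 : (V,) noise variance estimates
    df : residual degrees of freedom, n - 1 - rank(G)
    rank : effective rank of the design
    normalized_cov_params : G, the pseudo-inverse of X'X
    """

    def __init__(self, model, params, sigma2, df, rank, G, X, Y):
        self.model = model
        self.params = params
        self.sigma2 = sigma2
        self.df = df
        self.rank = rank
        self.normalized_cov_params = G
        self._X = X
        self._Y = Y

    @property
    def resid(self) -> np.ndarray:
        return self._Y - self._X @ self.params

    def contrast_estimable(self, contrast) -> bool:
        """True when C lies in the row space of the design."""
        C = np.asarray(contrast, dtype=float)
        A = self._X.T @ self._X
        proj = A @ (self.normalized_cov_params @ C)
        scale = max(np.linalg.norm(C), 1.0)
        return bool(np.linalg.norm(proj - C) <= 1e-8 * scale)

    def contrast_estimate(self, contrast=None) -> np.ndarray:
        """Per-voxel C' beta_hat (the contrast amplitude map)."""
        C = self._resolve_contrast(contrast)
        return C @ self.params

    def tmap(self, contrast=None) -> TMap:
        """Per-voxel activation index t_v = C'beta / sqrt(sigma2 C'GC)."""
        C = self._resolve_contrast(contrast)
        ctgc = float(C @ self.normalized_cov_params @ C)
        if ctgc <= 0:
            raise InvalidContrastError("C'GC must be positive")
        if not self.contrast_estimable(C):
            warnings.warn(
                "contrast is not estimable under the fitted (rank-deficient) "
                "design; t-map is based on the minimum-norm solution",
                stacklevel=2,
            )
        num = C @ self.params
        undefined = self.sigma2 <= 0
        denom = np.sqrt(np.where(undefined, 1.0, self.sigma2) * ctgc)
        values = np.where(undefined, np.nan, num / denom)
        return TMap(values=values, undefined=undefined, df=self.df, mask=self.model.mask)

    def _resolve_contrast(self, contrast):
        if contrast is None:
            contrast = self.model.design.contrast
        C = np.asarray(contrast, dtype=float)
        if C.shape != (self.model.design.p,):
            raise InvalidContrastError(
                f"contrast length {C.shape} does not match p={self.model.design.p}"
            )
        return C

    def summary(self) -> str:
        lines = [
            "Subject-level voxel-wise GLM",
            "=" * 34,
            f"n time points        {self._X.shape[0]:>8d}",
            f"p regressors         {self._X.shape[1]:>8d}",
            f"rank(G)              {self.rank:>8d}",
            f"df (n - 1 - rank)    {self.df:>8d}",
            f"n voxels             {self.params.shape[1]:>8d}",
            f"median sigma2        {np.median(self.sigma2):>12.4g}",
            f"contrast             {np.array2string(self.model.design.contrast, precision=0)}",
        ]
        return "\n".join(lines)


def fit_glm(series, design: DesignMatrix, mask=None, center: bool = True,
            rank_tol: float = RANK_TOL) -> SubjectGLMResults:
    """Functional wrapper: fit the voxel-wise GLM and return its results."""
    return SubjectGLM(series, design, mask=mask, center=center).fit(rank_tol=rank_tol)


def contrast_tmap(results: SubjectGLMResults, contrast=None) -> TMap:
    """Functional wrapper for :meth:`SubjectGLMResults.tmap`."""
    return results.tmap(contrast)
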