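"""Descriptive tables and correlation reports.

Descriptive rows report min/max/mean, the n-1 standard deviation and the
standard error SD/sqrt(n_valid), rounded half-away-from-zero.  Pearson
correlations use the exact t transform r * sqrt((n-2)/(1-r^2)) with
n-2 df for two-sided p-values, computed on pairwise-complete data.
Inter-cluster correlations are Bonferroni-corrected over the
k(k-1)/2 unordered pairs; cross-domain (cluster x covariate) tables are
deliberately left uncorrected and instead classify each cell's effect
size from |r| (negligible < 0.1 <= small < 0.3 <= moderate < 0.5 <= large),
the reporting convention for small exploratory samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .exceptions import InvalidInputError

DEFAULT_EFFECT_BINS = (0.1, 0.3, 0.5)
EFFECT_NAMES = ("negligible", "small", "moderate", "large")


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (2.675 -> 2.68), unlike banker's rounding."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def effect_class(r: float, bins=DEFAULT_EFFECT_BINS) -> str:
    """Classify |r| into negligible/small/moderate/large."""
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    for cut, name in zip(bins, EFFECT_NAMES):
        if a < cut:
            return name
    return EFFECT_NAMES[len(bins)]


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r, two-sided p (t transform), and n.

    Returns (nan, nan, n) when fewer than 4 complete pairs or either
    variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    xv, yv = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    sx, sy = np.sqrt((xv**2).sum()), np.sqrt((yv**2).sum())
    # zero variance up to rounding of the mean of a constant column
    x_scale = max(np.abs(x[ok]).max(), 1.0)
    y_scale = max(np.abs(y[ok]).max(), 1.0)
    if sx <= 1e-10 * x_scale or sy <= 1e-10 * y_scale:
        return np.nan, np.nan, n
    r = float(np.clip((xv * yv).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, float(np.finfo(float).tiny), n
    tval = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * t_dist.sf(abs(tval), n - 2))
    return r, max(p, np.finfo(float).tiny), n


@dataclass
class DescriptiveRow:
    name: str
    description: str
    min: float
    max: float
    mean: float
    sd: float
    se: float
    n_valid: int


def descriptive_table(
    data,
    descriptions: dict | None = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Min/Max/Mean/SD/SE table, one row per variable, in input order.

    ``data`` is a DataFrame or a mapping name -> values.  SD uses the
    n-1 denominator; SE = SD/sqrt(n_valid); all statistics are rounded
    half-away-from-zero at ``precision`` decimals.  Variables with fewer
    than two valid observations are skipped with a warning.
    """
    if isinstance(data, pd.DataFrame):
        items = [(c, data[c].to_numpy(dtype=float)) for c in data.columns]
    else:
        items = [(k, np.asarray(v, dtype=float)) for k, v in data.items()]
    descriptions = descriptions or {}
    rows = []
    for name, values in items:
        values = values[~np.isnan(values)]
        if values.size < 2:
            warnings.warn(
                f"variable {name!r} has {values.size} valid observations; skipped",
                stacklevel=2)
            continue
        sd = float(values.std(ddof=1))
        rows.append(DescriptiveRow(
            name=name,
            description=descriptions.get(name, ""),
            min=float(round_half_away(values.min(), precision)),
            max=float(round_half_away(values.max(), precision)),
            mean=float(round_half_away(values.mean(), precision)),
            sd=float(round_half_away(sd, precision)),
            se=float(round_half_away(sd / np.sqrt(values.size), precision)),
            n_valid=int(values.size),
        ))
    return pd.DataFrame([vars(r) for r in rows],
                        columns=["name", "description", "min", "max", "mean",
                                 "sd", "se", "n_valid"])


@dataclass
class CorrelationReport:
    """Pairwise correlation matrices with significance annotations."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    effect: pd.DataFrame
    family_size: int
    alpha: float = 0.05
    bonferroni: pd.DataFrame | None = None

    def long_frame(self, variable_sets: dict | None = None) -> pd.DataFrame:
        """Long-format table: one row per (row variable, column variable)."""
        variable_sets = variable_sets or {}
        rows = []
        for a in self.r.index:
            for b in self.r.columns:
                if a == b:
                    continue
                p = self.p.loc[a, b]
                rows.append({
                    "variable_set": variable_sets.get(a, ""),
                    "variable": a,
                    "cluster": b,
                    "r": self.r.loc[a, b],
                    "p": p,
                    "n_valid": self.n.loc[a, b],
                    "effect_class": self.effect.loc[a, b],
                    "significance": significance_stars(p),
                    "bonferroni_flag": bool(self.bonferroni.loc[a, b])
                    if self.bonferroni is not None else False,
                })
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _pairwise_report(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                     effect_bins) -> tuple:
    r = pd.DataFrame(np.nan, index=frame_a.columns, columns=frame_b.columns)
    p = r.copy()
    n = pd.DataFrame(0, index=frame_a.columns, columns=frame_b.columns)
    eff = pd.DataFrame("", index=frame_a.columns, columns=frame_b.columns)
    for a in frame_a.columns:
        for b in frame_b.columns:
            rv, pv, nv = pearson_with_p(frame_a[a], frame_b[b])
            r.loc[a, b], p.loc[a, b], n.loc[a, b] = rv, pv, nv
            eff.loc[a, b] = effect_class(rv, effect_bins)
    return r, p, n, eff


def intercluster_correlations(
    cluster_means: pd.DataFrame,
    alpha: float = 0.05,
    effect_bins=DEFAULT_EFFECT_BINS,
) -> CorrelationReport:
    """All pairwise Pearson correlations among cluster activation means.

    The Bonferroni family is the k(k-1)/2 unordered pairs (45 at k=10);
    a pair is flagged when p * m < alpha.  Diagonal cells are never
    tested.  Zero-variance columns yield undefined (NaN) cells.
    """
    if len(cluster_means) < 4:
        raise InvalidInputError("need at least 4 subjects")
    k = cluster_means.shape[1]
    m = k * (k - 1) // 2
    r, p, n, eff = _pairwise_report(cluster_means, cluster_means, effect_bins)
    col_scale = cluster_means.abs().max().clip(lower=1.0)
    degenerate = cluster_means.std(ddof=1) <= 1e-10 * col_scale
    np.fill_diagonal(r.values, np.where(degenerate, np.nan, 1.0))
    flags = (p * m < alpha).fillna(False)
    np.fill_diagonal(flags.values, False)
    np.fill_diagonal(p.values, np.nan)
    return CorrelationReport(r=r, p=p, n=n, effect=eff, family_size=m,
                             alpha=alpha, bonferroni=flags)


def cross_domain_correlations(
    cluster_means: pd.DataFrame,
    covariates: pd.DataFrame,
    effect_bins=DEFAULT_EFFECT_BINS,
    variable_sets: dict | None = None,
) -> tuple[CorrelationReport, pd.DataFrame]:
    """Correlate cluster means with behavioral/covariate variables.

    Subjects are aligned on the index; missing covariate entries are
    handled by pairwise-complete deletion and ``n_valid`` is recorded
    per cell.  No multiple-testing correction is applied: uncorrected
    significance stars and |r| effect-size classes are both emitted.
    Returns (report, long-format table).
    """
    common = cluster_means.index.intersection(covariates.index)
    if len(common) < 4:
        raise InvalidInputError("need at least 4 common subjects")
    cm = cluster_means.loc[common]
    cov = covariates.loc[common]
    r, p, n, eff = _pairwise_report(cov, cm, effect_bins)
    report = CorrelationReport(r=r, p=p, n=n, effect=eff,
                               family_size=r.size, bonferroni=None)
    return report, report.long_frame(variable_sets)


def correlation_heatmap(report: CorrelationReport, ax=None, cmap="RdBu_r"):
    """Render the r matrix as an annotated heatmap (matplotlib hook)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.6 * report.r.shape[1], 1 + 0.5 * report.r.shape[0]))
    im = ax.imshow(report.r.to_numpy(dtype=float), vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(report.r.shape[1]), report.r.columns, rotation=90)
    ax.set_yticks(range(report.r.shape[0]), report.r.index)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
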