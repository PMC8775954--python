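"""Population-level tables and nonparametric statistics.

Outputs mirror the population views of a morphology screen: shape-mode
frequency tables per (group, exposure time), fold-change-from-control
tables for the four geometric features, and Kruskal–Wallis tests with
Dunn's post hoc pairwise comparisons.

Fold changes use medians (all per-cell feature panels in this kind of
screen display median with interquartile range) and the statistical unit
is the individual cell pooled within a condition; per-image aggregation
is available for users concerned about pseudoreplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

FEATURES = ("perimeter_px", "area_px", "circularity", "aspect_ratio")


class DesignMappingError(ValueError):
    """A cell's image id has no row in the design table."""


class MissingControlError(ValueError):
    """No control-group cells at a required exposure time."""


@dataclass
class StatResult:
    """Kruskal–Wallis H with optional Dunn pairwise adjusted p-values."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None
    alpha: float = 0.05
    group_names: tuple = field(default_factory=tuple)


def attach_design(cells: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Join per-cell rows to (group, dose, exposure) via image_id."""
    meta = design[["image_id", "group", "dose_ug", "exposure_h"]]
    merged = cells.merge(meta, on="image_id", how="left", validate="m:1")
    orphans = merged.loc[merged["group"].isna(), "image_id"].unique()
    if len(orphans):
        raise DesignMappingError(
            f"images missing from design table: {sorted(map(str, orphans))}")
    return merged


def sm_frequencies(assignments: pd.DataFrame, design: pd.DataFrame,
                   k: int) -> pd.DataFrame:
    """Percent of cells per shape mode for each (group, exposure_h).

    Rows are observed conditions only (a condition with no cells is
    reported missing, never zero-filled); each row sums to 100 and
    carries its cell count ``n``.
    """
    merged = attach_design(assignments, design)
    rows = []
    for (group, t), sub in merged.groupby(["group", "exposure_h"], sort=True):
        n = len(sub)
        counts = sub["shape_mode"].value_counts()
        row = {"group": group, "exposure_h": t, "n": n}
        for mode in range(1, k + 1):
            row[f"SM{mode}"] = 100.0 * counts.get(mode, 0) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index(["group", "exposure_h"])


def feature_fold_change(cells: pd.DataFrame, design: pd.DataFrame,
                        features: tuple[str, ...] = FEATURES,
                        control_group: str = "healthy",
                        statistic: str = "median") -> pd.DataFrame:
    """Fold change vs the control group at matched exposure time.

    Entry = stat(feature | group, t) / stat(feature | control, t); rows
    are features, columns are (group, exposure_h).  Control-vs-control
    entries are exactly 1.
    """
    agg = {"median": np.median, "mean": np.mean}[statistic]
    merged = attach_design(cells, design)
    conditions = sorted(
        merged.groupby(["group", "exposure_h"]).groups,
        key=lambda gt: (gt[1], gt[0]))
    times = {t for _, t in conditions}
    for t in sorted(times):
        if (control_group, t) not in conditions:
            raise MissingControlError(
                f"no {control_group!r} cells at exposure {t} h")
    out = pd.DataFrame(
        index=list(features),
        columns=pd.MultiIndex.from_tuples(conditions,
                                          names=["group", "exposure_h"]),
        dtype=float)
    for feat in features:
        for group, t in conditions:
            sel = (merged["group"] == group) & (merged["exposure_h"] == t)
            ctrl = (merged["group"] == control_group) & (merged["exposure_h"] == t)
            if group == control_group:
                out.loc[feat, (group, t)] = 1.0
            else:
                out.loc[feat, (group, t)] = (agg(merged.loc[sel, feat])
                                             / agg(merged.loc[ctrl, feat]))
    return out


def kruskal_wallis(*samples, alpha: float = 0.05,
                   group_names=None) -> StatResult:
    """Kruskal–Wallis rank test across >= 2 groups.

    Tie-corrected H with a chi-square p-value on (groups - 1) degrees of
    freedom.  When every observation is identical the statistic is 0 and
    p is 1 (the tie correction would otherwise be degenerate).
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for i, s in enumerate(samples):
        if len(s) == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.ptp(pooled) == 0:
        return StatResult(0.0, 1.0, alpha=alpha,
                          group_names=tuple(group_names or
                                            range(len(samples))))
    h, p = sps.kruskal(*samples)
    return StatResult(float(h), float(p), alpha=alpha,
                      group_names=tuple(group_names or range(len(samples))))


def dunn_posthoc(samples, adjustment: str = "bonferroni",
                 group_names=None) -> pd.DataFrame:
    """Dunn's z-test on pooled ranks for all pairs of groups.

    ``z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j))`` with
    tie correction ``T = Σ(t³ − t) / (12(N − 1))``; two-sided normal
    p-values adjusted family-wise (bonferroni, holm, or none).  Returns a
    frame with one row per pair: z, p_raw, p_adj.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("Dunn's test needs at least two groups")
    names = list(group_names) if group_names is not None else list(
        range(len(samples)))
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(s) for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(samples))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    tie_corr = tie_term / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    rows = []
    for i, j in combinations(range(len(samples)), 2):
        denom = np.sqrt((var_base - tie_corr) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if adjustment == "none":
        table["p_adj"] = table["p_raw"]
    else:
        table["p_adj"] = multipletests(table["p_raw"], method=adjustment)[1]
    # family-wise adjustment never lowers a p-value
    table["p_adj"] = np.maximum(table["p_adj"], table["p_raw"])
    return table


def compare_feature(cells: pd.DataFrame, design: pd.DataFrame, feature: str,
                    exposure_h: float | None = None,
                    adjustment: str = "bonferroni") -> StatResult:
    """KW + Dunn across groups for one feature (optionally one time)."""
    merged = attach_design(cells, design)
    if exposure_h is not None:
        merged = merged[merged["exposure_h"] == exposure_h]
    groups = sorted(merged["group"].unique())
    samples = [merged.loc[merged["group"] == g, feature].dropna().to_numpy()
               for g in groups]
    res = kruskal_wallis(*samples, group_names=groups)
    res.pairwise = dunn_posthoc(samples, adjustment=adjustment,
                                group_names=groups)
    return res


def heatmap_export(table: pd.DataFrame, style: str, png_path: str | Path,
                   csv_path: str | Path) -> None:
    """Write the numeric table as CSV and a styled heatmap PNG.

    ``style='fold_change'`` uses a per-row two-color-to-white scale (the
    row maximum maps to white); ``style='frequency'`` uses a global
    red-yellow-green scale.  NaN cells render in gray.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table.to_csv(csv_path)
    values = table.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.6 * values.shape[1] + 2),
                 max(2.5, 0.5 * values.shape[0] + 1.5)))
    if style == "fold_change":
        # per-row normalization: row max -> 1 (rendered white at cmap top)
        row_max = np.nanmax(values, axis=1, keepdims=True)
        row_min = np.nanmin(values, axis=1, keepdims=True)
        span = np.where(row_max > row_min, row_max - row_min, 1.0)
        norm = (values - row_min) / span
        cmap = matplotlib.colormaps["Blues_r"].copy()
        cmap.set_bad("0.5")
        ax.imshow(norm, cmap=cmap, vmin=0, vmax=1, aspect="auto")
    elif style == "frequency":
        cmap = matplotlib.colormaps["RdYlGn"].copy()
        cmap.set_bad("0.5")
        ax.imshow(values, cmap=cmap, aspect="auto")
    else:
        raise ValueError(f"unknown heatmap style {style!r}")
    ax.set_yticks(range(values.shape[0]), [str(i) for i in table.index])
    ax.set_xticks(range(values.shape[1]),
                  [str(c) for c in table.columns], rotation=45, ha="right")
    for (i, j), v in np.ndenumerate(values):
        if np.isfinite(v):
            ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=7)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
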