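"""Pairwise spatial-proximity statistics between cell clusters.

For each ordered pair of cell clusters (a, b) within an ROI, the interaction
score is the average, over cluster-a cells, of the number of cluster-b cells
lying within the analysis radius.  Group differences (e.g. hilar N1 nodes of
higher-stage patients versus all remaining nodes) are assessed per pair with a
two-sided Wilcoxon rank-sum test and Benjamini-Hochberg FDR control across
the family of pairs.

The analysis unit for testing is the lymph node: per-ROI scores are averaged
per LN before testing (each point in the published comparisons is one LN);
per-ROI testing is available via ``unit="roi"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import StudyDesign
from .spatial_graph import SpatialGraph, neighborhood_composition

__all__ = [
    "pairwise_mean_neighbor_counts",
    "compare_groups",
    "higher_n1_contrast",
    "aggregate_roi_to_ln",
]


def pairwise_mean_neighbor_counts(
    cells: pd.DataFrame,
    graph: SpatialGraph,
    label_column: str = "cluster",
    vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Mean number of cluster-b neighbors per cluster-a cell, all ordered pairs.

    Returns a long-form frame (roi_id, cluster_a, cluster_b, mean_count,
    n_cells_a).  Pairs whose cluster_a has no cells in the ROI are omitted
    (missing, not zero); a=b pairs are included.  The bookkeeping identity
    |A| * mean(b around a) = |B| * mean(a around b) = number of within-radius
    A-B pairs holds exactly.
    """
    nbhd = neighborhood_composition(graph, cells, label_column, vocabulary)
    vocab = list(nbhd.columns)
    own = cells[label_column].astype(str).to_numpy()
    rows = []
    for a in vocab:
        in_a = own == a
        n_a = int(in_a.sum())
        if n_a == 0:
            continue
        means = nbhd.loc[in_a].mean(axis=0)
        for b in vocab:
            rows.append(
                {
                    "roi_id": graph.roi_id,
                    "cluster_a": a,
                    "cluster_b": b,
                    "mean_count": float(means[b]),
                    "n_cells_a": n_a,
                }
            )
    return pd.DataFrame(rows, columns=["roi_id", "cluster_a", "cluster_b", "mean_count", "n_cells_a"])


def higher_n1_contrast(designs: list[StudyDesign]) -> dict[str, str]:
    """Map each LN to 'higher_N1' (N1 station, higher-stage patient) or 'rest'."""
    return {
        d.ln_id: "higher_N1" if (d.station == "N1" and d.stage_group == "higher") else "rest"
        for d in designs
    }


def aggregate_roi_to_ln(
    values: pd.DataFrame,
    designs: list[StudyDesign],
    value_column: str = "value",
    metric_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Average per-ROI metric values to one value per LN and metric."""
    roi_to_ln = {roi: d.ln_id for d in designs for roi in d.roi_ids}
    orphan = set(values["roi_id"].astype(str)) - set(roi_to_ln)
    if orphan:
        raise ValueError(f"ROIs missing from the design: {sorted(orphan)}")
    df = values.copy()
    df["unit_id"] = df["roi_id"].astype(str).map(roi_to_ln)
    keys = ["unit_id"] + (metric_columns or [])
    out = df.groupby(keys, as_index=False)[value_column].mean()
    return out


@dataclass
class GroupTestResult:
    metric: str
    n_a: int
    n_b: int
    wilcoxon_p: float
    fdr_q: float
    direction: int
    median_a: float
    median_b: float


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with tie correction otherwise."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one unit")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_groups(
    unit_values: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    metric_column: str = "metric",
    value_column: str = "value",
) -> pd.DataFrame:
    """Rank-sum test per metric between two groups of analysis units.

    Parameters
    ----------
    unit_values : long-form frame with columns (unit_id, metric, value), one
        value per unit and metric.
    groups : mapping unit_id -> group label.
    group_a, group_b : the two group labels to contrast (direction is the
        sign of median(a) - median(b)).

    Returns a frame with one row per metric: two-sided Wilcoxon rank-sum p,
    Benjamini-Hochberg q across the metric family, group sizes, medians and
    direction.  Identical groups give p = 1; a single-metric family gives
    q = p.
    """
    missing = set(unit_values["unit_id"].astype(str)) - set(groups)
    if missing:
        raise ValueError(f"units without a group assignment: {sorted(missing)}")
    rows = []
    for metric, grp in unit_values.groupby(metric_column, sort=True):
        g = grp["unit_id"].astype(str).map(groups)
        a = grp.loc[g == group_a, value_column].to_numpy(dtype=float)
        b = grp.loc[g == group_b, value_column].to_numpy(dtype=float)
        p = _rank_sum_p(a, b)
        ma, mb = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "metric": metric,
                "n_a": len(a),
                "n_b": len(b),
                "wilcoxon_p": p,
                "median_a": ma,
                "median_b": mb,
                "direction": int(np.sign(ma - mb)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = multipletests(out["wilcoxon_p"], method="fdr_bh")[1]
    else:
        out["fdr_q"] = pd.Series(dtype=float)
    return out
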