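"""Per-lymph-node composition tables and differential composition.

All ROIs of a lymph node are pooled into one sample; labels (cell clusters or
spatial niches) are summarized as per-LN proportions.  Differential
composition across LN groups uses the rank-sum/Benjamini-Hochberg path — a
deliberately simple nonparametric stand-in for model-based compositional
regression: no patient-level random effect is modelled, the LN is the unit,
and output rows are annotated METHOD=wilcoxon-standin to make the
simplification visible downstream.
"""

from __future__ import annotations

import pandas as pd

from .interactions import compare_groups
from .io_formats import StudyDesign

__all__ = ["composition_per_ln", "differential_composition"]

METHOD_LABEL = "wilcoxon-standin"


def composition_per_ln(
    cells: pd.DataFrame,
    designs: list[StudyDesign],
    label_column: str = "cluster",
) -> pd.DataFrame:
    """Pooled per-LN label proportions.

    Returns (unit_id, label, n_cells, proportion); proportions per LN sum
    to 1.  A cell whose ROI is not in the design raises.
    """
    roi_to_ln = {roi: d.ln_id for d in designs for roi in d.roi_ids}
    rois = cells["roi_id"].astype(str)
    orphan = set(rois) - set(roi_to_ln)
    if orphan:
        raise ValueError(f"cells from ROIs outside the design: {sorted(orphan)}")
    df = cells.copy()
    df["unit_id"] = rois.map(roi_to_ln)
    df["_label"] = df[label_column].astype(str)
    counts = df.groupby(["unit_id", "_label"], sort=True).size().rename("n_cells").reset_index()
    totals = counts.groupby("unit_id")["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    # every label appears for every LN (zero rows included) so group tests
    # see complete per-unit vectors
    labels = sorted(df["_label"].unique())
    units = sorted(df["unit_id"].unique())
    full = pd.MultiIndex.from_product([units, labels], names=["unit_id", "_label"])
    counts = (
        counts.set_index(["unit_id", "_label"])
        .reindex(full, fill_value=0)
        .reset_index()
        .rename(columns={"_label": "label"})
    )
    counts["proportion"] = counts["proportion"].astype(float)
    return counts


def differential_composition(
    table: pd.DataFrame,
    groups: dict[str, str],
    group_a: str = "higher_N1",
    group_b: str = "rest",
) -> pd.DataFrame:
    """Rank-sum/BH test of per-LN proportions per label across a contrast.

    ``table`` is the output of :func:`composition_per_ln`.  Requires >= 2 LNs
    per group.  Output carries a ``method`` column labelling the stand-in.
    """
    for g in (group_a, group_b):
        n = sum(1 for u in table["unit_id"].unique() if groups.get(str(u)) == g)
        if n < 2:
            raise ValueError(f"group {g!r} has {n} lymph node(s); need >= 2")
    unit_values = table.rename(columns={"label": "metric", "proportion": "value"})[
        ["unit_id", "metric", "value"]
    ]
    out = compare_groups(unit_values, groups, group_a, group_b)
    out["method"] = METHOD_LABEL
    return out
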