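"""End-to-end cohort analysis: graphs -> niches -> follicles -> group tests.

``run_cohort_analysis`` is the in-memory engine: it takes a pooled,
cluster-labelled cell table plus the study design and carries it through
neighborhood construction, niche clustering, follicle detection with
decortication scoring, and the two group contrasts (differential niche
composition and decortication metrics).  The CLI's ``run`` subcommand and the
acceptance script are thin wrappers around it.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import composition_per_ln, differential_composition
from .follicles import (
    FollicleConfig,
    Region,
    analyze_follicles,
    follicle_cluster_enrichment,
)
from .interactions import compare_groups, higher_n1_contrast
from .io_formats import StudyDesign
from .niches import NicheModel, fit_niches, map_niche_roles, niche_profiles
from .spatial_graph import build_radius_graph, neighborhood_composition

__all__ = ["CohortResults", "run_cohort_analysis", "write_manifest"]


@dataclass
class CohortResults:
    """Everything the cohort pipeline computed."""

    cells: pd.DataFrame  # with 'niche' column attached
    niche_model: NicheModel
    niche_roles: dict[int, str]
    follicle_config: FollicleConfig
    gc_regions: dict[str, list[Region]]
    follicle_regions: dict[str, list[Region]]
    decortication_per_ln: pd.DataFrame
    decortication_tests: pd.DataFrame
    niche_composition: pd.DataFrame
    niche_tests: pd.DataFrame
    follicle_enrichment_tests: pd.DataFrame
    mean_neighbors_per_cell: float
    groups: dict[str, str] = field(default_factory=dict)

    def follicle_class_counts(self) -> pd.DataFrame:
        rows = []
        for roi_id, regions in self.follicle_regions.items():
            for r in regions:
                rows.append({"roi_id": roi_id, "follicle_class": r.follicle_class})
        if not rows:
            return pd.DataFrame(columns=["roi_id", "follicle_class"])
        return pd.DataFrame(rows)


def run_cohort_analysis(
    cells: pd.DataFrame,
    designs: list[StudyDesign],
    seed: int = 0,
    radius_um: float = 20.0,
    k_niches: int = 12,
    gc_cluster_labels: set[str] = frozenset({"GC-B"}),
    mz_cluster_labels: set[str] = frozenset({"mantle-B"}),
    min_region_cells: int = 20,
    decortication_threshold: float = 0.25,
) -> CohortResults:
    """Run the full spatial analysis over a labelled multi-LN cell table.

    Niches are fit once over the pooled neighborhood matrix of all ROIs, then
    mapped to GC / mantle-zone roles by their member composition
    (``gc_cluster_labels`` / ``mz_cluster_labels`` name the cell clusters that
    define each role).  Follicles are detected per ROI; decortication metrics
    are averaged per LN and contrasted between higher-stage-N1 nodes and the
    rest, as is per-LN niche composition.
    """
    cells = cells.reset_index(drop=True)
    vocabulary = sorted(map(str, cells["cluster"].unique()))
    nbhd_parts = []
    total_degree = 0
    for roi_id, roi_cells in cells.groupby("roi_id", sort=True):
        graph = build_radius_graph(roi_cells, radius_um)
        nbhd = neighborhood_composition(graph, roi_cells, "cluster", vocabulary)
        total_degree += 2 * graph.n_edges
        nbhd_parts.append(nbhd)
    nbhd_all = pd.concat(nbhd_parts).sort_index()

    model, niche_labels = fit_niches(nbhd_all, k=k_niches, seed=seed)
    cells = cells.copy()
    cells["niche"] = niche_labels
    model.niche_profiles = niche_profiles(cells, niche_labels, k=k_niches)
    roles = map_niche_roles(model.niche_profiles, set(gc_cluster_labels), set(mz_cluster_labels))
    gc_niches = {n for n, r in roles.items() if r == "GC"}
    mz_niches = {n for n, r in roles.items() if r == "MZ"}
    config = FollicleConfig(
        gc_niche_set=gc_niches,
        mz_niche_set=mz_niches,
        connect_radius_um=radius_um,
        min_region_cells=min_region_cells,
        decortication_threshold=decortication_threshold,
    )

    gc_regions: dict[str, list[Region]] = {}
    follicle_regions: dict[str, list[Region]] = {}
    deco_rows = []
    for roi_id, roi_cells in cells.groupby("roi_id", sort=True):
        gcs, follicles = analyze_follicles(roi_cells, config)
        gc_regions[str(roi_id)] = gcs
        follicle_regions[str(roi_id)] = follicles
        for r in follicles:
            deco_rows.append(
                {
                    "roi_id": str(roi_id),
                    "region_id": r.region_id,
                    "n_cells": r.n_cells,
                    "follicle_class": r.follicle_class,
                    "mz_fraction_around_gc": r.mz_fraction_around_gc,
                    "mz_fraction_of_follicle": r.mz_fraction_of_follicle,
                }
            )
    deco = pd.DataFrame(
        deco_rows,
        columns=[
            "roi_id", "region_id", "n_cells", "follicle_class",
            "mz_fraction_around_gc", "mz_fraction_of_follicle",
        ],
    )

    roi_to_ln = {roi: d.ln_id for d in designs for roi in d.roi_ids}
    deco["ln_id"] = deco["roi_id"].map(roi_to_ln)
    per_ln = (
        deco.groupby("ln_id")[["mz_fraction_around_gc", "mz_fraction_of_follicle"]]
        .mean()
        .reset_index()
    )

    groups = higher_n1_contrast(designs)
    unit_values = per_ln.melt(id_vars="ln_id", var_name="metric", value_name="value").rename(
        columns={"ln_id": "unit_id"}
    ).dropna(subset=["value"])
    deco_tests = compare_groups(unit_values, groups, "higher_N1", "rest")

    niche_comp = composition_per_ln(cells, designs, label_column="niche")
    niche_tests = differential_composition(niche_comp, groups)

    cells_by_roi = {str(roi): grp for roi, grp in cells.groupby("roi_id", sort=True)}
    enrichment = follicle_cluster_enrichment(
        cells_by_roi, follicle_regions, designs, groups
    )

    return CohortResults(
        cells=cells,
        niche_model=model,
        niche_roles=roles,
        follicle_config=config,
        gc_regions=gc_regions,
        follicle_regions=follicle_regions,
        decortication_per_ln=per_ln,
        decortication_tests=deco_tests,
        niche_composition=niche_comp,
        niche_tests=niche_tests,
        follicle_enrichment_tests=enrichment,
        mean_neighbors_per_cell=total_degree / max(len(cells), 1),
        groups=groups,
    )


def write_manifest(path: str | Path, config: dict, outputs: list[str]) -> None:
    """Record the resolved configuration, library versions, and outputs."""
    import sklearn
    import scipy

    manifest = {
        "config": config,
        "outputs": outputs,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
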