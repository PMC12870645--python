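"""Germinal-center and B-cell-follicle detection with decortication scoring.

Germinal centers (GC) are detected as densely interconnected groups of cells
from the GC niche set; whole follicles use the superset of GC plus mantle-zone
(MZ) niches.  "Densely interconnected" is operationalized as connected
components of the within-radius graph restricted to the target niches, with a
minimum component size.

Decortication ("removal of the bark") is the loss of the mantle-zone ring
around a germinal center.  It is scored as the fraction of MZ-niche cells
among the non-GC cells lying within the analysis radius of any GC member:
intact secondary follicles score high, decorticated follicles low.  Follicles
are classified dormant (no GC-niche core), decorticated (GC core but
perigerminal MZ fraction below threshold), or active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .interactions import compare_groups
from .io_formats import StudyDesign

__all__ = [
    "FollicleConfig",
    "Region",
    "detect_niche_regions",
    "mz_fraction_around_gc",
    "mz_fraction_of_follicle",
    "classify_follicle",
    "analyze_follicles",
    "perifollicular_composition",
    "follicle_cluster_enrichment",
]


@dataclass
class FollicleConfig:
    """Niche sets and geometric knobs for follicle analysis.

    Defaults mirror the niche taxonomy of the motivating dataset: niche 23 is
    the germinal-center niche and niches 10/13/15/21 the mantle-zone niches;
    the connection and perigerminal radius is the 20 um analysis radius and the
    perifollicular band is 100 um.  ``min_region_cells`` and
    ``decortication_threshold`` have no upstream-stated values and are exposed
    for sensitivity analysis.
    """

    gc_niche_set: frozenset = frozenset({23})
    mz_niche_set: frozenset = frozenset({10, 13, 15, 21})
    follicle_niche_set: frozenset | None = None
    connect_radius_um: float = 20.0
    min_region_cells: int = 20
    decortication_threshold: float = 0.25
    perifollicular_radius_um: float = 100.0

    def __post_init__(self) -> None:
        self.gc_niche_set = frozenset(self.gc_niche_set)
        self.mz_niche_set = frozenset(self.mz_niche_set)
        if self.follicle_niche_set is None:
            self.follicle_niche_set = self.gc_niche_set | self.mz_niche_set
        self.follicle_niche_set = frozenset(self.follicle_niche_set)
        if self.gc_niche_set & self.mz_niche_set:
            raise ValueError("GC and MZ niche sets must be disjoint")
        if not self.gc_niche_set <= self.follicle_niche_set:
            raise ValueError("GC niches must be a subset of the follicle niche set")
        if self.connect_radius_um <= 0 or self.perifollicular_radius_um <= 0:
            raise ValueError("radii must be positive")
        if not (0.0 < self.decortication_threshold < 1.0):
            raise ValueError("decortication_threshold must be in (0, 1)")


@dataclass
class Region:
    """A detected tissue region: a GC or a whole follicle."""

    region_id: str
    roi_id: str
    kind: str  # "GC" or "follicle"
    member_ids: np.ndarray
    mz_fraction_around_gc: float | None = None
    mz_fraction_of_follicle: float | None = None
    follicle_class: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.member_ids)


def _niche_series(cells: pd.DataFrame, niche_labels=None) -> pd.Series:
    if niche_labels is not None:
        s = pd.Series(np.asarray(niche_labels), index=cells.index)
    elif "niche" in cells.columns:
        s = cells["niche"]
    else:
        raise ValueError("no niche labels: pass niche_labels or a 'niche' column")
    if s.isna().any():
        raise ValueError("every cell needs a niche label")
    return s


def detect_niche_regions(
    cells: pd.DataFrame,
    target_niches,
    config: FollicleConfig | None = None,
    niche_labels=None,
    kind: str = "follicle",
) -> list[Region]:
    """Connected components of target-niche cells within the connect radius.

    Components smaller than ``min_region_cells`` are discarded.  Cells of one
    ROI only; regions are ordered by minimum member cell id for determinism.
    """
    config = config or FollicleConfig()
    niche = _niche_series(cells, niche_labels)
    target = set(target_niches)
    in_target = niche.isin(target).to_numpy()
    sub = cells.loc[in_target]
    if len(sub) == 0:
        return []
    rois = sub["roi_id"].unique()
    if len(rois) > 1:
        raise ValueError("detect_niche_regions expects cells of a single ROI")
    roi_id = str(rois[0])
    xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=config.connect_radius_um, output_type="ndarray")
    n = len(sub)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    ids = sub["cell_id"].to_numpy()
    regions = []
    for c in range(n_comp):
        members = ids[comp == c]
        if len(members) >= config.min_region_cells:
            regions.append(members)
    regions.sort(key=lambda m: m.min())
    return [
        Region(
            region_id=f"{roi_id}:{kind}:{i}",
            roi_id=roi_id,
            kind=kind,
            member_ids=np.sort(m),
        )
        for i, m in enumerate(regions)
    ]


def _within_radius_of(
    cells: pd.DataFrame, member_ids: np.ndarray, radius: float
) -> np.ndarray:
    """Boolean mask over ``cells``: within ``radius`` of any member, excluding members."""
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    is_member = cells["cell_id"].isin(member_ids).to_numpy()
    member_xy = xy[is_member]
    tree = cKDTree(member_xy)
    dist, _ = tree.query(xy, k=1)
    return (dist <= radius) & ~is_member


def mz_fraction_around_gc(
    cells: pd.DataFrame,
    gc_region: Region,
    config: FollicleConfig | None = None,
    niche_labels=None,
) -> tuple[float, dict]:
    """Fraction of MZ-niche cells among non-GC cells near the GC boundary.

    Numerator: cells with an MZ niche lying within the connect radius of any
    GC member (and not GC members themselves).  Denominator: all such non-GC
    cells.  An empty neighborhood (0/0) is reported as 0.0 with a flag.
    """
    config = config or FollicleConfig()
    if gc_region.n_cells == 0:
        raise ValueError("empty GC region")
    niche = _niche_series(cells, niche_labels)
    near = _within_radius_of(cells, gc_region.member_ids, config.connect_radius_um)
    denom = int(near.sum())
    if denom == 0:
        return 0.0, {"n_near": 0, "n_mz": 0, "empty_neighborhood": True}
    is_mz = niche.isin(config.mz_niche_set).to_numpy()
    num = int((near & is_mz).sum())
    return num / denom, {"n_near": denom, "n_mz": num, "empty_neighborhood": False}


def mz_fraction_of_follicle(
    cells: pd.DataFrame,
    follicle_region: Region,
    config: FollicleConfig | None = None,
    niche_labels=None,
) -> float:
    """Fraction of the follicle's own member cells carrying an MZ niche."""
    config = config or FollicleConfig()
    if follicle_region.n_cells == 0:
        raise ValueError("empty follicle region")
    niche = _niche_series(cells, niche_labels)
    members = cells["cell_id"].isin(follicle_region.member_ids).to_numpy()
    is_mz = niche.isin(config.mz_niche_set).to_numpy()
    return float((members & is_mz).sum() / members.sum())


def classify_follicle(
    region: Region,
    config: FollicleConfig | None = None,
    member_niches=None,
) -> str:
    """dormant (no GC-niche members) / decorticated (perigerminal MZ fraction
    below threshold) / active."""
    config = config or FollicleConfig()
    if member_niches is None:
        raise ValueError("member_niches (niche label per member cell) is required")
    member_niches = pd.Series(list(member_niches))
    has_gc = member_niches.isin(config.gc_niche_set).any()
    if not has_gc:
        return "dormant"
    if region.mz_fraction_around_gc is None:
        raise ValueError("mz_fraction_around_gc must be computed before classification")
    if region.mz_fraction_around_gc < config.decortication_threshold:
        return "decorticated"
    return "active"


def analyze_follicles(
    cells: pd.DataFrame,
    config: FollicleConfig | None = None,
    niche_labels=None,
) -> tuple[list[Region], list[Region]]:
    """Detect, score, and classify GCs and follicles in one ROI's cells.

    Returns (gc_regions, follicle_regions); each follicle carries both
    decortication metrics and a class.  The perigerminal MZ fraction of a
    follicle is taken from its own GC-niche members (dormant follicles have
    none and get no GC-side fraction).
    """
    config = config or FollicleConfig()
    niche = _niche_series(cells, niche_labels)
    gc_regions = detect_niche_regions(
        cells, config.gc_niche_set, config, niche_labels=niche, kind="GC"
    )
    follicle_regions = detect_niche_regions(
        cells, config.follicle_niche_set, config, niche_labels=niche, kind="follicle"
    )
    for region in follicle_regions:
        members = cells["cell_id"].isin(region.member_ids)
        member_niches = niche[members]
        region.mz_fraction_of_follicle = mz_fraction_of_follicle(
            cells, region, config, niche_labels=niche
        )
        gc_member_ids = cells.loc[
            members & niche.isin(config.gc_niche_set).to_numpy(), "cell_id"
        ].to_numpy()
        if len(gc_member_ids):
            core = Region(
                region_id=region.region_id + ":core",
                roi_id=region.roi_id,
                kind="GC",
                member_ids=gc_member_ids,
            )
            frac, info = mz_fraction_around_gc(cells, core, config, niche_labels=niche)
            region.mz_fraction_around_gc = frac
            if info["empty_neighborhood"]:
                region.flags.append("empty_perigerminal_neighborhood")
        region.follicle_class = classify_follicle(region, config, member_niches)
    for gc in gc_regions:
        frac, info = mz_fraction_around_gc(cells, gc, config, niche_labels=niche)
        gc.mz_fraction_around_gc = frac
        if info["empty_neighborhood"]:
            gc.flags.append("empty_perigerminal_neighborhood")
    return gc_regions, follicle_regions


def perifollicular_composition(
    cells: pd.DataFrame,
    follicle_regions: list[Region],
    config: FollicleConfig | None = None,
    niche_labels=None,
) -> pd.DataFrame:
    """Niche proportions among non-member cells within the perifollicular band.

    The band is all cells within ``perifollicular_radius_um`` of any member of
    any listed follicle, excluding the members themselves.  Returns a
    one-row-per-niche frame (niche, n_cells, proportion); an empty band gives
    an empty frame.
    """
    config = config or FollicleConfig()
    if not follicle_regions:
        raise ValueError("need at least one follicle region")
    niche = _niche_series(cells, niche_labels)
    all_members = np.concatenate([r.member_ids for r in follicle_regions])
    near = _within_radius_of(cells, all_members, config.perifollicular_radius_um)
    band = niche[near]
    if len(band) == 0:
        return pd.DataFrame(columns=["niche", "n_cells", "proportion"])
    counts = band.value_counts().sort_index()
    return pd.DataFrame(
        {
            "niche": counts.index,
            "n_cells": counts.to_numpy(),
            "proportion": counts.to_numpy() / counts.sum(),
        }
    )


def follicle_cluster_enrichment(
    cells_by_roi: dict[str, pd.DataFrame],
    regions_by_roi: dict[str, list[Region]],
    designs: list[StudyDesign],
    groups: dict[str, str],
    group_a: str = "higher_N1",
    group_b: str = "rest",
    label_column: str = "cluster",
) -> pd.DataFrame:
    """Which cell clusters are enriched inside follicles of one LN group.

    Per LN, the within-follicle proportion of each cluster label (pooled over
    that LN's follicle members across ROIs) is compared across the contrast
    with the rank-sum/BH path.  Clusters absent from every follicle test at
    p = 1 with zero proportions.
    """
    roi_to_ln = {roi: d.ln_id for d in designs for roi in d.roi_ids}
    vocab = sorted(
        {str(v) for cells in cells_by_roi.values() for v in cells[label_column].unique()}
    )
    per_ln_counts: dict[str, pd.Series] = {}
    for roi_id, regions in regions_by_roi.items():
        if roi_id not in roi_to_ln:
            raise ValueError(f"ROI {roi_id!r} missing from the design")
        ln = roi_to_ln[roi_id]
        cells = cells_by_roi[roi_id]
        member_ids = (
            np.concatenate([r.member_ids for r in regions]) if regions else np.empty(0)
        )
        members = cells.loc[cells["cell_id"].isin(member_ids)]
        counts = members[label_column].astype(str).value_counts().reindex(vocab, fill_value=0)
        per_ln_counts[ln] = per_ln_counts.get(ln, pd.Series(0, index=vocab)) + counts
    rows = []
    for ln, counts in per_ln_counts.items():
        total = counts.sum()
        for label in vocab:
            rows.append(
                {
                    "unit_id": ln,
                    "metric": label,
                    "value": counts[label] / total if total > 0 else 0.0,
                }
            )
    unit_values = pd.DataFrame(rows)
    return compare_groups(unit_values, groups, group_a, group_b)
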