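"""Synthetic lymph-node tissue maps with planted ground truth.

The generator emulates the architecture of a cortical/paracortical lymph-node
ROI at 1 um/pixel: circular B-cell follicles with a proliferating
germinal-center (GC) core, a mantle-zone annulus of naive B cells, and a thin
fibroblastic-reticular-cell (FRC) boundary ring, embedded in a paracortex of
T cells and myeloid populations.  Each compartment is a homogeneous Poisson
point process over its geometric support.

Two disease-relevant knobs are planted with recorded ground truth:

* ``decortication_level`` in [0, 1] thins the mantle by removing an angular
  sector of that fraction (0 = intact ring, 1 = mantle absent), which is how
  follicle "decortication" is modelled geometrically.
* ``infiltration_rate`` routes a fraction of suppressive myeloid cells into
  follicle interiors instead of the paracortex.

``generate_cohort`` builds multi-LN two-arm cohorts with arm-specific
parameters for group-comparison studies; ``render_image`` turns a cell map
into a multichannel image plus segmentation mask so the pixel and
quantification stages can be exercised end-to-end.

All randomness flows from the seed passed to each function; the same seed
yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ChannelImage, PanelTable, StudyDesign

__all__ = [
    "TissueSimParams",
    "GroundTruth",
    "generate_tissue",
    "generate_cohort",
    "render_image",
    "default_panel",
    "COMPARTMENTS",
]

COMPARTMENTS = (
    "GC-B",
    "mantle-B",
    "FRC-boundary",
    "paracortex-T",
    "suppressive-myeloid",
    "mregDC-like",
    "Treg-like",
)

_DEFAULT_DENSITIES = {
    # cells per mm^2 of the compartment's own support
    "GC-B": 6000.0,
    "mantle-B": 8000.0,
    "FRC-boundary": 2000.0,
    "paracortex-T": 2500.0,
    "suppressive-myeloid": 400.0,
    "mregDC-like": 150.0,
    "Treg-like": 300.0,
}


@dataclass
class TissueSimParams:
    """Geometry, densities, and planted-effect knobs for one synthetic ROI.

    Defaults reflect a ~1 mm^2 ROI with three secondary follicles of 120 um
    GC radius and a 40 um mantle, at densities giving a few thousand cells
    per ROI.
    """

    roi_size_um: tuple[float, float] = (1000.0, 1000.0)
    n_follicles: int = 3
    follicle_radius_um: float = 120.0
    mantle_width_um: float = 40.0
    frc_width_um: float = 10.0
    decortication_level: float = 0.0
    infiltration_rate: float = 0.05
    cell_density_per_mm2: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    follicle_kinds: list | None = None  # per-follicle "secondary" | "primary"
    cell_radius_um: float = 4.0
    marker_noise_sd: float = 0.5
    n_hot_pixels: int = 0

    def __post_init__(self) -> None:
        if self.follicle_radius_um <= 0 or self.mantle_width_um <= 0:
            raise ValueError("follicle radius and mantle width must be positive")
        if not (0.0 <= self.decortication_level <= 1.0):
            raise ValueError("decortication_level must be in [0, 1]")
        if not (0.0 <= self.infiltration_rate <= 1.0):
            raise ValueError("infiltration_rate must be in [0, 1]")
        if any(v <= 0 for v in self.cell_density_per_mm2.values()):
            raise ValueError("densities must be positive")

    @property
    def outer_radius_um(self) -> float:
        return self.follicle_radius_um + self.mantle_width_um + self.frc_width_um


@dataclass
class GroundTruth:
    """What was planted: per-follicle geometry/membership and arm effects."""

    follicles: list[dict] = field(default_factory=list)
    compartment_counts: dict = field(default_factory=dict)
    planted_effects: dict = field(default_factory=dict)
    hot_pixels: dict = field(default_factory=dict)  # roi_id -> list[(row, col)]


def _place_follicle_centers(params: TissueSimParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping follicle centers, or raise."""
    w, h = params.roi_size_um
    r = params.outer_radius_um
    if params.n_follicles == 0:
        return np.empty((0, 2))
    if 2 * r > min(w, h):
        raise ValueError(
            f"follicles of outer radius {r} um cannot fit a {w}x{h} um ROI; "
            "reduce the radius or enlarge the ROI"
        )
    centers: list[np.ndarray] = []
    min_sep = 2 * r + 10.0
    for _ in range(20000):
        if len(centers) == params.n_follicles:
            break
        cand = rng.uniform([r, r], [w - r, h - r])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < params.n_follicles:
        raise ValueError(
            f"could only place {len(centers)} of {params.n_follicles} follicles; "
            "request fewer or smaller follicles"
        )
    return np.array(centers)


def _poisson_disc(
    rng: np.random.Generator, center: np.ndarray, r_in: float, r_out: float,
    density_mm2: float, arc: tuple[float, float] | None = None,
) -> np.ndarray:
    """Uniform Poisson points in an annulus (or disc when r_in = 0).

    ``arc=(theta0, width)`` restricts to the kept angular arc of that width
    starting at theta0 (used for decorticated mantles).
    """
    frac = 1.0 if arc is None else arc[1] / (2 * math.pi)
    area_mm2 = math.pi * (r_out**2 - r_in**2) / 1e6 * frac
    n = rng.poisson(density_mm2 * area_mm2)
    if n == 0:
        return np.empty((0, 2))
    # area-uniform radius, uniform angle over the kept arc
    u = rng.uniform(size=n)
    radius = np.sqrt(r_in**2 + u * (r_out**2 - r_in**2))
    if arc is None:
        theta = rng.uniform(0.0, 2 * math.pi, size=n)
    else:
        theta = arc[0] + rng.uniform(0.0, arc[1], size=n)
    return center + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def _poisson_rect(
    rng: np.random.Generator, size: tuple[float, float], density_mm2: float,
    exclude_centers: np.ndarray, exclude_radius: float,
) -> np.ndarray:
    """Poisson points over the ROI rectangle minus discs around the centers."""
    w, h = size
    total_area = w * h / 1e6
    if len(exclude_centers):
        total_area -= len(exclude_centers) * math.pi * exclude_radius**2 / 1e6
    total_area = max(total_area, 0.0)
    n = rng.poisson(density_mm2 * total_area)
    pts: list[np.ndarray] = []
    got = 0
    while got < n:
        batch = rng.uniform([0, 0], [w, h], size=(max(2 * (n - got), 64), 2))
        if len(exclude_centers):
            d = np.min(
                np.linalg.norm(batch[:, None, :] - exclude_centers[None], axis=2), axis=1
            )
            batch = batch[d >= exclude_radius]
        take = batch[: n - got]
        pts.append(take)
        got += len(take)
    return np.concatenate(pts) if pts else np.empty((0, 2))


def generate_tissue(
    params: TissueSimParams, seed: int, roi_id: str = "roi1"
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one ROI's cell map plus its ground truth.

    The returned cell table has columns cell_id, roi_id, x_um, y_um, cluster,
    compartment (cluster equals the true compartment label).  Cells are in
    generation order with ids 1..n.
    """
    rng = np.random.default_rng(seed)
    centers = _place_follicle_centers(params, rng)
    kinds = params.follicle_kinds or ["secondary"] * params.n_follicles
    if len(kinds) != params.n_follicles:
        raise ValueError("follicle_kinds length must equal n_follicles")
    dens = params.cell_density_per_mm2
    r_gc = params.follicle_radius_um
    r_mz = r_gc + params.mantle_width_um
    r_frc = r_mz + params.frc_width_um

    xs: list[np.ndarray] = []
    comps: list[np.ndarray] = []
    truth = GroundTruth()
    next_id = 1

    def emit(points: np.ndarray, compartment: str) -> np.ndarray:
        nonlocal next_id
        ids = np.arange(next_id, next_id + len(points))
        next_id += len(points)
        xs.append(points)
        comps.append(np.repeat(compartment, len(points)))
        return ids

    for i, (center, kind) in enumerate(zip(centers, kinds)):
        level = params.decortication_level
        if kind == "primary":
            # dormant follicle: mantle-type B cells fill the whole disc, no GC
            gc_ids = np.empty(0, dtype=int)
            mz_pts = _poisson_disc(rng, center, 0.0, r_mz, dens["mantle-B"])
            planted_class = "dormant"
        else:
            gc_pts = _poisson_disc(rng, center, 0.0, r_gc, dens["GC-B"])
            gc_ids = emit(gc_pts, "GC-B")
            if level >= 1.0:
                mz_pts = np.empty((0, 2))
            else:
                theta0 = rng.uniform(0.0, 2 * math.pi)
                arc = (theta0, 2 * math.pi * (1.0 - level))
                mz_pts = _poisson_disc(rng, center, r_gc, r_mz, dens["mantle-B"], arc)
            planted_class = (
                "active" if level <= 0.25 else "decorticated" if level >= 0.75 else "partial"
            )
        mz_ids = emit(mz_pts, "mantle-B")
        frc_pts = _poisson_disc(rng, center, r_mz, r_frc, dens["FRC-boundary"])
        emit(frc_pts, "FRC-boundary")
        truth.follicles.append(
            {
                "roi_id": roi_id,
                "follicle_id": f"{roi_id}:f{i}",
                "center_um": tuple(center),
                "gc_radius_um": r_gc,
                "decortication_level": level if kind != "primary" else None,
                "kind": kind,
                "planted_class": planted_class,
                "gc_cell_ids": gc_ids.tolist(),
                "mz_cell_ids": mz_ids.tolist(),
            }
        )

    # paracortex compartments fill everywhere outside the GC cores, including
    # mantle annuli (T cells do percolate into follicle rims)
    for comp in ("paracortex-T", "mregDC-like", "Treg-like"):
        pts = _poisson_rect(rng, params.roi_size_um, dens[comp], centers, r_gc)
        emit(pts, comp)

    # suppressive myeloid cells: infiltration_rate of them go inside follicles
    w, h = params.roi_size_um
    n_supp = rng.poisson(dens["suppressive-myeloid"] * w * h / 1e6)
    n_in = rng.binomial(n_supp, params.infiltration_rate) if len(centers) else 0
    if n_in:
        which = rng.integers(0, len(centers), size=n_in)
        pts_in = np.concatenate(
            [
                _exact_disc(rng, centers[f], r_mz, int((which == f).sum()))
                for f in range(len(centers))
            ]
        )
        emit(pts_in, "suppressive-myeloid")
    n_out = n_supp - n_in
    if n_out:
        out = _exact_rect(rng, params.roi_size_um, n_out, centers, r_gc)
        emit(out, "suppressive-myeloid")

    xy = np.concatenate(xs) if xs else np.empty((0, 2))
    comp_arr = np.concatenate(comps) if comps else np.empty(0, dtype=object)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(xy) + 1),
            "roi_id": roi_id,
            "x_um": xy[:, 0] if len(xy) else np.empty(0),
            "y_um": xy[:, 1] if len(xy) else np.empty(0),
            "cluster": comp_arr,
            "compartment": comp_arr,
        }
    )
    truth.compartment_counts = cells["compartment"].value_counts().to_dict()
    return cells, truth


def _exact_disc(rng: np.random.Generator, center: np.ndarray, r: float, n: int) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    u = rng.uniform(size=n)
    radius = r * np.sqrt(u)
    theta = rng.uniform(0, 2 * math.pi, size=n)
    return center + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def _exact_rect(
    rng: np.random.Generator, size: tuple[float, float], n: int,
    exclude_centers: np.ndarray, exclude_radius: float,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    got = 0
    while got < n:
        batch = rng.uniform([0, 0], list(size), size=(max(2 * (n - got), 64), 2))
        if len(exclude_centers):
            d = np.min(
                np.linalg.norm(batch[:, None, :] - exclude_centers[None], axis=2), axis=1
            )
            batch = batch[d >= exclude_radius]
        take = batch[: n - got]
        pts.append(take)
        got += len(take)
    return np.concatenate(pts)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    arms: list[dict],
    params_by_arm: dict[str, TissueSimParams],
    seed: int,
    rois_per_ln: int = 1,
) -> tuple[pd.DataFrame, list[StudyDesign], GroundTruth]:
    """Simulate a multi-LN cohort with arm-specific tissue parameters.

    ``arms`` is a list of dicts with keys name, n_ln, station, stage_group;
    every LN of an arm shares that arm's :class:`TissueSimParams`.  Each LN
    gets its own patient.  Returns the pooled cell table (with an extra
    ``ln_id`` column), the per-LN design records, and the combined ground
    truth (planted effects record each arm's decortication and infiltration).
    """
    for arm in arms:
        if arm["n_ln"] < 2:
            raise ValueError(f"arm {arm['name']!r} needs >= 2 lymph nodes")
    rng = np.random.default_rng(seed)
    all_cells: list[pd.DataFrame] = []
    designs: list[StudyDesign] = []
    truth = GroundTruth()
    patient = 0
    for arm in arms:
        params = params_by_arm[arm["name"]]
        truth.planted_effects[arm["name"]] = {
            "decortication_level": params.decortication_level,
            "infiltration_rate": params.infiltration_rate,
            "n_ln": arm["n_ln"],
        }
        for i in range(arm["n_ln"]):
            patient += 1
            ln_id = f"{arm['name']}_LN{i + 1}"
            roi_ids = []
            for j in range(rois_per_ln):
                roi_id = f"{ln_id}_r{j + 1}"
                roi_seed = int(rng.integers(0, 2**31 - 1))
                cells, roi_truth = generate_tissue(params, roi_seed, roi_id)
                cells = cells.copy()
                cells["ln_id"] = ln_id
                all_cells.append(cells)
                truth.follicles.extend(roi_truth.follicles)
                roi_ids.append(roi_id)
            designs.append(
                StudyDesign(
                    ln_id=ln_id,
                    patient_id=f"P{patient}",
                    station=arm["station"],
                    stage_group=arm["stage_group"],
                    roi_ids=roi_ids,
                )
            )
    cells = pd.concat(all_cells, ignore_index=True)
    return cells, designs, truth


def higher_n1_preset(
    n_per_arm: int = 6,
    decortication_higher: float = 0.8,
    infiltration_higher: float = 0.35,
    base_params: TissueSimParams | None = None,
) -> tuple[list[dict], dict[str, TissueSimParams]]:
    """Two-arm study: hilar N1 nodes of higher-stage patients versus the rest.

    The higher-N1 arm carries elevated mantle decortication and suppressive
    myeloid infiltration; the control arm is intact tissue.
    """
    base = base_params or TissueSimParams()
    arms = [
        {"name": "higher_N1", "n_ln": n_per_arm, "station": "N1", "stage_group": "higher"},
        {"name": "rest", "n_ln": n_per_arm, "station": "N2", "stage_group": "lower"},
    ]
    params = {
        "higher_N1": replace(
            base,
            decortication_level=decortication_higher,
            infiltration_rate=infiltration_higher,
        ),
        "rest": replace(base, decortication_level=0.0, infiltration_rate=0.05),
    }
    return arms, params


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def default_panel(marker_names: list[str] | None = None) -> PanelTable:
    """Panel for rendered images: one marker channel per compartment plus two
    nuclear DNA channels and a segmentation-kit channel."""
    markers = marker_names if marker_names is not None else [f"M_{c}" for c in COMPARTMENTS]
    rows = [
        {"channel_name": m, "metal_tag": f"X{i:03d}", "role": "marker",
         "excluded_from_clustering": False}
        for i, m in enumerate(markers)
    ]
    rows += [
        {"channel_name": "DNA1", "metal_tag": "Ir191", "role": "nuclear",
         "excluded_from_clustering": True},
        {"channel_name": "DNA2", "metal_tag": "Ir193", "role": "nuclear",
         "excluded_from_clustering": True},
        {"channel_name": "SegKit", "metal_tag": "Pt196", "role": "segmentation",
         "excluded_from_clustering": True},
    ]
    return PanelTable(pd.DataFrame(rows))


def render_image(
    cells: pd.DataFrame,
    params: TissueSimParams,
    seed: int,
    marker_means: dict[str, dict[str, float]] | None = None,
) -> tuple[ChannelImage, np.ndarray, GroundTruth]:
    """Rasterize a cell map into a multichannel image and label mask.

    Each cell is drawn as a disc of ``cell_radius_um`` around its centroid;
    where discs overlap, each pixel belongs to the nearest centroid.  Channel
    intensity at a cell pixel is the cell label's channel mean plus Gaussian
    noise (sd ``marker_noise_sd``), floored at 0; background pixels are 0.
    ``n_hot_pixels`` extreme pixels are planted at recorded locations.
    By default each compartment lights its own marker channel (mean 10), every
    cell carries the DNA channels (mean 8) and the segmentation channel
    (mean 5).
    """
    rng = np.random.default_rng(seed)
    panel = default_panel()
    names = panel.channel_names
    labels = sorted(map(str, cells["cluster"].unique()))
    if marker_means is None:
        marker_means = {}
        for lab in labels:
            means = {n: 0.0 for n in names}
            means[f"M_{lab}"] = 10.0
            means["DNA1"] = 8.0
            means["DNA2"] = 8.0
            means["SegKit"] = 5.0
            marker_means[lab] = means
    for lab in labels:
        if lab not in marker_means:
            raise ValueError(f"no marker_means entry for label {lab!r}")

    w_um, h_um = params.roi_size_um
    H, W = int(round(h_um)), int(round(w_um))
    mask = np.zeros((H, W), dtype=np.int32)
    best = np.full((H, W), np.inf)
    r = params.cell_radius_um
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    for (x, y), cid in zip(xy, ids):
        c0, c1 = int(max(0, math.floor(x - r))), int(min(W - 1, math.ceil(x + r)))
        r0, r1 = int(max(0, math.floor(y - r))), int(min(H - 1, math.ceil(y + r)))
        if c1 < c0 or r1 < r0:
            continue
        cols, rows_ = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        d2 = (cols + 0.5 - x) ** 2 + (rows_ + 0.5 - y) ** 2
        inside = d2 <= r**2
        closer = inside & (d2 < best[r0 : r1 + 1, c0 : c1 + 1])
        mask[r0 : r1 + 1, c0 : c1 + 1][closer] = cid
        best[r0 : r1 + 1, c0 : c1 + 1][closer] = d2[closer]

    data = np.zeros((len(names), H, W))
    label_of = dict(zip(ids, cells["cluster"].astype(str)))
    cell_pixels = mask > 0
    flat_ids = mask[cell_pixels]
    for ci, name in enumerate(names):
        mean_by_label = {lab: marker_means[lab][name] for lab in labels}
        means = np.array([mean_by_label[label_of[cid]] for cid in flat_ids])
        if params.marker_noise_sd > 0:
            means = means + rng.normal(0.0, params.marker_noise_sd, size=len(means))
        ch = np.zeros((H, W))
        ch[cell_pixels] = np.clip(means, 0.0, None)
        data[ci] = ch

    truth = GroundTruth()
    if params.n_hot_pixels:
        locs = rng.choice(H * W, size=params.n_hot_pixels, replace=False)
        rows_h, cols_h = np.unravel_index(locs, (H, W))
        for k, (rr, cc) in enumerate(zip(rows_h, cols_h)):
            data[:, rr, cc] = 1e4 * (k + 1)
        truth.hot_pixels["roi"] = list(zip(rows_h.tolist(), cols_h.tolist()))

    roi_id = str(cells["roi_id"].iloc[0]) if len(cells) else "roi"
    image = ChannelImage(data, names, roi_id=roi_id, resolution_um=1.0)
    return image, mask, truth
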