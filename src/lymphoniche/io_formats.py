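"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions
-----------
* Multichannel ROI images are multi-page TIFFs, one page per channel, paired
  with a *panel* CSV naming each channel and its role (marker / nuclear /
  segmentation).  Channel identity is by name once the panel is attached,
  never by page order.
* Segmentation masks are single-page integer TIFFs (0 = background).
* Cell tables travel as CSV or Parquet with a fixed schema: ``cell_id``,
  ``roi_id``, ``x_um``, ``y_um``, one column per marker, and optional
  ``cluster`` / ``niche`` columns.
* The study design is a CSV with one row per (lymph node, ROI).

Coordinates are 0-based pixel indices; centroids are in micrometres with
x = column and y = row.  At the acquisition resolution of 1 um/pixel the two
coincide numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelImage",
    "PanelTable",
    "StudyDesign",
    "FormatError",
    "SchemaError",
    "IntegrityError",
    "ROLES",
    "STATIONS",
    "STAGE_GROUPS",
    "CELL_TABLE_BASE_COLUMNS",
    "read_panel",
    "write_panel",
    "read_roi_stack",
    "write_roi_stack",
    "read_mask",
    "write_mask",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "marker_columns",
    "read_design",
    "write_design",
    "design_frame",
]

ROLES = ("marker", "nuclear", "segmentation")
STATIONS = ("N1", "N2")
STAGE_GROUPS = ("lower", "higher")
CELL_TABLE_BASE_COLUMNS = ("cell_id", "roi_id", "x_um", "y_um")
OPTIONAL_CELL_COLUMNS = ("cluster", "niche")


class FormatError(ValueError):
    """A file's physical layout does not match what the format requires."""


class SchemaError(ValueError):
    """A table is missing a required column or holds an out-of-vocabulary value."""


class IntegrityError(ValueError):
    """A table violates a cross-row invariant (duplicates, conflicting mappings)."""


@dataclass
class ChannelImage:
    """One ROI's pixel data: ``data`` is channels x height x width."""

    data: np.ndarray
    channel_names: list[str]
    roi_id: str = ""
    resolution_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"ChannelImage data must be 3-D (C,H,W), got shape {self.data.shape}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{self.data.shape[0]} image channels but {len(self.channel_names)} names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in image") from None
        return self.data[idx]

    def copy(self) -> "ChannelImage":
        return ChannelImage(
            self.data.copy(), list(self.channel_names), self.roi_id, self.resolution_um
        )


@dataclass
class PanelTable:
    """Channel metadata: name, metal tag, role, and clustering-exclusion flag.

    The nuclear DNA intercalator channels (Ir191/Ir193) and the membrane
    segmentation-kit channel (Pt196) carry role ``nuclear`` / ``segmentation``
    so the preprocessing stage can skip them during background-median
    subtraction.  ``excluded_from_clustering`` flags channels measured but not
    used for phenotyping (high-background markers such as EpCAM or LAG3).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel_name", "metal_tag", "role", "excluded_from_clustering"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"panel missing columns: {sorted(missing)}")
        names = self.table["channel_name"]
        if names.duplicated().any():
            dup = names[names.duplicated()].iloc[0]
            raise IntegrityError(f"duplicate channel_name {dup!r} in panel")
        bad = set(self.table["role"]) - set(ROLES)
        if bad:
            raise SchemaError(f"unknown panel role(s): {sorted(bad)}")
        if not (self.table["role"] == "marker").any():
            raise SchemaError("panel must contain at least one marker channel")

    @property
    def channel_names(self) -> list[str]:
        return list(self.table["channel_name"])

    def names_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "channel_name"])

    @property
    def marker_names(self) -> list[str]:
        return self.names_with_role("marker")

    @property
    def background_subtracted_names(self) -> list[str]:
        """Channels eligible for global-median background subtraction.

        Everything except the nuclear and segmentation channels.
        """
        keep = self.table["role"] == "marker"
        return list(self.table.loc[keep, "channel_name"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class StudyDesign:
    """One lymph node: its patient, nodal station, stage group, and ROIs.

    ``station`` is N1 (hilar/interlobar) or N2 (mediastinal); ``stage_group``
    dichotomizes patients at pathological stage IB (lower = IA, higher >= IB).
    """

    ln_id: str
    patient_id: str
    station: str
    stage_group: str
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.station not in STATIONS:
            raise SchemaError(f"unknown station {self.station!r}; expected one of {STATIONS}")
        if self.stage_group not in STAGE_GROUPS:
            raise SchemaError(
                f"unknown stage_group {self.stage_group!r}; expected one of {STAGE_GROUPS}"
            )
        if not self.roi_ids:
            raise IntegrityError(f"lymph node {self.ln_id} has no ROIs")


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> PanelTable:
    df = pd.read_csv(path)
    if "excluded_from_clustering" in df.columns:
        df["excluded_from_clustering"] = df["excluded_from_clustering"].astype(bool)
    return PanelTable(df)


def write_panel(panel: PanelTable, path: str | Path) -> None:
    panel.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI stacks and masks
# ---------------------------------------------------------------------------

def read_roi_stack(
    path: str | Path, panel: PanelTable, roi_id: str = "", resolution_um: float = 1.0
) -> ChannelImage:
    """Load a multichannel TIFF and attach channel names from the panel.

    The page count must equal the panel row count; pages are matched to panel
    rows in order, after which identity is by name.
    """
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a 2-D or 3-D TIFF, got {arr.ndim}-D from {path}")
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"non-numeric pixel data ({arr.dtype}) in {path}")
    if arr.shape[0] != len(panel):
        raise FormatError(
            f"channel-count mismatch: TIFF has {arr.shape[0]} pages, panel has "
            f"{len(panel)} rows"
        )
    if not roi_id:
        roi_id = Path(path).stem
    return ChannelImage(arr.astype(float), panel.channel_names, roi_id, resolution_um)


def write_roi_stack(image: ChannelImage, path: str | Path) -> None:
    tifffile.imwrite(
        path, np.asarray(image.data, dtype=np.float32), photometric="minisblack"
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-page integer label mask (0 = background)."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise FormatError(f"label mask must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("label mask contains non-integer values")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise FormatError("label mask contains negative labels")
    return arr.astype(np.int64)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_TABLE_BASE_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s): {missing}")
    dup = cells.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        row = cells.loc[dup.idxmax()]
        raise IntegrityError(
            f"duplicate (roi_id, cell_id) = ({row['roi_id']!r}, {row['cell_id']!r})"
        )
    return cells


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Columns that hold per-channel mean intensities."""
    reserved = set(CELL_TABLE_BASE_COLUMNS) | set(OPTIONAL_CELL_COLUMNS) | {
        "area_px", "compartment", "ln_id",
    }
    return [c for c in cells.columns if c not in reserved]


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        cells = pd.read_parquet(path)
    else:
        cells = pd.read_csv(path)
    return validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(cells)
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        cells.to_parquet(path, index=False)
    else:
        cells.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[StudyDesign]:
    """Read the per-ROI design CSV and group it into per-LN records.

    Validates that each ROI belongs to exactly one lymph node and that station
    and stage-group values come from the closed vocabularies.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"ln_id", "patient_id", "station", "stage_group", "roi_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"design missing columns: {sorted(missing)}")
    roi_to_ln = df.groupby("roi_id")["ln_id"].nunique()
    conflicted = roi_to_ln[roi_to_ln > 1]
    if len(conflicted):
        raise IntegrityError(
            f"roi_id {conflicted.index[0]!r} is mapped to more than one lymph node"
        )
    designs: list[StudyDesign] = []
    for ln_id, grp in df.groupby("ln_id", sort=True):
        for col in ("patient_id", "station", "stage_group"):
            if grp[col].isna().any():
                raise SchemaError(f"missing {col} for lymph node {ln_id}")
            if grp[col].nunique() > 1:
                raise IntegrityError(f"conflicting {col} values for lymph node {ln_id}")
        designs.append(
            StudyDesign(
                ln_id=str(ln_id),
                patient_id=str(grp["patient_id"].iloc[0]),
                station=str(grp["station"].iloc[0]),
                stage_group=str(grp["stage_group"].iloc[0]),
                roi_ids=sorted(grp["roi_id"].astype(str)),
            )
        )
    return designs


def design_frame(designs: Sequence[StudyDesign]) -> pd.DataFrame:
    """Flatten per-LN records back to one row per ROI."""
    rows = [
        {
            "ln_id": d.ln_id,
            "patient_id": d.patient_id,
            "station": d.station,
            "stage_group": d.stage_group,
            "roi_id": roi,
        }
        for d in designs
        for roi in d.roi_ids
    ]
    return pd.DataFrame(rows)


def write_design(designs: Sequence[StudyDesign], path: str | Path) -> None:
    design_frame(designs).to_csv(path, index=False)
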