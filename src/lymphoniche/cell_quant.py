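"""Per-cell quantification: mean marker intensity and centroid per mask label.

Protein expression per cell is the arithmetic mean of the pixel intensities
inside the cell's segmentation label, for every channel.  The centroid is the
unweighted mean of the member pixel coordinates, reported in micrometres
(x = column, y = row).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import ChannelImage

__all__ = ["summarize_cells"]


def summarize_cells(image: ChannelImage, mask: np.ndarray, roi_id: str | None = None) -> pd.DataFrame:
    """Summarize a label mask over a preprocessed image into cell-table rows.

    Parameters
    ----------
    image : ChannelImage
        Preprocessed ROI stack.
    mask : ndarray of int, shape (H, W)
        Segmentation labels; 0 is background.  Labels need not be contiguous.
    roi_id : str, optional
        Overrides ``image.roi_id`` in the output.

    Returns
    -------
    DataFrame with one row per positive label, sorted by label, holding
    ``cell_id``, ``roi_id``, ``x_um``, ``y_um``, ``area_px`` and one column
    per channel.  An all-background mask yields an empty table.
    """
    mask = np.asarray(mask)
    if mask.shape != image.data.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.data.shape[1:]}"
        )
    roi = roi_id if roi_id is not None else image.roi_id
    labels = np.unique(mask)
    labels = labels[labels > 0]
    cols = {
        "cell_id": labels.astype(int),
        "roi_id": roi,
    }
    if labels.size == 0:
        empty = {**cols, "x_um": [], "y_um": [], "area_px": []}
        empty.update({name: [] for name in image.channel_names})
        return pd.DataFrame(empty)

    res = image.resolution_um
    centroids = ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    centroids = np.asarray(centroids)  # (n, 2) as (row, col)
    cols["x_um"] = centroids[:, 1] * res
    cols["y_um"] = centroids[:, 0] * res
    cols["area_px"] = ndimage.sum_labels(np.ones_like(mask, dtype=float), mask, labels).astype(int)
    for i, name in enumerate(image.channel_names):
        cols[name] = ndimage.mean(image.data[i], mask, labels)
    return pd.DataFrame(cols)
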